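import numpy as np
import pandas as pd
import pytest

from camtrapmeta.io import write_comparisons, write_studies
from camtrapmeta.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """A full-size synthetic evidence base (104 studies) with ground truth."""
    return simulate_dataset(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic evidence base for fast pipeline tests."""
    return simulate_dataset(SimulationConfig(n_studies=40), seed=3)


@pytest.fixture()
def small_csvs(tmp_path, small_dataset):
    studies, comparisons, _ = small_dataset
    spath = tmp_path / "studies.csv"
    cpath = tmp_path / "comparisons.csv"
    write_studies(studies, spath)
    write_comparisons(comparisons, cpath)
    return spath, cpath


@pytest.fixture()
def effect_frame_factory():
    """Build an effect-size frame with explicit per-study values."""

    def make(study_values: dict[str, list[float]], **extra_cols) -> pd.DataFrame:
        rows = []
        for sid, values in study_values.items():
            for v in values:
                rows.append({"study_id": sid, "effect_size": float(v), **extra_cols})
        return pd.DataFrame(rows)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
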