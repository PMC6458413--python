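"""Covariate standardization and study-level design construction.

Continuous covariates are centred at their mean and divided by twice their
standard deviation (Gelman's 2-SD rule), which puts them on a scale
comparable with untransformed 0/1 indicators; a standardized column then
has mean 0 and SD 0.5.  The minimum focal-species body weight is
log-transformed before standardization because of its strong positive skew.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import StudyRecord
from .vocab import RECOMMENDATION_LEVELS

#: Candidate study-level terms and the design column each owns.
STUDY_TERMS: dict[str, str] = {
    "camera_type": "film",
    "attractant": "attractant_used",
    "habitat": "habitat_open",
    "latitude": "latitude_std",
    "min_weight": "log_min_weight_std",
}


class TwoSDScaler(BaseEstimator, TransformerMixin):
    """Centre selected columns at their mean and scale by twice their SD.

    Parameters
    ----------
    columns : list of str or None
        Columns to standardize; None means all columns.
    ddof : int, default 0
        Delta degrees of freedom for the SD (population SD by default, so
        a two-point column {10, 30} maps to {-0.5, +0.5}).
    """

    def __init__(self, columns: list[str] | None = None, ddof: int = 0):
        self.columns = columns
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(X.columns) if self.columns is None else list(self.columns)
        self.columns_ = cols
        self.mean_ = {}
        self.scale_ = {}
        for c in cols:
            x = np.asarray(X[c], dtype=float)
            if np.unique(x).size < 2:
                raise ValueError(
                    f"column {c!r} has zero variance; cannot standardize")
            self.mean_[c] = float(x.mean())
            self.scale_[c] = 2.0 * float(x.std(ddof=self.ddof))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in self.columns_:
            out[c] = (np.asarray(X[c], dtype=float) - self.mean_[c]) / self.scale_[c]
        return out


@dataclass
class StandardizedDesign:
    """Study-level fixed-effect design with the ordinal response.

    ``frame`` columns: film, attractant_used, habitat_open (0/1 indicators
    with digital / not-used / closed as reference levels), latitude_std and
    log_min_weight_std (2-SD standardized).  ``response`` holds ordinal
    level indices 0..2 in the order other_method < ambiguous < camera_trap.
    """

    frame: pd.DataFrame
    response: np.ndarray
    scaler: TwoSDScaler
    study_ids: list[str]


def standardize(studies: Iterable[StudyRecord]) -> StandardizedDesign:
    """Build the standardized study-level design from validated records."""
    studies = list(studies)
    raw = pd.DataFrame(
        {
            "film": [1.0 if s.camera_type == "film" else 0.0 for s in studies],
            "attractant_used": [1.0 if s.attractant == "used" else 0.0
                                for s in studies],
            "habitat_open": [1.0 if s.habitat == "open" else 0.0 for s in studies],
            "latitude_std": [s.abs_latitude for s in studies],
            "log_min_weight_std": [np.log(s.min_weight_g) for s in studies],
        }
    )
    scaler = TwoSDScaler(columns=["latitude_std", "log_min_weight_std"])
    frame = scaler.fit_transform(raw)
    response = np.array(
        [RECOMMENDATION_LEVELS.index(s.recommendation) for s in studies],
        dtype=int)
    return StandardizedDesign(
        frame=frame, response=response, scaler=scaler,
        study_ids=[s.study_id for s in studies])


__all__ = ["TwoSDScaler", "StandardizedDesign", "standardize", "STUDY_TERMS"]
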