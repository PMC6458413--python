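"""Stratified bootstrap: stratification, determinism, CIs, Wald tests."""

import numpy as np
import pandas as pd
import pytest

from camtrapmeta.bootstrap import (
    BootstrapResult,
    pairwise_wald,
    replicate_medians,
    stratified_bootstrap,
    subgroup_bootstrap,
    wald_test,
)


def _group_frame(values_by_study, group="g"):
    rows = [
        {"study_id": sid, "effect_size": float(v), "grp": group}
        for sid, vals in values_by_study.items()
        for v in vals
    ]
    return pd.DataFrame(rows)


class TestStratifiedBootstrap:
    def test_degenerate_constant_group(self):
        frame = _group_frame({f"s{i}": [0.5] for i in range(20)})
        (res,) = stratified_bootstrap(frame, "grp", n_boot=200, seed=1)
        assert res.point_estimate == 0.5
        assert res.ci_low == res.ci_high == 0.5
        assert res.significant

    def test_symmetric_effects_centre_on_zero(self, rng):
        # one +x and one -x study per magnitude: the group median is 0
        mags = rng.uniform(0.2, 1.0, size=30)
        frame = _group_frame(
            {f"p{i}": [m] for i, m in enumerate(mags)}
            | {f"n{i}": [-m] for i, m in enumerate(mags)})
        (res,) = stratified_bootstrap(frame, "grp", n_boot=2000, seed=7)
        assert abs(res.point_estimate) < 0.05
        assert not res.significant

    def test_threshold_is_strict(self):
        frame = pd.concat([
            _group_frame({f"a{i}": [0.1 * i] for i in range(15)}, group="at"),
            _group_frame({f"b{i}": [0.1 * i] for i in range(16)}, group="above"),
        ])
        frame["grp"] = [ "at" ] * 15 + ["above"] * 16
        results = {r.group: r for r in
                   stratified_bootstrap(frame, "grp", n_boot=100,
                                        min_comparisons=15, seed=1)}
        assert results["at"].skipped
        assert not results["above"].skipped
        assert results["at"].n_comparisons == 15

    def test_seed_determinism_is_bit_exact(self, effect_frame_factory, rng):
        frame = effect_frame_factory(
            {f"s{i}": rng.normal(0.3, 0.5, rng.integers(1, 5)) for i in range(25)},
            grp="g")
        a = stratified_bootstrap(frame, "grp", n_boot=500, seed=42)
        b = stratified_bootstrap(frame, "grp", n_boot=500, seed=42)
        assert np.array_equal(a[0].replicates, b[0].replicates)
        assert a[0].point_estimate == b[0].point_estimate

    def test_adding_a_group_does_not_perturb_others(self, effect_frame_factory, rng):
        base = effect_frame_factory(
            {f"s{i}": rng.normal(0.3, 0.5, 2) for i in range(20)}, grp="g1")
        extra = effect_frame_factory(
            {f"t{i}": rng.normal(-0.1, 0.5, 2) for i in range(20)}, grp="g0")
        alone = stratified_bootstrap(base, "grp", n_boot=300, seed=5)
        both = stratified_bootstrap(pd.concat([extra, base]), "grp",
                                    n_boot=300, seed=5)
        g1 = {r.group: r for r in both}["g1"]
        assert np.array_equal(alone[0].replicates, g1.replicates)

    def test_shift_equivariance(self, effect_frame_factory, rng):
        frame = effect_frame_factory(
            {f"s{i}": rng.normal(0.0, 0.5, rng.integers(1, 4)) for i in range(30)},
            grp="g")
        shifted = frame.assign(effect_size=frame["effect_size"] + 0.7)
        (a,) = stratified_bootstrap(frame, "grp", n_boot=400, seed=9)
        (b,) = stratified_bootstrap(shifted, "grp", n_boot=400, seed=9)
        assert b.point_estimate == pytest.approx(a.point_estimate + 0.7, abs=1e-9)
        assert b.ci_low == pytest.approx(a.ci_low + 0.7, abs=1e-9)
        assert b.ci_high == pytest.approx(a.ci_high + 0.7, abs=1e-9)

    def test_equal_study_influence_under_comparison_inflation(self):
        """A study contributing 100 identical comparisons and a study
        contributing 1 have the same per-replicate influence: inflating a
        study's comparison count leaves the replicate draw unchanged."""
        values = {f"s{i}": [0.1 * i] for i in range(20)}
        plain = _group_frame(values)
        inflated = _group_frame({**values, "s0": [0.0] * 100})
        a = stratified_bootstrap(plain, "grp", n_boot=500, seed=3)
        b = stratified_bootstrap(inflated, "grp", n_boot=500, seed=3)
        assert np.array_equal(a[0].replicates, b[0].replicates)

    def test_empty_effects_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="empty"):
            out = stratified_bootstrap(
                pd.DataFrame(columns=["study_id", "effect_size", "grp"]), "grp")
        assert out == []

    def test_fixed_studies_scheme_keeps_study_set(self):
        # with one value per study and no resampling of studies, every
        # replicate median equals the sample median
        frame = _group_frame({f"s{i}": [float(i)] for i in range(17)})
        (res,) = stratified_bootstrap(frame, "grp", n_boot=100, seed=1,
                                      scheme="fixed_studies")
        assert res.ci_low == res.ci_high == res.point_estimate == 8.0
        with pytest.raises(ValueError, match="scheme"):
            replicate_medians(np.ones(3), np.arange(3), 10,
                              np.random.default_rng(0), scheme="bogus")


class TestSubgroupBootstrap:
    def test_two_level_factor_gives_two_results(self, effect_frame_factory, rng):
        a = effect_frame_factory(
            {f"s{i}": rng.normal(0.2, 0.3, 2) for i in range(20)},
            camera_type="digital")
        b = effect_frame_factory(
            {f"t{i}": rng.normal(-0.3, 0.3, 2) for i in range(20)},
            camera_type="film")
        results = subgroup_bootstrap(pd.concat([a, b]), "camera_type",
                                     n_boot=300, seed=2)
        assert sorted(r.group for r in results) == ["digital", "film"]
        assert not any(r.skipped for r in results)

    def test_sparse_level_reported_as_skipped(self, effect_frame_factory, rng):
        a = effect_frame_factory(
            {f"s{i}": [0.1] for i in range(20)}, habitat="closed")
        b = effect_frame_factory({"t0": [0.5]}, habitat="open")
        results = {r.group: r for r in
                   subgroup_bootstrap(pd.concat([a, b]), "habitat",
                                      n_boot=100, seed=2)}
        assert not results["closed"].skipped
        assert results["open"].skipped

    def test_missing_factor_column_raises(self, effect_frame_factory):
        frame = effect_frame_factory({"s1": [0.1]})
        with pytest.raises(KeyError, match="nope"):
            subgroup_bootstrap(frame, "nope")

    def test_true_subgroup_difference_is_detected_with_high_power(self):
        """With a 0.5 log-unit level difference across 60 studies the
        pairwise Wald test rejects at alpha=0.05 in >80% of repetitions."""
        master = np.random.default_rng(2026)
        reps, rejected = 500, 0
        for _ in range(reps):
            rows = []
            for lev, mu in (("a", 0.0), ("b", 0.5)):
                for s in range(30):
                    b = master.normal(0, 0.3)
                    for _ in range(int(master.integers(1, 4))):
                        rows.append({"study_id": f"{lev}{s}", "lev": lev,
                                     "effect_size": mu + b + master.normal(0, 0.4)})
            res = stratified_bootstrap(pd.DataFrame(rows), "lev", n_boot=500,
                                       seed=int(master.integers(2**31)))
            rejected += wald_test(res[0], res[1]).p < 0.05
        assert rejected / reps > 0.8


class TestWald:
    def _res(self, est, se, group="g"):
        return BootstrapResult(group=group, n_comparisons=20, n_studies=20,
                               point_estimate=est, se=se, n_boot=100)

    def test_identical_results_give_z_zero_p_one(self):
        w = wald_test(self._res(0.30, 0.1, "a"), self._res(0.30, 0.2, "b"))
        assert w.z == 0.0 and w.p == 1.0

    def test_small_z_gives_p_near_one(self):
        # z = 0.05 corresponds to p = 0.96
        w = wald_test(self._res(0.005, 0.1 / np.sqrt(2), "a"),
                      self._res(0.0, 0.1 / np.sqrt(2), "b"))
        assert w.z == pytest.approx(0.05, abs=1e-12)
        assert w.p == pytest.approx(0.9601, abs=1e-4)

    def test_zero_pooled_se_raises(self):
        with pytest.raises(ValueError, match="SE"):
            wald_test(self._res(0.1, 0.0, "a"), self._res(0.2, 0.0, "b"))

    def test_pairwise_skips_skipped_groups(self):
        results = [self._res(0.1, 0.1, "a"), self._res(0.2, 0.1, "b"),
                   BootstrapResult(group="c", n_comparisons=3, n_studies=3,
                                   skipped=True)]
        pairs = pairwise_wald(results)
        assert [(w.group_a, w.group_b) for w in pairs] == [("a", "b")]
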