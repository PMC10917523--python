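import numpy as np
import pytest
from scipy import stats as sps

from magicquant.kinetics import (
    AlignmentError,
    ChaseCurve,
    NormalizationError,
    build_curve,
    compare_timepoints,
    curves_from_table,
    fit_decay,
)
from magicquant.synth import ChaseSpec, generate_chase


class TestBuildCurve:
    def test_background_subtraction_and_normalization(self):
        c = build_curve([0.0, 10.0, 20.0], [110.0, 60.0, 35.0], background=10.0)
        np.testing.assert_allclose(c.relative, [1.0, 0.5, 0.25])

    def test_constant_raw_zero_background(self):
        c = build_curve([0.0, 10.0, 20.0], [80.0, 80.0, 80.0], background=0.0)
        np.testing.assert_allclose(c.relative, [1.0, 1.0, 1.0])

    def test_t0_not_above_background_raises(self):
        with pytest.raises(NormalizationError):
            build_curve([0.0, 10.0], [10.0, 5.0], background=10.0)

    def test_negative_subtracted_values_clipped(self, caplog):
        c = build_curve([0.0, 10.0], [110.0, 5.0], background=10.0)
        assert c.relative[1] == 0.0

    def test_rescaling_raw_and_background_invariant(self):
        t = [0.0, 10.0, 20.0]
        raw = np.array([110.0, 60.0, 35.0])
        a = build_curve(t, raw, 10.0)
        b = build_curve(t, 3.5 * raw, 35.0)
        np.testing.assert_allclose(a.relative, b.relative, rtol=1e-12)

    def test_t0_always_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = np.sort(rng.uniform(20, 200, 5))[::-1]
            c = build_curve(np.arange(5.0), raw, background=rng.uniform(0, 10))
            assert c.relative[0] == 1.0


class TestFitDecay:
    def test_exact_geometric_series(self):
        c = build_curve([0.0, 20.0, 40.0], [1.0, 0.5, 0.25], background=0.0)
        fit = fit_decay(c)
        assert fit.rate_per_min == pytest.approx(np.log(2) / 20.0, rel=1e-12)
        assert fit.half_life_min == pytest.approx(20.0, rel=1e-12)

    def test_constant_curve_zero_rate(self):
        c = build_curve([0.0, 10.0, 20.0], [5.0, 5.0, 5.0], background=0.0)
        fit = fit_decay(c)
        assert fit.rate_per_min == 0.0
        assert np.isinf(fit.half_life_min)

    def test_too_few_points_raises(self):
        c = build_curve([0.0, 10.0], [10.0, 5.0], background=0.0)
        with pytest.raises(ValueError):
            fit_decay(c)

    def test_noiseless_chase_recovers_rate_exactly(self):
        k = 0.045
        spec = ChaseSpec(n_cells=10, decay_rate_per_min=k, cell_cv=0.0, seed=0)
        (curve,) = curves_from_table(generate_chase(spec))
        fit = fit_decay(curve)
        assert fit.rate_per_min == pytest.approx(k, rel=1e-9)

    def test_noisy_chase_recovers_rate(self):
        k = 0.05
        spec = ChaseSpec(n_cells=2000, decay_rate_per_min=k, cell_cv=0.15, seed=1)
        (curve,) = curves_from_table(generate_chase(spec))
        fit = fit_decay(curve)
        assert fit.rate_per_min == pytest.approx(k, rel=0.10)


class TestCompareTimepoints:
    @staticmethod
    def _curve(group, rep, rels, t=(0.0, 10.0)):
        return ChaseCurve(
            timepoints_min=np.asarray(t),
            raw_means=np.asarray(rels),
            background=0.0,
            relative=np.asarray(rels),
            replicate=str(rep),
            group=group,
        )

    def test_identical_groups_p_one(self):
        curves = [
            self._curve("a", 1, [1.0, 0.7]),
            self._curve("a", 2, [1.0, 0.5]),
            self._curve("b", 1, [1.0, 0.7]),
            self._curve("b", 2, [1.0, 0.5]),
        ]
        res = compare_timepoints(curves)
        assert np.allclose(res["pvalue"], 1.0)

    def test_statistic_matches_hand_formula(self):
        curves = [
            self._curve("a", 1, [1.0, 0.9]),
            self._curve("a", 2, [1.0, 0.7]),
            self._curve("b", 1, [1.0, 0.5]),
            self._curve("b", 2, [1.0, 0.3]),
        ]
        res = compare_timepoints(curves, test="welch")
        a, b = np.array([0.9, 0.7]), np.array([0.5, 0.3])
        se = np.sqrt(a.var(ddof=1) / 2 + b.var(ddof=1) / 2)
        t_hand = (a.mean() - b.mean()) / se
        row = res[res["time_min"] == 10.0].iloc[0]
        assert row["statistic"] == pytest.approx(t_hand, rel=1e-12)

    def test_designed_effect_significant_late_not_at_t0(self):
        curves = []
        for group, k in (("slow", 0.02), ("fast", 0.06)):
            for rep in range(1, 5):
                spec = ChaseSpec(
                    n_cells=1500,
                    decay_rate_per_min=k,
                    cell_cv=0.15,
                    seed=100 * rep + (0 if group == "slow" else 7),
                )
                table = generate_chase(spec)
                table["group"] = group
                table["replicate"] = str(rep)
                curves.extend(curves_from_table(table))
        res = compare_timepoints(curves).set_index("time_min")
        assert res.loc[0.0, "pvalue"] == pytest.approx(1.0)  # both exactly 1 at t0
        assert res.loc[40.0, "pvalue"] < 0.05
        assert res.loc[30.0, "pvalue"] < 0.05

    def test_mismatched_grids_rejected(self):
        curves = [
            self._curve("a", 1, [1.0, 0.5]),
            self._curve("a", 2, [1.0, 0.5]),
            self._curve("b", 1, [1.0, 0.5], t=(0.0, 20.0)),
            self._curve("b", 2, [1.0, 0.5], t=(0.0, 20.0)),
        ]
        with pytest.raises(AlignmentError):
            compare_timepoints(curves)


class TestCurvesFromTable:
    def test_groups_and_background_rows(self):
        spec = ChaseSpec(n_cells=50, decay_rate_per_min=0.03, cell_cv=0.1, seed=3)
        t1 = generate_chase(spec)
        t1["group"] = "wt"
        t1["replicate"] = "1"
        spec2 = ChaseSpec(n_cells=50, decay_rate_per_min=0.03, cell_cv=0.1, seed=4)
        t2 = generate_chase(spec2)
        t2["group"] = "wt"
        t2["replicate"] = "2"
        import pandas as pd

        curves = curves_from_table(pd.concat([t1, t2]))
        assert len(curves) == 2
        for c in curves:
            assert c.relative[0] == 1.0
            assert c.background == pytest.approx(spec.background_mean)
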