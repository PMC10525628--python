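"""Bland–Altman, MAE/RMSE, ICC(2,1) and the bootstrap ICC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctrval.agreement import (
    LOA_Z,
    PairedSeries,
    bland_altman,
    compare_icc_bootstrap,
    expert_session_means,
    icc,
    intra_observer_matrix,
    mae_rmse,
    model_vs_experts_pairs,
    model_vs_experts_stacked_matrix,
    pivot_ctr,
)
from ctrval.errors import (
    CaseMismatchError,
    IncompleteMeasurementsError,
    InsufficientPairsError,
    RelativeUndefinedError,
)


def series(x, y, scale="absolute"):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return PairedSeries(case_id=list(range(len(x))), x=x, y=y, scale=scale)


class TestBlandAltman:
    def test_two_pair_example(self):
        # diffs {0.00, 0.02}: mean 0.01, sd 0.0141, LOAs mean +- 1.96 sd
        with pytest.warns(UserWarning, match="n < 3"):
            res = bland_altman(series([0.5, 0.5], [0.5, 0.52]))
        assert res.mean_diff == pytest.approx(0.01)
        assert res.sd_diff == pytest.approx(0.0141421356, abs=1e-9)
        assert res.loa_lower == pytest.approx(-0.0177185858, abs=1e-9)
        assert res.loa_upper == pytest.approx(0.0377185858, abs=1e-9)

    def test_constant_difference_collapses_loas(self):
        res = bland_altman(series([0.4, 0.5, 0.6], [0.41, 0.51, 0.61]))
        assert res.mean_diff == pytest.approx(0.01)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert res.loa_lower == pytest.approx(0.01)
        assert res.loa_upper == pytest.approx(0.01)

    def test_identity_gives_zeros(self):
        x = np.linspace(0.4, 0.7, 10)
        res = bland_altman(series(x, x))
        assert res.mean_diff == res.sd_diff == 0
        assert res.loa_lower == res.loa_upper == 0

    def test_parametric_ci_contains_loa(self, rng):
        d = rng.normal(0.01, 0.03, 60)
        res = bland_altman(series(np.zeros(60), d))
        assert res.loa_lower_ci[0] <= res.loa_lower <= res.loa_lower_ci[1]
        assert res.loa_upper_ci[0] <= res.loa_upper <= res.loa_upper_ci[1]
        assert res.loa_lower <= res.mean_diff <= res.loa_upper

    def test_bootstrap_ci_contains_loa_and_is_seeded(self, rng):
        d = rng.normal(0.0, 0.02, 80)
        s = series(np.zeros(80), d)
        r1 = bland_altman(s, ci_method="bootstrap", seed=11)
        r2 = bland_altman(s, ci_method="bootstrap", seed=11)
        assert r1 == r2
        assert r1.loa_lower_ci[0] <= r1.loa_lower <= r1.loa_lower_ci[1]

    def test_relative_scale_uses_pair_mean_percent(self):
        res = bland_altman(series([1.0, 1.0, 1.0], [1.1, 1.1, 1.1], "relative"))
        # 100 * 0.1 / 1.05
        assert res.mean_diff == pytest.approx(100 * 0.1 / 1.05)

    def test_relative_scale_rejects_nonpositive_pair_mean(self):
        with pytest.raises(RelativeUndefinedError, match="relative-undefined"):
            bland_altman(series([0.1, -0.2, 0.3], [0.1, 0.1, 0.3], "relative"))

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientPairsError):
            bland_altman(series([0.5], [0.6]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 0.1, 12)
        y = x + rng.normal(0, 0.05, 12)
        a = bland_altman(series(x, y))
        b = bland_altman(series(y, x))
        assert b.mean_diff == pytest.approx(-a.mean_diff)
        assert b.loa_lower == pytest.approx(-a.loa_upper)
        assert b.loa_upper == pytest.approx(-a.loa_lower)


class TestMaeRmse:
    def test_hand_example(self):
        mae, rmse = mae_rmse(series([0.0, 0.0], [0.01, -0.03]))
        assert mae == pytest.approx(0.02)
        assert rmse == pytest.approx(0.0223606797, abs=1e-9)

    def test_identity_and_single_pair(self):
        assert mae_rmse(series([0.5, 0.6], [0.5, 0.6])) == (0.0, 0.0)
        mae, rmse = mae_rmse(series([0.5], [0.55]))
        assert mae == rmse == pytest.approx(0.05)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_rmse_dominates_mae(self, diffs):
        d = np.asarray(diffs)
        mae, rmse = mae_rmse(series(np.zeros(len(d)), d))
        assert rmse >= mae - 1e-12
        if len(set(np.round(np.abs(d), 12))) == 1:
            assert rmse == pytest.approx(mae)


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        col = rng.normal(0.5, 0.1, 30)
        res = icc(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(126)
        case = rng.normal(0, 2, 500)  # true ICC = 4 / (4 + 1) = 0.8
        m = case[:, None] + rng.normal(0, 1, (500, 2))
        res = icc(m)
        assert res.ci[0] <= 0.8 <= res.ci[1]
        assert res.estimate == pytest.approx(0.8, abs=0.05)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(127)
        res = icc(rng.normal(0, 1, (1000, 2)))
        assert res.ci[0] <= 0.0 <= res.ci[1]

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        m = rng.normal(0, 2, 40)[:, None] + rng.normal(0, 1, (40, 3)) + [0.0, 0.3, -0.2]
        mine = icc(m)
        df = (
            pd.DataFrame(m, columns=list("abc"))
            .reset_index()
            .melt(id_vars="index", var_name="rater", value_name="score")
        )
        ref = pg.intraclass_corr(
            data=df, targets="index", raters="rater", ratings="score"
        ).set_index("Type")
        assert mine.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert mine.ci[0] == pytest.approx(lo, abs=5e-3)
        assert mine.ci[1] == pytest.approx(hi, abs=5e-3)

    def test_constant_matrix_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="constant"):
            res = icc(np.full((10, 2), 0.5))
        assert res.estimate == 1.0

    def test_shift_invariance_and_bias_penalty(self, rng):
        case = rng.normal(0, 1, 100)
        m = case[:, None] + rng.normal(0, 0.3, (100, 2))
        base = icc(m).estimate
        assert icc(m + 5.0).estimate == pytest.approx(base, abs=1e-9)
        biased = m.copy()
        biased[:, 1] += 0.5  # constant bias on one rater hurts absolute agreement
        assert icc(biased).estimate < base


class TestCompareIcc:
    def test_copy_gives_zero_delta_and_large_p(self, rng):
        m = rng.normal(0, 1, (50, 2)) + rng.normal(0, 2, 50)[:, None]
        res = compare_icc_bootstrap(m, m.copy(), n_boot=200, seed=1)
        assert res.delta == 0
        assert res.p_value > 0.9

    def test_separated_iccs_detected(self):
        rng = np.random.default_rng(8)
        case = rng.normal(0, 2, 160)
        tight = case[:, None] + rng.normal(0, 0.45, (160, 2))   # ICC ~ 0.95
        loose = case[:, None] + rng.normal(0, 2.0, (160, 2))    # ICC ~ 0.5
        res = compare_icc_bootstrap(tight, loose, n_boot=1000, seed=9)
        assert res.delta > 0.3
        assert res.p_value <= 0.002

    def test_p_floor_is_one_over_n_boot(self):
        rng = np.random.default_rng(10)
        case = rng.normal(0, 2, 200)
        a = case[:, None] + rng.normal(0, 0.2, (200, 2))
        b = rng.normal(0, 1, (200, 2))
        res = compare_icc_bootstrap(a, b, n_boot=500, seed=2)
        assert res.p_value == pytest.approx(1 / 500)

    def test_p_values_calibrated_under_no_difference(self):
        """With truly equal ICCs, p <= 0.05 occurs in at most ~5% of studies."""
        rng = np.random.default_rng(55)
        small = 0
        for _ in range(500):
            case = rng.normal(0, 2, 100)
            a = case[:, None] + rng.normal(0, 1, (100, 2))
            b = case[:, None] + rng.normal(0, 1, (100, 2))
            res = compare_icc_bootstrap(a, b, n_boot=200,
                                        seed=int(rng.integers(2**31)))
            small += res.p_value <= 0.05
        assert small / 500 <= 0.08

    def test_case_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(10, 2)), index=list("abcdefghij"))
        b = pd.DataFrame(rng.normal(size=(10, 2)), index=list("abcdefghiz"))
        with pytest.raises(CaseMismatchError):
            compare_icc_bootstrap(a, b, n_boot=10, seed=0)


class TestPairingHelpers:
    @staticmethod
    def _measurements():
        rows = []
        for case in range(6):
            for ann in ("expert1", "expert2"):
                for s in (1, 2):
                    rows.append(
                        {
                            "case_id": f"c{case}",
                            "annotator_id": ann,
                            "session": s,
                            "ctr": 0.4 + 0.01 * case + (0.005 if ann == "expert2" else 0)
                            + (0.002 if s == 2 else 0),
                            "pathology_category": "normal",
                        }
                    )
        return pd.DataFrame(rows)

    def test_pivot_and_session_means(self):
        meas = self._measurements()
        wide = pivot_ctr(meas)
        assert wide.shape == (6, 4)
        means = expert_session_means(meas)
        assert means.shape == (6, 2)
        assert means.loc["c0", "expert1"] == pytest.approx(0.401)

    def test_intra_matrix_columns_are_sessions(self):
        m = intra_observer_matrix(self._measurements(), "expert1")
        assert list(m.columns) == [1, 2]
        assert np.allclose(m[2] - m[1], 0.002)

    def test_model_pairing_modes(self):
        meas = self._measurements()
        model = pd.DataFrame(
            {"case_id": [f"c{i}" for i in range(6)], "ctr": np.linspace(0.4, 0.45, 6)}
        )
        mean_pairs = model_vs_experts_pairs(meas, model, mode="mean")
        stacked_pairs = model_vs_experts_pairs(meas, model, mode="stacked")
        assert mean_pairs.n == 6
        assert stacked_pairs.n == 24
        stacked = model_vs_experts_stacked_matrix(meas, model)
        assert stacked.shape == (24, 2)
        # every case appears once per expert dataset in the stacked index
        assert stacked.index.value_counts().eq(4).all()

    def test_incomplete_measurements_detected(self):
        meas = self._measurements().iloc[:-1]
        with pytest.raises(IncompleteMeasurementsError):
            pivot_ctr(meas)
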