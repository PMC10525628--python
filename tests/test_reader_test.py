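"""Diagnostic performance, pooling and the non-inferiority test."""

import numpy as np
import pytest

from ctrval.errors import EmptySubgroupError, UnstableMetricError
from ctrval.reader_test import (
    METRICS,
    ConfusionCounts,
    diagnostic_measures,
    noninferiority_test,
    pooled_reader_counts,
    run_reader_study,
)
from ctrval.synth import simulate_study


class TestDiagnosticMeasures:
    def test_hand_example(self):
        perf = diagnostic_measures(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert perf.sensitivity.estimate == pytest.approx(0.90)
        assert perf.specificity.estimate == pytest.approx(0.80)
        assert perf.ppv.estimate == pytest.approx(9 / 11)
        assert perf.npv.estimate == pytest.approx(8 / 9)
        assert perf.accuracy.estimate == pytest.approx(0.85)
        for metric in METRICS:
            p = perf[metric]
            assert p.lo <= p.estimate <= p.hi

    def test_perfect_rater(self):
        perf = diagnostic_measures(ConfusionCounts(tp=50, fn=0, tn=50, fp=0))
        assert all(perf[m].estimate == 1.0 for m in METRICS)

    def test_zero_denominator_is_undefined_not_zero(self):
        # all-positive reference read perfectly: specificity has no
        # denominator and neither does NPV (no negative calls at all)
        with pytest.warns(UserWarning, match="no-neg"):
            perf = diagnostic_measures(ConfusionCounts(tp=12, fn=0, tn=0, fp=0))
        assert np.isnan(perf.specificity.estimate)
        assert np.isnan(perf.npv.estimate)
        assert perf.sensitivity.estimate == 1.0
        # NPV with wrong negative calls is a defined 0, not undefined
        perf2 = diagnostic_measures(ConfusionCounts(tp=10, fn=2, tn=0, fp=1))
        assert perf2.npv.estimate == 0.0

    def test_clopper_pearson_flag(self):
        wilson = diagnostic_measures(ConfusionCounts(9, 2, 8, 1))
        exact = diagnostic_measures(ConfusionCounts(9, 2, 8, 1), ci_method="beta")
        assert exact.sensitivity.lo <= wilson.sensitivity.lo  # CP is wider

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestPooling:
    def test_identical_readers_scale_counts(self, rng):
        ref = rng.integers(0, 2, 30).astype(bool)
        single = np.where(ref, 1, 0)
        pooled = pooled_reader_counts(np.tile(single[:, None], (1, 4)), ref)
        one = pooled_reader_counts(single[:, None], ref)
        assert (pooled.tp, pooled.tn) == (4 * one.tp, 4 * one.tn)
        assert pooled.fp == pooled.fn == 0

    def test_single_reader_is_identity(self, rng):
        ref = rng.integers(0, 2, 40).astype(bool)
        pred = rng.integers(0, 2, 40)
        a = pooled_reader_counts(pred, ref)
        b = ConfusionCounts.from_labels(pred, ref)
        assert a == b

    def test_flipped_reader_gives_half_accuracy(self):
        ref = np.tile([0, 1], 20).astype(bool)
        a = ref.astype(int)
        counts = pooled_reader_counts(np.column_stack([a, 1 - a]), ref)
        perf = diagnostic_measures(counts, n_raters=2)
        assert perf.accuracy.estimate == pytest.approx(0.5)


class TestNonInferiority:
    def test_perfect_agreement_is_noninferior(self):
        ref = np.tile([0, 1], 80).astype(bool)
        labels = ref.astype(int)
        res = noninferiority_test(
            labels, np.tile(labels[:, None], (1, 5)), ref, n_boot=500, seed=0
        )
        assert res.delta == 0
        assert res.non_inferior
        assert res.p_one_sided <= 1 / 500 + 1e-12

    def test_large_deficit_is_inferior(self):
        rng = np.random.default_rng(13)
        ref = np.tile([0, 1], 80).astype(bool)
        readers = np.where(ref[:, None], rng.random((160, 5)) < 0.97, 0)
        model = np.where(ref, rng.random(160) < 0.82, 0)  # delta ~ -0.15
        res = noninferiority_test(model, readers, ref, n_boot=1000, seed=14)
        assert not res.non_inferior
        assert res.p_one_sided >= 0.025

    def test_verdict_matches_p_threshold(self):
        rng = np.random.default_rng(15)
        ref = np.tile([0, 1], 50).astype(bool)
        model = np.where(ref, rng.random(100) < 0.9, rng.random(100) < 0.1)
        readers = np.where(ref[:, None], rng.random((100, 3)) < 0.9, 0)
        res = noninferiority_test(model, readers, ref, n_boot=500, seed=16)
        assert res.non_inferior == (res.p_one_sided < 0.025)

    def test_percentile_method_available(self):
        ref = np.tile([0, 1], 40).astype(bool)
        labels = ref.astype(int)
        res = noninferiority_test(
            labels, labels[:, None], ref, n_boot=400, seed=3, method="percentile"
        )
        assert res.non_inferior

    def test_evidence_grows_with_sample_size(self):
        """For a fixed deficit inside the margin, mean p falls as n grows."""
        rng = np.random.default_rng(17)
        mean_p = []
        for n in (40, 160, 640):
            ps = []
            for _ in range(30):
                ref = np.tile([0, 1], n // 2).astype(bool)
                model = np.where(ref, rng.random(n) < 0.90,
                                 rng.random(n) < 0.08)
                readers = np.where(ref[:, None], rng.random((n, 5)) < 0.92,
                                   rng.random((n, 5)) < 0.08)
                ps.append(
                    noninferiority_test(
                        model, readers, ref, n_boot=500,
                        seed=int(rng.integers(2**31)),
                    ).p_one_sided
                )
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]

    def test_confidence_intervals_shrink_with_n(self):
        small = diagnostic_measures(ConfusionCounts(tp=18, fn=2, tn=16, fp=4))
        large = diagnostic_measures(ConfusionCounts(tp=180, fn=20, tn=160, fp=40))
        assert (large.sensitivity.hi - large.sensitivity.lo) < (
            small.sensitivity.hi - small.sensitivity.lo
        )

    def test_degenerate_subgroup_raises_unstable(self):
        # a single positive: sensitivity undefined in ~1/e of resamples
        ref = np.array([1] + [0] * 63).astype(bool)
        labels = ref.astype(int)
        with pytest.raises(UnstableMetricError, match="unstable-metric"):
            noninferiority_test(
                labels, labels[:, None], ref, metric="sensitivity",
                n_boot=400, seed=4,
            )


@pytest.fixture(scope="module")
def study():
    return simulate_study(seed=2024)


class TestRunReaderStudy:

    def test_report_schema_and_verdicts(self, study):
        report = run_reader_study(
            study.measurements,
            study.model_measurements[["case_id", "ctr"]],
            n_boot=400,
            seed=1,
        )
        assert set(report["subgroup"]) == {
            "overall", "normal", "pneumothorax", "effusion", "consolidation",
        }
        assert set(report["metric"]) == set(METRICS)
        ov = report[report["subgroup"] == "overall"]
        assert len(ov) == 5
        defined = report.dropna(subset=["model_value"])
        assert ((defined["model_value"] >= defined["model_ci_lo"] - 1e-12)
                & (defined["model_value"] <= defined["model_ci_hi"] + 1e-12)).all()

    def test_reference_firewall(self, study):
        """Perturbing reader and model data must not move the reference."""
        import pandas as pd

        model = study.model_measurements[["case_id", "ctr"]]
        base = run_reader_study(study.measurements, model, n_boot=100, seed=5)
        perturbed = study.measurements.copy()
        is_reader = perturbed["role"] == "reader"
        perturbed.loc[is_reader, "ctr"] = 1.0 - perturbed.loc[is_reader, "ctr"]
        bad_model = model.assign(ctr=1.0 - model["ctr"])
        moved = run_reader_study(perturbed, bad_model, n_boot=100, seed=5)
        # prevalence comes from the reference standard: experts only
        pd.testing.assert_series_equal(base["prevalence"], moved["prevalence"])

    def test_empty_subgroup_rejected(self, study):
        with pytest.raises(EmptySubgroupError, match="empty-subgroup"):
            run_reader_study(
                study.measurements,
                study.model_measurements[["case_id", "ctr"]],
                subgroups=["nodules"],
                n_boot=50,
                seed=2,
            )

    def test_median_reference_mode(self, study):
        report = run_reader_study(
            study.measurements,
            study.model_measurements[["case_id", "ctr"]],
            reference_mode="median",
            subgroups=[],
            n_boot=200,
            seed=3,
        )
        assert (report["subgroup"] == "overall").all()

    def test_missing_role_column_rejected(self, study):
        with pytest.raises(ValueError, match="role"):
            run_reader_study(
                study.measurements.drop(columns=["role"]),
                study.model_measurements[["case_id", "ctr"]],
            )
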