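"""Reader tests: diagnostic performance and non-inferiority of a model
versus pooled human readers, against a consensus reference standard.

The comparison follows the multi-reader design of a CTR validation study:
five readers each label every case, their decisions are pooled at the
decision level (n_cases x n_readers decisions), and the model's
sensitivity, specificity, PPV, NPV and accuracy are each tested for
non-inferiority against the pooled readers at an absolute margin of 10
percentage points, one-sided alpha 0.025.

The non-inferiority test is a cluster (case-level) bootstrap Wald test:
resampling cases keeps the model/reader pairing and the within-case
correlation of the pooled reader decisions, the bootstrap SD of the metric
difference estimates its standard error, and

    p = P( Z <= -(delta_hat + margin) / SE ),   delta_hat = theta_model - theta_readers,

is compared with 0.025.  A percentile-based p-value is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import consensus as _consensus
from .errors import (
    EmptySubgroupError,
    IncompleteReadersError,
    UnstableMetricError,
)

__all__ = [
    "METRICS",
    "ConfusionCounts",
    "Proportion",
    "DiagnosticPerformance",
    "NonInferiorityResult",
    "diagnostic_measures",
    "pooled_reader_counts",
    "noninferiority_test",
    "run_reader_study",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 decision counts; positive = cardiomegaly."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted, reference) -> "ConfusionCounts":
        pred = np.asarray(predicted, dtype=bool)
        ref = np.asarray(reference, dtype=bool)
        if pred.shape != ref.shape:
            raise ValueError("predicted and reference must have the same shape")
        return cls(
            tp=int((pred & ref).sum()),
            fp=int((pred & ~ref).sum()),
            tn=int((~pred & ~ref).sum()),
            fn=int((~pred & ref).sum()),
        )


class Proportion(NamedTuple):
    """A proportion with its confidence interval (NaN when undefined)."""

    estimate: float
    lo: float
    hi: float


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion
    n_decisions: int
    n_cases: int
    n_raters: int

    def __getitem__(self, metric: str) -> Proportion:
        if metric not in METRICS:
            raise KeyError(metric)
        return getattr(self, metric)


_NUM_DEN = {
    "sensitivity": (lambda c: c.tp, lambda c: c.tp + c.fn),
    "specificity": (lambda c: c.tn, lambda c: c.tn + c.fp),
    "ppv": (lambda c: c.tp, lambda c: c.tp + c.fp),
    "npv": (lambda c: c.tn, lambda c: c.tn + c.fn),
    "accuracy": (lambda c: c.tp + c.tn, lambda c: c.total),
}

_NO_DENOM_WARNING = {
    "sensitivity": "no-positives",
    "specificity": "no-negatives",
    "ppv": "no-positive-calls",
    "npv": "no-negative-calls",
    "accuracy": "no-decisions",
}


def diagnostic_measures(
    counts: ConfusionCounts,
    ci_method: str = "wilson",
    alpha: float = 0.05,
    n_cases: int | None = None,
    n_raters: int = 1,
) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and accuracy with binomial CIs.

    CIs are Wilson score intervals by default (``ci_method='beta'`` gives
    Clopper–Pearson).  A measure whose denominator is zero is reported as
    undefined (NaN) with a warning, never as 0.
    """
    if ci_method not in ("wilson", "beta"):
        raise ValueError("ci_method must be 'wilson' or 'beta' (Clopper-Pearson)")
    values: dict[str, Proportion] = {}
    for name in METRICS:
        num_f, den_f = _NUM_DEN[name]
        num, den = num_f(counts), den_f(counts)
        if den == 0:
            warnings.warn(f"{_NO_DENOM_WARNING[name]}: {name} undefined", stacklevel=2)
            values[name] = Proportion(float("nan"), float("nan"), float("nan"))
            continue
        lo, hi = proportion_confint(num, den, alpha=alpha, method=ci_method)
        values[name] = Proportion(num / den, float(lo), float(hi))
    return DiagnosticPerformance(
        **values,
        n_decisions=counts.total,
        n_cases=counts.total // max(n_raters, 1) if n_cases is None else n_cases,
        n_raters=n_raters,
    )


def pooled_reader_counts(
    reader_labels: np.ndarray | pd.DataFrame, reference
) -> ConfusionCounts:
    """Pool all reader decisions against the per-case reference.

    ``reader_labels`` is a cases x readers binary matrix; every reader must
    label every case.  Pooling k identical readers yields exactly k times
    the single-reader counts.
    """
    mat = np.asarray(reader_labels)
    if mat.ndim == 1:
        mat = mat[:, None]
    if np.isnan(np.asarray(mat, dtype=float)).any():
        raise IncompleteReadersError("incomplete-readers: missing decisions")
    ref = np.asarray(reference, dtype=bool)
    if mat.shape[0] != ref.shape[0]:
        raise ValueError("reader matrix and reference must cover the same cases")
    pred = mat.astype(bool)
    ref2 = np.broadcast_to(ref[:, None], pred.shape)
    return ConfusionCounts(
        tp=int((pred & ref2).sum()),
        fp=int((pred & ~ref2).sum()),
        tn=int((~pred & ~ref2).sum()),
        fn=int((~pred & ref2).sum()),
    )


@dataclass(frozen=True)
class NonInferiorityResult:
    """One-sided non-inferiority comparison (model - readers)."""

    metric: str
    model_value: float
    readers_value: float
    delta: float
    margin: float
    p_one_sided: float
    non_inferior: bool
    se: float
    n_boot: int
    seed: int | None
    method: str


def _metric_arrays(name: str, tp, fp, tn, fn):
    """Vectorized metric over resampled count arrays; NaN where undefined."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    tn = np.asarray(tn, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if name == "sensitivity":
        num, den = tp, tp + fn
    elif name == "specificity":
        num, den = tn, tn + fp
    elif name == "ppv":
        num, den = tp, tp + fp
    elif name == "npv":
        num, den = tn, tn + fn
    elif name == "accuracy":
        num, den = tp + tn, tp + fp + tn + fn
    else:
        raise ValueError(f"unknown metric {name!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def noninferiority_test(
    model_labels,
    reader_labels,
    reference,
    metric: str = "sensitivity",
    margin: float = 0.10,
    n_boot: int = 2000,
    seed: int | None = None,
    method: str = "wald",
    max_undefined_frac: float = 0.20,
) -> NonInferiorityResult:
    """Case-bootstrap non-inferiority test of ``theta_model - theta_readers``.

    H0: delta <= -margin vs H1: delta > -margin, verdict at one-sided
    p < 0.025.  ``method='wald'`` uses the bootstrap SE with a normal tail;
    ``method='percentile'`` reports the fraction of bootstrap deltas at or
    below -margin.  If the metric is undefined in more than
    ``max_undefined_frac`` of resamples the subgroup is too degenerate and
    an ``unstable-metric`` error is raised.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if method not in ("wald", "percentile"):
        raise ValueError("method must be 'wald' or 'percentile'")
    model = np.asarray(model_labels, dtype=bool)
    readers = np.asarray(reader_labels)
    if readers.ndim == 1:
        readers = readers[:, None]
    readers = readers.astype(bool)
    ref = np.asarray(reference, dtype=bool)
    n = ref.shape[0]
    if model.shape[0] != n or readers.shape[0] != n:
        raise ValueError("model, readers and reference must cover the same cases")

    # per-case count contributions
    m_tp = (model & ref).astype(np.int64)
    m_fp = (model & ~ref).astype(np.int64)
    m_tn = (~model & ~ref).astype(np.int64)
    m_fn = (~model & ref).astype(np.int64)
    refk = ref[:, None]
    r_tp = (readers & refk).sum(axis=1)
    r_fp = (readers & ~refk).sum(axis=1)
    r_tn = (~readers & ~refk).sum(axis=1)
    r_fn = (~readers & refk).sum(axis=1)

    theta_m = float(_metric_arrays(metric, m_tp.sum(), m_fp.sum(), m_tn.sum(), m_fn.sum()))
    theta_r = float(_metric_arrays(metric, r_tp.sum(), r_fp.sum(), r_tn.sum(), r_fn.sum()))
    delta = theta_m - theta_r

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    d_m = _metric_arrays(
        metric, m_tp[idx].sum(1), m_fp[idx].sum(1), m_tn[idx].sum(1), m_fn[idx].sum(1)
    )
    d_r = _metric_arrays(
        metric, r_tp[idx].sum(1), r_fp[idx].sum(1), r_tn[idx].sum(1), r_fn[idx].sum(1)
    )
    deltas = d_m - d_r
    undefined = np.isnan(deltas).mean()
    if undefined > max_undefined_frac or np.isnan(delta):
        raise UnstableMetricError(
            f"unstable-metric: {metric} undefined in "
            f"{undefined:.0%} of bootstrap resamples"
        )
    deltas = deltas[~np.isnan(deltas)]
    se = float(deltas.std(ddof=1))
    min_p = 1.0 / n_boot
    if method == "wald":
        if se == 0.0:
            p = min_p if delta > -margin else 1.0
        else:
            p = float(stats.norm.cdf(-(delta + margin) / se))
            p = min(max(p, min_p), 1.0)
    else:
        p = (1.0 + np.sum(deltas <= -margin)) / (deltas.size + 1.0)
        p = float(min(max(p, min_p), 1.0))
    return NonInferiorityResult(
        metric=metric,
        model_value=theta_m,
        readers_value=theta_r,
        delta=float(delta),
        margin=margin,
        p_one_sided=p,
        non_inferior=bool(p < 0.025),
        se=se,
        n_boot=n_boot,
        seed=seed,
        method=method,
    )


# ---------------------------------------------------------------------------
# Full reader study (Table-3 shaped report)
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "subgroup",
    "n_cases",
    "prevalence",
    "metric",
    "model_value",
    "model_ci_lo",
    "model_ci_hi",
    "readers_value",
    "readers_ci_lo",
    "readers_ci_hi",
    "delta",
    "p_noninferiority",
    "non_inferior",
]


def build_reference(
    expert_measurements: pd.DataFrame,
    cutoff: float = 0.50,
    mode: str = "dawid-skene",
) -> pd.Series:
    """Per-case binary reference from the expert annotation sets only."""
    if mode == "dawid-skene":
        lm = _consensus.LabelMatrix.from_measurements(expert_measurements, cutoff)
        result = _consensus.dawid_skene(lm)
        return pd.Series(result.hard_labels, index=lm.case_ids, name="label")
    if mode == "median":
        return _consensus.median_reference(expert_measurements, cutoff)
    raise ValueError("reference mode must be 'dawid-skene' or 'median'")


def run_reader_study(
    measurements: pd.DataFrame,
    model_measurements: pd.DataFrame,
    cutoff: float = 0.50,
    reference_mode: str = "dawid-skene",
    subgroups: list[str] | None = None,
    margin: float = 0.10,
    n_boot: int = 2000,
    seed: int | None = None,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Full diagnostic grid: overall + pathology subgroups x 5 metrics.

    ``measurements`` holds experts and readers in long format, told apart
    by a ``role`` column; the reference standard is built only from the
    expert rows (never from the readers or the model).  Subgroups default
    to the distinct ``pathology_category`` values.  Metrics undefined in a
    subgroup (single reference class) are reported as NaN with a warning
    and their non-inferiority p omitted.
    """
    if "role" not in measurements.columns:
        raise ValueError("measurements must carry a 'role' column (expert/reader)")
    experts = measurements[measurements["role"] == "expert"]
    readers = measurements[measurements["role"] == "reader"]
    if experts.empty or readers.empty:
        raise ValueError("measurements must contain both expert and reader rows")

    if reference is None:
        reference = build_reference(experts, cutoff=cutoff, mode=reference_mode)
    reference = reference.sort_index()
    case_ids = reference.index

    reader_wide = readers.pivot_table(
        index="case_id", columns="annotator_id", values="ctr"
    ).sort_index()
    if reader_wide.isna().any().any():
        raise IncompleteReadersError("incomplete-readers: missing reader decisions")
    model_s = model_measurements.set_index("case_id")["ctr"].sort_index()
    if not (reader_wide.index.equals(case_ids) and model_s.index.equals(case_ids)):
        raise ValueError("experts, readers and model must cover the same case set")
    reader_labels = pd.DataFrame(
        _consensus.binarize(reader_wide.to_numpy(), cutoff),
        index=reader_wide.index,
        columns=reader_wide.columns,
    )
    model_labels = pd.Series(
        _consensus.binarize(model_s.to_numpy(), cutoff), index=case_ids
    )

    category = (
        measurements.drop_duplicates("case_id")
        .set_index("case_id")["pathology_category"]
        .reindex(case_ids)
    )
    if subgroups is None:
        subgroups = sorted(category.dropna().unique().tolist())

    n_readers = reader_labels.shape[1]
    rows = []
    rng = np.random.default_rng(seed)
    for name in ["overall", *subgroups]:
        mask = np.ones(len(case_ids), dtype=bool) if name == "overall" else (
            category == name
        ).to_numpy()
        if mask.sum() == 0:
            raise EmptySubgroupError(f"empty-subgroup: {name!r} selected no cases")
        ref_g = reference.to_numpy()[mask]
        mod_g = model_labels.to_numpy()[mask]
        read_g = reader_labels.to_numpy()[mask]
        perf_m = diagnostic_measures(
            ConfusionCounts.from_labels(mod_g, ref_g), n_cases=int(mask.sum())
        )
        perf_r = diagnostic_measures(
            pooled_reader_counts(read_g, ref_g),
            n_cases=int(mask.sum()),
            n_raters=n_readers,
        )
        for metric in METRICS:
            pm, pr = perf_m[metric], perf_r[metric]
            p_ni, verdict, delta = float("nan"), None, float("nan")
            if not (np.isnan(pm.estimate) or np.isnan(pr.estimate)):
                try:
                    ni = noninferiority_test(
                        mod_g,
                        read_g,
                        ref_g,
                        metric=metric,
                        margin=margin,
                        n_boot=n_boot,
                        seed=int(rng.integers(2**31)),
                    )
                    p_ni, verdict, delta = ni.p_one_sided, ni.non_inferior, ni.delta
                except UnstableMetricError as exc:
                    warnings.warn(f"subgroup {name!r}: {exc}", stacklevel=2)
            rows.append(
                (
                    name,
                    int(mask.sum()),
                    float(ref_g.mean()),
                    metric,
                    pm.estimate,
                    pm.lo,
                    pm.hi,
                    pr.estimate,
                    pr.lo,
                    pr.hi,
                    delta,
                    p_ni,
                    verdict,
                )
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
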