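"""Agreement statistics for paired CTR measurements.

Implements the agreement toolbox used to compare an automatic CTR reader
with human experts:

* Bland–Altman mean difference and 95% limits of agreement (LOA), on the
  absolute or the relative (percentage-of-pair-mean) scale, with either
  parametric or case-bootstrap confidence intervals for the LOAs;
* MAE and RMSE of the paired differences;
* ICC(2,1) — two-way random effects, absolute agreement, single measures —
  with the standard F-based confidence interval;
* a paired case-bootstrap comparison of two ICCs.

Pairing conventions for the four expert datasets (2 radiologists x 2
sessions) live in the ``*_pairs`` / ``*_matrix`` helpers at the bottom so
that the whole pipeline shares one definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CaseMismatchError,
    IncompleteMeasurementsError,
    InsufficientPairsError,
    RelativeUndefinedError,
)

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "IccResult",
    "IccComparison",
    "LOA_Z",
    "bland_altman",
    "mae_rmse",
    "icc",
    "compare_icc_bootstrap",
    "pivot_ctr",
    "expert_session_means",
    "intra_observer_matrix",
    "model_vs_experts_pairs",
    "model_vs_experts_stacked_matrix",
]

#: Normal quantile used for 95% limits of agreement (mean +- 1.96 sd).
LOA_Z = 1.96


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements of the same cases by two sources.

    ``x`` is the reference source and ``y`` the comparison source; the
    Bland–Altman difference is ``y - x``.  ``scale`` selects absolute
    differences or relative differences in percent of the pair mean
    ``(x + y) / 2``.
    """

    case_id: list
    x: np.ndarray
    y: np.ndarray
    scale: str = "absolute"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.case_id) != x.size:
            raise ValueError("case_id length must match the measurements")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed in a PairedSeries")
        if self.scale not in ("absolute", "relative"):
            raise ValueError("scale must be 'absolute' or 'relative'")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def differences(self) -> np.ndarray:
        """Per-case differences on the series' scale."""
        d = self.y - self.x
        if self.scale == "relative":
            means = (self.x + self.y) / 2.0
            if (means <= 0).any():
                raise RelativeUndefinedError(
                    "relative-undefined: a pair mean is non-positive"
                )
            d = 100.0 * d / means
        return d


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary: mean difference, LOAs and their CIs."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    scale: str
    ci_method: str


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) estimate with its F-based confidence interval."""

    estimate: float
    ci: tuple[float, float]
    kind: str
    n_cases: int
    n_raters: int


@dataclass(frozen=True)
class IccComparison:
    """Observed ICC difference and its bootstrap two-sided p-value."""

    icc_a: float
    icc_b: float
    delta: float
    p_value: float
    n_boot: int
    seed: int | None = None
    boot_deltas: np.ndarray | None = field(default=None, repr=False, compare=False)


def _loa_se_factor(n: int) -> float:
    """Standard-error factor of a limit of agreement: sqrt(1/n + z^2/(2(n-1)))."""
    return float(np.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1))))


def bland_altman(
    pairs: PairedSeries,
    ci_method: str = "parametric",
    n_boot: int = 1000,
    seed: int | None = None,
) -> AgreementResult:
    """Bland–Altman analysis with confidence intervals for the LOAs.

    LOAs are ``mean +- 1.96 sd`` of the differences.  Parametric CIs use
    ``se(LOA) = sd * sqrt(1/n + 1.96^2 / (2(n-1)))`` with a t(n-1)
    quantile; bootstrap CIs are seeded case-resampling percentile
    intervals.  CIs require n >= 3 and are NaN below that.
    """
    if pairs.n < 2:
        raise InsufficientPairsError("insufficient-pairs: need at least 2 pairs")
    if ci_method not in ("parametric", "bootstrap"):
        raise ValueError("ci_method must be 'parametric' or 'bootstrap'")
    d = pairs.differences()
    n = pairs.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = mean - LOA_Z * sd
    upper = mean + LOA_Z * sd

    if n < 3:
        warnings.warn("n < 3: LOA confidence intervals are undefined", stacklevel=2)
        nan_ci = (float("nan"), float("nan"))
        return AgreementResult(n, mean, sd, lower, upper, nan_ci, nan_ci, pairs.scale, ci_method)

    if ci_method == "parametric":
        se = sd * _loa_se_factor(n)
        t = stats.t.ppf(0.975, n - 1)
        lo_ci = (lower - t * se, lower + t * se)
        hi_ci = (upper - t * se, upper + t * se)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        db = d[idx]
        mb = db.mean(axis=1)
        sb = db.std(axis=1, ddof=1)
        lo_star = mb - LOA_Z * sb
        hi_star = mb + LOA_Z * sb
        lo_ci = tuple(np.percentile(lo_star, [2.5, 97.5]))
        hi_ci = tuple(np.percentile(hi_star, [2.5, 97.5]))
        # percentile intervals need not contain a zero-variance point estimate
        lo_ci = (min(lo_ci[0], lower), max(lo_ci[1], lower))
        hi_ci = (min(hi_ci[0], upper), max(hi_ci[1], upper))

    return AgreementResult(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=lower,
        loa_upper=upper,
        loa_lower_ci=(float(lo_ci[0]), float(lo_ci[1])),
        loa_upper_ci=(float(hi_ci[0]), float(hi_ci[1])),
        scale=pairs.scale,
        ci_method=ci_method,
    )


def mae_rmse(pairs: PairedSeries) -> tuple[float, float]:
    """Mean absolute error and root-mean-square error of ``y - x``.

    MAE = mean(|y_i - x_i|); RMSE = sqrt(mean((y_i - x_i)^2)).  RMSE >= MAE
    always, with equality iff all absolute differences are equal.
    """
    if pairs.n < 1:
        raise InsufficientPairsError("insufficient-pairs: need at least 1 pair")
    d = pairs.y - pairs.x
    return float(np.abs(d).mean()), float(np.sqrt((d**2).mean()))


def _icc2_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=cases, columns=raters)."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc2_point(m: np.ndarray) -> float:
    """Fast ICC(2,1) point estimate (no CI); used inside bootstraps."""
    n, k = m.shape
    msr, msc, mse = _icc2_mean_squares(m)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return (msr - mse) / denom


def icc(
    ratings: np.ndarray | pd.DataFrame,
    kind: str = "inter",
    alpha: float = 0.05,
) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Parameters
    ----------
    ratings
        cases x raters matrix with no missing cells (>= 5 cases, >= 2 raters).
    kind
        Free-text tag ("intra" or "inter") carried into the result.
    alpha
        Two-sided CI level (default 95% CI).

    The confidence interval is the standard F-based interval for ICC(2,1)
    (McGraw–Wong), with the Satterthwaite degrees of freedom for the
    denominator.  A constant matrix (zero variance everywhere) is perfect
    agreement by convention: estimate 1 with a degenerate CI and a warning.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D cases x raters matrix")
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 cases")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed")

    if np.ptp(m) == 0:
        warnings.warn("constant ratings matrix: ICC defined as 1", stacklevel=2)
        return IccResult(1.0, (float("nan"), float("nan")), kind, n, k)

    msr, msc, mse = _icc2_mean_squares(m)
    est = icc2_point(m)

    # F-based CI for ICC(2,1), McGraw & Wong (1996)
    fj = msc / mse if mse > 0 else np.inf
    a = k * est * fj + n * (1 + (k - 1) * est) - k * est
    vn = (k - 1) * (n - 1) * a**2
    vd = (n - 1) * k**2 * est**2 * fj**2 + (n * (1 + (k - 1) * est) - k * est) ** 2
    v = vn / vd
    f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return IccResult(float(est), (lo, hi), kind, n, k)


def _case_row_positions(ratings) -> tuple[list, list[np.ndarray]]:
    """Unique cases (in first-appearance order) and their row positions.

    A DataFrame index identifies cases and may repeat (stacked designs);
    a bare array treats every row as its own case.
    """
    if isinstance(ratings, pd.DataFrame):
        idx = ratings.index
        cases = list(dict.fromkeys(idx))
        pos = {c: [] for c in cases}
        for i, c in enumerate(idx):
            pos[c].append(i)
        return cases, [np.asarray(pos[c]) for c in cases]
    n = np.asarray(ratings).shape[0]
    return list(range(n)), [np.asarray([i]) for i in range(n)]


def compare_icc_bootstrap(
    ratings_a: np.ndarray | pd.DataFrame,
    ratings_b: np.ndarray | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    return_distribution: bool = False,
) -> IccComparison:
    """Paired case-bootstrap comparison of two ICC(2,1) coefficients.

    Both matrices must cover the same case set (cases are DataFrame index
    labels, which may repeat in stacked designs, or plain row numbers for
    bare arrays).  Each bootstrap draw resamples CASES with replacement and
    applies the same resample to both matrices — cases are the exchangeable
    unit and the two coefficients stay paired.  The two-sided p-value is
    ``2 * min(P(delta* <= 0), P(delta* >= 0))``, floored at ``1 / n_boot``
    so that 0 is never reported.
    """
    cases_a, pos_a = _case_row_positions(ratings_a)
    cases_b, pos_b = _case_row_positions(ratings_b)
    if list(cases_a) != list(cases_b):
        raise CaseMismatchError("case-mismatch: matrices cover different case sets")
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    n_cases = len(cases_a)

    def gather(mat, pos, case_idx):
        rows = np.concatenate([pos[j] for j in case_idx])
        return mat[rows]

    # fast path: every case occupies the same number of rows
    ga = np.vstack(pos_a) if len({p.size for p in pos_a}) == 1 else None
    gb = np.vstack(pos_b) if len({p.size for p in pos_b}) == 1 else None

    delta = icc2_point(a) - icc2_point(b)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        case_idx = rng.integers(0, n_cases, size=n_cases)
        ra = a[ga[case_idx].ravel()] if ga is not None else gather(a, pos_a, case_idx)
        rb = b[gb[case_idx].ravel()] if gb is not None else gather(b, pos_b, case_idx)
        deltas[i] = icc2_point(ra) - icc2_point(rb)
    p_low = np.mean(deltas <= 0)
    p_high = np.mean(deltas >= 0)
    p = max(2.0 * min(p_low, p_high), 1.0 / n_boot)
    p = min(p, 1.0)
    return IccComparison(
        icc_a=float(icc2_point(a)),
        icc_b=float(icc2_point(b)),
        delta=float(delta),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
        boot_deltas=deltas if return_distribution else None,
    )


# ---------------------------------------------------------------------------
# Pairing conventions for the long-format measurement table
# (columns: case_id, annotator_id, session, ctr, ...).
# ---------------------------------------------------------------------------

def pivot_ctr(measurements: pd.DataFrame) -> pd.DataFrame:
    """Wide case x (annotator, session) CTR table, sorted by case_id."""
    wide = measurements.pivot_table(
        index="case_id", columns=["annotator_id", "session"], values="ctr"
    ).sort_index()
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise IncompleteMeasurementsError(
            f"incomplete-measurements: cases missing measurements: {missing[:5]}"
        )
    return wide


def expert_session_means(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-radiologist session-mean CTR, one column per radiologist."""
    wide = pivot_ctr(measurements)
    return wide.T.groupby(level="annotator_id").mean().T


def intra_observer_matrix(measurements: pd.DataFrame, annotator_id) -> pd.DataFrame:
    """Session-1 vs session-2 CTR columns for one radiologist."""
    sub = measurements[measurements["annotator_id"] == annotator_id]
    if sub.empty:
        raise ValueError(f"no measurements for annotator {annotator_id!r}")
    return sub.pivot_table(index="case_id", columns="session", values="ctr").sort_index()


def model_vs_experts_pairs(
    measurements: pd.DataFrame,
    model: pd.DataFrame,
    scale: str = "absolute",
    mode: str = "mean",
) -> PairedSeries:
    """Paired series for 'model versus the thoracic radiologists'.

    ``mode='mean'`` pairs the model CTR with the per-case mean of the four
    expert measurements (one pair per case); ``mode='stacked'`` pairs the
    model with each of the four expert datasets (four pairs per case).
    """
    wide = pivot_ctr(measurements)
    model_s = model.set_index("case_id")["ctr"].sort_index()
    if not wide.index.equals(model_s.index):
        raise CaseMismatchError("case-mismatch: model and expert case sets differ")
    if mode == "mean":
        x = wide.mean(axis=1).to_numpy()
        y = model_s.to_numpy()
        cases = list(wide.index)
    elif mode == "stacked":
        x = wide.to_numpy().ravel(order="F")
        y = np.tile(model_s.to_numpy(), wide.shape[1])
        cases = list(wide.index) * wide.shape[1]
    else:
        raise ValueError("mode must be 'mean' or 'stacked'")
    return PairedSeries(case_id=cases, x=x, y=y, scale=scale)


def model_vs_experts_stacked_matrix(
    measurements: pd.DataFrame, model: pd.DataFrame
) -> pd.DataFrame:
    """Two-column stacked design for the model-vs-radiologists ICC.

    The model column is paired with each of the four expert datasets and
    the pairings are stacked (4n rows, 2 columns), yielding a single
    coefficient comparable to the radiologist–radiologist ICC.  The row
    index repeats each case once per expert dataset so that case-level
    bootstrap helpers can still resample blocks.
    """
    wide = pivot_ctr(measurements)
    model_s = model.set_index("case_id")["ctr"].sort_index()
    if not wide.index.equals(model_s.index):
        raise CaseMismatchError("case-mismatch: model and expert case sets differ")
    blocks = []
    for col in wide.columns:
        blocks.append(
            pd.DataFrame(
                {"model": model_s.to_numpy(), "expert": wide[col].to_numpy()},
                index=wide.index,
            )
        )
    return pd.concat(blocks, axis=0)
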