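"""Binary reference standards for cardiomegaly: Dawid–Skene EM and medians.

Cardiomegaly is defined as CTR strictly greater than a cutoff (0.50 by
default; 0.55 for "significant cardiomegaly").  Given several annotation
sets that each binarize their own CTR measurements, this module builds a
consensus reference:

* :func:`dawid_skene` — the two-class Dawid–Skene model, fitted by EM.
  Each annotation set is treated as a conditionally independent annotator
  with its own 2x2 confusion matrix; the E-step recomputes per-case
  posteriors of the latent true label by Bayes, the M-step re-estimates
  the class prior and the confusion matrices (optionally Laplace-smoothed
  to keep few-annotator fits away from degenerate 0/1 probabilities).
* :func:`median_reference` — the sensitivity analysis: per-case median of
  the CTR measurements, binarized at the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompleteMeasurementsError

__all__ = [
    "LabelMatrix",
    "ConsensusResult",
    "binarize",
    "dawid_skene",
    "median_reference",
]


def binarize(ctr, cutoff: float = 0.50):
    """1 iff CTR > cutoff (strict: a CTR exactly at the cutoff is negative).

    Accepts a scalar or an array; returns the matching shape with int
    labels.
    """
    arr = np.asarray(ctr)
    out = (arr > cutoff).astype(int)
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LabelMatrix:
    """Binary labels from several annotation sets (cases x sets)."""

    labels: np.ndarray
    set_ids: list
    case_ids: list
    cutoff: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=int)
        if arr.ndim != 2:
            raise ValueError("labels must be 2-D (cases x annotation sets)")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be strictly binary (0/1)")
        if len(self.set_ids) != arr.shape[1]:
            raise ValueError("set_ids must match the number of columns")
        if len(self.case_ids) != arr.shape[0]:
            raise ValueError("case_ids must match the number of rows")
        if self.cutoff is not None and not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        object.__setattr__(self, "labels", arr)

    @classmethod
    def from_measurements(
        cls, measurements: pd.DataFrame, cutoff: float = 0.50
    ) -> "LabelMatrix":
        """Binarize a long measurement table into one column per
        (annotator, session) dataset."""
        wide = measurements.pivot_table(
            index="case_id", columns=["annotator_id", "session"], values="ctr"
        ).sort_index()
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise IncompleteMeasurementsError(
                f"incomplete-measurements: {missing[:5]}"
            )
        return cls(
            labels=binarize(wide.to_numpy(), cutoff),
            set_ids=[f"{a}/s{s}" for a, s in wide.columns],
            case_ids=list(wide.index),
            cutoff=cutoff,
        )


@dataclass(frozen=True)
class ConsensusResult:
    """Dawid–Skene output: posteriors, hard labels, confusion matrices, prior.

    ``confusion[j]`` is the 2x2 row-stochastic matrix of annotation set j:
    row = true class, column = emitted label.  ``hard_labels`` is 1 where
    the posterior is >= 0.5 (a posterior tie counts as cardiomegaly,
    favouring sensitivity in a screening context).
    """

    posterior: np.ndarray
    hard_labels: np.ndarray
    confusion: np.ndarray
    prior: float
    n_iter: int
    converged: bool
    case_ids: list
    set_ids: list


def dawid_skene(
    labels: LabelMatrix,
    tol: float = 1e-6,
    max_iter: int = 100,
    smoothing: float = 1.0,
    seed: int | None = None,
) -> ConsensusResult:
    """Two-class Dawid–Skene consensus fitted by EM.

    Parameters
    ----------
    labels
        Binary cases x sets matrix (>= 2 cases; single-set input degrades
        to a warned pass-through).
    tol
        Convergence threshold on the maximum absolute posterior change.
    max_iter
        EM iteration cap.
    smoothing
        Laplace pseudo-count added to every confusion cell (and to the
        prior) in the M-step.  The default +1 prevents zero-probability
        lock-in with few annotation sets; pass 0 for the original
        unsmoothed formulation.
    seed
        Reserved for future random restarts; the default fit is
        deterministic (vote-fraction initialization).

    The EM initializes posteriors from the per-case vote fraction, and the
    hard labels are 1 where the final posterior is >= 0.5.
    """
    del seed  # deterministic: vote-fraction init, no random restarts
    mat = labels.labels
    n, m = mat.shape
    if n < 2:
        raise ValueError("need at least 2 cases")

    if m == 1:
        warnings.warn(
            "single annotation set: consensus is a pass-through of its labels",
            stacklevel=2,
        )
        q = mat[:, 0].astype(float)
        conf = np.array([[[0.99, 0.01], [0.01, 0.99]]])  # identity-leaning
        return ConsensusResult(
            posterior=q,
            hard_labels=mat[:, 0].copy(),
            confusion=conf,
            prior=float(q.mean()),
            n_iter=0,
            converged=True,
            case_ids=list(labels.case_ids),
            set_ids=list(labels.set_ids),
        )

    votes = mat.mean(axis=1)
    if np.ptp(mat) == 0:
        warnings.warn(
            "all labels identical across sets and cases: prior collapses to "
            "the unanimous class",
            stacklevel=2,
        )
    majority = (votes >= 0.5).astype(int)
    if len(np.unique(majority)) < 2:
        warnings.warn(
            "majority vote is single-class: the fit may be degenerate",
            stacklevel=2,
        )

    q = votes.astype(float)  # posterior P(true = 1)
    s = float(smoothing)
    n_iter = 0
    converged = False
    eps = 1e-12
    for n_iter in range(1, max_iter + 1):
        # M-step
        w1 = q.sum()
        w0 = n - w1
        prior = (w1 + s) / (n + 2 * s)
        # confusion[j, t, l] = P(set j emits l | true class t)
        conf = np.empty((m, 2, 2))
        for t, w, wsum in ((1, q, w1), (0, 1 - q, w0)):
            c1 = (w[:, None] * mat).sum(axis=0)  # emitted-1 mass per set
            conf[:, t, 1] = (c1 + s) / (wsum + 2 * s)
            conf[:, t, 0] = 1.0 - conf[:, t, 1]
        # E-step
        log1 = np.log(prior + eps) + np.where(
            mat == 1, np.log(conf[:, 1, 1] + eps), np.log(conf[:, 1, 0] + eps)
        ).sum(axis=1)
        log0 = np.log(1 - prior + eps) + np.where(
            mat == 1, np.log(conf[:, 0, 1] + eps), np.log(conf[:, 0, 0] + eps)
        ).sum(axis=1)
        mx = np.maximum(log1, log0)
        q_new = np.exp(log1 - mx) / (np.exp(log1 - mx) + np.exp(log0 - mx))
        change = float(np.max(np.abs(q_new - q)))
        q = q_new
        if change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations", stacklevel=2)
    hard = (q >= 0.5).astype(int)
    return ConsensusResult(
        posterior=q,
        hard_labels=hard,
        confusion=conf,
        prior=float(prior),
        n_iter=n_iter,
        converged=converged,
        case_ids=list(labels.case_ids),
        set_ids=list(labels.set_ids),
    )


def median_reference(
    measurements: pd.DataFrame | dict, cutoff: float = 0.50
) -> pd.Series:
    """Per-case median CTR, binarized at ``cutoff`` (strict inequality).

    ``measurements`` is either a long table with ``case_id`` and ``ctr``
    columns or a mapping case_id -> list of CTRs.  An even measurement
    count medians as the mean of the two middle values.  A case with no
    measurements raises ``incomplete-measurements``.
    """
    if isinstance(measurements, dict):
        items = sorted(measurements.items())
        empty = [c for c, v in items if len(v) == 0]
        if empty:
            raise IncompleteMeasurementsError(f"incomplete-measurements: {empty[:5]}")
        med = pd.Series({c: float(np.median(v)) for c, v in items})
    else:
        if measurements.empty:
            raise IncompleteMeasurementsError("incomplete-measurements: empty table")
        med = measurements.groupby("case_id")["ctr"].median().sort_index()
    return pd.Series(binarize(med.to_numpy(), cutoff), index=med.index, name="label")
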