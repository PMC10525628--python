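"""Sample size for a Bland–Altman agreement study.

The design question: how many paired measurements are needed so that, with
probability at least 1 - beta, the two-sided (1 - alpha) confidence
intervals of BOTH 95% limits of agreement fall inside the maximum
clinically allowed difference +-delta_max?

Model: differences d_i ~ N(mu_d, sd_d^2).  For a sample of size n the
estimated limits are dbar +- 1.96 s, and each limit's CI half-width is
t_{1-alpha/2, n-1} * s * sqrt(1/n + 1.96^2 / (2(n-1))).  The sample mean
and SD are independent, dbar ~ N(mu_d, sd_d^2/n) and
s ~ sd_d * chi_{n-1} / sqrt(n-1), so the containment probability is
computed exactly by integrating the normal probability over the chi
density of s (Gauss–Legendre quadrature); a seeded Monte-Carlo oracle is
provided as an independent cross-check.

Two conventions for allocating the type II error across the two limits are
implemented:

* ``per-limit`` (default): each limit's CI must be contained with
  probability >= 1 - beta/2.  This matches the sample sizes produced by
  the medical-statistics calculators commonly cited for this design.
* ``joint``: both CIs contained simultaneously with probability
  >= 1 - beta (slightly smaller n).

Both sample sizes are reported on the result object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import GoalUnachievableError

__all__ = [
    "DesignParams",
    "SampleSizeResult",
    "containment_probability",
    "mc_containment_probability",
    "ba_sample_size",
]

_LOA_Z = stats.norm.ppf(0.975)  # 95% limits of agreement multiplier
_MIN_N = 3


@dataclass(frozen=True)
class DesignParams:
    """Inputs of the agreement-study sample-size calculation.

    mu_d / sd_d are the expected mean and SD of the paired differences,
    delta_max the maximum allowed difference between the methods.  The
    goal is only achievable when ``delta_max > |mu_d| + 1.96 sd_d``:
    otherwise even the true limits of agreement lie outside the allowed
    band and no n helps.
    """

    mu_d: float
    sd_d: float
    delta_max: float
    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_d <= 0:
            raise ValueError("sd_d must be positive")
        if not (0 < self.alpha < 0.5) or not (0 < self.beta < 0.5):
            raise ValueError("alpha and beta must lie in (0, 0.5)")
        if self.delta_max <= abs(self.mu_d) + _LOA_Z * self.sd_d:
            raise GoalUnachievableError(
                "goal-unachievable: delta_max <= |mu_d| + 1.96 sd_d, the true "
                "limits of agreement already exceed the allowed difference, "
                "so the containment probability cannot reach 1 - beta for any "
                "n (it tends to a value < 1 - beta as n -> infinity)"
            )


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimum n under the selected convention, with both variants reported."""

    n: int
    allocation: str
    n_per_limit: int
    n_joint: int
    power_at_n: float
    params: DesignParams


def _ci_multiplier(n: int, alpha: float) -> float:
    """Half-width of a LOA confidence interval, in units of the sample SD."""
    se_factor = np.sqrt(1.0 / n + _LOA_Z**2 / (2.0 * (n - 1)))
    return float(stats.t.ppf(1 - alpha / 2, n - 1) * se_factor)


def containment_probability(
    n: int, params: DesignParams, n_nodes: int = 400
) -> tuple[float, float, float]:
    """Exact (quadrature) containment probabilities at sample size n.

    Returns ``(p_lower, p_upper, p_joint)``: the probabilities that the CI
    of the lower limit stays above -delta_max, that the CI of the upper
    limit stays below +delta_max, and that both hold simultaneously.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    mu, sd, delta = params.mu_d, params.sd_d, params.delta_max
    nu = n - 1
    mult = _LOA_Z + _ci_multiplier(n, params.alpha)
    # integrate over the sampling distribution of s
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    s_hi = sd * (1.0 + 8.0 / np.sqrt(nu))  # far right tail of chi
    s = (nodes + 1.0) / 2.0 * s_hi
    w = weights * s_hi / 2.0
    pdf = stats.chi.pdf(s * np.sqrt(nu) / sd, nu) * np.sqrt(nu) / sd
    sem = sd / np.sqrt(n)
    # given s: upper bound inside iff dbar < delta - mult*s;
    #          lower bound inside iff dbar > -delta + mult*s
    p_up = stats.norm.cdf((delta - mult * s - mu) / sem)
    p_lo = 1.0 - stats.norm.cdf((-delta + mult * s - mu) / sem)
    p_joint = np.clip(p_up + p_lo - 1.0, 0.0, None)
    return (
        float(np.sum(w * pdf * p_lo)),
        float(np.sum(w * pdf * p_up)),
        float(np.sum(w * pdf * p_joint)),
    )


def mc_containment_probability(
    n: int,
    params: DesignParams,
    n_rep: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Monte-Carlo oracle for :func:`containment_probability`.

    Simulates ``n_rep`` studies of size n and counts how often each LOA
    confidence bound (and both together) stays inside +-delta_max.
    """
    mu, sd, delta = params.mu_d, params.sd_d, params.delta_max
    nu = n - 1
    rng = np.random.default_rng(seed)
    dbar = rng.normal(mu, sd / np.sqrt(n), size=n_rep)
    s = sd * np.sqrt(rng.chisquare(nu, size=n_rep) / nu)
    mult = _LOA_Z + _ci_multiplier(n, params.alpha)
    ok_up = dbar + mult * s < delta
    ok_lo = dbar - mult * s > -delta
    return (
        float(ok_lo.mean()),
        float(ok_up.mean()),
        float((ok_lo & ok_up).mean()),
    )


def _min_n(params: DesignParams, criterion, n_max: int) -> int:
    for n in range(_MIN_N, n_max + 1):
        if criterion(n):
            return n
    raise GoalUnachievableError(
        f"goal-unachievable: no n <= {n_max} satisfies the design goal"
    )


def ba_sample_size(
    params: DesignParams,
    beta_allocation: str = "per-limit",
    n_max: int = 100_000,
) -> SampleSizeResult:
    """Minimum sample size for the Bland–Altman agreement design.

    ``beta_allocation='per-limit'`` (default) requires each limit's CI to
    be contained with probability 1 - beta/2; ``'joint'`` requires both
    simultaneously with probability 1 - beta.  The minimum returned n is 3
    (a sample SD needs n >= 2, and the CI a little more than that to be
    meaningful).

    Both variants are computed and carried on the result.
    """
    if beta_allocation not in ("per-limit", "joint"):
        raise ValueError("beta_allocation must be 'per-limit' or 'joint'")
    beta = params.beta

    def crit_per_limit(n: int) -> bool:
        p_lo, p_up, _ = containment_probability(n, params)
        return min(p_lo, p_up) >= 1 - beta / 2

    def crit_joint(n: int) -> bool:
        return containment_probability(n, params)[2] >= 1 - beta

    n_per_limit = _min_n(params, crit_per_limit, n_max)
    n_joint = _min_n(params, crit_joint, n_max)
    n = n_per_limit if beta_allocation == "per-limit" else n_joint
    p_lo, p_up, p_joint = containment_probability(n, params)
    power = min(p_lo, p_up) if beta_allocation == "per-limit" else p_joint
    return SampleSizeResult(
        n=n,
        allocation=beta_allocation,
        n_per_limit=n_per_limit,
        n_joint=n_joint,
        power_at_n=power,
        params=params,
    )
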