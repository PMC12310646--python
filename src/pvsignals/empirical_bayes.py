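"""Bayesian shrinkage statistics for disproportionality analysis.

Two shrinkage estimators are implemented on top of the observed count ``a``
and its expectation under drug–event independence ``E = (a+b)(a+c)/N``:

* **MGPS** (multi-item gamma Poisson shrinker, DuMouchel 1999): the
  relative reporting rate λ of each cell is given a two-component gamma
  mixture prior whose five parameters (α₁, β₁, α₂, β₂, w) are fitted by
  maximum marginal likelihood over all cells of the drug×event grid — the
  marginal of a gamma-Poisson cell is negative binomial.  The per-cell
  posterior is again a two-component gamma mixture; EBGM is its geometric
  mean ``exp(E[log λ])`` and EB05 the 5th posterior percentile.

* **BCPNN information component**: IC = log₂ of the shrunken
  observed-to-expected ratio.  Two conventions are available: the
  closed-form Norén approximation ``IC = log2((a+0.5)/(E+0.5))`` with its
  credibility bound, and an EBGM-coupled convention ``IC = log2(EBGM)``
  with a normal-approximation lower bound, matching published tables in
  which IC and EBGM are two scales of one shrunken estimate.

All computations are deterministic; the prior fit uses a fixed start and a
bounded quasi-Newton optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "PriorParams",
    "PosteriorMixture",
    "ShrinkageResult",
    "CANONICAL_PRIOR_START",
    "expected_count",
    "fit_gamma_mixture_prior",
    "posterior",
    "compute_ebgm",
    "compute_eb05",
    "ebgm05_normal_approx",
    "compute_ic",
]

#: (alpha1, beta1, alpha2, beta2, w) — DuMouchel's canonical starting point
CANONICAL_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

_PARAM_BOUNDS = [(1e-4, 1e4)] * 4 + [(1e-4, 1 - 1e-4)]
_LN2 = math.log(2.0)


def expected_count(cell) -> float:
    """Expected report count under independence, ``E = (a+b)(a+c)/N``.

    ``cell`` is anything exposing integer attributes ``a, b, c, d``.
    """
    n = cell.a + cell.b + cell.c + cell.d
    if n <= 0:
        raise ValueError("contingency total N must be positive")
    return (cell.a + cell.b) * (cell.a + cell.c) / n


@dataclass(frozen=True)
class PriorParams:
    """Fitted two-component gamma mixture prior for λ."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes/rates must be positive")
        if not (0 < self.w <= 1):
            raise ValueError("mixture weight w must be in (0, 1]")

    @property
    def mean(self) -> float:
        """Prior mean of λ (mixture-weighted)."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha1": self.alpha1, "beta1": self.beta1,
            "alpha2": self.alpha2, "beta2": self.beta2,
            "w": self.w, "loglik": self.loglik,
        }


@dataclass(frozen=True)
class PosteriorMixture:
    """Per-cell posterior: mixture of Gamma(shape1, rate1), Gamma(shape2, rate2)."""

    q: float
    shape1: float
    rate1: float
    shape2: float
    rate2: float

    def __post_init__(self) -> None:
        if not (0 <= self.q <= 1):
            raise ValueError("posterior weight q must be in [0, 1]")

    def cdf(self, x: float) -> float:
        return self.q * stats.gamma.cdf(x, self.shape1, scale=1 / self.rate1) + (
            1 - self.q
        ) * stats.gamma.cdf(x, self.shape2, scale=1 / self.rate2)


@dataclass(frozen=True)
class ShrinkageResult:
    """EBGM/EB05 plus the information component in a stated convention."""

    ebgm: float
    ebgm05: float
    ic: float
    ic025: float
    convention: str = "noren"


def _mixture_nb_loglik(params: Sequence[float], a: np.ndarray, e: np.ndarray,
                       truncated: bool = False) -> float:
    """Log marginal likelihood of counts under the gamma-mixture prior.

    The marginal of Poisson(λE) with λ ~ Gamma(α, β) is NB(α, β/(β+E)).
    With ``truncated`` the likelihood conditions on a ≥ 1 (zero cells
    unobserved).
    """
    a1, b1, a2, b2, w = params
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    ll = np.logaddexp(math.log(w) + lp1, math.log1p(-w) + lp2)
    if truncated:
        lz1 = stats.nbinom.logpmf(0, a1, b1 / (b1 + e))
        lz2 = stats.nbinom.logpmf(0, a2, b2 / (b2 + e))
        lz = np.logaddexp(math.log(w) + lz1, math.log1p(-w) + lz2)
        ll = ll - np.log1p(-np.exp(lz))
    return float(np.sum(ll))


def fit_gamma_mixture_prior(
    cells: Iterable[tuple[float, float]],
    start: Sequence[float] = CANONICAL_PRIOR_START,
    truncated: bool = False,
) -> PriorParams:
    """Fit the five-parameter gamma-mixture prior by maximum likelihood.

    ``cells`` is an iterable of ``(a, E)`` pairs covering the whole
    drug×event grid (zero-count cells included, unless ``truncated`` fits
    on a ≥ 1 cells only).  Optimization is bounded L-BFGS-B from the
    canonical start; if the likelihood is non-finite there, a fixed
    log-spaced grid of restarts is tried in deterministic order.
    """
    arr = np.asarray(list(cells), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("cells must be a non-empty sequence of (a, E) pairs")
    a, e = arr[:, 0], arr[:, 1]
    if np.any(e <= 0):
        raise ValueError("all expected counts E must be positive")
    if truncated:
        keep = a >= 1
        a, e = a[keep], e[keep]
        if a.size == 0:
            raise ValueError("no cells with a >= 1 for truncated fit")

    def nll(p: np.ndarray) -> float:
        v = _mixture_nb_loglik(p, a, e, truncated)
        return -v if math.isfinite(v) else 1e12

    starts = [tuple(start)]
    if not math.isfinite(_mixture_nb_loglik(start, a, e, truncated)):
        grid = [10.0 ** k for k in (-2, -1, 0, 1)]
        starts = [(s1, s1, s2, s2, 0.5) for s1 in grid for s2 in grid]

    best = None
    for s in starts:
        res = optimize.minimize(nll, x0=np.asarray(s), method="L-BFGS-B",
                                bounds=_PARAM_BOUNDS)
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and math.isfinite(best.fun):
            break
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("gamma-mixture prior fit failed from all starts")
    a1, b1, a2, b2, w = best.x
    return PriorParams(a1, b1, a2, b2, w, loglik=-float(best.fun))


def posterior(a: float, e: float, prior: PriorParams) -> PosteriorMixture:
    """Conjugate posterior of λ given count ``a`` and expectation ``e``.

    The mixture weight updates by Bayes' rule over the two negative
    binomial marginals; each gamma component updates conjugately to
    ``Gamma(alpha + a, beta + E)``.
    """
    if e <= 0:
        raise ValueError("expected count E must be positive")
    if a < 0:
        raise ValueError("observed count a must be non-negative")
    if prior.w >= 1.0:
        q = 1.0
    else:
        lp1 = math.log(prior.w) + float(
            stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
        )
        lp2 = math.log1p(-prior.w) + float(
            stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
        )
        m = max(lp1, lp2)
        q = math.exp(lp1 - m) / (math.exp(lp1 - m) + math.exp(lp2 - m))
    return PosteriorMixture(
        q=q,
        shape1=prior.alpha1 + a,
        rate1=prior.beta1 + e,
        shape2=prior.alpha2 + a,
        rate2=prior.beta2 + e,
    )


def compute_ebgm(post: PosteriorMixture) -> float:
    """Posterior geometric mean of λ: ``exp(E[log λ])`` via digamma."""
    log_gm = post.q * (special.digamma(post.shape1) - math.log(post.rate1)) + (
        1 - post.q
    ) * (special.digamma(post.shape2) - math.log(post.rate2))
    return math.exp(log_gm)


def compute_eb05(post: PosteriorMixture, p: float = 0.05) -> float:
    """Exact p-quantile of the posterior mixture by root bracketing.

    Solves ``q F₁(x) + (1−q) F₂(x) = p`` to relative tolerance 1e−8; the
    bracket is the interval between the two component quantiles.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    q1 = float(stats.gamma.ppf(p, post.shape1, scale=1 / post.rate1))
    q2 = float(stats.gamma.ppf(p, post.shape2, scale=1 / post.rate2))
    if post.q >= 1.0:
        return q1
    if post.q <= 0.0:
        return q2
    lo, hi = min(q1, q2), max(q1, q2)
    if math.isclose(lo, hi, rel_tol=1e-12):
        return lo
    # the quantile lies between the component quantiles; guard the bracket
    # endpoints against rounding in the mixture CDF
    if post.cdf(lo) - p >= 0:
        return lo
    if post.cdf(hi) - p <= 0:
        return hi
    return float(optimize.brentq(lambda x: post.cdf(x) - p, lo, hi,
                                 rtol=1e-10, xtol=1e-300, maxiter=200))


def ebgm05_normal_approx(ebgm: float, a: float, z: float = 1.645) -> float:
    """Log-normal approximation to EB05: ``EBGM · exp(−z/√a)``.

    Reproduces published EBGM05 columns computed that way; NaN when a = 0.
    """
    if a <= 0:
        return math.nan
    return ebgm * math.exp(-z / math.sqrt(a))


def compute_ic(
    a: float,
    e: float,
    post: PosteriorMixture | None = None,
    convention: str = "noren",
    z: float = 1.96,
) -> tuple[float, float]:
    """Information component and its lower 2.5% bound.

    ``noren``: closed-form shrinkage IC = log2((a+0.5)/(E+0.5)) with the
    Norén credibility bound IC − 3.3(a+0.5)^{−1/2} − 2.0(a+0.5)^{−3/4}.

    ``ebgm_coupled``: IC = log2(EBGM) from the MGPS posterior (required),
    with normal-approximation bound IC − z/(√a·ln2); IC025 is NaN at a=0.
    """
    if convention == "noren":
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -0.75
        return ic, ic025
    if convention == "ebgm_coupled":
        if post is None:
            raise ValueError("ebgm_coupled IC requires the MGPS posterior")
        ic = math.log2(compute_ebgm(post))
        ic025 = ic - z / (math.sqrt(a) * _LN2) if a > 0 else math.nan
        return ic, ic025
    raise ValueError(f"unknown IC convention {convention!r}")


def shrinkage_statistics(
    a: float,
    e: float,
    prior: PriorParams,
    ic_convention: str = "noren",
    eb05_method: str = "exact",
) -> ShrinkageResult:
    """Convenience: full MGPS + IC chain for one cell."""
    post = posterior(a, e, prior)
    ebgm = compute_ebgm(post)
    if eb05_method == "exact":
        eb05 = compute_eb05(post)
    elif eb05_method == "normal_approx":
        eb05 = ebgm05_normal_approx(ebgm, a)
    else:
        raise ValueError(f"unknown eb05 method {eb05_method!r}")
    ic, ic025 = compute_ic(a, e, post, convention=ic_convention)
    return ShrinkageResult(ebgm=ebgm, ebgm05=eb05, ic=ic, ic025=ic025,
                          convention=ic_convention)
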