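"""Maximum-entropy machinery for size/degree distributions.

The stationary size distribution of the stable-size process maximizes
Gibbs-Shannon entropy subject to two constraints measured on the system:

* the mean log-size ``C = mean(ln n_i)`` — the log of the geometric mean
  of the urn sizes, which encodes the (stationary) sum of the per-urn
  one-step entropies up to an additive constant, and
* the mean size ``E = mean(n_i)``.

The constrained maximization yields a power law with exponential cutoff

    P(n) = K n^-(alpha+1) exp(-beta n),      n in [a0, inf),

where ``beta = 0`` gives the closed form ``alpha = 1/(C - ln a0)``, and
in general ``(alpha, beta)`` is found by a two-dimensional root solve of
the moment constraints (evaluated by adaptive quadrature).

Because the large-n Gaussian approximation of a binomial's entropy is
zero at n = 1, samples with many size-1 urns (high turnover) need a
corrected constraint ``C_corr`` in which the n = 1 term is replaced by
the exact-entropy ratio s(1,q)/s(2,q) (~0.6 over a wide q range) times
the n = 2 contribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "EntropySummary",
    "MaxEntSolution",
    "binomial_entropy_exact",
    "small_n_entropy_ratio",
    "per_urn_entropy",
    "compute_C",
    "compute_C_corrected",
    "entropy_summary",
    "alpha_from_C",
    "normalization_K",
    "density_moments",
    "solve_alpha_beta",
    "discrete_pmf",
    "solve_entropy_multiplier",
]

_LN2PIE = math.log(2.0 * math.pi * math.e)


@dataclass(frozen=True)
class EntropySummary:
    """Entropy constraint estimates from one size sample (all in nats)."""

    C_raw: float
    C_corr: float
    C_star: float
    n1_fraction: float
    ratio_small_n: float


@dataclass(frozen=True)
class MaxEntSolution:
    """Solution (alpha, beta, K) of the constrained entropy maximization."""

    alpha: float
    beta: float
    K: float
    lam: float
    a0: float
    implied_C: float
    implied_E: float

    def pdf(self, n):
        n = np.asarray(n, dtype=float)
        out = np.zeros_like(n)
        ok = n >= self.a0
        out[ok] = self.K * n[ok] ** -(self.alpha + 1.0) * np.exp(-self.beta * n[ok])
        return out


def binomial_entropy_exact(n: int, q: float) -> float:
    """Shannon entropy (nats) of Binomial(n, q) by direct summation.

    Uses the convention 0 ln 0 = 0; intended for small n where the
    Gaussian approximation fails.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if q in (0.0, 1.0):
        return 0.0
    k = np.arange(n + 1)
    p = stats.binom.pmf(k, n, q)
    return float(-np.sum(special.xlogy(p, p)))


def small_n_entropy_ratio(q: float) -> float:
    """Exact entropy ratio s(1, q) / s(2, q); ~0.6 for a wide range of q."""
    if not 0.0 < q < 1.0:
        raise ValueError("ratio undefined for degenerate q in {0, 1}")
    return binomial_entropy_exact(1, q) / binomial_entropy_exact(2, q)


def per_urn_entropy(n: float, q: float, mode: str = "shrink_only") -> float:
    """Large-n Gaussian entropy 0.5 ln(2 pi e sigma^2(n)) of one urn's step.

    sigma^2(n) = c(q) n, with c the per-ball variance coefficient:
    2q/(1+q)^2 when shrinking balances growth (case I), q(1-q) for pure
    binomial growth (case II).  The additive constant cancels in the
    entropy constraint C, so only the n-dependence is load-bearing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 0.5 * (_LN2PIE + math.log(_variance_coeff(q, mode) * n))


def compute_C(sizes) -> float:
    """Entropy constraint C = mean(ln n_i), the log geometric mean size."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty size sample")
    if (sizes < 1).any():
        raise ValueError("all sizes must be >= 1")
    return float(np.mean(np.log(sizes)))


def compute_C_corrected(sizes, q: float, mode: str = "exit_only") -> float:
    """Corrected constraint C_corr: fix the vanishing n = 1 contribution.

    On the ln-n scale used by ``compute_C``, an urn of size 2 contributes
    ln 2 and an urn of size 1 contributes 0, although its one-step
    distribution still carries entropy.  The exact small-n ratio
    r(q) = s(1,q)/s(2,q) restores it: size-1 urns contribute
    ``r(q) * ln 2`` instead of 0.  With no size-1 urns, C_corr = C_raw.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty size sample")
    if (sizes < 1).any():
        raise ValueError("all sizes must be >= 1")
    ratio = small_n_entropy_ratio(q)
    terms = np.log(sizes)
    terms[sizes == 1] = ratio * math.log(2.0)
    return float(np.mean(terms))


def entropy_summary(sizes, q: float, mode: str = "exit_only") -> EntropySummary:
    """Raw and corrected C plus the additive-constant variant C*."""
    sizes = np.asarray(sizes, dtype=float)
    C_raw = compute_C(sizes)
    C_corr = compute_C_corrected(sizes, q, mode)
    # C* keeps the additive Gaussian constant: mean of 0.5 ln(2 pi e sigma^2)
    C_star = float(
        np.mean(0.5 * (_LN2PIE + np.log(_variance_coeff(q, mode) * sizes)))
    )
    return EntropySummary(
        C_raw=C_raw,
        C_corr=C_corr,
        C_star=C_star,
        n1_fraction=float(np.mean(sizes == 1)),
        ratio_small_n=small_n_entropy_ratio(q),
    )


def _variance_coeff(q: float, mode: str) -> float:
    # case I: growth Bin(n, q) then thinning at q/(1+q) -> Var = 2q/(1+q)^2 n
    if mode in ("shrink_only", "mixed"):
        return 2.0 * q / (1.0 + q) ** 2
    if mode == "exit_only":
        return q * (1.0 - q)
    raise ValueError(f"unknown mode {mode!r}")


def alpha_from_C(C: float, a0: float = 1.0) -> float:
    """Closed-form exponent for beta = 0: alpha = 1 / (C - ln a0)."""
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    gap = C - math.log(a0)
    if gap <= 0:
        raise ValueError("infeasible constraint: need C > ln(a0)")
    return 1.0 / gap


def _raw_moments(alpha: float, beta: float, a0: float) -> tuple[float, float, float]:
    """Unnormalized moments (I0, I1, IL) of n^-(alpha+1) e^(-beta n) on [a0, inf).

    I0 = integral of the kernel, I1 = integral of n * kernel,
    IL = integral of ln(n) * kernel.  Adaptive quadrature with the
    integration split at a few multiples of max(a0, 1/beta) for
    stability; pure power-law closed forms are used when beta ~ 0.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta < 1e-12:
        if alpha <= 0:
            raise ValueError("non-normalizable: beta = 0 requires alpha > 0")
        I0 = a0 ** -alpha / alpha
        I1 = a0 ** (1.0 - alpha) / (alpha - 1.0) if alpha > 1 else math.inf
        IL = a0 ** -alpha * (math.log(a0) / alpha + 1.0 / alpha**2)
        return I0, I1, IL

    def kernel(n):
        return n ** -(alpha + 1.0) * math.exp(-beta * n)

    pts = sorted({a0 * 2, a0 * 10, 1.0 / beta, 10.0 / beta})
    pts = [p for p in pts if p > a0]

    def adaptive(f):
        total = 0.0
        lo = a0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            for p in pts:
                val, _ = integrate.quad(f, lo, p, epsabs=1e-12, epsrel=1e-10, limit=200)
                total += val
                lo = p
            val, _ = integrate.quad(f, lo, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200)
        return total + val

    I0 = adaptive(kernel)
    I1 = adaptive(lambda n: n * kernel(n))
    IL = adaptive(lambda n: math.log(n) * kernel(n))
    return I0, I1, IL


def normalization_K(alpha: float, beta: float, a0: float = 1.0) -> float:
    """Normalization constant of K n^-(alpha+1) e^(-beta n) on [a0, inf).

    Closed form K = alpha a0^alpha when beta = 0.
    """
    I0, _, _ = _raw_moments(alpha, beta, a0)
    if not np.isfinite(I0) or I0 <= 0:
        raise ValueError("non-normalizable parameter combination")
    return 1.0 / I0


def density_moments(alpha: float, beta: float, a0: float = 1.0) -> tuple[float, float]:
    """(C, E) implied by the density: (E[ln n], E[n])."""
    I0, I1, IL = _raw_moments(alpha, beta, a0)
    return IL / I0, I1 / I0


def solve_alpha_beta(
    C: float, E: float, a0: float = 1.0, x0: tuple[float, float] | None = None
) -> MaxEntSolution:
    """Solve the moment constraints E[ln n] = C, E[n] = E for (alpha, beta).

    A bounded least-squares root find over alpha in (0.01, 10),
    beta in [0, 10]; residuals are relative.  Raises if no root is found
    inside the box (round-trip residual above 1e-6).
    """
    if not C > math.log(a0):
        raise ValueError("infeasible: need C > ln(a0)")
    if not E > a0:
        raise ValueError("infeasible: need E > a0")

    def residuals(x):
        al, lb = x
        beta = math.exp(lb)
        try:
            c_imp, e_imp = density_moments(al, beta, a0)
        except (ValueError, OverflowError):
            return [10.0, 10.0]
        if not (np.isfinite(c_imp) and np.isfinite(e_imp)):
            return [10.0, 10.0]
        return [(c_imp - C) / max(abs(C), 1e-3), (e_imp - E) / E]

    if x0 is None:
        x0 = (max(alpha_from_C(C, a0), 0.05), 1.0 / E)
    guesses = [x0, (0.5, 0.01), (1.0, 0.1), (0.1, 1.0 / E)]
    best = None
    for al0, b0 in guesses:
        sol = optimize.least_squares(
            residuals,
            x0=[min(max(al0, 0.02), 9.5), math.log(max(b0, 1e-8))],
            bounds=([0.01, math.log(1e-10)], [10.0, math.log(10.0)]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-16:
            break
    alpha = float(best.x[0])
    beta = float(math.exp(best.x[1]))
    if beta < 1e-9:
        beta = 0.0
    c_imp, e_imp = density_moments(alpha, beta, a0)
    resid = max(abs(c_imp - C) / max(abs(C), 1e-3), abs(e_imp - E) / E)
    if resid > 1e-6:
        raise ValueError(
            f"no root in search box: residuals C={c_imp - C:.3g}, E={e_imp - E:.3g}"
        )
    return MaxEntSolution(
        alpha=alpha,
        beta=beta,
        K=normalization_K(alpha, beta, a0),
        lam=alpha + 1.0,
        a0=a0,
        implied_C=c_imp,
        implied_E=e_imp,
    )


def discrete_pmf(alpha: float, beta: float, a0: int = 1, n_max: int = 10**6) -> np.ndarray:
    """Discrete renormalization of the continuous law on {a0, ..., n_max}.

    Returns the pmf array indexed from a0 (element 0 is P(a0)).
    """
    n = np.arange(a0, n_max + 1, dtype=float)
    w = n ** -(alpha + 1.0) * np.exp(-beta * n)
    return w / w.sum()


def solve_entropy_multiplier(
    values: np.ndarray,
    entropies: np.ndarray,
    energies: np.ndarray,
    C: float,
    E: float,
) -> tuple[float, float, np.ndarray]:
    """Generic discrete maxent solve: P ∝ exp(-lam*s(v) - beta*eps(v)).

    Finds the multipliers (lam, beta) matching the constraints
    mean_P[s] = C and mean_P[eps] = E over the discretized support
    ``values``.  When the per-state entropies ``s`` are constant, the
    entropy constraint is satisfied for every lam and the solver returns
    lam ~ 0 (the constraint is inactive), which is the mechanism by
    which the Maxwell-Boltzmann distribution drops its entropy
    constraint while size-dependent processes keep it.
    """
    s = np.asarray(entropies, dtype=float)
    eps = np.asarray(energies, dtype=float)

    def pmf(lam, beta):
        logw = -lam * s - beta * eps
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def residuals(x):
        p = pmf(*x)
        return [float(p @ s - C), float((p @ eps - E) / max(abs(E), 1e-12))]

    sol = optimize.least_squares(residuals, x0=[0.0, 0.0], xtol=1e-15, ftol=1e-15)
    lam, beta = map(float, sol.x)
    return lam, beta, pmf(lam, beta)
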