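"""Individual and aggregate growth-rate distributions.

For a persisting urn of size ``n``, the one-step growth rate
``g = n_{t+1}/n_t`` is Gaussian with mean 1 and variance ``c/n`` (the
per-ball variance coefficient ``c`` follows from the binomial step
laws: ``c = q(1+q)`` in case I, ``q(1-q)`` in case II).  Pooling over
urns drawn from the stationary size law ``rho(n) ∝ n^-(alpha+1)
e^(-beta n)`` mixes Gaussians of very different widths and produces the
characteristic tent-shaped aggregate distribution; for ``alpha = 0.5``
and ``beta = 0`` the mixture has the closed form

    G(g) ∝ Gamma(0, n0 (g-1)^2 / (2c)),

an upper incomplete gamma function (the exponential integral E1),
which for ``c = 1`` reads ``Gamma(0, n0 (g-1)^2 / 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .entropy_maxent import normalization_K

__all__ = [
    "GrowthRateModel",
    "variance_coefficient",
    "individual_growth_pdf",
    "aggregate_growth_pdf",
    "closed_form_aggregate",
    "normalized_closed_form",
    "closed_form_cdf",
    "empirical_growth_rates",
]


@dataclass(frozen=True)
class GrowthRateModel:
    """Mixture model for the aggregate growth rate.

    ``c``: per-ball variance coefficient (sigma_g^2(n) = c/n);
    ``n0``: lower bound of the mixing size density;
    ``alpha, beta``: parameters of the stationary size law.
    """

    c: float = 1.0
    n0: float = 1.0
    alpha: float = 0.5
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.n0 < 1:
            raise ValueError("need c > 0 and n0 >= 1")


def variance_coefficient(q: float, mode: str = "shrink_only") -> float:
    """Per-ball variance coefficient c of the one-step size change.

    Case I (growth Bin(n, q) followed by thinning at the stationary
    shrink rate delta = q/(1+q)): Var = n [ (1-d)^2 q(1-q) + d(1-d)(1+q) ]
    = n 2q/(1+q)^2.  Case II (pure binomial growth): Var = n q(1-q).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if mode in ("shrink_only", "mixed"):
        return 2.0 * q / (1.0 + q) ** 2
    if mode == "exit_only":
        return q * (1.0 - q)
    raise ValueError(f"unknown mode {mode!r}")


def individual_growth_pdf(g, n: float, c: float):
    """Gaussian growth-rate density: mean 1, variance c/n."""
    if n <= 0 or c <= 0:
        raise ValueError("n and c must be positive")
    g = np.asarray(g, dtype=float)
    var = c / n
    return np.exp(-((g - 1.0) ** 2) / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def aggregate_growth_pdf(g, model: GrowthRateModel):
    """Aggregate growth-rate density: the size-mixture of Gaussians.

    G(g) = int_{n0}^inf G(g|n) rho(n) dn with rho the normalized
    power-law-with-cutoff size density; evaluated by adaptive
    quadrature.  Normalization in g is inherited from rho and G(g|n).
    """
    K = normalization_K(model.alpha, model.beta, model.n0)
    g_arr = np.atleast_1d(np.asarray(g, dtype=float))
    out = np.empty_like(g_arr)
    for i, gv in enumerate(g_arr):
        a = (gv - 1.0) ** 2 / (2.0 * model.c)

        def integrand(n):
            return (
                math.sqrt(n / (2.0 * math.pi * model.c))
                * math.exp(-n * a)
                * K
                * n ** -(model.alpha + 1.0)
                * math.exp(-model.beta * n)
            )

        total = 0.0
        lo = model.n0
        cuts = [model.n0 * 10]
        if a > 0:
            cuts += [1.0 / a, 10.0 / a]
        if model.beta > 0:
            cuts += [10.0 / model.beta]
        for p in sorted({cc for cc in cuts if cc > lo}):
            val, err = integrate.quad(integrand, lo, p, epsabs=1e-12, epsrel=1e-9, limit=200)
            total += val
            lo = p
        val, err = integrate.quad(integrand, lo, np.inf, epsabs=1e-12, epsrel=1e-9, limit=200)
        total += val
        out[i] = total
    return out if np.ndim(g) else float(out[0])


def closed_form_aggregate(g, n0: float = 1.0, c: float = 1.0):
    """Unnormalized closed form Gamma(0, n0 (g-1)^2 / (2c)) = E1(.).

    Diverges logarithmically at g = 1 (a ValueError is raised there).
    """
    g_arr = np.atleast_1d(np.asarray(g, dtype=float))
    x = n0 * (g_arr - 1.0) ** 2 / (2.0 * c)
    if (x == 0).any():
        raise ValueError("closed form diverges (logarithmically) at g = 1")
    out = special.exp1(x)
    return out if np.ndim(g) else float(out[0])


def _closed_form_norm(n0: float, c: float) -> float:
    # int E1(s u^2) du over u in (-inf, inf), s = n0/(2c):
    # = 2 * Gamma(3/2)/ (3/2 ... ) closed form: int_0^inf E1(s u^2) du
    # = sqrt(pi/s) * 2/2 ... evaluate numerically for robustness
    s = n0 / (2.0 * c)
    val, _ = integrate.quad(lambda u: special.exp1(s * u * u), 0, np.inf, limit=200)
    return 2.0 * val


def normalized_closed_form(g, n0: float = 1.0, c: float = 1.0):
    """Closed-form aggregate density normalized to unit mass in g."""
    return closed_form_aggregate(g, n0, c) / _closed_form_norm(n0, c)


def closed_form_cdf(g, n0: float = 1.0, c: float = 1.0):
    """CDF of the normalized closed form (for KS comparisons).

    Uses the antiderivative of E1: int E1(s u^2) du =
    u E1(s u^2) + sqrt(pi/s) erf(u sqrt(s)) (up to a constant).
    """
    s = n0 / (2.0 * c)
    g_arr = np.atleast_1d(np.asarray(g, dtype=float))
    u = g_arr - 1.0
    with np.errstate(invalid="ignore"):
        anti = u * special.exp1(s * u * u) + math.sqrt(math.pi / s) * special.erf(
            u * math.sqrt(s)
        )
    anti = np.where(u == 0.0, 0.0, anti)  # u E1 -> 0 as u -> 0
    total = 2.0 * (0.0 + math.sqrt(math.pi / s))  # limit of anti at +inf minus -inf
    cdf = (anti + math.sqrt(math.pi / s)) / total
    return cdf if np.ndim(g) else float(cdf[0])


def empirical_growth_rates(size_snapshots) -> np.ndarray:
    """Pooled growth rates g = n_t / n_{t-1} from consecutive snapshots.

    ``size_snapshots`` is either a sequence of aligned size vectors
    (with None entries, exited or replaced urns already excluded by the
    caller) or an (N, 2) array of persisting-urn pairs as produced by
    ``urn_process.run(collect_pairs=True)``.
    """
    arr = np.asarray(size_snapshots, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 1] / arr[:, 0]
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two snapshots or an (N, 2) pair array")
    g = arr[1:] / arr[:-1]
    return g.ravel()
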