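"""Estimators for the size-distribution parameters and fluctuation scaling.

``fit_powerlaw_cutoff`` fits the discrete law

    P(n) = n^-(alpha+1) exp(-beta n) / Z(alpha, beta),   n = a0, a0+1, ...

by maximum likelihood (the normalizing series is summed with a tail
bound; the Hurwitz zeta closed form is used at beta = 0).  Standard
errors come from the observed information, which for this exponential
family is ``N * Cov_Z[(ln n, n)]``.

``estimate_omega`` estimates the fluctuation-scaling exponent omega in
``sd(n_{t+1} - n_t | n_t = n) ∝ n^omega`` by geometric binning of
consecutive-size pairs and OLS of log bin standard deviation on log bin
center: 0.5 for binomial-type dynamics, 1 for multiplicative noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "FitResult",
    "OmegaEstimate",
    "fit_powerlaw_cutoff",
    "fit_powerlaw_cutoff_pmf",
    "estimate_omega",
    "log_binned_histogram",
]


@dataclass(frozen=True)
class FitResult:
    """MLE of (alpha, beta) with observed-information standard errors."""

    alpha_hat: float
    beta_hat: float
    stderr_alpha: float
    stderr_beta: float
    loglik: float
    n_samples: int
    a0: float
    at_boundary: bool = False


@dataclass(frozen=True)
class OmegaEstimate:
    """Fluctuation-scaling exponent from binned log-log regression."""

    omega_hat: float
    intercept: float
    r2: float
    n_bins: int


_SERIES_CAP = 200_000


def _log_partition_stats(alpha: float, beta: float, a0: int) -> tuple[float, float, float, float, float, float]:
    """(ln Z, E[ln n], E[n], Var[ln n], Var[n], Cov[ln n, n]) under Z.

    Sums the series in blocks until the term falls below 1e-16 of the
    running sum; if the cutoff has not localized the series within
    200 000 terms, the remaining tail (smooth and slowly varying there)
    is added as midpoint-rule integrals by adaptive quadrature.
    """
    if beta < 1e-12:
        if alpha <= 0.05:
            raise OverflowError("series diverges as beta -> 0 with alpha <= 0")
        lam = alpha + 1.0
        Z = special.zeta(lam, a0)
        h = 1e-5
        dZ = (special.zeta(lam + h, a0) - special.zeta(lam - h, a0)) / (2 * h)
        d2Z = (
            special.zeta(lam + h, a0) - 2 * Z + special.zeta(lam - h, a0)
        ) / h**2
        m_log = -dZ / Z
        v_log = d2Z / Z - m_log**2
        # E[n] may diverge (alpha <= 1); flagged as inf
        if alpha > 1.0:
            Z1 = special.zeta(lam - 1.0, a0)
            m_n = Z1 / Z
        else:
            m_n = math.inf
        return math.log(Z), m_log, m_n, v_log, math.inf, math.inf

    block = 4096
    start = a0
    S = Slog = Sn = Slog2 = Sn2 = Slogn = 0.0
    log_scale = -(alpha + 1.0) * math.log(a0) - beta * a0
    converged = False
    while start <= a0 + _SERIES_CAP:
        n = np.arange(start, start + block, dtype=float)
        logw = -(alpha + 1.0) * np.log(n) - beta * n
        w = np.exp(logw - log_scale)
        ln_n = np.log(n)
        S += w.sum()
        Slog += (w * ln_n).sum()
        Sn += (w * n).sum()
        Slog2 += (w * ln_n**2).sum()
        Sn2 += (w * n**2).sum()
        Slogn += (w * ln_n * n).sum()
        if w[-1] * n[-1] ** 2 < 1e-16 * max(S, 1e-300):
            converged = True
            break
        start += block

    if not converged:
        # midpoint-rule tail: sum_{n >= start} g(n) ~ int_{start - 1/2}^inf g
        lo = start - 0.5

        def tail(extra):
            def g(n):
                return math.exp(
                    -(alpha + 1.0) * math.log(n) - beta * n - log_scale + extra(n)
                )

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", integrate.IntegrationWarning)
                val, _ = integrate.quad(
                    g, lo, np.inf, epsabs=0.0, epsrel=1e-10, limit=400
                )
            return val

        S += tail(lambda n: 0.0)
        Slog += tail(lambda n: math.log(math.log(n)))
        Sn += tail(lambda n: math.log(n))
        Slog2 += tail(lambda n: 2.0 * math.log(math.log(n)))
        Sn2 += tail(lambda n: 2.0 * math.log(n))
        Slogn += tail(lambda n: math.log(n) + math.log(math.log(n)))

    m_log = Slog / S
    m_n = Sn / S
    return (
        math.log(S) + log_scale,
        m_log,
        m_n,
        Slog2 / S - m_log**2,
        Sn2 / S - m_n**2,
        Slogn / S - m_log * m_n,
    )


def fit_powerlaw_cutoff_pmf(
    values: np.ndarray,
    weights: np.ndarray,
    a0: int = 1,
    n_eff: int | None = None,
    fix_beta: float | None = None,
) -> FitResult:
    """Weighted discrete MLE of (alpha, beta) on (value, weight) pairs.

    ``weights`` may be counts or probabilities; ``n_eff`` sets the
    effective sample size used for standard errors (defaults to the
    weight total).  With ``fix_beta`` the cutoff is held fixed and only
    alpha is estimated (``fix_beta=0`` is the discrete Pareto MLE).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = values >= a0
    values, weights = values[keep], weights[keep]
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("no samples at or above a0")
    if np.unique(values).size < 2:
        raise ValueError("degenerate sample: all values equal")
    W = weights.sum()
    n_eff = int(round(W)) if n_eff is None else n_eff
    mean_log = float(weights @ np.log(values)) / W
    mean_n = float(weights @ values) / W

    def nll_grad(x):
        al, lb = x
        beta = math.exp(lb)
        try:
            lnZ, m_log, m_n, *_ = _log_partition_stats(al, beta, a0)
        except OverflowError:
            return 1e10, np.array([0.0, 0.0])
        val = lnZ + (al + 1.0) * mean_log + beta * mean_n
        if not np.isfinite(m_n):
            m_n = mean_n  # flat in beta at the boundary
        return val, np.array([mean_log - m_log, beta * (mean_n - m_n)])

    if fix_beta is not None:

        def nll_alpha(al):
            lnZ, m_log, *_ = _log_partition_stats(float(al[0]), fix_beta, a0)
            return lnZ + (al[0] + 1.0) * mean_log + fix_beta * mean_n, np.array(
                [mean_log - m_log]
            )

        res = optimize.minimize(
            nll_alpha,
            x0=[max(1.0 / max(mean_log, 0.05), 0.2)],
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.06, 10.0) if fix_beta < 1e-12 else (-2.0, 10.0)],
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
        )
        alpha, beta = float(res.x[0]), float(fix_beta)
        best = res
        at_boundary = False
    else:
        best = None
        for al0, b0 in [(max(1.0 / max(mean_log, 0.05), 0.2), 1.0 / mean_n), (0.5, 0.01)]:
            res = optimize.minimize(
                nll_grad,
                x0=[min(max(al0, -1.5), 9.5), math.log(b0)],
                jac=True,
                method="L-BFGS-B",
                bounds=[(-2.0, 10.0), (math.log(1e-10), math.log(5.0))],
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        alpha = float(best.x[0])
        beta = float(math.exp(best.x[1]))
        at_boundary = beta < 1e-8
        if at_boundary:
            beta = 0.0

    # observed information = n_eff * Cov_Z[(ln n, n)]
    _, _, _, v_log, v_n, cov = _log_partition_stats(alpha, max(beta, 1e-12), a0)
    if fix_beta is not None:
        stderr_alpha = math.sqrt(1.0 / (n_eff * v_log))
        stderr_beta = 0.0
        return FitResult(
            alpha_hat=alpha,
            beta_hat=beta,
            stderr_alpha=stderr_alpha,
            stderr_beta=stderr_beta,
            loglik=-best.fun * n_eff,
            n_samples=n_eff,
            a0=a0,
            at_boundary=at_boundary,
        )
    if not np.isfinite(v_n):
        stderr_alpha = math.sqrt(1.0 / (n_eff * v_log))
        stderr_beta = math.inf
    else:
        info = n_eff * np.array([[v_log, cov], [cov, v_n]])
        cov_mat = np.linalg.inv(info)
        stderr_alpha = math.sqrt(cov_mat[0, 0])
        stderr_beta = math.sqrt(cov_mat[1, 1])
    return FitResult(
        alpha_hat=alpha,
        beta_hat=beta,
        stderr_alpha=stderr_alpha,
        stderr_beta=stderr_beta,
        loglik=-best.fun * n_eff,
        n_samples=n_eff,
        a0=a0,
        at_boundary=at_boundary,
    )


def fit_powerlaw_cutoff(samples, a0: int = 1, fix_beta: float | None = None) -> FitResult:
    """Discrete MLE of (alpha, beta) from an integer size/degree sample.

    Only samples >= a0 enter the (conditional) likelihood.
    """
    samples = np.asarray(samples)
    if samples.size < 10:
        raise ValueError("need at least 10 samples")
    values, counts = np.unique(samples[samples >= a0], return_counts=True)
    return fit_powerlaw_cutoff_pmf(values, counts.astype(float), a0=a0, fix_beta=fix_beta)


def estimate_omega(
    pairs: np.ndarray,
    growth_factor: np.ndarray | float | None = None,
    ratio: float = 1.5,
    min_count: int = 30,
    min_bins: int = 5,
    min_size: float = 2.0,
) -> OmegaEstimate:
    """Fluctuation-scaling exponent from consecutive-size pairs.

    Pairs ``(n_t, n_{t+1})`` are binned geometrically by ``n_t``
    (bin-width ratio ``ratio``); within each bin the standard deviation
    of the change ``n_{t+1} - n_t`` is computed, bins with fewer than
    ``min_count`` pairs being merged upward; the slope of
    ``ln sd`` on ``ln`` (geometric bin center) is ``omega_hat``.

    ``growth_factor`` is the known conditional one-step growth factor
    f_t of the iteration each pair came from (per pair, or a scalar);
    when given, the change is measured about the conditional mean,
    ``n_{t+1} - f_t n_t``.  This matters for the adaptive stable-size
    process, where iteration-to-iteration fluctuations of the global
    rates (q_t, delta_shrink_t) would otherwise contaminate the
    conditional standard deviation with a component ∝ n.

    Pairs with ``n_t < min_size`` are dropped (default 2): at the
    reflecting boundary n = 1 the survivor-conditioned change is
    censored (units hitting zero are replaced and excluded), which
    deflates the measured sd there.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (N, 2) array")
    n_t, n_t1 = pairs[:, 0], pairs[:, 1]
    if (n_t <= 0).any():
        raise ValueError("sizes must be positive")
    if growth_factor is None:
        change = n_t1 - n_t
    else:
        change = n_t1 - np.asarray(growth_factor, dtype=float) * n_t
    keep = n_t >= min_size
    if not keep.any():
        raise ValueError("no pairs at or above min_size")
    n_t, change = n_t[keep], change[keep]
    log_n = np.log(n_t)
    n_edges = max(int(np.ceil((log_n.max() - log_n.min()) / math.log(ratio))), 1) + 1
    edges = log_n.min() + math.log(ratio) * np.arange(n_edges + 1)
    idx = np.clip(np.digitize(log_n, edges) - 1, 0, n_edges - 1)

    centers, sds = [], []
    pend_vals: list[np.ndarray] = []
    pend_logs: list[np.ndarray] = []
    for b in range(n_edges):
        sel = idx == b
        if not sel.any() and not pend_vals:
            continue
        pend_vals.append(change[sel])
        pend_logs.append(log_n[sel])
        vals = np.concatenate(pend_vals)
        if vals.size >= min_count:
            logs = np.concatenate(pend_logs)
            centers.append(logs.mean())
            sds.append(vals.std(ddof=1))
            pend_vals, pend_logs = [], []
    if len(centers) < min_bins:
        raise ValueError(f"only {len(centers)} occupied bins; need >= {min_bins}")
    x = np.asarray(centers)
    y = np.log(np.asarray(sds))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return OmegaEstimate(
        omega_hat=float(slope),
        intercept=float(intercept),
        r2=r2,
        n_bins=len(centers),
    )


def log_binned_histogram(
    samples, ratio: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-bin density estimate for double-logarithmic plots.

    Returns (geometric bin centers, densities); densities are counts
    normalized by total count and bin width, so sum(density * width) = 1.
    Empty bins are omitted.
    """
    samples = np.asarray(samples, dtype=float)
    if (samples <= 0).any():
        raise ValueError("samples must be positive")
    lo = samples.min()
    if samples.max() == lo:
        return np.array([lo]), np.array([1.0 / (lo * (ratio - 1.0))])
    n_bins = int(np.ceil(math.log(samples.max() / lo) / math.log(ratio))) + 1
    edges = lo * ratio ** np.arange(n_bins + 1)
    edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(samples, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / counts.sum() / widths
    keep = counts > 0
    return centers[keep], dens[keep]
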