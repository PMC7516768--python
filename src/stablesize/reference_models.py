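"""Reference systems that validate the entropy method independently.

Three classical processes exercise the same constrained entropy
maximization with different constraint structure:

* **Maxwell-Boltzmann**: particle velocities under an energy constraint
  only.  The per-particle one-step entropies are independent of the
  particle's own velocity, so the entropy-sum constraint is inactive
  (its multiplier vanishes) and a plain Gaussian results.
* **Yule / Barabasi-Albert**: a growing urn system (balls added
  preferentially, then a new size-1 urn).  The entropy-sum constraint
  is active but there is no mean-size constraint (the system grows), so
  the stationary law is a pure power law without cutoff.
* **Multiplicative noise**: the Kesten-type recursion n <- gamma*n +
  delta with mean-1 multiplicative noise.  Written additively, the
  noise term has sd ∝ n (omega = 1 fluctuation scaling), producing a
  power-law tail above a size threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .entropy_maxent import solve_entropy_multiplier

__all__ = [
    "ReferenceConfig",
    "MaxwellBoltzmannResult",
    "mep_gaussian_check",
    "simulate_yule",
    "simulate_multiplicative_noise",
]


@dataclass(frozen=True)
class ReferenceConfig:
    """Parameters for the reference-model simulators."""

    model: str = "multiplicative_noise"
    N_add: int = 10
    gamma_mean: float = 1.0
    gamma_sd: float = 0.1
    delta_add: float = 1.0
    n_reset: float = 1.0
    M: int = 10_000
    T: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("maxwell_boltzmann", "yule", "multiplicative_noise"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.N_add < 1:
            raise ValueError("N_add must be >= 1")
        if self.n_reset < 1:
            raise ValueError("n_reset must be >= 1")
        if self.gamma_mean != 1.0:
            raise ValueError("stationary operation requires gamma mean 1")


@dataclass(frozen=True)
class MaxwellBoltzmannResult:
    """Closed-form 1-D velocity law P(v) = K exp(-beta v^2) plus checks."""

    beta: float
    variance: float
    lambda_hat: float

    def pdf(self, v):
        v = np.asarray(v, dtype=float)
        return math.sqrt(self.beta / math.pi) * np.exp(-self.beta * v * v)


def mep_gaussian_check(beta: float, v_max: float = 12.0, n_grid: int = 4001) -> MaxwellBoltzmannResult:
    """Maximum-entropy velocity distribution under the energy constraint.

    The per-particle shock entropies do not depend on the particle's own
    velocity, so the entropy-sum constraint drops out of the
    maximization: the generic two-constraint solver returns a
    multiplier ``lambda_hat ~ 0`` for it, and the result is a centered
    Gaussian with variance 1/(2 beta).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    var = 1.0 / (2.0 * beta)
    scale = math.sqrt(var)
    v = np.linspace(-v_max * scale, v_max * scale, n_grid)
    entropies = np.ones_like(v)  # velocity-independent per-particle entropy
    energies = v * v
    lam, _, _ = solve_entropy_multiplier(
        v, entropies, energies, C=1.0, E=var
    )
    return MaxwellBoltzmannResult(beta=beta, variance=var, lambda_hat=lam)


def simulate_yule(config: ReferenceConfig) -> np.ndarray:
    """Yule process in discrete steps: N_add preferential balls, then a
    new size-1 urn; runs until M urns exist.  Returns the urn sizes.

    Preferential selection is implemented by keeping one entry per ball
    (choosing a uniform ball selects its urn with probability
    proportional to size), so the run is O(total balls).

    Seed configuration: two urns of one ball each.
    """
    rng = np.random.default_rng(config.seed)
    n_urns = config.M
    total_balls = 2 + (n_urns - 2) * (config.N_add + 1)
    owners = np.empty(total_balls, dtype=np.int64)
    owners[0], owners[1] = 0, 1
    n_balls = 2
    sizes = np.zeros(n_urns, dtype=np.int64)
    sizes[0] = sizes[1] = 1
    for new_urn in range(2, n_urns):
        # sequential preferential additions: each new ball is eligible
        # for subsequent picks within the same step
        for _ in range(config.N_add):
            urn = owners[int(rng.integers(0, n_balls))]
            owners[n_balls] = urn
            sizes[urn] += 1
            n_balls += 1
        owners[n_balls] = new_urn
        sizes[new_urn] = 1
        n_balls += 1
    return sizes


def simulate_multiplicative_noise(
    config: ReferenceConfig, pair_start: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Kesten recursion n <- gamma n + delta with reflection at 1.

    gamma is lognormal with mean 1 and standard deviation ``gamma_sd``
    (so the log-size drift is negative and a stationary heavy-tailed law
    exists); delta is uniform on [0, delta_add]; units falling below 1
    are reset to ``n_reset``.  Returns (final sizes, (n_t, n_{t+1})
    pairs pooled from iterations >= pair_start).
    """
    rng = np.random.default_rng(config.seed)
    sigma2 = math.log(1.0 + config.gamma_sd**2)
    mu_ln = -0.5 * sigma2
    n = np.full(config.M, float(config.n_reset))
    pairs = []
    for t in range(config.T):
        gamma = rng.lognormal(mu_ln, math.sqrt(sigma2), size=config.M)
        delta = rng.uniform(0.0, config.delta_add, size=config.M)
        n_next = gamma * n + delta
        reset = n_next < 1.0
        n_next[reset] = config.n_reset
        if t >= pair_start:
            keep = ~reset
            pairs.append(np.column_stack([n[keep], n_next[keep]]))
        if n_next.mean() > 1e9:
            raise RuntimeError(
                "divergence: reduce gamma_sd (the multiplicative noise variance)"
            )
        n = n_next
    pair_arr = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2))
    return n, pair_arr
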