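"""Exact stationary distribution of the single-urn size Markov chain.

With the growth probability ``q`` and shrink probability fixed at their
mean-field stationary values (``delta_shrink = q/(1+q)``, which makes
one grow-shrink cycle a per-urn martingale), the size of a single urn is
a Markov chain on the positive integers.  This module builds its exact
one-step transition law on a truncated support {1, ..., n_max} and
computes the stationary distribution by power iteration — an
independent, simulation-free route to the stationary size distribution
against which both the simulator and the maximum-entropy prediction can
be validated.

Transition structure per mode:

* ``shrink_only`` (case I): Binomial growth X ~ Bin(n, q) convolved
  with Binomial thinning Y ~ Bin(n + X, delta_shrink).
* ``exit_only`` (case II): with probability ``delta_exit`` the urn is
  replaced (size jumps to 1); otherwise it grows by X ~ Bin(n, q).
* ``mixed``: exit mass at 1 plus the grow-shrink composition.

Mass reaching size 0 is remapped to 1 (the replaced urn is "the same
urn"); mass above ``n_max`` is accumulated at ``n_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OracleConfig", "transition_matrix", "transition_pmf", "stationary_distribution"]


@dataclass(frozen=True)
class OracleConfig:
    """Parameters of the fixed-parameter single-urn chain."""

    n_max: int = 2000
    mode: str = "exit_only"
    q: float = 0.05
    delta_shrink: float | None = None
    delta_exit: float = 0.0
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_max < 50:
            raise ValueError("n_max must be >= 50")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.mode not in ("shrink_only", "exit_only", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("exit_only", "mixed") and not 0.0 <= self.delta_exit <= 1.0:
            raise ValueError("delta_exit must lie in [0, 1]")
        if self.delta_shrink is None:
            # mean-field stationary value: expected shrink cancels growth
            object.__setattr__(self, "delta_shrink", self.q / (1.0 + self.q))


def _growth_matrix(n_max: int, q: float) -> np.ndarray:
    """G[n-1, m]: probability that an urn of size n grows to size m = n + X."""
    sizes = np.arange(1, n_max + 1)
    m = np.arange(0, 2 * n_max + 1)
    # X = m - n, valid for 0 <= X <= n
    G = stats.binom.pmf(m[None, :] - sizes[:, None], sizes[:, None], q)
    return G


def _thinning_matrix(m_max: int, delta: float, j_max: int) -> np.ndarray:
    """B[m, j]: probability that m balls thin to j survivors, j <= j_max.

    Survivors ~ Bin(m, 1 - delta); mass with j > j_max is accumulated in
    the last column.
    """
    m = np.arange(0, m_max + 1)
    j = np.arange(0, j_max + 1)
    B = stats.binom.pmf(j[None, :], m[:, None], 1.0 - delta)
    # tail mass above j_max -> last column
    B[:, -1] += np.clip(1.0 - B.sum(axis=1), 0.0, None)
    return B


def transition_matrix(config: OracleConfig) -> np.ndarray:
    """Full one-step transition matrix T[n-1, n'-1] on {1, ..., n_max}."""
    n_max = config.n_max
    G = _growth_matrix(n_max, config.q)  # (n_max, 2*n_max+1)

    if config.mode == "exit_only":
        # no shrinking: post-growth size is the outcome
        law = G.copy()
    else:
        B = _thinning_matrix(2 * n_max, config.delta_shrink, n_max)  # (2n+1, n+1)
        law = G @ B  # (n_max, n_max + 1), columns are sizes 0..n_max
        # remap size 0 to 1 (replacement) and drop the 0 column
        law[:, 1] += law[:, 0]
        law = law[:, 1:]
        # extend to the exit-only column convention: columns = sizes 1..n_max
        full = np.zeros((n_max, n_max))
        full[:, : law.shape[1]] = law
        law = full

    if config.mode == "exit_only":
        # columns of G are sizes 0..2n_max; clip to 1..n_max with tail at n_max
        out = np.zeros((n_max, n_max))
        out[:, : n_max - 1] = law[:, 1:n_max]
        out[:, 0] += law[:, 0]  # size 0 cannot occur post-growth, kept for safety
        out[:, -1] += law[:, n_max:].sum(axis=1)
        law = out

    if config.mode in ("exit_only", "mixed"):
        law *= 1.0 - config.delta_exit
        law[:, 0] += config.delta_exit

    # numerical guard: renormalize rows (deviations are ~1e-15)
    law /= law.sum(axis=1, keepdims=True)
    return law


def transition_pmf(n: int, config: OracleConfig) -> np.ndarray:
    """One-iteration size distribution p(n' | n) over sizes 1..n_max."""
    if not 1 <= n <= config.n_max:
        raise ValueError(f"n must lie in [1, {config.n_max}]")
    return transition_matrix(config)[n - 1]


def stationary_distribution(
    config: OracleConfig, T: np.ndarray | None = None, max_iter: int = 10**6
) -> np.ndarray:
    """Stationary pmf over {1, ..., n_max} by deterministic power iteration.

    Starts from the uniform distribution and iterates ``p <- p T`` until
    the total-variation change drops below ``config.tol``.
    """
    if T is None:
        T = transition_matrix(config)
    p = np.full(config.n_max, 1.0 / config.n_max)
    for _ in range(max_iter):
        p_next = p @ T
        p_next /= p_next.sum()
        if 0.5 * np.abs(p_next - p).sum() < config.tol:
            return p_next
        p = p_next
    raise RuntimeError("power iteration did not converge")
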