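"""Discrete-time simulator of the stable-size urn/ball process.

A system of ``M`` urns holds a fluctuating total of ``N`` balls.  One
iteration consists of four sub-steps:

1. *Growth*: every ball attracts a new ball with probability ``q_t``
   (urn ``i`` gains ``X_i ~ Binomial(n_i, q_t)``).
2. *Shrink*: every ball vanishes with probability
   ``delta_shrink_t = sum(X) / (N_t + sum(X))``, chosen so the expected
   post-shrink total equals the pre-growth total.
3. *Exit*: every urn is emptied (set to size 0) with probability
   ``delta_exit``.
4. *Replace*: empty urns are refilled with a single ball, so the urn
   count ``M`` is strictly conserved while ``N_t`` fluctuates around its
   initial value.

``q_t`` is re-adjusted after each iteration so the expected total after
growth is always ``N_0 (1 + q_0)``, which makes the total ball count
stationary and the expected one-step size change of a persisting urn
zero (a martingale per urn).

Three limiting cases are exposed as modes: ``shrink_only`` (case I, no
urn exit), ``exit_only`` (case II, no shrinking) and ``mixed``
(case III).  The fraction of removed balls attributable to urn exit is
the turnover rate ``mu``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Mode",
    "ProcessConfig",
    "UrnState",
    "IterationOutcome",
    "TurnoverSummary",
    "RunResult",
    "grow_step",
    "shrink_step",
    "exit_step",
    "replace_step",
    "update_q",
    "iterate",
    "run",
    "measure_turnover",
]

_Q_EPS = 1e-6


class Mode(str, Enum):
    """Which ball-removal mechanisms are active."""

    shrink_only = "shrink_only"
    exit_only = "exit_only"
    mixed = "mixed"


@dataclass(frozen=True)
class ProcessConfig:
    """Full parameterization of one urn-process run.

    Parameters
    ----------
    M : int
        Number of urns (strictly conserved).
    N0 : int
        Initial total number of balls; the mean urn size is ``E = N0/M``.
    q0 : float
        Initial per-ball attraction probability, in (0, 1).
    delta_exit : float
        Per-iteration urn exit probability (step 3), in [0, 1].
    mode : Mode
        Which removal mechanisms operate.
    T : int
        Number of recorded iterations.
    burn_in : int
        Iterations discarded before recording starts.
    seed : int
        Seed for the process RNG.
    thin : int
        Record a size snapshot every ``thin`` recorded iterations
        (reduces autocorrelation in pooled samples).
    adaptive : bool
        If True (default) ``q_t`` follows the global adjustment rule and
        ``delta_shrink_t`` is recomputed from each iteration's gains.
        If False, ``q`` is held at ``q0`` and the shrink probability at
        ``q0/(1+q0)``, which decouples the urns into independent
        single-urn Markov chains (the regime the exact oracle solves).
    """

    M: int
    N0: int
    q0: float
    delta_exit: float = 0.0
    mode: Mode = Mode.shrink_only
    T: int = 1000
    burn_in: int = 0
    seed: int = 0
    thin: int = 10
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        if self.N0 < self.M:
            raise ValueError("N0 must be >= M (every urn holds >= 1 ball)")
        if not 0.0 < self.q0 < 1.0:
            raise ValueError("q0 must lie in (0, 1)")
        if not 0.0 <= self.delta_exit <= 1.0:
            raise ValueError("delta_exit must lie in [0, 1]")
        mode = Mode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is Mode.shrink_only and self.delta_exit != 0.0:
            raise ValueError("shrink_only mode requires delta_exit = 0")
        if self.T < 0 or self.burn_in < 0:
            raise ValueError("T and burn_in must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def mean_size(self) -> float:
        return self.N0 / self.M

    @classmethod
    def from_mean_size(cls, M: int, E: float, **kwargs) -> "ProcessConfig":
        """Build a config from the mean urn size ``E`` (``N0 = M*E``)."""
        return cls(M=M, N0=int(round(M * E)), **kwargs)


@dataclass
class UrnState:
    """Sizes of the ``M`` urns plus the bookkeeping scalars ``q_t, N_t``."""

    sizes: np.ndarray
    t: int
    q_t: float
    N_t: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1:
            raise ValueError("sizes must be a 1-D vector")

    def validate(self) -> None:
        if (self.sizes < 1).any():
            raise ValueError("all urn sizes must be >= 1 at iteration boundaries")
        if int(self.sizes.sum()) != self.N_t:
            raise ValueError("N_t must equal sum(sizes)")


@dataclass
class IterationOutcome:
    """Per-iteration tallies: gains X_i, losses Y_i and turnover bookkeeping."""

    gains: np.ndarray
    losses: np.ndarray
    exited_ids: np.ndarray
    n_replaced: int
    delta_shrink_t: float
    balls_removed_by_shrink: int
    balls_removed_by_exit: int


@dataclass(frozen=True)
class TurnoverSummary:
    """Turnover rate ``mu`` and related per-run ball-flow averages."""

    mu: float
    delta_exit_balls: float
    mean_size: float
    median_size: float


@dataclass
class RunResult:
    """Everything a run produces: final state, outcomes, samples, pairs."""

    state: UrnState
    outcomes: list
    size_samples: np.ndarray
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    trajectory: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    # conditional one-step growth factor (1+q_t)(1-delta_shrink_t) of the
    # iteration each pair was recorded in; n_{t+1} - f * n_t is the
    # fluctuation whose sd scales as n^omega
    pair_growth_factor: np.ndarray = field(default_factory=lambda: np.empty(0))


def grow_step(state: UrnState, rng: np.random.Generator) -> tuple[UrnState, np.ndarray]:
    """Step 1: each urn gains ``X_i ~ Binomial(n_i, q_t)`` balls."""
    if not 0.0 < state.q_t < 1.0:
        raise ValueError(f"q_t must lie in (0, 1), got {state.q_t}")
    gains = rng.binomial(state.sizes, state.q_t)
    new = UrnState(state.sizes + gains, state.t, state.q_t, state.N_t)
    return new, gains


def shrink_step(
    state: UrnState,
    gains: np.ndarray,
    rng: np.random.Generator,
    mode: Mode = Mode.shrink_only,
    delta_shrink: float | None = None,
    N_target: int | None = None,
) -> tuple[UrnState, np.ndarray, float]:
    """Step 2: every ball vanishes with probability ``delta_shrink_t``.

    The probability is chosen so the expected post-shrink total equals
    the conserved total ``N_target`` (the run's initial ``N0``):
    ``delta = (N_t + sum(X) - N_target) / (N_t + sum(X))``, which is the
    mean-reverting generalization of ``sum(X) / (N_t + sum(X))`` (the
    two coincide when ``N_t = N_target``; with no target the pre-growth
    total is restored).  A fixed ``delta_shrink`` may be supplied for
    the decoupled (non-adaptive) regime.
    """
    mode = Mode(mode)
    if mode is Mode.exit_only:
        raise ValueError("shrink_step is disabled in exit_only mode")
    total_gain = int(np.sum(gains))
    if delta_shrink is None:
        target = state.N_t if N_target is None else N_target
        post_growth = state.N_t + total_gain
        delta_shrink = max(0.0, (post_growth - target) / post_growth) if post_growth else 0.0
    losses = (
        rng.binomial(state.sizes, delta_shrink) if delta_shrink > 0 else np.zeros_like(state.sizes)
    )
    new = UrnState(state.sizes - losses, state.t, state.q_t, state.N_t)
    return new, losses, delta_shrink


def exit_step(
    state: UrnState, delta_exit: float, rng: np.random.Generator
) -> tuple[UrnState, np.ndarray]:
    """Step 3: each urn is independently emptied with probability ``delta_exit``."""
    if not 0.0 <= delta_exit <= 1.0:
        raise ValueError("delta_exit must lie in [0, 1]")
    mask = rng.random(state.sizes.shape[0]) < delta_exit
    sizes = state.sizes.copy()
    sizes[mask] = 0
    return UrnState(sizes, state.t, state.q_t, state.N_t), np.flatnonzero(mask)


def replace_step(state: UrnState) -> tuple[UrnState, int]:
    """Step 4: refill every empty urn with one ball; ``M`` is conserved."""
    sizes = state.sizes.copy()
    zero = sizes == 0
    n_replaced = int(zero.sum())
    sizes[zero] = 1
    return UrnState(sizes, state.t, state.q_t, state.N_t), n_replaced


def update_q(N_t: int, config: ProcessConfig) -> float:
    """Adjust q so the expected total after growth is ``N0 (1 + q0)``.

    ``q_{t+1} = N0 (1 + q0) / N_t - 1``, clamped into ``(0, 1)``; the
    clamp only engages after extreme fluctuations of ``N_t``.
    """
    if N_t <= 0:
        raise ValueError("degenerate state: N_t must be positive")
    q = config.N0 * (1.0 + config.q0) / N_t - 1.0
    if not _Q_EPS <= q <= 1.0 - _Q_EPS:
        # constant message so the default warning filter shows it once
        warnings.warn(
            "adjusted q fell outside (0,1) after a large fluctuation of N_t; "
            "clamping to preserve the mean-reversion intent",
            RuntimeWarning,
            stacklevel=2,
        )
        q = min(max(q, _Q_EPS), 1.0 - _Q_EPS)
    return q


def iterate(
    state: UrnState, config: ProcessConfig, rng: np.random.Generator
) -> tuple[UrnState, IterationOutcome]:
    """One full iteration of steps 1-4 plus the q adjustment."""
    mode = config.mode
    pre_exit_sizes = None

    state, gains = grow_step(state, rng)
    if mode is Mode.exit_only:
        losses = np.zeros_like(gains)
        delta_shrink_t = 0.0
    else:
        fixed = None if config.adaptive else config.q0 / (1.0 + config.q0)
        target = config.N0 if config.adaptive else None
        state, losses, delta_shrink_t = shrink_step(state, gains, rng, mode, fixed, target)

    if mode is Mode.shrink_only:
        exited = np.empty(0, dtype=np.int64)
    else:
        pre_exit_sizes = state.sizes.copy()
        state, exited = exit_step(state, config.delta_exit, rng)

    balls_by_exit = 0
    if exited.size:
        balls_by_exit = int(pre_exit_sizes[exited].sum())
    balls_by_shrink = int(losses.sum())

    state, n_replaced = replace_step(state)
    N_next = int(state.sizes.sum())
    q_next = update_q(N_next, config) if config.adaptive else config.q0
    new_state = UrnState(state.sizes, state.t + 1, q_next, N_next)

    outcome = IterationOutcome(
        gains=gains,
        losses=losses,
        exited_ids=exited,
        n_replaced=n_replaced,
        delta_shrink_t=delta_shrink_t,
        balls_removed_by_shrink=balls_by_shrink,
        balls_removed_by_exit=balls_by_exit,
    )
    return new_state, outcome


def initial_state(config: ProcessConfig) -> UrnState:
    """All urns start at ``round(N0/M)`` balls; transients are discarded
    by ``burn_in`` and the stationary law does not depend on this choice."""
    size0 = max(1, int(round(config.N0 / config.M)))
    sizes = np.full(config.M, size0, dtype=np.int64)
    return UrnState(sizes, 0, config.q0, int(sizes.sum()))


def run(config: ProcessConfig, collect_pairs: bool = False) -> RunResult:
    """Run ``burn_in + T`` iterations and collect post-burn-in snapshots.

    Size snapshots are pooled every ``config.thin`` recorded iterations.
    With ``collect_pairs=True``, consecutive-size pairs ``(n_t, n_{t+1})``
    are recorded for *persisting* urns only — urns that exited or were
    replaced (shrunk to zero) between the two snapshots are excluded, as
    the one-step fluctuation law is defined only for survivors.
    """
    rng = np.random.default_rng(config.seed)
    state = initial_state(config)
    outcomes: list[IterationOutcome] = []
    samples: list[np.ndarray] = []
    pairs: list[np.ndarray] = []
    factors: list[np.ndarray] = []
    traj = np.empty((config.T, 3))

    for k in range(config.burn_in):
        state, _ = iterate(state, config, rng)

    for k in range(config.T):
        prev_sizes = state.sizes.copy()
        q_pre = state.q_t
        state, outcome = iterate(state, config, rng)
        outcomes.append(outcome)
        traj[k] = (state.t, state.N_t, state.q_t)
        if k % config.thin == 0:
            samples.append(state.sizes.copy())
        if collect_pairs:
            persisted = np.ones(config.M, dtype=bool)
            persisted[outcome.exited_ids] = False
            # replacement resets to size 1; a persisting urn at size 1 is
            # indistinguishable in the size vector, so flag via losses:
            replaced = (prev_sizes + outcome.gains - outcome.losses) == 0
            persisted &= ~replaced
            pairs.append(
                np.column_stack([prev_sizes[persisted], state.sizes[persisted]])
            )
            f = (1.0 + q_pre) * (1.0 - outcome.delta_shrink_t)
            factors.append(np.full(int(persisted.sum()), f))

    size_samples = (
        np.concatenate(samples) if samples else np.empty(0, dtype=np.int64)
    )
    pair_arr = (
        np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
    )
    factor_arr = np.concatenate(factors) if factors else np.empty(0)
    return RunResult(state, outcomes, size_samples, pair_arr, traj, factor_arr)


def measure_turnover(
    outcomes: list, sizes: np.ndarray
) -> TurnoverSummary:
    """Turnover rate ``mu``: fraction of removed balls due to urn exit.

    ``mu = exit_balls / (exit_balls + shrink_balls)`` totalled over the
    recorded iterations; ``delta_exit_balls`` is the mean per-iteration
    fraction of balls removed by exit.
    """
    if not outcomes:
        raise ValueError("at least one iteration is required")
    exit_balls = sum(o.balls_removed_by_exit for o in outcomes)
    shrink_balls = sum(o.balls_removed_by_shrink for o in outcomes)
    total = exit_balls + shrink_balls
    if total == 0:
        raise ValueError("no balls were removed; turnover undefined")
    sizes = np.asarray(sizes)
    mean_size = float(sizes.mean())
    n_balls_mean = mean_size * len(outcomes[0].gains)
    return TurnoverSummary(
        mu=exit_balls / total,
        delta_exit_balls=exit_balls / (len(outcomes) * n_balls_mean),
        mean_size=mean_size,
        median_size=float(np.median(sizes)),
    )
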