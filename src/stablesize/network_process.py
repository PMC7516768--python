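"""Network analogue of the stable-size process.

``M`` nodes are connected by ``N`` undirected, unweighted edges; degree
plays the role of urn size.  One iteration consists of

1-2. *Rewiring*: a uniformly random edge is broken; a receiver ``i`` is
     picked with probability proportional to its degree, and a new
     neighbor ``j`` (not already adjacent to ``i``) likewise — both
     preferential.  The edge count is unchanged.
3.   *Exit*: nodes exit (rate ``delta_exit``, or deterministically at a
     given lifespan) and all their edges are broken.
4.   *Entry*: exited nodes re-enter with exactly one edge to a
     preferentially chosen neighbor; further preferential edges are
     added until the edge count is restored to ``N``.

Because an exiting node's broken edges always also remove degree from
surviving nodes (one edge end each), at most half of the removed edge
ends can be attributed to exit, so the turnover rate is bounded by
``mu <= 0.5`` — which is why the network variant always carries an
exponential degree cutoff.

Degree-proportional sampling is done by picking a uniform end of a
uniform edge, which is O(1) per draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .urn_process import TurnoverSummary

logger = logging.getLogger(__name__)

__all__ = ["NetworkConfig", "NetworkState", "rewire_step", "node_exit_step",
           "node_entry_step", "run_network", "NetworkRunResult"]

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of one network-process run."""

    M: int
    N: int
    delta_exit: float = 0.0
    exit_rule: str = "rate"
    lifespan: int = 0
    rewires_per_iteration: int | None = None
    T: int = 1000
    burn_in: int = 0
    seed: int = 0
    thin: int = 10

    def __post_init__(self) -> None:
        if self.M < 3 or self.N < 1:
            raise ValueError("need M >= 3 and N >= 1")
        if 2 * self.N < self.M:
            raise ValueError("need N >= M/2 so every node can hold an edge")
        if self.N > self.M * (self.M - 1) // 2:
            raise ValueError("N exceeds the simple-graph maximum")
        if self.exit_rule not in ("rate", "lifespan"):
            raise ValueError("exit_rule must be 'rate' or 'lifespan'")
        if self.exit_rule == "lifespan" and self.lifespan < 1:
            raise ValueError("lifespan exit rule needs lifespan >= 1")
        if not 0.0 <= self.delta_exit <= 1.0:
            raise ValueError("delta_exit must lie in [0, 1]")
        if self.rewires_per_iteration is None:
            # rewiring and turnover on comparable timescales
            object.__setattr__(
                self, "rewires_per_iteration", max(1, self.N // 10)
            )


@dataclass
class NetworkState:
    """Simple graph as an edge array plus adjacency sets and node ages."""

    edges: list
    adj: list
    degrees: np.ndarray
    ages: np.ndarray
    t: int = 0

    @classmethod
    def random_graph(cls, M: int, N: int, rng: np.random.Generator) -> "NetworkState":
        """Start from a ring (guaranteeing connectivity of degrees >= 1)
        plus uniformly random extra edges up to N."""
        adj = [set() for _ in range(M)]
        edges: list[tuple[int, int]] = []

        def add(u, v):
            adj[u].add(v)
            adj[v].add(u)
            edges.append((u, v))

        for u in range(min(M, N)):
            add(u, (u + 1) % M)
        while len(edges) < N:
            u, v = rng.integers(0, M, size=2)
            if u != v and v not in adj[u]:
                add(int(u), int(v))
        degrees = np.array([len(a) for a in adj], dtype=np.int64)
        return cls(edges, adj, degrees, np.zeros(M, dtype=np.int64))

    def check_invariants(self) -> None:
        assert int(self.degrees.sum()) == 2 * len(self.edges)
        for u, v in self.edges:
            assert u != v and v in self.adj[u] and u in self.adj[v]


def _preferential_node(state: NetworkState, rng: np.random.Generator) -> int:
    """Uniform end of a uniform edge = node sampled with prob ∝ degree.

    Falls back to a uniform node if the graph is momentarily edgeless
    (possible only when every node exits in the same iteration).
    """
    if not state.edges:
        return int(rng.integers(len(state.adj)))
    e = state.edges[rng.integers(len(state.edges))]
    return e[rng.integers(2)]


def _remove_edge_at(state: NetworkState, k: int) -> tuple[int, int]:
    u, v = state.edges[k]
    state.edges[k] = state.edges[-1]
    state.edges.pop()
    state.adj[u].discard(v)
    state.adj[v].discard(u)
    state.degrees[u] -= 1
    state.degrees[v] -= 1
    return u, v


def _add_edge(state: NetworkState, u: int, v: int) -> None:
    state.edges.append((u, v))
    state.adj[u].add(v)
    state.adj[v].add(u)
    state.degrees[u] += 1
    state.degrees[v] += 1


def rewire_step(state: NetworkState, rng: np.random.Generator) -> NetworkState:
    """Break one random edge; re-create one edge between preferential i, j."""
    if not state.edges:
        raise ValueError("rewire_step requires at least one edge")
    for _ in range(_MAX_RESAMPLE):
        k = int(rng.integers(len(state.edges)))
        u, v = _remove_edge_at(state, k)
        for _ in range(_MAX_RESAMPLE):
            i = _preferential_node(state, rng)
            j = _preferential_node(state, rng)
            if i != j and j not in state.adj[i]:
                _add_edge(state, i, j)
                return state
        # no feasible (i, j): restore the broken edge and resample it
        _add_edge(state, u, v)
        logger.debug("rewire: no feasible pair, resampling broken edge")
    raise RuntimeError("rewire_step: bounded resampling exhausted")


def node_exit_step(
    state: NetworkState, config: NetworkConfig, rng: np.random.Generator
) -> tuple[NetworkState, np.ndarray, int]:
    """Exit nodes per the configured rule; break all of their edges.

    Returns the exited ids and the number of broken edges.  Survivor
    ages are incremented; exiting nodes restart at age 0.
    """
    M = len(state.adj)
    if config.exit_rule == "rate":
        mask = rng.random(M) < config.delta_exit
    else:
        mask = state.ages >= config.lifespan - 1
    exited = np.flatnonzero(mask)
    exited_set = set(exited.tolist())
    broken = 0
    if exited_set:
        kept = []
        for u, v in state.edges:
            if u in exited_set or v in exited_set:
                state.adj[u].discard(v)
                state.adj[v].discard(u)
                state.degrees[u] -= 1
                state.degrees[v] -= 1
                broken += 1
            else:
                kept.append((u, v))
        state.edges = kept
    state.ages += 1
    state.ages[exited] = 0
    return state, exited, broken


def node_entry_step(
    state: NetworkState,
    config: NetworkConfig,
    rng: np.random.Generator,
    exited: np.ndarray,
) -> NetworkState:
    """Re-introduce exited (and stranded degree-0) nodes, restore N edges.

    Each re-entering node receives exactly one edge to a preferentially
    chosen neighbor; remaining edges are added between preferential
    non-adjacent pairs until the edge count is back to N.
    """
    # degree-0 survivors are re-linked like re-entering nodes
    zero = np.flatnonzero(state.degrees == 0)
    for u in zero:
        for _ in range(_MAX_RESAMPLE):
            j = _preferential_node(state, rng)
            if j != u and j not in state.adj[u]:
                _add_edge(state, int(u), j)
                break
        else:
            raise RuntimeError("node_entry_step: could not link re-entering node")
    deficit = config.N - len(state.edges)
    for _ in range(deficit):
        for _ in range(_MAX_RESAMPLE):
            i = _preferential_node(state, rng)
            j = _preferential_node(state, rng)
            if i != j and j not in state.adj[i]:
                _add_edge(state, i, j)
                break
        else:
            raise RuntimeError("node_entry_step: could not restore edge count")
    return state


@dataclass
class NetworkRunResult:
    state: NetworkState
    degree_samples: np.ndarray
    turnover: TurnoverSummary
    mu_per_iteration: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_network(config: NetworkConfig) -> NetworkRunResult:
    """Run the network process and pool post-burn-in degree snapshots.

    The turnover rate mu is the fraction of removed edge ends that sat
    on exiting nodes, out of all edge ends removed in the iteration
    (exit-broken edges contribute one exit end and, unless both
    endpoints exit, one survivor end; rewired edges contribute two
    survivor ends).
    """
    rng = np.random.default_rng(config.seed)
    state = NetworkState.random_graph(config.M, config.N, rng)
    if config.exit_rule == "lifespan":
        # stagger ages so cohorts of ~M/lifespan nodes exit per iteration
        state.ages = rng.integers(0, config.lifespan, size=config.M)

    exit_ends_total = 0
    all_ends_total = 0
    mus = []
    samples: list[np.ndarray] = []

    for it in range(config.burn_in + config.T):
        recording = it >= config.burn_in
        for _ in range(config.rewires_per_iteration):
            rewire_step(state, rng)
        deg_before = state.degrees.copy()
        state, exited, broken = node_exit_step(state, config, rng)
        exit_ends = int(deg_before[exited].sum())
        total_ends = 2 * broken + 2 * config.rewires_per_iteration
        state = node_entry_step(state, config, rng, exited)
        state.t += 1
        if recording:
            if total_ends:
                exit_ends_total += exit_ends
                all_ends_total += total_ends
                mus.append(exit_ends / total_ends)
            k = it - config.burn_in
            if k % config.thin == 0:
                samples.append(state.degrees.copy())

    degree_samples = (
        np.concatenate(samples) if samples else np.empty(0, dtype=np.int64)
    )
    degrees = state.degrees
    turnover = TurnoverSummary(
        mu=exit_ends_total / all_ends_total if all_ends_total else 0.0,
        delta_exit_balls=exit_ends_total / max(1, config.T * 2 * config.N),
        mean_size=float(degrees.mean()),
        median_size=float(np.median(degrees)),
    )
    return NetworkRunResult(state, degree_samples, turnover, np.asarray(mus))
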