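"""Agent-based evolutionary simulation on arbitrary interaction graphs.

Each node holds one of the six strategies.  Per step, every agent plays
the full iterated encounter with each neighbour (payoffs enter as the
per-encounter round averages, summed over neighbours) and then, in the
synchronous default, every agent simultaneously picks one random
neighbour and imitates it with the Fermi probability.  Observables follow
the standard spatial-games toolkit: per-step strategy frequencies, the
population cooperation level, and the neighbourhood composition matrix
that exposes strategy clustering.

States are numpy arrays of strategy indices in the canonical order of
:data:`guilt_egt.game.STRATEGIES`; the update loop is vectorized over
nodes via a padded neighbour table, so a 30x30 lattice advances a few
thousand steps per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .game import STRATEGIES, STRATEGY_LABELS, Strategy, StrategyMatrix

__all__ = [
    "ABMConfig",
    "Trajectory",
    "NeighbourhoodComposition",
    "GraphArrays",
    "initialize_population",
    "compute_fitness",
    "imitation_update",
    "run_simulation",
    "cooperation_level",
    "neighbourhood_composition",
]

_NS = len(STRATEGIES)
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class ABMConfig:
    """Simulation protocol.

    ``steps`` evolution steps are run and the final ``window`` steps are
    averaged for reporting; ``replicates`` independent runs (fresh random
    initial state each) are derived from ``seed``.
    """

    steps: int = 20_000
    window: int = 2_000
    beta: float = 1.0
    update_mode: str = "synchronous"
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.window > self.steps and self.steps > 0:
            raise ValueError("window must be <= steps")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.update_mode not in ("synchronous", "asynchronous"):
            raise ValueError("update_mode must be 'synchronous' or 'asynchronous'")


class GraphArrays:
    """Padded neighbour table for vectorized updates on a fixed graph."""

    def __init__(self, graph: nx.Graph):
        n = graph.number_of_nodes()
        if n == 0:
            raise ValueError("graph has no nodes")
        if sorted(graph.nodes()) != list(range(n)):
            raise ValueError("node ids must be 0..N-1")
        self.n = n
        self.degrees = np.array([graph.degree(v) for v in range(n)], dtype=np.int64)
        if self.degrees.min() == 0:
            raise ValueError("isolated nodes are not supported")
        maxdeg = int(self.degrees.max())
        self.neighbours = np.zeros((n, maxdeg), dtype=np.int64)
        for v in range(n):
            nbrs = list(graph.neighbors(v))
            self.neighbours[v, : len(nbrs)] = nbrs
        self.mask = np.arange(maxdeg)[None, :] < self.degrees[:, None]
        self.n_edges = graph.number_of_edges()


def _as_arrays(graph) -> GraphArrays:
    return graph if isinstance(graph, GraphArrays) else GraphArrays(graph)


def initialize_population(graph, seed: int | None = None) -> np.ndarray:
    """Uniform random strategy assignment, one of six per node."""
    ga = _as_arrays(graph)
    rng = np.random.default_rng(seed)
    return rng.integers(0, _NS, size=ga.n)


def compute_fitness(state: np.ndarray, graph, matrix: StrategyMatrix) -> np.ndarray:
    """Fitness of each node: payoff summed over encounters with neighbours."""
    ga = _as_arrays(graph)
    nb_state = state[ga.neighbours]
    pay = matrix.values[state[:, None], nb_state]
    return np.where(ga.mask, pay, 0.0).sum(axis=1)


def _fermi_vec(f_self: np.ndarray, f_other: np.ndarray, beta: float) -> np.ndarray:
    x = np.clip(-beta * (f_other - f_self), -_EXP_CLAMP, _EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(x))


def imitation_update(
    state: np.ndarray,
    graph,
    fitness: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    mode: str = "synchronous",
) -> np.ndarray:
    """One evolution step under the pairwise-comparison rule.

    Synchronous (default): every agent picks one neighbour uniformly and
    adopts its *pre-update* strategy with Fermi probability, all adoptions
    applied simultaneously.  Asynchronous: agents revise one at a time in
    random order, recomputing the two relevant fitnesses from the current
    state before each revision.
    """
    ga = _as_arrays(graph)
    if mode == "synchronous":
        pick = (rng.random(ga.n) * ga.degrees).astype(np.int64)
        models = ga.neighbours[np.arange(ga.n), pick]
        p = _fermi_vec(fitness, fitness[models], beta)
        adopt = rng.random(ga.n) < p
        new_state = state.copy()
        new_state[adopt] = state[models[adopt]]
        return new_state
    if mode == "asynchronous":
        raise ValueError(
            "asynchronous updates recompute fitness per revision and need the "
            "payoff matrix; run them through run_simulation(update_mode='asynchronous')"
        )
    raise ValueError(f"unknown update mode {mode!r}")


def _async_step(
    state: np.ndarray,
    ga: GraphArrays,
    matrix: np.ndarray,
    beta: float,
    rng: np.random.Generator,
) -> None:
    """N random sequential single-agent revisions, in place."""
    order = rng.permutation(ga.n)
    for v in order:
        deg_v = ga.degrees[v]
        u = ga.neighbours[v, rng.integers(deg_v)]
        nb_v = ga.neighbours[v, :deg_v]
        nb_u = ga.neighbours[u, : ga.degrees[u]]
        f_v = matrix[state[v], state[nb_v]].sum()
        f_u = matrix[state[u], state[nb_u]].sum()
        x = np.clip(-beta * (f_u - f_v), -_EXP_CLAMP, _EXP_CLAMP)
        if rng.random() < 1.0 / (1.0 + np.exp(x)):
            state[v] = state[u]


def cooperation_level(state: np.ndarray, graph, coop_matrix: StrategyMatrix) -> float:
    """Fraction of cooperative acts among all acts in one step.

    Mean over all ordered neighbour pairs (v, u) of the expected per-round
    cooperation frequency of v's strategy against u's.
    """
    ga = _as_arrays(graph)
    nb_state = state[ga.neighbours]
    coop = coop_matrix.values[state[:, None], nb_state]
    return float(np.where(ga.mask, coop, 0.0).sum() / (2 * ga.n_edges))


@dataclass
class Trajectory:
    """Recorded observables of one or more replicate runs.

    ``frequencies`` has shape (replicates, steps+1, 6) and each vector sums
    to 1; ``cooperation`` has shape (replicates, steps+1) with values in
    [0, 1]; index 0 is the initial state.  ``final_states`` holds the last
    population state of each replicate for composition analysis.
    """

    frequencies: np.ndarray
    cooperation: np.ndarray
    window: int
    final_states: np.ndarray
    labels: tuple[str, ...] = STRATEGY_LABELS

    @property
    def replicates(self) -> int:
        return self.frequencies.shape[0]

    def window_frequencies(self) -> np.ndarray:
        """Per-replicate strategy frequencies averaged over the final window."""
        w = max(self.window, 1)
        return self.frequencies[:, -w:, :].mean(axis=1)

    def window_cooperation(self) -> np.ndarray:
        w = max(self.window, 1)
        return self.cooperation[:, -w:].mean(axis=1)

    def mean_window_frequencies(self) -> np.ndarray:
        return self.window_frequencies().mean(axis=0)

    def mean_window_cooperation(self) -> float:
        return float(self.window_cooperation().mean())

    def modal_strategy(self, replicate: int) -> str:
        return self.labels[int(np.argmax(self.window_frequencies()[replicate]))]


def run_simulation(
    graph,
    matrix: StrategyMatrix,
    coop_matrix: StrategyMatrix,
    config: ABMConfig,
    initial_state: np.ndarray | None = None,
) -> Trajectory:
    """Run the evolutionary process and record per-step observables.

    Each replicate draws a fresh uniform initial state from a seed derived
    from ``config.seed`` (or starts from ``initial_state`` if given), then
    alternates fitness computation and imitation for ``config.steps``
    steps.  Identical (graph, config) inputs reproduce identical
    trajectories.
    """
    ga = _as_arrays(graph)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates) % (2**31)
    freqs = np.empty((config.replicates, config.steps + 1, _NS))
    coops = np.empty((config.replicates, config.steps + 1))
    finals = np.empty((config.replicates, ga.n), dtype=np.int64)
    for rep in range(config.replicates):
        rng = np.random.default_rng(int(seeds[rep]))
        if initial_state is None:
            state = rng.integers(0, _NS, size=ga.n)
        else:
            state = np.asarray(initial_state, dtype=np.int64).copy()
            if state.shape != (ga.n,):
                raise ValueError("initial_state length must equal the node count")
        freqs[rep, 0] = np.bincount(state, minlength=_NS) / ga.n
        coops[rep, 0] = cooperation_level(state, ga, coop_matrix)
        for t in range(1, config.steps + 1):
            if config.update_mode == "synchronous":
                fitness = compute_fitness(state, ga, matrix)
                state = imitation_update(state, ga, fitness, config.beta, rng)
            else:
                _async_step(state, ga, matrix.values, config.beta, rng)
            freqs[rep, t] = np.bincount(state, minlength=_NS) / ga.n
            coops[rep, t] = cooperation_level(state, ga, coop_matrix)
        finals[rep] = state
    return Trajectory(freqs, coops, config.window, finals)


@dataclass
class NeighbourhoodComposition:
    """Mean neighbour-strategy fractions per focal strategy.

    Row i gives, averaged over agents playing strategy i, the fraction of
    their neighbours playing each strategy; rows of absent strategies are
    NaN and flagged in ``present``.
    """

    matrix: np.ndarray
    overall_frequencies: np.ndarray
    present: np.ndarray
    labels: tuple[str, ...] = STRATEGY_LABELS

    def same_strategy_fraction(self, label: str) -> float:
        i = self.labels.index(label)
        if not self.present[i]:
            raise ValueError(f"strategy {label} absent from the population")
        return float(self.matrix[i, i])


def neighbourhood_composition(state: np.ndarray, graph) -> NeighbourhoodComposition:
    """Compute the clustering observable from one population state."""
    ga = _as_arrays(graph)
    nb_state = state[ga.neighbours]
    onehot = np.zeros((ga.n, ga.neighbours.shape[1], _NS))
    np.put_along_axis(onehot, nb_state[..., None], 1.0, axis=2)
    onehot *= ga.mask[..., None]
    frac = onehot.sum(axis=1) / ga.degrees[:, None]  # per-node neighbour fractions
    comp = np.full((_NS, _NS), np.nan)
    present = np.zeros(_NS, dtype=bool)
    for s in range(_NS):
        sel = state == s
        if sel.any():
            present[s] = True
            comp[s] = frac[sel].mean(axis=0)
    overall = np.bincount(state, minlength=_NS) / ga.n
    return NeighbourhoodComposition(comp, overall, present)
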