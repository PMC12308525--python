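"""Parameter-sweep orchestration over guilt cost grids and topologies.

A sweep varies the guilt cost ``gamma`` (and optionally the social cost
``gamma_s`` and donation benefit ``b``) and reports long-run strategy
frequencies plus the total cooperation level: analytically via the
small-mutation Markov chain for well-mixed populations, or via the
agent-based simulator for complete-graph, lattice and scale-free
topologies.  Results come back as a long-format pandas DataFrame ready
for CSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import networks
from .abm import ABMConfig, run_simulation
from .game import STRATEGY_LABELS, GameParams, closed_form_payoffs, cooperation_matrix
from .wellmixed import PopulationSpec, markov_chain, stationary_cooperation_level

logger = logging.getLogger(__name__)

__all__ = ["SweepSpec", "run_sweep", "fixture_suite", "FixtureSuite"]

TOPOLOGIES = ("wellmixed_analytic", "complete", "lattice", "scalefree")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a topology, donation-game grids, and protocol settings.

    ``gamma_grid`` / ``gamma_s_values`` / ``b_values`` form the product
    grid; ``c`` is the fixed cooperation cost; ``N`` is ignored for the
    lattice (rows x cols) and scale-free (graph bank) topologies.
    """

    topology: str = "wellmixed_analytic"
    gamma_grid: tuple[float, ...] = tuple(np.arange(0.0, 10.5, 0.5))
    gamma_s_values: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    b_values: tuple[float, ...] = (2.0, 4.0)
    c: float = 1.0
    omega: int = 10
    beta: float = 1.0
    N: int = 100
    lattice_rows: int = 30
    lattice_cols: int = 30
    sf_n: int = 1000
    sf_m: int = 2
    sf_graphs: int = 2
    abm: ABMConfig = field(default_factory=ABMConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if not (self.gamma_grid and self.gamma_s_values and self.b_values):
            raise ValueError("parameter grids must be nonempty")


def _sweep_graphs(spec: SweepSpec) -> list[nx.Graph]:
    if spec.topology == "complete":
        return [networks.complete_graph(spec.N)]
    if spec.topology == "lattice":
        return [networks.periodic_lattice(spec.lattice_rows, spec.lattice_cols)]
    if spec.topology == "scalefree":
        return networks.preseed_networks(spec.sf_graphs, spec.sf_n, spec.sf_m, spec.seed)
    return []


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep; one row per (b, gamma_s, gamma, strategy).

    Columns: topology, b, gamma_s, gamma, strategy, frequency,
    frequency_sd (ABM only), cooperation, replicates.  Infeasible
    parameter points (invalid payoff ordering) are skipped with a warning.
    """
    rows = []
    graphs = _sweep_graphs(spec)
    for b in spec.b_values:
        for gs in spec.gamma_s_values:
            for gamma in spec.gamma_grid:
                try:
                    params = GameParams.donation(
                        b, spec.c, omega=spec.omega, gamma=gamma, gamma_s=gs
                    )
                except ValueError as exc:
                    logger.warning("skipping b=%s gamma_s=%s gamma=%s: %s", b, gs, gamma, exc)
                    continue
                matrix = closed_form_payoffs(params)
                coop = cooperation_matrix(params)
                if spec.topology == "wellmixed_analytic":
                    mc = markov_chain(PopulationSpec(spec.N, spec.beta), matrix)
                    freqs = mc.stationary
                    freq_sd = np.zeros(6)
                    coop_level = stationary_cooperation_level(mc, coop)
                    n_rep = 1
                else:
                    per_rep = []
                    per_coop = []
                    for gi, graph in enumerate(graphs):
                        cfg = ABMConfig(
                            steps=spec.abm.steps,
                            window=spec.abm.window,
                            beta=spec.beta,
                            update_mode=spec.abm.update_mode,
                            seed=spec.abm.seed + 7919 * gi,
                            replicates=spec.abm.replicates,
                        )
                        traj = run_simulation(graph, matrix, coop, cfg)
                        per_rep.append(traj.window_frequencies())
                        per_coop.append(traj.window_cooperation())
                    all_rep = np.vstack(per_rep)
                    freqs = all_rep.mean(axis=0)
                    freq_sd = all_rep.std(axis=0)
                    coop_level = float(np.concatenate(per_coop).mean())
                    n_rep = all_rep.shape[0]
                for s, label in enumerate(STRATEGY_LABELS):
                    rows.append(
                        {
                            "topology": spec.topology,
                            "b": b,
                            "gamma_s": gs,
                            "gamma": gamma,
                            "strategy": label,
                            "frequency": float(freqs[s]),
                            "frequency_sd": float(freq_sd[s]),
                            "cooperation": coop_level,
                            "replicates": n_rep,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FixtureSuite:
    """Small deterministic objects for unit tests and examples."""

    lattice_3x3: nx.Graph
    ba_12: nx.Graph
    complete_6: nx.Graph
    params: GameParams
    state_3x3: np.ndarray


def fixture_suite(seed: int = 0) -> FixtureSuite:
    """Tiny graphs and canonical parameters (T=2, R=1, P=0, S=-1, Omega=10)."""
    rng = np.random.default_rng(seed)
    return FixtureSuite(
        lattice_3x3=networks.periodic_lattice(3, 3),
        ba_12=networks.barabasi_albert(12, 2, seed=seed),
        complete_6=networks.complete_graph(6),
        params=GameParams(T=2.0, R=1.0, P=0.0, S=-1.0, omega=10, gamma=1.0, gamma_s=0.1),
        state_3x3=rng.integers(0, 6, size=9),
    )
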