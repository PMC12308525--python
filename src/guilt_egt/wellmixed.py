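"""Exact stochastic evolutionary dynamics in finite well-mixed populations.

A population of ``N`` agents updates by the pairwise-comparison (Fermi)
rule with selection intensity ``beta``.  In the small-mutation limit at
most two strategies coexist, so the long-run dynamics reduce to a Markov
chain over monomorphic states whose transition probabilities are single-
mutant fixation probabilities; the chain's stationary distribution gives
the relative time spent in each strategy.  The module also provides a
Monte Carlo oracle for the fixation formula, the risk-dominance criterion
and its closed-form thresholds for the guilt strategies, and deterministic
replicator dynamics on the 6-strategy simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import logsumexp

from .game import (
    DGCN,
    DGCS,
    DGDN,
    DGDS,
    STRATEGIES,
    STRATEGY_INDEX,
    C,
    D,
    GameParams,
    Strategy,
    StrategyMatrix,
    closed_form_payoffs,
)

__all__ = [
    "PopulationSpec",
    "MarkovChainResult",
    "ThresholdReport",
    "fermi_probability",
    "average_payoffs",
    "step_probabilities",
    "fixation_probability",
    "monte_carlo_fixation",
    "markov_chain",
    "risk_dominant",
    "risk_dominance_margin",
    "analytic_thresholds",
    "replicator_trajectory",
    "stationary_cooperation_level",
]

#: exponent clamp keeping exp() finite for |beta * delta_f| up to ~1e4
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class PopulationSpec:
    """Finite well-mixed population: size N and selection intensity beta."""

    N: int = 100
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.beta < 0:
            raise ValueError("selection intensity beta must be >= 0")


def fermi_probability(f_a: float, f_b: float, beta: float) -> float:
    """Probability that agent A (fitness f_a) imitates agent B (fitness f_b).

    The pairwise-comparison rule ``p = (1 + exp(-beta (f_b - f_a)))^-1``:
    1/2 at equal fitness or beta = 0, approaching a step function as beta
    grows.  The exponent is clamped for numerical stability.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.clip(-beta * (np.asarray(f_b) - np.asarray(f_a)), -_EXP_CLAMP, _EXP_CLAMP)
    return float(1.0 / (1.0 + np.exp(x)))


def average_payoffs(
    k: int, N: int, pi_aa: float, pi_ab: float, pi_ba: float, pi_bb: float
) -> tuple[float, float]:
    """Mean payoffs (Pi_A, Pi_B) with k A-players among N, excluding self-play.

    ``Pi_A(k) = ((k-1) pi_AA + (N-k) pi_AB) / (N-1)`` and symmetrically for
    B; each agent meets every other agent exactly once.
    """
    if not 0 <= k <= N:
        raise ValueError(f"k={k} out of range [0, {N}]")
    pa = ((k - 1) * pi_aa + (N - k) * pi_ab) / (N - 1)
    pb = (k * pi_ba + (N - k - 1) * pi_bb) / (N - 1)
    return pa, pb


def step_probabilities(
    k: int,
    spec: PopulationSpec,
    pi_aa: float,
    pi_ab: float,
    pi_ba: float,
    pi_bb: float,
) -> tuple[float, float]:
    """Probabilities (T+, T-) that the count of A-players moves by +1 / -1.

    ``T±(k) = (N-k)/N * k/N * (1 + exp(∓beta (Pi_A - Pi_B)))^-1``; both are
    zero in the absorbing monomorphic states k = 0 and k = N.
    """
    N = spec.N
    if not 0 <= k <= N:
        raise ValueError(f"k={k} out of range [0, {N}]")
    if k in (0, N):
        return 0.0, 0.0
    pa, pb = average_payoffs(k, N, pi_aa, pi_ab, pi_ba, pi_bb)
    base = (N - k) / N * k / N
    t_plus = base * fermi_probability(pb, pa, spec.beta)
    t_minus = base * fermi_probability(pa, pb, spec.beta)
    return t_plus, t_minus


def _log_ratio_cumsums(spec: PopulationSpec, pi_aa, pi_ab, pi_ba, pi_bb) -> np.ndarray:
    """log of the partial products prod_{j<=i} T-(j)/T+(j), i = 1..N-1.

    Uses the identity T-(k)/T+(k) = exp(-beta (Pi_A(k) - Pi_B(k))) so the
    product is a plain sum of payoff differences, exact at beta = 0.
    """
    N, beta = spec.N, spec.beta
    k = np.arange(1, N)
    pa = ((k - 1) * pi_aa + (N - k) * pi_ab) / (N - 1)
    pb = (k * pi_ba + (N - k - 1) * pi_bb) / (N - 1)
    return np.cumsum(-beta * (pa - pb))


def fixation_probability(
    mutant: Strategy,
    resident: Strategy,
    spec: PopulationSpec,
    matrix: StrategyMatrix,
) -> float:
    """Fixation probability of a single mutant in a resident population.

    ``rho = (1 + sum_{i=1}^{N-1} prod_{j=1}^{i} T-(j)/T+(j))^-1``, accumulated
    in log space; equals exactly 1/N at beta = 0 for any strategy pair.
    """
    if mutant == resident:
        raise ValueError("mutant and resident strategies must differ")
    pi_aa = matrix.loc(mutant, mutant)
    pi_ab = matrix.loc(mutant, resident)
    pi_ba = matrix.loc(resident, mutant)
    pi_bb = matrix.loc(resident, resident)
    cum = _log_ratio_cumsums(spec, pi_aa, pi_ab, pi_ba, pi_bb)
    log_denom = logsumexp(np.concatenate(([0.0], cum)))
    if -log_denom < np.log(1e-300):
        return 0.0
    return float(np.exp(-log_denom))


def monte_carlo_fixation(
    mutant: Strategy,
    resident: Strategy,
    spec: PopulationSpec,
    matrix: StrategyMatrix,
    trials: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte Carlo estimate (fraction fixed, standard error) of fixation.

    Simulates the birth–death imitation chain on the mutant count k: a
    random focal agent imitates a random other agent with Fermi probability.
    Steps that leave k unchanged do not affect which absorbing state is
    reached, so the embedded jump chain with upward probability
    ``T+ / (T+ + T-)`` is simulated instead, vectorized across trials.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    N = spec.N
    pi_aa = matrix.loc(mutant, mutant)
    pi_ab = matrix.loc(mutant, resident)
    pi_ba = matrix.loc(resident, mutant)
    pi_bb = matrix.loc(resident, resident)
    p_up = np.zeros(N + 1)
    for k in range(1, N):
        pa, pb = average_payoffs(k, N, pi_aa, pi_ab, pi_ba, pi_bb)
        # conditional on a change, k moves up with the Fermi probability
        x = np.clip(-spec.beta * (pa - pb), -_EXP_CLAMP, _EXP_CLAMP)
        p_up[k] = 1.0 / (1.0 + np.exp(x))
    rng = np.random.default_rng(seed)
    k_state = np.ones(trials, dtype=np.int64)
    active = np.ones(trials, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        ks = k_state[idx]
        up = rng.random(idx.size) < p_up[ks]
        ks = np.where(up, ks + 1, ks - 1)
        k_state[idx] = ks
        active[idx] = (ks != 0) & (ks != N)
    fixed = float(np.mean(k_state == N))
    se = float(np.sqrt(max(fixed * (1 - fixed), 1e-12) / trials))
    return fixed, se


@dataclass(frozen=True)
class MarkovChainResult:
    """Small-mutation-limit Markov chain over monomorphic states.

    ``rho[i, j]`` is the fixation probability of a single j-mutant among
    i-residents; the transition matrix has ``M[i, j] = rho[i, j] / (q - 1)``
    off the diagonal, so row i describes where a resident-i population
    moves when a rare mutant appears.
    """

    strategies: tuple[Strategy, ...]
    rho: np.ndarray
    M: np.ndarray
    stationary: np.ndarray
    spec: PopulationSpec

    @property
    def q(self) -> int:
        return len(self.strategies)

    def stationary_by_label(self) -> dict[str, float]:
        return {s.label: float(p) for s, p in zip(self.strategies, self.stationary)}


def markov_chain(
    spec: PopulationSpec,
    matrix: StrategyMatrix,
    strategies: tuple[Strategy, ...] = STRATEGIES,
) -> MarkovChainResult:
    """Build the small-mutation Markov chain and its stationary distribution.

    The stationary vector is the normalized left null vector of ``M - I``,
    computed by a linear solve; a reducible chain (some fixation probability
    exactly zero in both directions making the stationary distribution
    non-unique) raises rather than silently averaging recurrent classes.
    """
    q = len(strategies)
    if q < 2:
        raise ValueError("need at least two strategies")
    rho = np.zeros((q, q))
    for i, res in enumerate(strategies):
        for j, mut in enumerate(strategies):
            if i != j:
                rho[i, j] = fixation_probability(mut, res, spec, matrix)
    M = rho / (q - 1)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))

    # stationary: pi (M - I) = 0 with sum(pi) = 1, solved as a linear system
    A = np.vstack([(M - np.eye(q)).T, np.ones(q)])
    b = np.zeros(q + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.max(np.abs(pi @ M - pi)))
    if residual > 1e-8 or np.any(pi < -1e-10):
        raise RuntimeError(
            "stationary distribution not unique or not found "
            f"(residual {residual:g}); the chain may be reducible"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return MarkovChainResult(tuple(strategies), rho, M, pi, spec)


def stationary_cooperation_level(
    result: MarkovChainResult, coop_matrix: StrategyMatrix
) -> float:
    """Long-run cooperation: stationary-weighted monomorphic self-play rates."""
    diag = np.array([coop_matrix.loc(s, s) for s in result.strategies])
    return float(result.stationary @ diag)


def risk_dominance_margin(a: Strategy, b: Strategy, matrix: StrategyMatrix) -> float:
    """Signed margin (pi_AA + pi_AB) - (pi_BA + pi_BB); positive favours A."""
    return (matrix.loc(a, a) + matrix.loc(a, b)) - (matrix.loc(b, a) + matrix.loc(b, b))


def risk_dominant(
    a: Strategy, b: Strategy, matrix: StrategyMatrix, tol: float = 1e-12
) -> Strategy | None:
    """Risk-dominant strategy of a pair, or None if neutral.

    A risk-dominates B when ``pi_AA + pi_AB > pi_BA + pi_BB``, which for
    large N predicts the stronger fixation direction between the two
    monomorphic states.  Equality within relative tolerance ``tol`` is
    reported as neutral.
    """
    if a == b:
        raise ValueError("strategies must differ")
    margin = risk_dominance_margin(a, b, matrix)
    scale = max(
        1.0,
        abs(matrix.loc(a, a)) + abs(matrix.loc(a, b)),
        abs(matrix.loc(b, a)) + abs(matrix.loc(b, b)),
    )
    if abs(margin) <= tol * scale:
        return None
    return a if margin > 0 else b


@dataclass(frozen=True)
class ThresholdReport:
    """Closed-form risk-dominance thresholds for social guilt (DGCS).

    Margins are signed (positive = condition holds); booleans use strict
    inequalities.  ``cycle_present`` marks the DGCS -> DGCN -> D -> DGCS
    cycle: DGCN beats DGCS whenever ``gamma_s > 0``, D always beats DGCN,
    and DGCS beats D when ``gamma + (Omega+1) gamma_s < (Omega-1)(R-P)``.
    """

    dgcs_beats_dgds: bool
    dgcs_beats_dgdn: bool
    dgcs_beats_d: bool
    dgcs_beats_c: bool
    cycle_present: bool
    margin_dgds: float
    margin_dgdn: float
    margin_d: float
    margin_c: float


def analytic_thresholds(params: GameParams) -> ThresholdReport:
    """Evaluate the closed-form viability conditions for social guilt.

    DGCS risk-dominates DGDS iff ``gamma + gamma_s > c``; DGDN iff
    ``(Omega-1) gamma - gamma_s > (Omega-1) c``; D iff
    ``gamma + (Omega+1) gamma_s < (Omega-1)(R - P)``; and C iff
    ``gamma + gamma_s < c`` (the reverse of the DGDS condition), with
    ``c = (T - R + P - S)/2``.
    """
    g, gs, om, c = params.gamma, params.gamma_s, params.omega, params.c
    m_dgds = (g + gs) - c
    m_dgdn = (om - 1) * g - gs - (om - 1) * c
    m_d = (om - 1) * (params.R - params.P) - (g + (om + 1) * gs)
    m_c = c - (g + gs)
    return ThresholdReport(
        dgcs_beats_dgds=m_dgds > 0,
        dgcs_beats_dgdn=m_dgdn > 0,
        dgcs_beats_d=m_d > 0,
        dgcs_beats_c=m_c > 0,
        cycle_present=(m_d > 0) and (gs > 0),
        margin_dgds=m_dgds,
        margin_dgdn=m_dgdn,
        margin_d=m_d,
        margin_c=m_c,
    )


def replicator_trajectory(
    x0: np.ndarray,
    matrix: StrategyMatrix,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate dx_i/dt = x_i (f_i - mean f) with f = A x on the simplex.

    Returns frequencies of shape (len(t_grid), q); each output point is
    renormalized (drift before renormalization stays below ~1e-8).
    """
    x0 = np.asarray(x0, dtype=float)
    A = matrix.values
    q = A.shape[0]
    if x0.shape != (q,) or np.any(x0 < 0) or abs(x0.sum() - 1) > 1e-9:
        raise ValueError("initial frequencies must be a point on the simplex")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_t, x):
        f = A @ x
        return x * (f - x @ f)

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        rtol=rtol,
        atol=1e-12,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    traj = sol.y.T
    traj = np.clip(traj, 0.0, None)
    return traj / traj.sum(axis=1, keepdims=True)


def transition_directions(
    result: MarkovChainResult,
) -> dict[tuple[str, str], str]:
    """For each unordered pair, which fixation direction is stronger.

    Returns {(label_i, label_j): winner_label or 'neutral'} comparing
    rho[i -> j] with rho[j -> i] (the arrows of a transition diagram).
    """
    out: dict[tuple[str, str], str] = {}
    labels = [s.label for s in result.strategies]
    for i in range(result.q):
        for j in range(i + 1, result.q):
            fwd, bwd = result.rho[i, j], result.rho[j, i]
            if np.isclose(fwd, bwd, rtol=1e-9, atol=1e-15):
                out[(labels[i], labels[j])] = "neutral"
            else:
                out[(labels[i], labels[j])] = labels[j] if fwd > bwd else labels[i]
    return out
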