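"""Core game model: guilt-prone strategies in the iterated prisoner's dilemma.

Two players repeat a one-shot prisoner's dilemma (payoffs ``T > R > P > S``,
with ``2R > T + S``) for ``Omega`` rounds.  Besides the unconditional
cooperator (C) and defector (D), four *emotional* strategies carry a guilt
threshold ``G = 0``: after a defection they consider wrong, they immediately
alleviate their guilt at cost ``gamma``.  *Adaptive* emotional strategies
(DGCN, DGCS) additionally switch to cooperation after feeling guilt;
*social* ones (DGDS, DGCS) condition guilt on the co-player's own
guilt-proneness and pay an observation cost ``gamma_s`` in every round they
defect.

The module provides a round-by-round encounter simulator
(:func:`play_encounter`), the 6x6 per-round-average payoff matrix in both
simulated and closed form (:func:`payoff_matrix`), and the matching
cooperation-frequency matrix (:func:`cooperation_matrix`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GameParams",
    "Strategy",
    "EncounterOutcome",
    "StrategyMatrix",
    "STRATEGIES",
    "STRATEGY_LABELS",
    "C",
    "D",
    "DGDN",
    "DGCN",
    "DGDS",
    "DGCS",
    "play_encounter",
    "payoff_matrix",
    "closed_form_payoffs",
    "simulated_payoffs",
    "cooperation_matrix",
]

COOPERATE = "C"
DEFECT = "D"


@dataclass(frozen=True)
class GameParams:
    """Payoff and cost parameters of one iterated encounter.

    Parameters
    ----------
    T, R, P, S
        One-shot prisoner's dilemma payoffs (temptation, reward,
        punishment, sucker), required to satisfy ``T > R > P > S`` and
        ``2R > T + S``.
    omega
        Number of rounds per encounter (``>= 1``).
    gamma
        Guilt-alleviation cost paid in each round the agent defects and
        feels guilty.
    gamma_s
        Social observation cost paid by a *social* emotional agent in each
        round it defects, whether or not guilt is felt.
    """

    T: float
    R: float
    P: float
    S: float
    omega: int = 10
    gamma: float = 0.0
    gamma_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"prisoner's dilemma ordering T > R > P > S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError("iterated-game condition 2R > T + S violated")
        if self.gamma < 0 or self.gamma_s < 0:
            raise ValueError("guilt costs gamma and gamma_s must be >= 0")
        if int(self.omega) != self.omega or self.omega < 1:
            raise ValueError("omega must be an integer >= 1")

    @classmethod
    def donation(
        cls,
        b: float,
        c: float,
        omega: int = 10,
        gamma: float = 0.0,
        gamma_s: float = 0.0,
    ) -> "GameParams":
        """Donation-game parameterization: T=b, R=b-c, P=0, S=-c (b > c > 0)."""
        if not b > c > 0:
            raise ValueError("donation game requires b > c > 0")
        return cls(T=b, R=b - c, P=0.0, S=-c, omega=omega, gamma=gamma, gamma_s=gamma_s)

    @property
    def theta(self) -> int:
        """Rounds after the first: Theta = Omega - 1."""
        return self.omega - 1

    @property
    def c(self) -> float:
        """Effective cooperation cost (T - R + P - S) / 2."""
        return (self.T - self.R + self.P - self.S) / 2.0

    def pd_payoff(self, own: str, other: str) -> float:
        """One-shot payoff for ``own`` action against ``other`` action."""
        if own == COOPERATE:
            return self.R if other == COOPERATE else self.S
        return self.T if other == COOPERATE else self.P


@dataclass(frozen=True)
class Strategy:
    """A behavioural genotype for the iterated encounter.

    ``guilt_threshold`` is 0 for emotional agents (guilt after a single
    wrongdoing) and ``inf`` for unemotional ones; other values construct but
    are rejected by :func:`play_encounter`.
    """

    label: str
    initial_action: str
    guilt_threshold: float
    adaptive: bool
    social: bool

    @property
    def emotional(self) -> bool:
        return self.guilt_threshold == 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


C = Strategy("C", COOPERATE, math.inf, adaptive=False, social=False)
D = Strategy("D", DEFECT, math.inf, adaptive=False, social=False)
DGDN = Strategy("DGDN", DEFECT, 0.0, adaptive=False, social=False)
DGCN = Strategy("DGCN", DEFECT, 0.0, adaptive=True, social=False)
DGDS = Strategy("DGDS", DEFECT, 0.0, adaptive=False, social=True)
DGCS = Strategy("DGCS", DEFECT, 0.0, adaptive=True, social=True)

#: Canonical strategy order used by every 6x6 matrix in the package.
STRATEGIES: tuple[Strategy, ...] = (C, D, DGDN, DGCN, DGDS, DGCS)
STRATEGY_LABELS: tuple[str, ...] = tuple(s.label for s in STRATEGIES)
STRATEGY_INDEX: dict[str, int] = {s.label: i for i, s in enumerate(STRATEGIES)}


def strategy_by_label(label: str) -> Strategy:
    try:
        return STRATEGIES[STRATEGY_INDEX[label]]
    except KeyError:
        raise KeyError(f"unknown strategy label {label!r}; expected one of {STRATEGY_LABELS}")


@dataclass
class EncounterOutcome:
    """Per-player result of one full Omega-round encounter."""

    strategy: Strategy
    avg_payoff: float
    action_trace: list[str]
    cooperation_count: int
    guilt_cost_paid: float
    social_cost_paid: float
    guilt_level: int  # residual guilt g after within-encounter alleviation
    transgressions: int  # rounds in which guilt was felt


class _PlayerState:
    __slots__ = (
        "strategy",
        "action",
        "pd_sum",
        "trace",
        "coop",
        "guilt_cost",
        "social_cost",
        "g",
        "transgressions",
    )

    def __init__(self, strategy: Strategy) -> None:
        self.strategy = strategy
        self.action = strategy.initial_action
        self.pd_sum = 0.0
        self.trace: list[str] = []
        self.coop = 0
        self.guilt_cost = 0.0
        self.social_cost = 0.0
        self.g = 0
        self.transgressions = 0


def play_encounter(
    row: Strategy, col: Strategy, params: GameParams
) -> tuple[EncounterOutcome, EncounterOutcome]:
    """Simulate one Omega-round encounter and return both players' outcomes.

    Each round both players act from their current action state and accrue
    the one-shot payoff.  Afterwards, each *emotional* player that defected
    this round (i) pays ``gamma_s`` if social, (ii) determines guilt — a
    non-social agent always feels guilt; a social agent withholds guilt only
    when its co-player both defected this round and is unemotional — and
    (iii) if guilty, pays ``gamma`` and, if adaptive, cooperates for all
    remaining rounds.  Unemotional players never pay costs and never change
    action, so the whole encounter is deterministic.
    """
    for s in (row, col):
        if s.guilt_threshold not in (0.0, math.inf):
            raise ValueError(
                f"guilt threshold {s.guilt_threshold} unsupported: only G=0 "
                "(emotional) and G=inf (unemotional) are modelled"
            )

    a, b = _PlayerState(row), _PlayerState(col)
    for _ in range(params.omega):
        act_a, act_b = a.action, b.action
        for me, my_act, other, other_act in ((a, act_a, b, act_b), (b, act_b, a, act_a)):
            me.trace.append(my_act)
            me.pd_sum += params.pd_payoff(my_act, other_act)
            if my_act == COOPERATE:
                me.coop += 1
                continue
            if not me.strategy.emotional:
                me.g += 1  # unemotional guilt accrues but never crosses G=inf
                continue
            if me.strategy.social:
                me.social_cost += params.gamma_s
                guilty = not (other_act == DEFECT and not other.strategy.emotional)
            else:
                guilty = True
            if guilty:
                me.transgressions += 1
                me.guilt_cost += params.gamma  # g rises to 1 then is alleviated
                if me.strategy.adaptive:
                    me.action = COOPERATE

    def outcome(p: _PlayerState) -> EncounterOutcome:
        return EncounterOutcome(
            strategy=p.strategy,
            avg_payoff=(p.pd_sum - p.guilt_cost - p.social_cost) / params.omega,
            action_trace=p.trace,
            cooperation_count=p.coop,
            guilt_cost_paid=p.guilt_cost,
            social_cost_paid=p.social_cost,
            guilt_level=p.g,
            transgressions=p.transgressions,
        )

    return outcome(a), outcome(b)


@dataclass(frozen=True)
class StrategyMatrix:
    """6x6 matrix keyed by the canonical strategy order (row vs column)."""

    values: np.ndarray
    labels: tuple[str, ...] = STRATEGY_LABELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match strategy labels")

    def loc(self, row: str | Strategy, col: str | Strategy) -> float:
        r = row.label if isinstance(row, Strategy) else row
        c = col.label if isinstance(col, Strategy) else col
        return float(self.values[STRATEGY_INDEX[r], STRATEGY_INDEX[c]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def simulated_payoffs(params: GameParams) -> StrategyMatrix:
    """6x6 per-round-average payoff matrix from round-by-round simulation."""
    m = np.empty((6, 6))
    for i, si in enumerate(STRATEGIES):
        for j, sj in enumerate(STRATEGIES):
            m[i, j] = play_encounter(si, sj, params)[0].avg_payoff
    return StrategyMatrix(m)


def closed_form_payoffs(params: GameParams) -> StrategyMatrix:
    """Closed-form 6x6 per-round-average payoff matrix.

    With ``Theta = Omega - 1`` the entries are derived from the encounter
    rules: non-adaptive emotional strategies pay their costs every round,
    adaptive ones defect only in round one (except DGCS against D, which
    never feels guilt, keeps defecting and pays ``gamma_s`` every round).
    """
    T, R, P, S = params.T, params.R, params.P, params.S
    g, gs = params.gamma, params.gamma_s
    th, om = params.theta, params.omega
    m = np.array(
        [
            # C
            [R, S, S, (S + R * th) / om, S, (S + R * th) / om],
            # D
            [T, P, P, (P + T * th) / om, P, P],
            # DGDN: defects and feels guilt every round
            [T - g, P - g, P - g, (P + T * th) / om - g, P - g, (P + T * th) / om - g],
            # DGCN: one guilty defection, then cooperates
            [
                (T - g + R * th) / om,
                (P - g + S * th) / om,
                (P - g + S * th) / om,
                (P - g + R * th) / om,
                (P - g + S * th) / om,
                (P - g + R * th) / om,
            ],
            # DGDS: defects every round, guilt withheld only vs D
            [
                T - g - gs,
                P - gs,
                P - g - gs,
                (P + T * th) / om - g - gs,
                P - g - gs,
                (P + T * th) / om - g - gs,
            ],
            # DGCS: one guilty defection then cooperation, except vs D
            [
                (T - g - gs + R * th) / om,
                P - gs,
                (P - g - gs + S * th) / om,
                (P - g - gs + R * th) / om,
                (P - g - gs + S * th) / om,
                (P - g - gs + R * th) / om,
            ],
        ]
    )
    return StrategyMatrix(m)


def payoff_matrix(params: GameParams, *, check_tol: float | None = 1e-12) -> StrategyMatrix:
    """Payoff matrix cross-validated between simulation and closed form.

    By default the round-by-round simulation is checked entrywise against
    the closed form to ``check_tol``; a discrepancy raises, since the two
    derivations must be exactly equivalent.  Pass ``check_tol=None`` to
    skip the cross-check (e.g. inside tight parameter sweeps).
    """
    closed = closed_form_payoffs(params)
    if check_tol is not None:
        sim = simulated_payoffs(params)
        err = np.max(np.abs(sim.values - closed.values))
        if err > check_tol:
            raise AssertionError(
                f"simulated and closed-form payoff matrices disagree (max |diff| = {err:g})"
            )
    return closed


def cooperation_matrix(params: GameParams) -> StrategyMatrix:
    """Expected per-round cooperation frequency of the row strategy.

    Entry (i, j) = cooperation_count / Omega from the deterministic
    encounter of strategy i against strategy j; values lie in [0, 1].
    """
    m = np.empty((6, 6))
    for i, si in enumerate(STRATEGIES):
        for j, sj in enumerate(STRATEGIES):
            m[i, j] = play_encounter(si, sj, params)[0].cooperation_count / params.omega
    return StrategyMatrix(m)
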