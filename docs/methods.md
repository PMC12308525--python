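# Methods

## Model

Two agents play a prisoner's dilemma (payoffs T > R > P > S for
temptation, reward, punishment and sucker, with 2R > T + S so that
alternating exploitation cannot beat mutual cooperation) repeated for Ω
rounds per encounter. The donation-game convenience form sets T = b,
R = b − c, P = 0, S = −c with benefit b > cost c > 0.

A strategy is a triple (initial action, guilt threshold G, sociality).
Agents with G = +∞ never feel guilt (*unemotional*); agents with G = 0
feel guilt after a single wrongdoing (*emotional*) and must immediately
alleviate it at cost γ per guilty defection. These are the only two
thresholds modelled; the `Strategy` type accepts other values but the
encounter engine rejects them. Emotional agents come in four variants
along two axes:

- **adaptive** (DGCN, DGCS): on feeling guilt they switch from defection
  to cooperation for the rest of the encounter; non-adaptive variants
  (DGDN, DGDS) keep defecting and keep paying.
- **social** (DGDS, DGCS): guilt is conditioned on the co-player's own
  guilt-proneness — a social agent withholds guilt only when its
  co-player defected in the same round *and* is unemotional (an
  unrepentant defector). Observing the co-player costs γ_s in every
  round the social agent defects, guilt or no guilt. Non-social agents
  (DGDN, DGCN) feel guilt unconditionally and pay no observation cost.

Together with the unconditional cooperator C and defector D this gives
six strategies, always ordered (C, D, DGDN, DGCN, DGDS, DGCS).

Guilt is encounter-local: the transgression counter resets between
encounters and no emotional state persists across simulation steps.
Execution noise (trembling-hand mistakes) and apology/forgiveness
mechanisms are out of scope.

## Payoff matrix

`play_encounter` simulates the Ω rounds deterministically;
`closed_form_payoffs` states the same 6×6 matrix of *per-round-average*
payoffs analytically (with Θ = Ω − 1), e.g. DGCS vs DGCS earns
(P − γ − γ_s + RΘ)/Ω: one mutual guilty defection, then Θ rounds of
mutual cooperation. The two derivations are cross-checked entrywise to
1e−12 on every call of `payoff_matrix` and over random parameter draws
in the tests; they are algebraically equivalent, so the check guards
only against implementation drift. One subtlety the closed form
encodes: DGCS against D never feels guilt, keeps defecting, and pays
γ_s every round (entry P − γ_s), whereas DGCN against D feels guilt,
switches, and is exploited for Θ rounds (entry (P − γ + SΘ)/Ω). The
two adaptive variants are therefore *not* payoff-identical even at
γ = γ_s = 0; they are payoff-identical everywhere except the D column,
which is why they are exactly neutral under risk dominance iff γ_s = 0.

## Well-mixed dynamics

Imitation follows the pairwise-comparison rule: A adopts B's strategy
with probability (1 + e^(−β(f_B − f_A)))^−1, with selection intensity
β (default 1.0; β = 0 is neutral drift). With k A-players among N, the
average payoffs exclude self-interaction, and the count moves ±1 with
T±(k) = (N−k)/N · k/N · Fermi(±β ΔΠ). The fixation probability of a
single mutant is ρ = (1 + Σ_i Π_{j≤i} T−(j)/T+(j))^−1, computed in log
space via the identity T−/T+ = e^(−β ΔΠ) (hence exactly 1/N at β = 0);
probabilities underflowing 1e−300 are reported as 0.

In the small-mutation limit the population is monomorphic almost
always, and the dynamics reduce to a Markov chain over the six
monomorphic states with off-diagonal transitions ρ/(q−1). We use the
convention M[i][j] = (fixation probability of a single j-mutant among
i-residents)/(q−1) — the standard construction; one source formulation
indexes the same quantity transposed. The stationary distribution is
the normalized left null vector of M − I from a least-squares solve;
a residual above 1e−8 or negative masses raise rather than silently
averaging recurrent classes. With β finite all ρ > 0, so the chain is
irreducible in practice.

Risk dominance (A over B iff π_AA + π_AB > π_BA + π_BB, neutral at
equality within 1e−12 relative) predicts the stronger fixation arrow in
the large-N limit. Closed-form consequences for social guilt, each
verified symbolically and numerically against the matrix:

- DGCS ≻ DGDS  ⇔ γ + γ_s > c, and DGCS ≻ C is its reverse;
- DGCS ≻ DGDN  ⇔ (Ω−1)γ − γ_s > (Ω−1)c (needs γ > c);
- DGCS ≻ D    ⇔ γ + (Ω+1)γ_s < (Ω−1)(R−P);
- DGCS/DGCN neutral iff γ_s = 0, DGCN ≺ D always — giving the
  DGCS → DGCN → D → DGCS cycle whenever the third condition holds with
  γ_s > 0.

A finite-size caveat: at N = 100 the fixation comparison weights the
self-play and cross payoffs as (N−2)(π_AA − π_BB) + N(π_AB − π_BA), so
a pair with *exactly* zero risk-dominance margin but different payoff
entries (e.g. DGDN vs C at γ = c) can still show a directional arrow.
Tests therefore assert arrow agreement for non-neutral pairs, and
symmetry only where the payoff entries themselves coincide.

The Monte Carlo oracle for ρ simulates the embedded jump chain of the
birth–death process (upward with probability T+/(T+ + T−)): lazy
self-transitions cannot change which absorbing state is reached, so the
absorption probabilities are identical to the full chain's, and the
trials vectorize across replicates.

Replicator dynamics dx_i/dt = x_i(f_i − ⟨f⟩) with f = Ax are integrated
with LSODA at rtol 1e−8 and renormalized at output points (drift below
1e−8); equilibria are explored by fixed-point scans from random
interior starts rather than symbolic enumeration.

## Agent-based model

Agents occupy the nodes of a complete graph, a periodic square lattice
(von Neumann neighbourhood, degree 4), or a Barabási–Albert scale-free
graph; the interaction and imitation networks coincide. Per step, every
agent's fitness is the sum over neighbours of the per-encounter average
payoff (no degree normalization, so hubs accrue more fitness — the
standard convention in cooperation-on-networks work). In the default
*synchronous* update every agent then picks one neighbour uniformly and
adopts its pre-update strategy with Fermi probability, all adoptions
applied at once; an *asynchronous* random-sequential mode (each
revision recomputes the two local fitnesses from the current state) is
available for robustness checks, since the verbal description of the
protocol does not disambiguate the two. Initial states are uniform
over the six strategies.

The BA generator starts from m0 = m + 1 fully interconnected seed nodes
(so every seed has nonzero degree and preferential attachment is well
defined without an initial-attractiveness constant) and attaches each
arriving node to m distinct nodes with probability proportional to
degree; graphs are simple and connected by construction, with mean
degree 2m − O(1/N) (3.994 at N = 1000, m = 2). A reproducible bank of
pre-seeded graphs supports averaging over network realizations.

Observables: per-step strategy frequencies; the cooperation level
(mean over ordered neighbour pairs of the expected per-round
cooperation frequency of the first member, i.e. the fraction of
cooperative acts per step); and the neighbourhood composition matrix
(per focal strategy, the mean neighbour-strategy fractions), whose
diagonal excess over the overall frequency measures assortment.
Reported quantities are final-window averages per replicate, then
averaged across replicates, with per-replicate values retained.

### Problem sizes

The reference protocol in the literature runs 10^6 steps with the final
10^5 averaged over 30 realizations. This package's default desk-scale
protocol — used by the tests and the acceptance script — runs the
30×30 lattice for 2×10^4 synchronous steps, averaging the final 2×10^3,
over 5 replicates. Synchronous dynamics on this lattice in fact fixate
within roughly 10^2–10^3 steps, so final windows are typically
monomorphic; assortment is therefore measured *pooled* across replicate
end states (mean same-strategy neighbour fraction of DGCS agents vs the
pooled DGCS frequency), which reproduces the per-run-bar-plus-overall-
percentage reading of the clustering observable. All sizes are
configurable up to the reference protocol.

## What the experiments show (and don't)

At the canonical payoffs (T=2, R=1, P=0, S=−1, Ω=10, i.e. b=2, c=1)
with γ_s = 0 and N = 100, the stationary distribution puts its mode on
DGCS near γ ≈ c (0.66 at γ=1.2, 0.51 at γ=1.5); as γ grows further, D's
mass rises and overtakes DGCS (0.59 vs 0.36 at γ=2) even though DGCS
still risk-dominates D — social guilt peaks at intermediate guilt cost.
Non-social adaptive guilt never exceeds ~1% of stationary mass (it is
strongly dominated by D; its residual mass comes from neutral drift
with DGCS at γ_s = 0). On the lattice at b=2, γ=4, γ_s=0, DGCS is the
modal outcome in most replicates and cooperation far exceeds the
well-mixed stationary level — structure protects guilt-prone clusters
from exploiters.

These simulations are self-generated game dynamics, not data fits:
passing tests show internal consistency of the analytics and that the
scaled-down stochastic runs reproduce the qualitative structured-
population effects; they say nothing about human or animal behaviour,
and the 5-replicate scaled protocol has inherent sampling variability
(the per-replicate probability that DGCS wins the lattice run is
roughly 0.7–0.8, estimated over larger replicate sets).

## Known limitations

- Only G ∈ {0, ∞}; intermediate guilt thresholds are rejected.
- Small-mutation limit only; no explicit mutation rate in the chain,
  and no mutation during spatial runs.
- No noise in the game, no apology/forgiveness, no coevolving networks.
- The replicator module integrates trajectories; it does not enumerate
  boundary equilibria symbolically.
- Scale-free sweeps at full (10-graph × 20-replicate) scale are
  cluster-sized; defaults use smaller banks.
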