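# Methods

## Model

Agents occupy the nodes of an undirected simple graph and hold a binary
choice with spin encoding σ(A) = +1, σ(B) = −1.  Agent *i* has a net
preference `Δo_i = o_A − o_B` (utility units; only the difference ever
enters the model) and a conformity weight `w_i` (utility per neighbor).
The marginal utility of A over B is

    ΔU_i = Δo_i + w_i (#A_i − #B_i),

with `#A_i, #B_i` the neighbor counts on each option; the dependence on
the *difference* reflects the competing nature of the options.  An
update resamples the agent's choice from the Fermi rule
`p_i(A) = expit(β ΔU_i)` — a fresh draw, not a switch-only rule, so the
current choice carries no inertia of its own.  β defaults to 100, which
with |Δo| = 10 and integer neighbor differences makes every decision
with `|ΔU| ≥ 1` deterministic to ~4e−44; the model is then a threshold
model, and residual randomness comes from the update order and
neighborhood composition, not from decisions.

Dynamics are asynchronous: one step picks a uniformly random agent;
one sweep is N steps and is the time unit throughout (schedules,
horizons, and rates are expressed in sweeps, making timescales
N-independent).  Exactly one agent can change per step; ties
(`ΔU = 0`) resolve by the rule itself at p = 1/2.

Agent types are derivable from sign(w) only: conformist (w > 0),
anticonformist (w < 0), nonconformist (w = 0).  Default magnitudes are
w = ±1.  With the default networks (minimum degree 20) this puts the
system in the strong-conformity regime `|w| k ≥ 20 > |Δo| = 10`: a
unanimous neighborhood overrides any preference, which is the regime
where conformity traps exist.  All magnitudes are configurable per
subpopulation.

## Networks and placement

Erdős–Rényi graphs G(n, p) use p = mean_degree/(n−1); above the
connectivity threshold the draw is repeated (≤100×) until connected,
below it the giant component is used and its size recorded — isolated
shells would bias alignment statistics while contributing no social
coupling.  Barabási–Albert graphs grow from a complete seed on m
nodes, guaranteeing minimum degree m; the default m = 20 matches the
reference setup's k_min.

Anticonformist placement targets a Pearson (point-biserial) correlation
ρ between node degree and the anticonformist indicator.  The assignment
starts from the extremal configuration (anticonformists on the top
round(fN) degrees for ρ ≥ 0, bottom for ρ < 0, ties broken by node id)
and greedily swaps the attributes of random (anticonformist, other)
pairs, accepting a swap only if it does not increase |ρ − target|, until
|ρ − target| ≤ 0.01 (configurable) or 10⁶ swaps.  Because ρ is an affine
function of the summed anticonformist degree, acceptance is evaluated
incrementally and the loop is monotone by construction.  Targets
outside the range attainable for the degree sequence are rejected up
front.  Swaps exchange attributes only; the edge set is untouched.

Degree assortativity is tuned by two-edge, degree-ordered rewiring:
draw two edges with four distinct endpoints and reconnect them with the
two highest-degree endpoints together (assortative), highest-to-lowest
(disassortative), or a random alternative pairing (neutral), rejecting
self-loops and multi-edges so the degree sequence is preserved exactly.
Run to exhaustion the biased modes reach extreme coefficients (r ≈
+0.45 / −0.7 on BA(500, 20)); comparisons across regimes therefore use
an optional target-r stop (Newman's r recomputed periodically) so the
modes are compared at matched moderate |r| (±0.3 by default in the
tests).  Note the unbiased baseline of a heavy-tailed degree sequence
is itself mildly disassortative (structural cut-off), so "neutral"
means r near that baseline, not exactly zero.

## Environments

Three schedule kinds: *static* (each agent keeps its own fixed Δo —
the heterogeneous-preference experiments), *linear*
`Δo(t) = Δo₀ − r·t` shared by all agents, and *sinusoidal*
`Δo(t) = A₀ sin(2πt/T + φ)` shared by all agents.  Dynamic-environment
defaults: Δo₀ = 10, r = 0.1 per sweep (zero crossing at sweep 100 of a
400-sweep horizon) and A₀ = 10, T = 200 sweeps, φ = 0 over 700 sweeps
(three complete half-cycle windows), keeping the preference scale of
the static experiments and several cycles per run.

## Equilibrium, recording, reproducibility

Quasi-equilibrium for constant environments is declared when no agent
flips for 50 consecutive sweeps, with a hard horizon of 2,000 sweeps;
equilibrium alignment averages the final 10 recorded sweeps.  A pure
flip-free criterion alone cannot be guaranteed (anticonformist pairs
can cycle), hence the hard horizon; trajectories carry an explicit
equilibrium flag.  Dynamic environments disable early stopping.

One master seed spawns independent substreams per realization and,
within a realization, for network construction, placement,
initialization, and dynamics, so any component can be varied with the
others held fixed.  The sweep kernel is numba-compiled; a pure-Python
single-step implementation defines the reference semantics and is
cross-checked against the kernel in the tests.

## Metrics

**Alignment**: fraction of agents whose choice matches sign(Δo); agents
with Δo = 0 are excluded (their count reported) rather than assigned a
side arbitrarily.  "Expression achieved" uses alignment ≥ 0.9 by
default; because the transition is sharp the binary outcome is
insensitive to the exact threshold, and summaries report it at
θ ∈ {0.8, 0.9, 0.95}.  For trajectories of homogeneous subpopulations
the aligned fraction is computed from per-subpopulation A-fractions;
under shared dynamic schedules, tracking alignment compares the
population to sign(Δo(t)) over time.

**Volatility** is reported two ways: the spec-style rate (flips per
agent per sweep after a 100-sweep burn-in) and the fraction of
individuals changing their choice at least once after the burn-in
(`changers_fraction`).  Both peak at the critical anticonformist
fraction; neither exceeds twice the f = 0.5 level at these study
conditions, because anticonformists sustain an equilibrium churn
(β = 100 removes decision noise but not neighborhood-composition
fluctuation) of the same order as the critical excess.

**Tipping** (linear schedules): the lag between the schedule's zero
crossing and the first record where the global B-fraction reaches 0.5
(0.9 available); runs that never reach the threshold report an explicit
not-tipped sentinel.  **Lead time** (sinusoidal schedules): per
environment zero-crossing with a complete half-cycle of data, the
nearest same-direction majority switch (linear interpolation through
0.5) of a subpopulation within half a period; the mean of
(switch − crossing), negative when the group moves before the
environment.

**Welfare** uses package-local definitions: preference utility
`mean σ_i Δo_i / 2`, social utility `mean (w_i/2) Σ_j σ_i σ_j`, total
their exact sum.  These are stand-ins for quantities whose exact
reference formulas are not available to this package, and are flagged
as such in the API docs.

## Mean-field analysis

The well-mixed companion replaces neighbor counts by the annealed
approximation `#A ≈ kX` with X the global A-fraction and k an effective
degree, giving the self-consistency map
`G(X) = Σ_s n_s expit(β(Δo_s + w_s k(2X−1)))`.  Roots of G(X) = X are
located by a sign-change scan (default grid 2,000) refined by Brent's
method; stability uses a central finite difference of G (step 1e−6),
with one-sided drift for boundary roots.  The critical anticonformist
fraction bisects in f for the loss of bistability (anticonformists
replace each base subpopulation proportionally), reporting the jump in
the followed stable branch — the transition is discontinuous in the
well-mixed setting.

**Choice of effective degree.**  k is a required parameter.  For
matched comparisons with BA simulations the package uses k = k_min
(= m), not the mean degree, and this is a deliberate choice: the
network transition is a cascade nucleated by the lowest-degree class
(the flip condition `k_i(1 − 2f) < |Δo|` is met first at small k_i,
and quenched binomial fluctuations of neighborhood composition seed
the escape), so the single-k map that best predicts the simulated
transition is the one for the gating class.  Empirically, the
simulated alignment curve (BA or ER, N = 500–2,000) crosses 0.75 at
f ≈ 0.25–0.26; the map with k = k_min = 20 puts the fold at
f* = 0.248, while k = mean degree (≈39) puts it at 0.372.  A
degree-resolved mean field would capture this within the formalism but
is out of scope; the single-k map with k = mean degree remains
available by passing that k.

The exact finite-N companion builds the single-update Markov chain
over per-subpopulation A-counts on the complete graph (neighbor counts
exclude self).  Ergodic chains yield the stationary law by a linear
solve; at large β absorbing consensus states appear, in which case
absorption probabilities from a supplied initial distribution are
returned and flagged.  State spaces are capped at 1e5.

## Synthetic data and what the tests show

All populations are generated internally; there is no external data.
The generator reproduces the reference study conditions: BA networks
with k_min = 20 (ER available), half/half preferences Δo = ±10,
w = ±1, β = 100, initial consensus on A, with desk-scale defaults
N = 500 and 12–20 realizations (reference sizes 1,000–2,000 and 100
realizations are available behind a flag).  Real social networks have
clustering, community structure, degree-degree correlations, and
preference-network correlations that ER/BA graphs lack, and real
preferences are neither binary-symmetric nor homogeneous within
groups; passing tests therefore validate the mechanism (trap breaking,
centrality leverage, tipping acceleration, lead/lag), not calibrated
predictions for any empirical system.

## Numerical choices

expit is used for the Fermi rule (no overflow at any β·ΔU; the
compiled kernel clamps |βΔU| > 36, beyond double resolution of the
probability).  Initial A-counts are drawn without replacement so the
realized initial fraction is exact to rounding.  Subpopulation counts
use largest-remainder rounding.  Placement correlation of a constant
vector is defined as 0.  Fixed-point dedup tolerance is 1e−9; root
residuals are verified < 1e−8 in tests.

## Known limitations

Single-k mean field (no degree classes or pair approximation); no
synchronous updating, agent memory, identity, or network coevolution;
welfare definitions are local stand-ins; the volatility peak criterion
relative to f = 0.5 is not met at these conditions (see above); the
lead-time matching window (half a period) can miss switches of
severely lagging subpopulations, which then simply drop out of the
average rather than being extrapolated.
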