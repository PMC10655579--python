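# Methods

## The model

`pairbond` simulates a fixed-size population of agents whose social life
consists of exclusive dyadic relationships.  All decisions are binary and
probabilistic, driven by four persistent emotional states per agent —
attachment (stay vs. leave), cooperativeness (cooperate vs. defect),
deceit (mask a defection vs. not) and courtship (court vs. bond) — each a
real number in [−1, 1].  A state *s* maps to the probability of the
first-listed action through a sigmoid; the default is the piecewise-linear
π(s) = clip(s + ½, 0, 1), which makes strategies deterministic outside
(−½, ½) and linearly stochastic inside.  A smooth logistic
1/(1 + e^{−a·s}) is available for sensitivity runs (`SigmoidSpec("smooth",
a)`); both agree at s = 0 and in the saturation limits.

Every emotional state is governed by six heritable traits (base, decay,
and one response per outcome R/T/P/S; 24 traits in all, each confined to
[−1, 1]).  On pairing with a new partner the states are reset to the
genetic bases.  After each interaction the state updates from the agent's
*perceived* outcome Ω:

    ŝ = s + 2·G_Ω
    s' = clip(ŝ + (G_base − ŝ)·|G_decay|, −1, 1)

The doubling makes a single maximal response able to drive a state across
its whole range; the decay pulls states back toward the base so repeated
identical outcomes do not pin strategies at the deterministic extremes.
The update can transiently leave [−1, 1] (ŝ up to ±3), so the post-decay
value is clamped; clamping is applied after the decay step, not to ŝ.
The decay trait may evolve negative but acts through its magnitude.

### Life cycle per iteration

1. **Pairing.**  All unattached agents are shuffled and paired; an odd
   agent waits one iteration.  Emotions reset to base.
2. **Courtship.**  Each new pair repeatedly: draws court-vs-bond (bonding
   needs consensus of both); if at least one courts, both pay c_cou and
   play one no-payoff interaction with full emotion updates, then each
   draws stay-vs-leave (leaving is unilateral and free).  At most 20
   courtship interactions per iteration; a pair that exhausts the cap
   without bonding consensus is dissolved (both unattached, no extra
   cost).  The cap rarely binds in practice.  With courtship disabled,
   new pairs bond immediately.
3. **Bonded round.**  Every bonded pair — newly bonded pairs included —
   plays one prisoner's dilemma (R=3, T=5, S=−1, P=0 by default; stag-hunt
   and snowdrift presets for sensitivity).  Unless divorce is prohibited,
   each partner then draws stay-vs-leave; if either leaves, both pay
   c_div and are unattached next iteration.
4. **Moran step.**  Each agent dies independently with probability m.
   Widowed partners become unattached at no cost.  Each dead agent is
   replaced by a mutated clone of a survivor sampled with probability
   proportional to lifetime payoff shifted positive (payoff − min + 10⁻⁶);
   if by chance nobody survives, parents are drawn uniformly from the
   pre-death population.  Newborns are unattached with zero payoff.

Within one round: intended actions are drawn from π(s_c); under action
noise each executed action flips with probability ξ; payoffs always follow
executed actions.  A defector with deceit enabled deceives with
probability π(s_d), paying c_dec, and its partner's perceived outcome is
computed as if the deceiver had cooperated (S→R for a cooperating victim,
P→T for a defecting one).  Under perceptual noise each agent's perceived
outcome is then flipped (R↔S, T↔P) with probability ξ — one perception
event per agent per round, applied consistently to all four emotion
updates, matching the single-flip structure of the mean-field model (an
alternative reading would flip each state independently).  Deceit
determines the apparent action first; noise then corrupts the channel.
Agents always know their own executed action; only the partner-action
component of perception can be wrong.  Deceit is also available during
courtship at the same cost, since courtship decisions run on the same
architecture.

### Feature toggles

Disabling a mechanism leaves its genetic architecture intact but unread
(drifting), so experimental conditions differ minimally.  Without
bookkeeping, the post-interaction state is set directly to the outcome
response trait (s_e = G_eΩ) — a one-interaction memory in the style of
classical iterated-PD strategy spaces.  Without courtship, pairs bond on
contact.  Under prohibited divorce, bonds end only by death (courting
pairs can still separate).

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 500 | population size (sensitivity runs use other sizes) |
| m | 0.01 | per-iteration mortality |
| iterations | 100,000 | run length |
| init_sigma | 0.25 | founder trait s.d. (Normal(0, σ), clamped) |
| mut_sigma | 0.04 | per-trait mutation s.d. |
| ξ | 0–0.20 | noise level (perceptual or action) |
| c_cou | 0 / 0.4 / 0.8 | cost per courtship interaction |
| c_div | 0 / 4 / 16 | divorce cost to each partner |
| c_dec | 0–1.6 | cost per deception |
| max_courtship | 20 | courtship interactions per iteration cap |

All costs are in payoff units of the stage game.  The crossed design
(`paper_grid`) enumerates noise kinds × levels × cost levels × mechanism
toggles, holding a disabled mechanism's cost at its first level to avoid
redundant cells.

## Strategy classification

A genotype's likely behaviour after outcome Ω from a stated prior
(s_c, s_a) is computed by one application of the update rule (with
clamping, exactly as simulated; the outcome-trait lookup when bookkeeping
is off): divorce if s_a′ ≤ 0, cooperate if s_a′ > 0 and s_c′ > 0, else
defect.  The (R, T, P, S) response pattern is matched against the category
table with precedence Quitter → Defector → Opportunist → exact rows; the
precedence makes the 81 patterns partition exactly (verified by
enumeration).  The boundary case s_a′ = 0 counts as divorce.  A pattern
with divorce on R and defection (not cooperation) on both T and P is
counted Defector, not Quitter.  Prior-state presets are negative
(s_c=−1, s_a=−0.5; lower attachment would have divorced deterministically
already), neutral (0, 0) and positive (1, 1).  Classification is
genotype-based, not trajectory-based.

## Mean-field analytics

For analysis the traits and states are treated as unbounded and the decay
as nonnegative; perceptual noise only.  Given cooperation probabilities
p, p′ the outcome distribution is ω = (pp′, p(1−p′), (1−p)p′,
(1−p)(1−p′)) over (R, S, T, P), and

    E[s(t+1)] = s(1−G_v) + G_b·G_v + ω · 2(1−G_v)[(1−ξ)G_i + ξG_j]

with j the noise-flipped outcome of i.  In the small-decay limit the
per-interaction attachment drift against a partner cooperating with
probability x (focal cooperating surely) is

    Δ(x) = G_aR[(1−ξ)x + (1−x)ξ] + G_aS[ξx + (1−x)(1−ξ)]

linear in x with slope (G_aR − G_aS)(1 − 2ξ).  `delta_attachment` returns
this undoubled weighted-response term by default; the raw state increment
of the update rule carries an extra factor 2 (`include_update_factor`),
which affects neither sign nor monotonicity.  `build_detector` solves the
fixed-point condition s* = G_ab + (2(1−G_v)/G_v)·Δ(x) = 0 at x = 1−ε for
G_aS given G_ab = 0.5 and G_aR chosen inside the trait bounds (default
decay 0.01 so a finite fixed point exists; the zero-decay limit is the
sign of Δ itself).  Detection is feasible exactly when ξ < ½.  Mean-field
vs. simulation consistency is tested only in regimes where neither the
state clamp nor sigmoid saturation is active — there the piecewise sigmoid
is linear, so the recursion on means is exact.

## Determinism and numerics

Every run is driven by one `numpy.random.Generator(PCG64)` seeded from the
config; identical (config, seed) reproduces every output bit-for-bit.
Sweep replicates derive child seeds as CRC32 of (base seed, cell id,
replicate index), keeping them stable, collision-resistant and resumable.
The population is stored as a struct of arrays and all phases operate on
index vectors; the two-agent operations are singleton calls into the same
kernels, so there is a single implementation path.  Trait bounds use the
closed interval [−1, 1] (the open-interval boundary has probability ~0
under Gaussian mutation and is behaviourally indistinguishable past the
sigmoid's saturation at ±½).  Fitness weights use payoff − min + 10⁻⁶,
the simplest strictly positive rank-preserving transform; reproduction
uses the raw cumulative lifetime payoff.  Per-agent ledgers (PD totals and
counts of courtships, deceptions, divorces) are carried alongside payoffs
so tests can assert the books balance to machine precision.

## Metrics

The mutual-cooperation rate of an iteration is the fraction of *bonded*
PD rounds in which both executed actions were cooperate — realized
behaviour, not intentions or perceptions; an iteration with no bonded
rounds counts 0 rather than missing, so a never-bonding population reads
as non-cooperative.  Metrics are recorded every `thin` iterations (default
100) plus the final iteration; genotypes are dumped at the last iteration
only.  Run-level courtship effort is the mean number of courtship
interactions per new pairing over the whole run; across runs we report the
mean of the top quartile (ceil(n/4) largest run means) and the maximum.

## What the scaled-down experiments show — and what they do not

The full-scale experiments behind the headline evolutionary findings are
100,000-iteration runs of 500 agents with ~100 replicates per condition —
cluster-scale work.  The package's tests and acceptance script replicate
the qualitative findings at N = 200 and 20,000 iterations with 6–8
replicates per condition: (i) at perceptual noise 0.12 with costly
divorce and no deceit, bookkeeping+courtship sustains significantly more
mutual cooperation than the memoryless no-courtship condition (one-sided
Mann–Whitney, α = 0.05); (ii) free deceit collapses cooperation below
0.1 even with both mechanisms on.  These sizes keep a full verification
run in the minutes range on one CPU while leaving the orderings clearly
resolved; they do not reproduce the printed full-scale magnitudes, and
between-replicate variance at this scale is large (cooperation dynamics
are dominated by critical transitions).  The synthetic populations are
the study conditions themselves — the model has no external data — so
passing tests demonstrate internal correctness and the stated qualitative
phenomena, not calibration to any empirical system.

## Known limitations

- Pairing is uniformly random; there is no mate choice among candidates,
  spatial structure, or extrapair interaction.
- Payoffs are symmetric within a pair; deceit is all-or-nothing and never
  probabilistically detected.
- The analytical module covers perceptual noise only and ignores bounds;
  its detector construction presumes a deterministically cooperating
  focal agent.
- The classifier's precedence resolves table ambiguities (documented
  above); genotypes are classified by one-step lookahead, so strategies
  conditioning on longer histories are projected onto the nearest
  category.
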