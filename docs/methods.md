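# Methods

This note records the model, the estimators, the numerical choices and the
limits of what the desk-scale experiments demonstrate.

## Aoristic patterns from sherd records

A record is (site, ware, year_from, year_to) with inclusive calendar years
in astronomical numbering (200 BC = −200; no special year 0).  Its per-year
weight is 1/duration: a find dated AD 1–10 contributes 0.10 to each of
those years, AD 1–100 contributes 0.01.  Per site and ware, weights of all
records are summed per year and **capped at 1**, so the per-year score is
interpretable as a presence probability; bin values are means of per-year
scores over each half-open 10-year bin.  The default grid is 50 bins over
[−200, 300).

The cap is a modelling choice: summed partial probabilities can exceed one
at richly recorded sites, while the analysis only ever uses presence or
absence.  A `presence="threshold"` switch treats any positive evidence as
presence 1 — the other defensible reading — and is propagated through the
pattern functions.

*Pattern A*[p, w] is the mean presence probability over sites.  *Pattern
B*[p, k] is the mean over sites of P(exactly k of the five wares present),
computed by treating a site's per-ware presence probabilities as
independent Bernoulli events and expanding the count distribution exactly
(Poisson binomial, dynamic-programming convolution).  How fractional
presence should enter diversity counts is genuinely underdetermined;
independence is the least-structured completion, and with presence values
in {0, 1} it reduces exactly to the empirical histogram of per-site ware
counts (a tested invariant).  Rows of B sum to 1 within 1e−9.

Sites whose records all fall outside the grid contribute zeros, not
errors; a fully empty record table is an error unless sites are declared
explicitly.

## The market model

Agents: N = 500 by default (one settlement's aggregated traders each);
one producer per ware, dormant outside its availability window, all other
agents produce money (the sixth good, always active).  Value vectors — the
transmitted cultural trait — hold one strictly positive value per good,
initialised uniform on (0, 1] and redrawn for a ware whenever it (re)enters
the market.  Dormant producers keep their identity; roles are never
reassigned.

Chronology: the conventional six phases of ware availability partition
[−200, 300]; simulation step s maps to year −200 + 500·s/t.  An
`include_its=False` chronology supports the sensitivity run without the
western import.

Each economic step:

1. **Production.**  Each active ware producer gains q_ware =
   (#consumers)/(#active wares) units; each consumer gains q_money = 1.
   These defaults balance aggregate ware supply against aggregate money
   demand; both are configurable.
2. **Trade.**  Every ordered pair (i, j) with distinct produced goods is
   visited once, in fresh random order.  Buyer i bids b = v_i(g_j)/v_i(g_i);
   seller j asks a = v_j(g_j)/v_j(g_i); one unit of g_j moves iff b ≥ a,
   the seller holds a unit and the buyer can pay the geometric-mean price
   √(ab) in its own good.  The rule is one concrete instantiation of
   mutually-beneficial bilateral exchange from private values; it conserves
   goods exactly and is isolated in a single kernel for substitution.
   Acquisition tallies count non-money inflows on **both** sides of a trade
   (units bought, and ware received as payment when a consumer sells
   money): the two channels are the same economic event seen from either
   ordered pair, and counting one only would make ledgers depend on pair
   orientation.
3. **Consumption.**  All inventories are zeroed.

Every ω economic steps (ω ≥ 2) a cultural step runs.  Scores are
1 − min(1, |c − T|/T) where c is the tally since the last cultural step —
non-money units for consumers, money earned for producers — and T defaults
to ω (one unit per economic step).  The form realises "enough but not too
much" on [0, 1], as the copying algorithm's comparisons against uniform
draws require.  Then the learning variant updates value vectors, and
innovation perturbs, for each agent with probability μ, one uniformly
chosen active-good value to a fresh draw on
(max(1e−9, v(1−μ_max)), v(1+μ_max)) — positive however large the spread.

Learning operates within produced-good groups; with one producer per ware
the consumers (money group) are the only group where copying can occur,
which is the intended reading: the hypotheses concern the settlement
traders' buying strategies.  *Unbiased*: each agent copies a uniformly
chosen other member's whole vector with probability λ, simultaneously
(from a pre-step snapshot, so a pair at λ = 1 swaps).  *Success-biased*:
a replacement quota ⌊0.2·N/n_good⌋ (capped at group size − 1) is filled by
admitting agents j when a uniform draw exceeds score(j)^λ_str; candidates
then copy models i accepted when a uniform draw falls below score(i)^λ_str
**and** score(i) > score(j) strictly.  The strictness means equal scores
never copy.  λ_str enters as the exponent in both selection tests, with
λ_str = 1 the plain algorithm; both phases are bounded by 10 × group size
attempts, and leftover candidates are dropped with a log entry (the loop
would otherwise not terminate when no higher-scoring model exists).  The
replaced agent, not the model, leaves the candidate set after a copy —
the only reading under which the loop drains.  Whole-vector copying is the
default (a strategy is the whole list); `copy_scope="single_good"` copies
only the group's good.

Reporting: t is rounded down to the nearest multiple of 50·ω so the 50
reporting periods hold a whole number of cultural steps each; t below one
cultural step per period is an error.  The acquisition log is
(50 periods × consumers × wares) units acquired.  A consumer "has" a ware
in a period iff it acquired any units, and simulated patterns A/B are
shares over consumers (producers trivially hold their own ware and are
excluded).

## Distance

δ(s, d) = (1/(P·|W|)) Σ_p Σ_i (s_ip − d_ip)², on the [0, 1] proportion
scale (0.865, not 86.5), so δ ≤ 1; the combined statistic is
Δ = (δ_A + δ_B)/2.  The mean-of-squares form is consistent with the worked
single-cell example ((0.865 − 0.1)² = 0.585225 ≈ 0.585) and with epsilon
thresholds of order 0.01; a `rooted_per_period` alternative (per-period
Euclidean norms, same normalisation) is provided.

## ABC-PMC

Priors: μ ~ U(0,1), μ_max ~ U(0,10), λ ~ U(0,1), λ_str ~ U(0,10),
t ~ U(50,1000), ω ~ U(1,50), subject to the hard constraints ω ≥ 2 and
50 ≤ t/ω ≤ 1000, enforced by rejection sampling.  Parameters a variant
does not use are carried (sampled, perturbed) but ignored by the
simulator.  θ is continuous; t and ω are rounded to integers at simulation
time, and the rare rounding that exits the feasible region scores an
infinite distance.

Level 1 proposes from the prior.  Later levels resample the previous pool
by weight and add Gaussian noise with covariance **2× the weighted
empirical pool covariance**, the common adaptive choice; a degenerate pool
(singular covariance, or a single particle) falls back to diagonal jitter
with standard deviation 1% of each parameter's prior range.  Rates are
clamped to [0, 1] and scale parameters to (0, ∞) — but not to their prior
upper bounds, so later generations can explore past them.  Proposals
violating the hard constraints are redrawn.

Importance weights: w_i ∝ π(θ_i) / Σ_j w_j K(θ_i | θ_j) (prior over
kernel mixture), the standard correction for adaptive proposals; clamping
makes the kernel density approximate near the boundary, which we accept.
`weights="uniform"` reproduces plain unweighted PMC.  Particles that
wander outside the prior support get zero weight.  If every weight
vanishes the level falls back to uniform weights with a warning.

Epsilon ladders: the published 13-step ladder
(0.13, 0.011, 0.0109, …, 0.0099) is available for full-scale runs.  At
desk scale two self-tuning options are used: an adaptive ladder (level
s+1 = median of level s's accepted distances; level 1 accepts everything)
for single-model inference, and a fixed quantile ladder calibrated from a
prior-predictive pilot **pooled over the models being compared** for model
selection — a shared ladder is what makes cross-model acceptance rates,
and hence Bayes factors, comparable.  Each level is bounded by a proposal
budget; an exhausted level returns its partial pool flagged incomplete and
stops the ladder.

Model evidence is approximated at the final level as
L = (Σ raw importance weights of accepted) / (proposals attempted), which
reduces to the plain acceptance rate under uniform weights; K = L₁/L₂, with
K = +∞ and a warning when the denominator accepts nothing.  Whole-run
acceptance totals are *not* used: evidence must be read at a common final
epsilon.  When two runs stall at different depths the factor is computed
at the deepest level both attempted.

Posterior summaries: per-parameter weighted Gaussian KDE (Silverman
bandwidth); the mode is the density argmax on a 512-point grid extended 3
bandwidths past the sample range; the p% HDR is the smallest
density-ranked set of grid points covering mass p, merged into contiguous
intervals (possibly several, for multimodal pools).  A numerically
point-mass parameter gets a zero-width HDR; fewer than 10 particles is an
error.

Determinism: all randomness flows from one master seed.  Per-proposal
simulator seeds are counter-based (`SeedSequence((seed, level, counter))`),
so the simulator — a pure function of (θ, seed) — can be evaluated in any
order or on any map backend without changing results.

## Synthetic data

The generator emulates the *shape* of the empirical record set, not its
numbers: 178 sites of lognormal richness (most sparse), five wares with
the chronology's availability windows, early-ware dominance (ESA record
dates skewed early via a Beta(1, 1.6) profile, so its share declines as
the western import's window opens), and dating widths drawn from a
narrow/broad mixture (60% uniform 10–50 years, 40% uniform 100–300 years)
clipped to the ware's window.  Site/ware adoption is Bernoulli with
probability 1 − exp(−3·size·weight); the requested record total (default
8,730) is then allocated multinomially across adopted pairs, so counts are
exact.  Generated dates always lie inside the generating ware's window (a
tested invariant), and tables round-trip losslessly through the parser.

What passing tests on these data do **not** show: that the generator's
marginal record densities match the real database (no numerical fit is
attempted — the real table remains an optional input with the same CSV
schema), nor that inference at desk scale has the power of the full-scale
study.

## Desk-scale study conditions

The standing ground truth for validation experiments is the
independent-learning model at N = 50 agents, t = 200 economic steps,
ω = 4, μ = 0.3, μ_max = 2.0.  Parameter recovery uses pools of 100
particles down a four-level adaptive ladder (proposal budget 30× quota);
model selection uses pools of 50 down a fixed four-level pooled-pilot
ladder (20 pilot simulations per model, budget 20× quota).  The conjugate
normal-mean toy problem (prior N(0,1), 20 observations, unit noise,
distance = |difference of sample means|) checks the sampler against a
known posterior: the final-pool mean should sit within 3 Monte-Carlo
standard errors (weighted sd / √ESS) of the analytic posterior mean.

These sizes are the package's desk-scale choices; they keep a full
validation sweep in the minutes range on one CPU.  At this scale
posteriors are wide — coverage checks pass because the HDRs are honest
about that width, not because the parameters are sharply identified — and
Bayes factors carry Monte-Carlo noise of order tens of percent.  The
full-scale configuration (N = 500, the published ladder, pools of 500,
~10^6 simulations) runs through exactly the same code paths.

## Numerical choices and degenerate inputs

* Per-year presence scores capped at 1 *before* bin averaging.
* Poisson-binomial expansion is exact (no normal approximation).
* Trade executes only if the buyer can pay the full geometric-mean price;
  lots are one unit per ordered pair per round.
* Innovation's positivity floor is 1e−9.
* The pair-shuffle inside the trade kernel uses scaled-float index draws
  (cheaper than bounded integer draws in the hot loop; the bias is
  O(2⁻⁵³) per draw).
* Prior rejection sampling and kernel redraws carry large attempt caps; a
  kernel that cannot find a feasible jitter returns the (feasible)
  resampled particle itself.
* Epsilon ladders must be strictly decreasing; quantile ladders nudge ties
  downward by a relative 1e−9.

## Known limitations

* No spatial structure, transport costs or network topology; trade is a
  single global market.
* The trade mechanics beyond the conservation contract (price rule, lot
  size, production quantities) are plausible instantiations, not
  identified quantities; conclusions should be read conditional on them.
* Pattern B's independence assumption ignores within-site correlation of
  ware presence.
* Acceptance-rate evidence is a coarse marginal-likelihood estimator; it
  inherits Monte-Carlo noise from both the pilot ladder and the final
  level, and no regression adjustment is applied.
* Quantity/weight information in the archaeological record is deliberately
  unused (unreliable across excavations); only presence/absence enters.
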