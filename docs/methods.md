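# Methods

This note documents the model the package implements, the constants and
defaults it uses, what the synthetic generator does and does not emulate,
and the numerical choices behind estimation.

## Model

State: a directed binary adjacency matrix over N fixed actors (no
self-ties) and one integer-coded behavior per actor with hard coding bounds
[z_min, z_max].  Fixed covariates: sex, grade, black race, Hispanic
ethnicity (binary/ordinal categories), age (years), household income ($1k;
missing values mean-imputed and flagged).

Dynamics: between two observation waves, change opportunities arrive as a
Poisson process with total intensity N·(λ_net + λ_beh) over a unit-length
period — equivalently, exponential waiting times.  Each opportunity selects
an actor uniformly and is a network opportunity with probability
λ_net/(λ_net + λ_beh).  This is the *unconditional* simulation convention:
the period length is fixed at 1 and the rates are free parameters, rather
than conditioning the simulation on the observed amount of change.  Both the
period length and this choice are configuration, not data-driven.

Network ministep: the candidate set is the current state plus the N−1
states reachable by toggling one outgoing tie (keep-same plus N−1 toggles —
"as many choices as there are actors"; self-ties are never offered; no
multi-tie moves).  Behavior ministep: z − 1, z, z + 1, with the infeasible
move removed at the bounds.  The chosen action follows a multinomial logit:
p(c) ∝ exp f(c), computed with max-subtraction for overflow safety.  The
rule is invariant to adding a constant to all candidate objectives, which
several reported quantities rely on (below).

Effects (network function, canonical order): outdegree, reciprocity,
transitive triplets Σ_{j,h} x_ij x_ih x_jh, same-sex/grade/black/hispanic
tie counts, centered age- and income-similarity sums, behavior ego
(outdegree × centered own behavior), behavior alter (sum of alters'
centered behavior), behavior similarity (centered similarity sum).
Behavior function: linear and quadratic shape in (z − z̄) plus average
similarity (the peer-influence effect), with average similarity defined as
0 for isolates, so a friendless ego's choices are driven by shape alone.

Behavior values enter the ego and alter network effects centered by z̄.
Centering is the standard convention for these statistics and keeps them on
an interpretable scale; the worked-scenario arithmetic is consistent with
it.

Similarity: sim(v_i, v_j) = 1 − |v_i − v_j|/range, centered by the mean
dyadic similarity.  By default z̄, the range and the centering mean are
pooled over all actors and both waves; all three are overridable per
behavior, which is how constants recovered from published worked examples
are injected.

## Published parameter sets and backed-out constants

`sabm.published` carries the fitted parameters of the six school × behavior
models (two schools: "Jefferson", rural and homogeneous, and "Sunshine",
urban and diverse; three behaviors: integer BMI, screen time in 10 h/week
categories 0–9, active-sports score 0–3).  Three constants needed to
evaluate the BMI behavior objective were not reported and are recovered
from the printed worked-scenario objective values
(`backout_worked_constants`):

- the three centered similarities (−0.1075, −0.0772, −0.0470) follow by
  subtracting the friendless scenario's shape-only objectives from the
  two-alter scenario's objectives and dividing by β_avsim = 14.10;
- consecutive candidates change |ego − alter| by one unit, so the
  similarity increment per BMI unit is their mean spacing, 0.0302, giving
  an effective range of ≈ 33.06 (the observed BMI span, 44.3 − 13.8 = 30.5,
  is also supported via configuration — the two disagree in the source and
  both readings are exposed);
- the centering mean ≈ 0.865 follows from the middle similarity at the
  7-unit gap.

Two published readings conflict internally and are left as documented
ambiguities: the ego-BMI ("sociability") coefficient appears as both 0.14
(worked-example prose) and 0.014 (parameter table) — the worked network
reconstruction uses 0.14 and states so in its output — and the printed
"+0.047" up-move similarity has the opposite sign of the value implied by
the printed objectives (−0.047); the package follows the objective values.

The probability tables (behavior change by ego level × common alter level)
do not need the centering mean at all: with all alters at one level the
centering term shifts every candidate objective equally and cancels in the
choice rule.  The screen-time table centers at z̄ ≈ 1.49 categories
(14.9 h/week ÷ 10); because that centering is not stated in the source, the
screen-time cells carry a wider tolerance (±0.03) in the tests.

The worked network scenario (4 actors; printed objectives −2.77, −2.52,
−0.26, −3.18) identifies only the combination
0.91·(centered age similarity) + 0.54·(centered BMI similarity) — the
candidate design matrix is rank-1 in those two unknowns — so
`worked_examples` recovers that combination by least squares and reports
the reconstruction error (max ≈ 0.03, keep-same reconstructs to −2.80
against the printed −2.77).  The probabilities themselves are recomputed
from the printed objectives exactly.

## Synthetic school generator

The generator produces two-wave panels with a known data-generating
process.  Wave 1 ties come from an independent-dyad model: for each
unordered pair, the first direction is Bernoulli with log-odds = baseline +
homophily weights × attribute matches/similarities, and the reverse
direction receives a reciprocity boost if the first realized.  The baseline
is calibrated by bisection so the expected mean out-degree hits its target
(realized values land within ±0.1–0.2 at N ≥ 120).  Wave 1 behaviors are
drawn from a configurable integer distribution (rounded normal for
BMI-like, truncated geometric for screen-time-like, categorical for
sports-like marginals; BMI integers round half away from zero).  Wave 2 is
the endpoint of a recorded ministep simulation from wave 1 under the
ground-truth parameters; panels whose realized change counts fall outside
configured bands are redrawn, and the generation error reports the realized
counts when the bands cannot be met.

What it emulates: directed nominations (optionally capped at 10, ≤ 5 per
sex), sparse networks, reciprocity excess, attribute homophily,
school-like attribute and behavior marginals, mean-imputed missing income.
What it does not: transitivity in the *initial* network (the dyad model is
deliberately not an exponential-family graph model — wave-1 triplet counts
are lower than in real school networks, and transitive structure enters
only through the evolution process), degree heterogeneity beyond what
homophily induces, survey nonresponse and attrition, and any dependence
between attributes.  Passing tests therefore demonstrate that the
estimator recovers known mechanisms under this stylized process, not that
it would do so under every real-data pathology.

Presets: `jefferson_like` (default N = 120, a scaled-down dense homogeneous
school: mean out-degree target 3.5, grades 9–11, no Black students, BMI
14–44) and `sunshine_like` (default N = 200, sparser and diverse: mean
out-degree 1.8, 21% Black, 41% Hispanic, 39% missing income).  The
ground-truth parameters of each preset are the published parameters of the
corresponding school model.

## Estimation

Method of moments on a two-wave panel.  Targets: the rate parameters are
matched to change distances (number of tie variables differing between
waves; sum of absolute behavior changes), each network effect to the
wave-2 sum of its per-ego statistic (evaluated with wave-2 behavior), the
behavior shape effects to Σ(z − z̄) and Σ(z − z̄)², and the influence effect
to the wave-2 sum of per-ego average similarity.  Homophily effects whose
attribute is constant in the school are dropped automatically with a
warning (their statistic is collinear with outdegree — e.g. race homophily
in a racially homogeneous school).

Stochastic approximation: derivatives of expected targets with respect to
parameters are estimated by symmetric finite differences with common random
numbers (default perturbation 0.75 for effect weights, 20% for rates).
Phase 2 iterates θ ← θ − a · diag(D)⁻¹ (simulated − observed) over
subphases (defaults: 30/60/90/120 iterations; reduced study settings
20/40/60/90) with the gain a halved at each subphase from a₀ = 0.2, the
diagonal re-estimated each subphase and pooled across subphases, steps
clipped at 0.3·(1 + |θ|) per coordinate, each subphase ended on the Polyak
average of its tail, and the final subphase averaged over its whole path.
The diagonal update was chosen after the full-Newton step
θ ← θ − a·D⁻¹(dev) proved divergent under Monte-Carlo noise in D, even with
damping and clipping: matching each target primarily through its own
parameter is slower on strongly coupled pairs (outdegree/reciprocity,
behavior homophily/influence) but never explodes.  If any convergence
t-ratio (mean deviation / sd of simulated targets over the phase-3 runs)
exceeds 0.15 in absolute value, phase 2 restarts from the current point
with halved subphase lengths and gains that continue decreasing; remaining
non-convergence is flagged in the result, never silent.

Standard errors: Monte-Carlo delta method, cov(θ̂) = D⁻¹ Σ D⁻ᵀ with Σ the
covariance of the phase-3 simulated targets (≥ 100 runs required; default
500, reduced 120) and D a fresh finite-difference estimate at θ̂.  A
zero-variance simulated target or a singular D raises an error naming the
offending/collinear effects rather than reporting a misleading zero.  This
replaces the score-function standard errors used with this model family
elsewhere; results label the method `monte_carlo_delta`.  On a two-actor
model whose moments are enumerable exactly (four-state continuous-time
Markov chain, unit-time distribution by matrix exponential), the simulated
moments and the delta-method errors agree with the closed form within
Monte-Carlo tolerance (tests).

Initial values: rates at 1.5 × (observed changes / N), β_deg = −1, all
other effects 0.  Rates are floored at 0.05 during iteration.  Estimation
is seed-reproducible end to end; every result records its seed.

## Simulation study (tests)

The recovery study generates 20 panels at N = 60 (mean out-degree 3,
behavior coded 0–6, rates 3.0/2.0, β_deg = −2.5, β_rec = 2.0): ten with
behavior homophily only (β_beh_sim = 3, β_avsim = 0) and ten with peer
influence only (β_avsim = 3, β_beh_sim = 0).  Each panel is fitted at the
reduced phase lengths with six free parameters.  The acceptance test
requires ≥ 90% of fits to cover every true parameter within 3 reported
standard errors and the absent mechanism to be non-significant (|estimate|
≤ 2 SE) in ≥ 80% — i.e., selection and influence injected separately are
recovered separately.  The study sizes (N, phase lengths, 20 replicates)
are the package's desk-scale defaults; at these run lengths roughly half
the fits end with a largest |t| between 0.15 and 0.35, which widens their
standard errors honestly rather than biasing the estimates.

## Degenerate inputs and tie-breaks

No self-ties ever enter a candidate set.  Isolates contribute 0 average
similarity (0/0 := 0).  A constant attribute makes its similarity
identically 1 (span fallback 1.0) and its homophily effect droppable.
Behavior candidates at the coding bounds are truncated, mirroring the "na"
cells of the probability tables.  ChoiceDistributions must sum to 1 within
1e−12.  Sampling uses inverse-CDF on the cumulative probabilities of the
candidate list, so traces are bitwise reproducible for a given seed.

## Known limitations

Rates are homogeneous across actors (no covariate-dependent rate
functions); composition is fixed (no joiners/leavers); only two waves; one
behavior per model.  The wave-1 generator's lack of initial transitivity
means the transitive-triplets effect is identified mostly from evolution,
not from the initial state.  The full-matrix Newton update and
score-function standard errors of mature SABM software are intentionally
not implemented; the diagonal scheme trades some efficiency for
robustness at small N.
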