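# Methods

## The problem

When several carers provision a shared brood — a breeding pair plus a
variable number of helpers — each visit to the nest is a discrete,
timestamped investment event. "Turn-taking" is the tendency of a carer to
visit after *another* carer rather than repeat its own visit. Observed
alternation, however, conflates two mechanisms:

* **passive turn-taking** — alternation that arises without any carer
  attending to the others: more carers mechanically dilute repeat visits,
  unequal visit rates shift the expectation, and a refractory period (the
  minimum time to travel from the nest, forage, and return) blocks quick
  repeats while leaving the nest open to everybody else;
* **active turn-taking** — a carer genuinely suppressing its own rate while
  it is the most recent visitor and releasing it once somebody else visits.

The package separates the two: a continuous-time Markov model quantifies the
who-follows-whom rate structure, and a within-carer interval-shuffling
randomization builds the passive-only null against which the observed
statistics are judged.

## The rate model

The state of the nest is the identity of the last visitor. Every visit is an
exactly observed transition, so the data reduce to sufficient statistics
`n[i][j]` (visits by carer *j* while *i* was last) and exposures `T[i]`
(total time with *i* last, over fully observed within-day intervals), and

```
logL(q) = Σ_ij n[i][j] log q[i][j] − Σ_i T[i] Σ_j q[i][j].
```

Three nested parameterizations are fitted, all with closed-form MLEs:

| model          | free rates                          | parameters | MLE |
|----------------|-------------------------------------|-----------:|-----|
| full           | q[i][j] for every ordered pair      | c²         | n[i][j]/T[i] |
| per-individual | λᵢ (following another), μᵢ (repeat) | 2c         | λ̂ᵢ = Σ_{j≠i} n[j][i] / Σ_{j≠i} T[j]; μ̂ᵢ = n[i][i]/T[i] |
| pooled         | λ₀, μ₀ shared by all carers         | 2          | λ̂₀ = Σ_{i≠j} n[i][j] / ((c−1) Σ T); μ̂₀ = Σ n[i][i] / Σ T |

Model comparison uses likelihood-ratio tests with χ² reference
distributions (df = difference in parameter counts). Turn-taking is
summarized per carer by λ̂ᵢ/μ̂ᵢ and at group level by
mean(λ̂ᵢ)/mean(μ̂ᵢ); the pooled λ̂₀/μ̂₀ is reported alongside as a
robustness statistic. A Wilcoxon signed-rank test of λ̂ᵢ against μ̂ᵢ uses
the exact distribution up to 25 carers and the normal approximation beyond
(or whenever ties defeat the exact distribution).

Assumptions and their handling:

* **Exponential holding times.** Refractory periods violate this; that is
  precisely why conclusions about *active* turn-taking rest on the
  randomization test, not on the Markov fit alone. No semi-Markov model is
  fitted.
* **No censoring terms.** The interval before a day's first visit (state
  unknown) and after its last visit contribute nothing. This keeps every fit
  closed-form and is the standard treatment for exactly observed event
  sequences; the omitted right-censoring term is one per carer-day and is
  negligible at the visit densities of interest.
* **Boundary zeros.** A transition never observed gets rate 0 at the MLE;
  LRTs computed from fits with boundary zeros are flagged, since the χ²
  approximation degrades there.
* **Units.** Exposures are kept in seconds internally; the likelihood and
  fits are unit-agnostic and rates are converted to per-hour only in
  reports. Rescaling time rescales rates inversely, shifts logL by a
  deterministic Jacobian, and leaves every LRT statistic unchanged (tested).

The 2c-state "dummy + reset" encoding (a second state per carer entered on a
repeat visit, with a fixed very high reset rate back) exists only as a
structural export for cross-validation against general multi-state fitting
toolchains, which cannot represent self-transitions directly. Our likelihood
never uses it.

## Sequence statistics

* **Alternation proportion** — fraction of consecutive within-day visit
  pairs with different visitors; pairs never span a day boundary.
* **k-category runs test** — conditions on the per-carer visit counts, so it
  corrects the naive alternation expectation for group size and rate
  inequality. `E[R] = (N(N+1) − Σnᵢ²)/N` and
  `Var[R] = [Σnᵢ²(Σnᵢ² + N(N+1)) − 2NΣnᵢ³ − N³]/(N²(N−1))`; both are exact
  (verified against exhaustive enumeration of every composition with
  N ≤ 8). A seeded Monte-Carlo mode (permutation of the sequence, add-one
  p-value) is the reference; the normal approximation uses no continuity
  correction, so the two drift apart by up to ~0.05 for sequences of less
  than about a hundred visits — the Monte-Carlo mode is preferred near
  decision thresholds.
* **Bout test** — group IVIs of the first observation day, dichotomized at
  the median (ties short), tested one-sided for *fewer* runs than the
  Wald-Wolfowitz expectation: clustering of short intervals indicates
  synchronous provisioning bouts, which would undermine the premise that
  carers respond to individual visits.
* **Ordering diagnostic** — per carer, Spearman correlation of IVI length
  against temporal index with a two-sided permutation p-score. Interval
  shuffling is only a valid null when intervals are exchangeable within a
  carer-day; systematic trends would bias it, so the pipeline warns when the
  mean p-score leaves [0.05, 0.95]. The specific ordering statistic is this
  package's choice of a simple trend test; other monotone-association
  statistics would serve equally.

## The dissociation (randomization) test

For each carer-day, the observed inter-visit intervals are randomly
re-ordered and artificial visit times rebuilt from the carer's observed
first visit; all carers' artificial times are merged (exact ties ordered
uniformly at random, freshly per replicate) into an artificial day. The
shuffle preserves, exactly: the visit count, the IVI multiset, and the first
and last visit time of every carer-day — asserted in tests for every
replicate. What it destroys is only the cross-carer timing structure, i.e.
any active response. Default 1000 replicates.

For each statistic (alternation proportion; group λ/μ ratio) the test
reports `p_active = (#{null ≥ observed} + 1)/(n_reps + 1)` — one-sided,
because active turn-taking can only push the statistic up — and a
`passive_flag` set when the entire null range sits above the
no-turn-taking reference (ratio 1, or the counts-only alternation
expectation `1 − Σnᵢ(nᵢ−1)/(N(N−1))` pooled over days): passive structure
alone then produces turn-taking. Anchoring at the first visit rather than
the day start preserves day phenology and makes the last-visit-time
conservation exact; the choice is immaterial to the statistics, which
depend only on order and gaps. If the per-individual ratio is undefined
(zero mean repeat rate) in more than 5% of replicates, the pooled ratio is
substituted and flagged.

## Data ingestion and filtering

Raw PIT-tag reads are collapsed into visits by gap-chaining: a read extends
the carer's current visit while the gap to that carer's previous read is at
most 2 min (configurable), and the visit is stamped at the chain's first
read (arrival). Chaining per-gap, rather than a fixed window from the first
read, is the common transponder-processing convention; note it imposes a
2-min floor on individual IVIs, itself a small passive-turn-taking term.
Days are half-open calendar windows supplied by config (default: calendar
dates). Filters: days with brood age ≤ 10 days removed (brooding females
confound provisioning), the fledge day removed when known, visits inside
user-declared disturbance windows removed. No automatic disturbance
detection is attempted.

Significant carers: iteratively, the least-visiting carer is excluded when
its count fails to *exceed* 20% of the mean count of the rest (a count
exactly at the cutoff is excluded); only the current minimum is tested each
round. The retained set is a fixed point of the rule and independent of
input order. Fitting requires every significant carer to have more than 10
visits and at least two carers; more than 6 carers only warns (data demand
grows as c²).

## The simulator

Three modes generate `ProvisioningAttempt` objects indistinguishable in
structure from ingested field data:

* **markov** — the fitted model run generatively (competing exponentials);
  ground truth for recovery and calibration studies. The first visitor of a
  day is drawn from column-averaged rates; the first interval never enters
  the likelihood, so this cannot bias fits.
* **mechanistic** — renewal carers with an optional refractory period
  (fixed or gamma) and an active-response multiplier β on a carer's hazard
  while it is the last visitor. β = 1 gives passive-only data; β < 1 maps
  exactly onto the λ > μ signature the rate model measures. Simulation is
  exact: hazards are piecewise constant between events and refractory
  expirations, and clocks are redrawn at each change point (valid by
  memorylessness).
* **bouts** — Poisson bout onsets at which each carer visits with fixed
  probability at a uniform jittered offset; exercises the bout runs test.

Defaults portray the cooperative-breeder setting the analysis addresses:
4 carers (pair + 2 helpers), base rate 7 visits/h each (median individual
IVIs of roughly 6–10 min), gamma(2, 90 s) refractory (mean 3 min,
travel-plus-foraging scale), 12-h observation days, 3 days, β = 1. What the
simulator does *not* emulate: diurnal rate variation, weather and brood-age
effects, prey-size variation, group foraging trips other than the explicit
bout mode, and tag-read dropout. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated mechanisms, not
robustness to every field nuisance.

## Test problem sizes and numerical choices

The verification suite runs at sizes chosen to keep the full run within a
few tens of seconds while leaving comfortable statistical margins: LRT
calibration uses 500 pooled-truth replicates of ~300 visits (KS uniformity);
parameter recovery uses one c = 4 attempt of ~1000 visits (median relative
error < 10% on transitions with expected count ≥ 20, expectation computed
from the embedded chain's stationary law); the null-alternation check uses
> 100,000 events (agreement with 0.5 within 3 Monte-Carlo SDs); the
dissociation calibration uses 200 single-day replicates of a 3-carer
refractory-only group with 200 shuffles each, and its power curve 100
paired replicates per suppression level (common random numbers across
levels). The numerical MLE oracle maximizes the log-likelihood
coordinate-wise (the likelihood is separable per rate) by bounded scalar
minimization in log-rate space to xatol 1e-13, with the rate-zero boundary
probed explicitly.

Tie-breaking conventions, chosen once and documented: exact time ties at
ingest keep input order (stable sort); merged ties in the randomization are
ordered uniformly at random per replicate (a deterministic rule would bias
who "follows" whom); median ties in the bout test are "short"; helper-rank
ties break by carer id. Degenerate inputs (single-category sequences,
constant IVIs, zero exposures) return flagged results rather than raising,
so batch runs always complete.

## Known limitations

* No semi-Markov (non-exponential holding time) fitting and no covariates
  on rates; the randomization test is the instrument for refractory
  structure.
* The χ² reference for LRTs is asymptotic and flagged, not corrected, when
  boundary-zero rates are present.
* The bout test's median threshold has power only when within-bout and
  between-bout intervals are comparably frequent; strongly unbalanced bout
  regimes can even push the run count above expectation.
* Reported rate units are per hour by convention; published per-study rate
  scales vary and are not harmonized.
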