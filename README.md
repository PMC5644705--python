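# turnmark

Turn-taking analysis of cooperative offspring provisioning from timestamped
nest-visit records.

When several carers — a breeding pair plus helpers — provision a brood, each
nest visit is a discrete investment event, and a natural question is whether
carers *take turns*: visit after another bird rather than repeat their own
visit. Raw alternation is a misleading answer, because group size, unequal
visit rates, and refractory periods (the minimum time to travel and forage
between a carer's own visits) all produce alternation without any carer
responding to any other. `turnmark` implements the full analysis that
separates the two:

* **ingestion** — collapse raw PIT-tag (RFID) reads into visits with a
  gap-chained 2-min rule, segment observation days, and apply the standard
  brood-age, fledge-day, and disturbance filters;
* **carer classification** — the iterative "20% of the rest" rule for
  significant carers, with validity checks for model fitting;
* **rate models** — a continuous-time Markov chain whose state is the last
  visitor, fitted at three nested levels (full `c²`-rate, per-individual
  `λᵢ/μᵢ`, pooled `λ₀/μ₀`) with closed-form MLEs and likelihood-ratio
  tests; turn-taking appears as λ (rate of visiting after another bird)
  exceeding μ (repeat rate);
* **sequence statistics** — alternation proportions, a k-category runs test
  that corrects for group size and rate inequality, a Wald-Wolfowitz runs
  test for synchronous provisioning bouts, and IVI summaries;
* **the dissociation test** — shuffle each carer-day's inter-visit
  intervals, rebuild artificial days, and re-analyze: the null keeps every
  passive mechanism (including refractory structure) and destroys only the
  cross-carer response, so an observed statistic in the null's upper tail
  is evidence of *active* turn-taking;
* **a mechanistic simulator** — markov, refractory/response, and bout modes
  with known ground truth, used throughout the test suite.

## Worked example

Simulate a 3-carer group with a 3-min refractory period *and* a real active
response (a carer's hazard is suppressed to 60% while it is the last
visitor), then run the full pipeline:

```python
import numpy as np
from turnmark import SimConfig, Refractory, simulate, run_attempt, PipelineConfig

attempt = simulate(SimConfig(
    mode="mechanistic", c=3, base_rates=np.full(3, 7.5),   # visits/h
    refractory=Refractory("fixed", duration=180.0),        # seconds
    repeat_suppression=0.6, day_length=8 * 3600, n_days=2, seed=20,
    attempt_id="demo"))
report = run_attempt(attempt, PipelineConfig(n_reps=1000, seed=1))
```

With these seeds the report contains (values as printed by the code):

* 247 visits by 3 significant carers; alternation proportion **0.914**,
  k-category runs test p ≈ 8e-17 — far more alternation than random
  arrangement of the same visit counts;
* per-individual rates (per hour) λ̂ᵢ = [7.2, 7.2, 6.8] vs
  μ̂ᵢ = [2.0, 1.4, 0.7]: every carer visits several times faster after
  another bird; group ratio λ̄/μ̄ = **5.24**;
* randomization test (1000 interval shuffles): the null alternation range
  is 0.747–0.882 and the null ratio range 1.52–3.71, so
  `passive_flag = True` for both — the refractory period alone already
  produces turn-taking (null ratio ≫ 1) — yet the observed values sit above
  both ranges with `p_active = 0.001`: the active response is detected on
  top of the passive structure.

Setting `repeat_suppression=1.0` (no response) leaves the passive flags in
place but returns `p_active` to uniform — that separation is exactly what
the method is for.

The same pipeline runs from the shell on CSV/YAML inputs:

```
turnmark simulate --config sim.yaml --out visits.csv
turnmark run --visits visits.csv --seed 1 --out report.json
```

with further verbs `ingest`, `classify`, `stats`, `fit`, `randomize`, and
`batch` for stage-by-stage use on field data. See `docs/methods.md` for the
model, the test formulas, all conventions, and known limitations.

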