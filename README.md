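# moralsv

Do people value human lives the way they value money?  One way to ask the
question quantitatively is to give the same person two structurally
identical choice tasks — trading a small immediate payment against a larger
delayed one, and trading one life against a larger group of lives — fit the
same subjective-value model to both, and compare the fitted valuation
machinery behaviorally and neurally.  `moralsv` implements that analysis as
a tested, reusable Python pipeline, together with a synthetic cohort
generator so that every stage can be exercised and validated without
participant data.

It is aimed at computational cognitive neuroscientists and
neuroeconomists who want to fit discounting models to binary choices,
match conditions on choice certainty, run group statistics on discount
constants, and recover subjective-value signals from (synthetic) BOLD
timeseries with a parametric-modulation GLM.

## The model

Both tasks share a hyperbolic subjective-value (SV) model applied to the
subject's *own perception* of the discounting attribute:

```
financial:  SV_LL = LL / (1 + K_f · T)
moral:      SV_HL = HL / (1 + K_m · D)
```

* `LL` — larger-later amount (20–120 CHF), offered against 20 CHF today;
* `T` — the subject's rating of the delay (0 = extremely short, 100 =
  extremely long; delays span 1–180 days);
* `HL` — lives saved by sacrificing one person (1–10), against sparing that
  person (one life);
* `D` — the subject's rating of how wrong that person's prior crime was
  (0 = not at all, 100 = extremely wrong; six criminal-record ranks);
* `K_f`, `K_m` — per-subject discount constants (per rating unit).

Choices follow a logistic rule on the SV difference with a per-subject
temperature `β`:

```
P(choose target) = 1 / (1 + exp(−β · (SV_target − SV_reference)))
```

Per-subject `(K, β)` are estimated by bounded maximum likelihood with
multi-start optimization, and fit quality is scored as the R² between
model-predicted and empirical cell-wise choice proportions.  Downstream
stages reproduce the full analysis chain: exclusion of extreme-certainty
financial trial types (the 20 and 22 CHF offers) with paired t-tests on
standardized choice and RT slopes to verify the tasks are matched; a
Spearman correlation between `K_f` and `K_m` across subjects; and a
first-level GLM in which trial-wise SVs, mean-centered and convolved with a
canonical double-gamma HRF, act as parametric modulators — with
moral-vs-financial contrasts, minimum-statistic conjunctions, and spherical
ROI summaries.

## Worked example

```python
import moralsv as m

agent = m.sample_agent(m.PopulationConfig(), seed=10, subject_id="sub-01")
print(f"true K_f   = {agent.k_f:.6f}   true beta_f   = {agent.beta_f:.3f}")

design = m.build_design("financial", repeats=3)      # 180 trials
data = m.simulate_choices(agent, design, seed=11)
fit = m.fit_subject(data, seed=0)
print(f"fitted K_f = {fit.k_hat:.6f}   fitted beta_f = {fit.beta_hat:.3f}")
print(f"log-likelihood = {fit.loglik:.1f}   discount-curve R2 = {fit.discount_r2:.3f}")

rating = agent.perception.delay[90]                  # this subject's rating of 90 days
sv = m.sv_financial(100.0, fit.k_hat, rating)
print(f"rated 90 days as {rating:.1f}/100 -> SV(100 CHF @ 90 d) = {sv:.1f} CHF")
```

prints

```
true K_f   = 0.002173   true beta_f   = 2.201
fitted K_f = 0.002027   fitted beta_f = 2.119
log-likelihood = -12.2   discount-curve R2 = 0.895
rated 90 days as 86.0/100 -> SV(100 CHF @ 90 d) = 85.2 CHF
```

The fitted discount constant and temperature recover the generating values
from 180 simulated choices; the last line shows the model in action — for
this subject, 100 CHF in 90 days is subjectively worth about 85 CHF today.

The same workflow is available from the shell:

```bash
moralsv reproduce-synthetic --seed 1 --out-dir out/
```

simulates a 25-subject cohort on both tasks, fits every subject, runs the
certainty matching and group statistics, simulates and analyzes a BOLD
volume, and writes choice/fit tables (TSV), match and cohort reports
(JSON), t-maps (NIfTI) and a manifest of content hashes.  Runs are
byte-for-byte reproducible given the same configuration.

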