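# Methods

## Model and estimation

Both tasks are modeled with the same one-parameter hyperbolic discount,
`SV = magnitude / (1 + K · rating)`, applied to the subject's own 0–100
perception rating of the discounting attribute (felt duration of the delay;
judged wrongness of the to-be-sacrificed person's crime).  K is therefore
expressed *per rating unit*, not per day or per rank — a unit convention
that matters when comparing discount constants across studies and is the
convention in which the package's default population ranges
(K_f ∈ [3.78e-5, 0.043], K_m ∈ [0.093, 7.08]) are stated.  The reference
options (20 CHF today; sparing the one person, one life) carry no
discounting attribute and keep fixed values.

Choice probabilities are logistic in the SV difference with a per-subject,
per-task temperature β (units 1/CHF and 1/life respectively).  The exact
functional form of the choice rule is a modeling choice; logistic-of-SV-
difference is the standard softmax rule of the temporal-discounting
literature and is what `choice_loglik` implements.  Per-trial probabilities
are clipped to [1e-12, 1−1e-12] so the log-likelihood is always finite.

`fit_subject` maximizes the likelihood over (log K, β) with L-BFGS-B,
bounds K ∈ [1e-6, 20] (covering both population ranges with wide margin)
and β ∈ [0, 100], and 10 multi-starts log-spaced in K; the β start is set
to 1/sd(SV−ref) at the starting K.  Datasets with all-identical choices are
non-identifiable: they are fitted anyway (K typically lands on a bound),
flagged, and a warning is emitted.  `grid_search_fit` provides a fully
vectorized exhaustive log-grid reference against which the optimizer is
validated.

Fit quality (`discount_curve_r2`) is, by default, the R² between
model-predicted choice probabilities and empirical choice proportions over
(magnitude × level) cells.  An alternative based on indifference points —
comparing model-implied indifference magnitudes per level with
linearly-interpolated empirical crossings — is available via
`method="indifference"`.  The cell-proportion version is undefined (NaN)
when fewer than two cells exist or the empirical proportions have zero
variance.  Note a structural property: with unrepeated trial types, cell
proportions are binary, and near-indifference cells depress R² even when
scored with the *true* parameters; meaningful R² values require repeated
trial types (the package default is three repeats, 180 trials per task,
a realistic session length).

`choice_slope` estimates the standardized logistic slope of choice on
within-subject z-scored SV using Firth's bias-reduced penalized likelihood
(Jeffreys-prior penalty).  Two reasons: low-noise subjects routinely
produce perfectly separated data where the plain MLE diverges, and the
leading-order small-sample bias of the plain MLE differs between the two
tasks' SV designs, which would masquerade as a cross-task slope difference.
On well-conditioned data the Firth estimate agrees with the ordinary MLE to
within a few percent (checked against statsmodels).  `rt_slope` is ordinary
least squares of RT on z-scored SV.

## Certainty matching

Trial "types" in the financial task are larger-later amounts, collapsed
across delays.  Certainty per type is |mean P(chose target) − 0.5|, pooling
subjects' per-type choice frequencies.  `mode="paper"` removes the 20 and
22 CHF types; `mode="data_driven"` removes the top-`n` types by certainty,
with a deterministic tie-break (lower acceptance rate first, then smaller
amount) because saturated types tie at exactly 0.5.  Cross-task equivalence
is then tested with two-sided paired t-tests on the standardized choice and
RT slopes (df = n_subjects − 1).

An analytic point worth recording: under the hyperbolic model with K_f
capped at 0.043 per rating unit and ratings capped at 100, the largest
possible discount divisor is 5.3, so a 120 CHF offer retains SV ≥ 22.6 CHF
and is *always* accepted in the noiseless limit — its minimum acceptance
margin (2.6 CHF) is smaller than the 20/22 CHF rejection margins only for
agents near the top of the K_f range.  The extreme-certainty status of the
20/22 CHF types is therefore a property of steeply discounting cohorts, not
of cohorts spanning the full K_f range (where flat discounters are
near-indifferent about small offers and certain about large ones).
`PopulationConfig.strong_discounting()` encodes that regime (K_f
log-uniform on [0.038, 0.043], β_f on [0.5, 1.2]) and is the intended
condition for demonstrating the data-driven exclusion.  Even there, single
cohorts occasionally reorder the closely ranked types through a handful of
chance acceptances; the exclusion set should be read as the modal outcome
across cohorts (rate ≈ 0.8–0.9).

## Synthetic cohorts

The generator emulates the study conditions: 25 subjects; a financial
design of 10 amounts {20, 22, 25, 30, 35, 45, 60, 80, 100, 120} CHF × 6
delays {1, 7, 14, 30, 90, 180} days; a moral design of 10 group sizes × 6
criminal-record ranks; discount constants log-uniform within the empirical
population ranges; temperatures log-uniform with β_f ∈ [0.5, 3] /CHF and
β_m ∈ [1, 5] /life (sharp enough that 60-trial datasets carry usable
information about K, noisy enough that the likelihood is not flat).

Perception defaults: delay ratings follow a logarithmic (Weber–Fechner)
map `T(d) = 100·ln(1+d)/ln(181)`; a linear map would assign one-day delays
a rating of 0.56/100, making short-delay cells carry no measurable
discounting for any plausible K.  Deservingness ratings are linear in rank,
`D(r) = 100·(r−1)/5`, so a clean record discounts nothing.  Per-subject
monotone jitter multiplies the rating increments by log-normal noise
(sd 0.1) and renormalizes the top level.

RTs are generated as `intercept − slope·|ΔSV| + Gaussian noise` (sd 150
ms), floored at 200 ms — a difficulty proxy, not a process model (no
drift-diffusion dynamics).  The per-task slope ranges are scaled by the
~19:1 ratio of the tasks' mean |ΔSV| so that the two tasks are RT-matched
at the group level, with grand-mean RTs near 1.22 s, matching the study
situation the pipeline assumes (task comparability).

`matched_slope_cohort` builds cohorts whose *expected* standardized slopes
are equal across tasks by construction, for type-I-error checks of the
slope comparison: because the logistic choice rule is correctly specified
on the z-scored SV scale with slope β·sd(SV), and the expected RT slope is
−b·cov(|SV−ref|, SV)/sd(SV), both are invertible per agent; each agent
receives one target choice slope (log-uniform on [0.8, 1.5]) and one target
RT slope (half-normal, sd 40 ms) hit exactly in expectation by both tasks.
The target range is kept moderate because very steep logistic slopes
saturate into separation, where estimates are penalty-dominated and
task-asymmetric; within this range the cross-task type-I rate of the paired
tests is ≈6–9% at a nominal 5%.

BOLD fixtures are 12×12×12 voxel volumes (3 mm isotropic, TR 2 s) — enough
to exercise the GLM, deliberately not a brain simulation.  Trials from both
tasks are laid out serially with uniform 3–7 s jittered intervals.  Truth
clusters are voxel spheres tied to a modulator (e.g. `financial_sv` or
`-moral_sv`) whose timeseries is amplitude × the same HRF-convolved,
mean-centered modulator regressor the GLM constructs, plus white noise;
consequently an injected amplitude equals the expected recovered beta
exactly, and recovery bias measures the engine, not the generator.  White
noise, no hemodynamic nonlinearity, no motion or physiological confounds.

## GLM

Per task, the design holds one onset stick regressor and one parametric
modulator (trial SVs mean-centered within task, then convolved), built on a
16× oversampled grid with a canonical double-gamma HRF (gamma shapes 6 and
16 s, undershoot ratio 1:6, peak-normalized), plus Legendre drift columns
(order 2) and an intercept.  Modulators are *not* orthogonalized against
onset regressors beyond mean-centering — stated explicitly because SPM's
serial orthogonalization differs.  Estimation is ordinary least squares per
voxel (no AR(1) prewhitening; adequate for white-noise fixtures);
t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c) with residual df = scans − rank(X).  Voxels
whose residual sum of squares is at round-off level are masked (t = NaN).
Rank-deficient designs are refused, not silently fitted.

`contrast_sv_domains` compares the two tasks' modulators; negating a
modulator column and negating its contrast weight are algebraically
identical, and both spellings are supported.  `conjunction` implements the
minimum-statistic rule min(t_a, t_b) > threshold.  With disjoint injected
effects the conjunction contains no systematic voxels; chance survivors
appear at the nominal rate (inside a genuine cluster of one effect, the
other map's noise exceeds t = 3 with p ≈ 0.0014 per voxel), i.e. on the
order of 0.1 voxels per volume — an empty conjunction is the typical, not
the guaranteed, outcome.  `roi_mean` averages a map over a sphere defined
in millimeters on the isotropic voxel grid (0-based voxel center, default
8 mm radius).

## Numerical and reproducibility choices

All randomness flows through numpy Generators seeded explicitly; cohorts
spawn per-subject streams via `SeedSequence`, so datasets are bit-identical
across runs.  The pipeline writes TSV with a fixed float format and JSON
with sorted keys, and NIfTI uncompressed, making whole-run outputs
byte-stable; the manifest records SHA-256 hashes of every file.  CLI exit
codes: 0 ok, 1 validation error, 2 runtime error.

## Known limitations

* **Identifiability ceiling for K_m.**  With deservingness ratings up to
  100, any K_m ≳ 1 drives the SV of every non-clean-record cell toward
  zero; choices become insensitive to K, so the top decade of the K_m
  population range is identifiable only through logistic tail
  probabilities.  A grid-oracle experiment with the true β supplied puts
  the 60-trial Spearman recovery ceiling at ≈0.74–0.94 across cohorts
  (median ≈0.84) and the 600-trial ceiling at ≈0.90–0.97.  Short moral
  sessions therefore cannot reliably rank steep moral discounters; the
  financial task does not share the problem at these ranges (60-trial
  recovery ≈0.95).  Raising β_m does not help: near-deterministic choices
  flatten the likelihood in K and degrade recovery at all session lengths.
* The RT model is a linear difficulty proxy; parameters of real RT
  distributions (skew, fast errors) are out of scope.
* The GLM omits physiological noise models, temporal autocorrelation,
  random-field multiple-comparison corrections and anatomical labeling;
  passing its tests demonstrates engine correctness on white-noise
  fixtures, not robustness on real scans.
* Synthetic perception curves are smooth monotone maps with mild jitter;
  real rating data can be non-monotone and lumpy, which the fitting code
  accepts but the generator does not emulate.
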