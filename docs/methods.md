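# Methods

## Model and assumptions

The budget treats target localization during a tracked fraction as a
chain of four steps — CTV↔seed-CoM deformation, seed-configuration
variation, correlation model, prediction model — and assumes the steps
are statistically independent. That is knowingly conservative:
configuration deformation surely leaks into the correlation error, but
treating the sources as independent and summing in quadrature never
understates the total. Every step's error distribution is reduced to an
expanded uncertainty `U = |μ| + 2σ` and, assuming a normal PDF, a
standard uncertainty `e = U/2`; the per-axis combined value is the
root-sum-square of the four `e` terms, expanded with coverage factor
k = 2 (~95% confidence). The resulting `U_combined` is read as the
geometric margin needed to keep 95% of CTV points covered with 95%
confidence — a purely geometric statement; dose-based margin recipes
are out of scope.

σ is always the sample standard deviation (ddof = 1). The `|μ| + 2σ`
form deliberately keeps any systematic offset: a biased error stream
widens the budget by its full bias, not its quadrature.

### The seed-step halving and its `2σ` term

The seed estimator halves every signed inter-seed distance change
before taking `|μ| + 2σ`: with two seeds, a distance change of `d`
displaces the CoM by `d/2`, and that two-seed worst case is applied
regardless of seed count. Halving each sample or halving the final `U`
is numerically identical; the per-sample form is implemented. One
published statement of this estimator prints the spread term as `2σ²`,
which is dimensionally inconsistent (mm² added to mm) and disagrees
with the correlation/prediction estimators' `2σ`; the package defaults
to `2σ` and exposes the literal `2σ²` reading behind a
`literal_variance` flag for comparison.

### Exclusion rules

Correlation samples are excluded when they were used to build a model
before irradiation (flagged `model_build`), when flagged as rebuild
triggers, and when they sit in a run of ≥3 consecutive samples
exceeding 3 mm on any axis — the configured rebuild condition. Seed
migration is handled on the solid rigid error
`SRerror = max_pairs |d_CT − d_LIVE|`: if more than half of a
fraction's live images exceed 3 mm, the seed whose removal most reduces
the median SRerror is disabled and the check repeats; tracking floors
at two seeds, below which the condition is only flagged. The 50%
persistence threshold is this package's operational reading of
"detected after the CT" — a single noisy image should not disable a
seed. Operating limits 1.5 mm (standard) and 5 mm (treatment refusal)
are annotated on the SRerror series.

### Deformation assignment

Border distance ≤ 0 mm (CoM inside the CTV) → 2.1 mm; 0–30 mm outside
→ 3.0 mm; ≥ 30 mm → `DeformationRuleNotApplicable` is raised, never a
silent number. The two constants originate from published
deformation-field correlation analyses and are consumed as given
inputs, identical on all three axes.

## Motion ranges

The modeled CoM trajectory is segmented into breathing cycles at
successive maxima of the dominant-motion axis after a linear detrend,
with a minimum peak separation of half the nominal breathing period
(default 4 s) and a prominence floor of 10% of the detrended span to
suppress noise peaks. Per cycle and axis the amplitude is max − min of
the raw trace; baseline drift is deliberately not removed, and no
amplitude exclusion criterion is applied. Summaries: Rm (mean), R95%
(95th percentile, linear-interpolation quantile), median, and the mean
over amplitudes inside the closed 5th–95th percentile band. Cohort
statistics average per-patient means (not pooled fractions), weighting
every patient equally. An alternative reading of the source procedure —
one amplitude per model sample rather than per cycle — exists; the
cycle-based reading is implemented because it is deterministic and
matches the per-cycle peak-to-trough intent.

## Margin evaluation

Pass is inclusive (`U_combined ≤ margin`) and percentages are rounded
half-up to whole percent; this convention reproduces the published
5 mm (94/100/94) and 6 mm (100/100/100) rows exactly. The published
3–4 mm rows differ by one patient in places from any convention
applied to the published (rounded) inputs, so the package reports
computed and published values side by side without forcing agreement.
Combination uses per-patient mean step uncertainties across fractions.
An optional end-to-end tracking term (0.7 mm expanded, phantom
measured) can be quadrature-added; it is off by default because the
phantom test already exercises the correlation/prediction chain, and
when enabled it adds roughly 0.1–0.2 mm to typical combined values.

## Synthetic data generator

`simulate_fraction` emulates the measurement chain, not the vendor
algorithms: correlation and prediction errors are drawn directly from
their generating distributions rather than re-deriving model fits,
because the budget consumes error streams, not models. Components:

* **Breathing**: `cos⁴` waveform (dwell at the exhale baseline, which
  is where planning CTs are acquired; a pure sine is selectable),
  per-cycle period jitter (SD 5% of the 4 s period), linear baseline
  drift of 0.5 mm/min along the dominant-motion direction.
* **Amplitudes**: defaults (3.15, 0.6, 1.15) mm SI/LAT/AP — half the
  reference cohort's mean peak-to-trough ranges of 6.3/1.2/2.3 mm.
* **Live images**: every 60 s, rigid CT configuration + motion +
  independent isotropic per-seed Gaussian jitter (SD 0.5 mm, giving a
  seed-step U of √2·0.5 ≈ 0.71 mm, at the low end of the reference
  cohort's 0.5–2.0 mm).
* **Correlation errors**: per-axis `Normal(μ_c, σ_c)`, defaults μ = 0,
  σ = (0.75, 0.35, 0.45) mm — a U of 1.5 mm on SI, matching the
  reference cohort's mean correlation error of 1.5 mm.
* **Prediction errors**: per-axis `Normal(0, 0.08 × amplitude)`; the
  0.08 multiplier of amplitude equals a 0.04 slope of SD against the
  peak-to-trough range Rm, the value observed for the hybrid predictor.
* **Recorded model trace**: the smooth model output (true motion); the
  correlation error lives only in the error columns. White noise added
  to the trace would inflate per-cycle amplitudes unphysically — the
  real model output varies smoothly between X-ray updates.
* Model streams are sampled at 4 Hz over a 1800 s fraction; the first
  8 samples are flagged `model_build`.

Ground truth per fraction: `U_seeds = √2 × jitter SD` (a distance
between two independently jittered seeds changes with SD √2·σ,
linearized for jitter ≪ seed separation; halving gives σ/√2 and
`U = 2σ/√2`), `U_correlation = |μ_c| + 2σ_c`,
`U_prediction = 2 × 0.08 × amplitude`, `Rm = R95% = 2 × amplitude`.

`make_cohort` draws per patient one amplitude multiplier (uniform
0.5–2×) applied to both amplitudes and correlation SDs — which is what
produces the positive error-vs-range correlation across a cohort — a
seed-CoM offset multiplier (0.5–2.5×, mixing CoM-inside and CoM-outside
geometries) and a fraction count in 3–5. Randomness flows from one
master seed through named child streams in fixed spawn order, so
adding a stream never perturbs existing ones and outputs are
bit-identical across runs.

What the generator does **not** emulate: hysteresis (inhale/exhale path
splitting), autocorrelated or non-Gaussian error streams, interfraction
baseline shifts, irregular imaging cadence, and X-ray-update-locked
correlation-error dynamics. Passing recovery tests therefore shows the
estimators are correct for distributions matching their assumptions;
it does not validate the normality of real tracking errors.

## Numerical choices and problem sizes

Quantiles are linear-interpolation (type 7) everywhere. Percentages
round half-up. Cycle detection needs ≥2 peaks, else a `ValueError`;
constant traces are rejected rather than returning zero cycles. All
estimators require ≥2 samples. Statistical tests run at sizes chosen
for tight yet fast checks: ~10⁴ model samples for 5–10% recovery of
`|μ|+2σ`, 20 fractions for cross-fraction recovery, 2×10⁵–4×10⁵ draws
for the Monte-Carlo quadrature cross-check, cohorts of 10–16 for rank
correlation and margin-table properties.

## Known limitations

* The log-file schema is this package's own clean stand-in; real vendor
  logs are proprietary and are not parsed.
* The deformation constants are consumed, not derived; cases ≥30 mm
  outside the CTV have no assigned value by construction.
* Reproduction of the published per-patient combined uncertainties is
  limited by the published inputs' 0.1 mm rounding (deviations up to
  ~0.12 mm in a few cells); the margin percentages, the 2.3–5.2 mm
  range and the two >5 mm patients are insensitive to this.
* Fiducial-free (surface/lung-tracking) workflows and dose-level
  coverage statements are out of scope.
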