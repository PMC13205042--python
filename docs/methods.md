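# Methods

## The stability statistic

`abrstab` quantifies auditory-brainstem neural stability — the
trial-to-trial repeatability of stimulus-locked evoked activity — as the
Pearson correlation between two independently averaged response waveforms,
Fisher-transformed for modeling:

    r  = corr(w₁[t], w₂[t])  over a component window,    Zr = atanh(r).

The two subaverages are built so that they draw on disjoint sweep sets and
are balanced across stimulus polarity, recording channel, and collection
order. For alternating-polarity speech recordings, each scalp channel (A, B)
contributes a condensation buffer and a rarefaction buffer of 1500 accepted
sweeps each; subaverage 1 averages A-condensation with B-rarefaction,
subaverage 2 averages B-condensation with A-rarefaction. Each subaverage
therefore holds 3000 sweeps, 1500 per polarity and 1500 per channel.
Any component whose sign flips with stimulus polarity (cochlear
microphonic, electrical stimulus artifact) is carried with weight
(+1500 − 1500)/3000 = 0 in both subaverages: it cancels identically rather
than inflating the apparent correlation. Channel- and order-locked
differences are balanced the same way.

Click recordings use a single polarity, so the collection-order halves of
each channel's buffer substitute for the polarity split: subaverage 1 =
first half of channel A + second half of channel B; subaverage 2 = the
complement. Disjointness and channel/order balance are preserved exactly.
(Which split the original acquisition used is not documented anywhere we
know of; the collection-order split is this package's documented choice,
exposed in `build_click_subaverages`.)

Component windows (ms post onset, half-open `[start, end)` with floor-based
ms→index conversion so adjacent windows never share samples):
click 1–8, full speech response 0–55, onset 5–10, sustained/FFR 22–40,
offset 45–50. Correlations of a constant slice raise an error rather than
silently returning 0; |r| is clamped to 1 − 1e-7 before `atanh` because
noiseless simulations legitimately reach r = 1.

### Closed-form attenuation

With additive noise of per-sweep, per-sample variance σ² (independent
across sweeps) and n sweeps per subaverage, the averaged noise has variance
σ²/n per sample, and

    E[r] ≈ V_s / (V_s + σ²/n),

where V_s is the variance of the underlying response waveform over the
window. This is the generator-level oracle used in tests and in the
acceptance script: at n = 3000 the Monte-Carlo mean over 200 replicates
agrees with the prediction to well under 0.02. For band-limited noise the
same formula holds with σ² the in-band variance; the generator rescales
filtered noise so its stationary variance equals `noise_sd²` exactly.

## Preprocessing

Offline reproduction of recording-time processing: a 100–3000 Hz
4th-order Butterworth bandpass applied forward–backward (zero phase, so
component latencies are untouched), per-sweep artifact rejection at
±35 μV — "exceeding" is strict, a sweep peaking at exactly 35.0 μV is
kept — and accumulation of the first 1500 accepted sweeps per buffer in
arrival order. Rejection is applied to filtered sweeps by default
(`reject_on="filtered"`), matching online systems that filter before
averaging; the flag allows rejection on raw sweeps instead. Rejection is
per-sweep on the per-sample absolute maximum, hence order-independent as a
set.

## Response presence and noise metrics

Speech-response presence is a spectral F-test on the sustained (22–40 ms)
portion of the grand average: power at the FFT bin nearest the fundamental
(f₀ = 100 Hz) divided by the mean power of 2K flanking bins, referred to
F(2, 2·2K); defaults K = 5 per side, α = 0.05, Hann window, FFT
zero-padded to 4096 points.

Bin placement is the one place the implementation departs from the naive
reading of "adjacent FFT bins". On a zero-padded grid, neighbouring padded
bins of an 18-ms segment are separated by ≈ 4.9 Hz — far inside one
resolution element (Rayleigh spacing ≈ 55.6 Hz) — and are therefore almost
perfectly correlated, which destroys the F reference distribution. Noise
bins are instead placed on the natural-resolution grid, spaced three
Rayleigh bins apart: Hann-windowed DFT coefficients at that spacing are
exactly uncorrelated under white noise, so the null distribution (and the
test's type-I error, verified at 1000 replicates) is exact. A two-Rayleigh-
bin guard band around the signal bin is always excluded, and because
100 Hz sits too close to the band edge for K bins to fit below it, the
deficit is taken from above. The single-bin statistic (no harmonic
pooling) is implemented; harmonic-sum or Hotelling-T² variants are out of
scope.

Click-response presence is *not* algorithmically determined — in the
recordings this package models it rests on visual identification of waves
I/III/V by trained scorers — so the pipeline accepts an external presence
flag per participant rather than pretending to automate human judgment.

Prestimulus noise is the RMS over −p ≤ t < 0 with p = 10% of the analysed
response length: 0.8 ms for the click (8 ms window). For the speech
response the stated convention of 5 ms is used even though a literal 10%
of the 55 ms window would give 5.5 ms; the stated value wins and the
generic rule remains available as a helper.

## Trait scores

AQ totals span 0–50. Child-form items (0–3 Likert) are dichotomized
(0/1 → 0, 2/3 → 1) and summed; adolescent/adult forms are ingested
pre-scored, with `aq_form` recording provenance so parent-report-only
sensitivity analyses remain possible. SRS-2 enters as T-scores directly
(raw→T tables are proprietary). Cohort validation keeps a participant iff
they have ≥ 1 stability record and a complete AQ or SRS-2 score;
missingness is preserved rather than imputed, so a participant can enter
the AQ models and be absent from the SRS-2 models.

## Mixed-model inference

Long-format Zr values (one row per participant × component) are modeled
with a participant random intercept and nested fixed-effect structures:

    M0: Zr ~ component                      + (1 | participant)
    M1: Zr ~ component + trait              + (1 | participant)
    M2: Zr ~ component × trait              + (1 | participant)
    M3: Zr ~ component × trait + age + VCI  + (1 | participant)

Components are sum-coded with the click level implied (its effect is minus
the sum of the shown four), so estimates are deviations from the grand mean
and the five effects sum to zero by construction. All fits use maximum
likelihood — never REML — because BIC comparison and likelihood-ratio tests
require it; BIC = −2ℓ + k·ln(n_obs) with k counting fixed effects plus the
two variance components, matching the convention of the major mixed-model
packages. Model selection takes the minimum BIC; ΔBIC is reported relative
to the best model, and fits on differing observation sets are refused
(BIC is not comparable across them). For comparability, the nested set is
fit on rows complete for every variable the richest model uses.

Per-coefficient t-tests use Satterthwaite degrees of freedom computed from
the fitted covariance: for a contrast c, f(θ) = cᵀ Cov_β(θ) c with
θ = (σ²_b, σ²_e), df = 2f²/(gᵀAg) where g is the finite-difference gradient
of f and A the inverse expected ML information of θ (available in closed
form for the random-intercept model). The likelihood itself is maximised by
statsmodels' `MixedLM`; the Satterthwaite layer is this package's, and the
test suite verifies estimates, standard errors, dfs, and BIC against
lme4/lmerTest to printed precision on a synthetic cohort. At the boundary
σ²_b → 0 the gradient is taken one-sided and the df is clamped to
[1, n_obs − p].

Pairwise component contrasts are differences of estimated marginal means
(covariates held at their sample means), with Tukey studentized-range
adjustment at the contrast's Satterthwaite df. The two-level case is
computed exactly through the t distribution (q = t√2 identity). Adjusted
p-values are floored at the unadjusted value so monotonicity of the
adjustment survives extreme-tail numerical underflow.

Variance explained follows the variance-partition convention for mixed
models: marginal R² = σ²_fixed/(σ²_fixed+σ²_b+σ²_e) with σ²_fixed the
population variance of the fitted fixed-effect predictions, conditional R²
adds σ²_b to the numerator. ΔR² for a trait is the difference in marginal
R² between nested fits on identical observations. Subscale contributions
are tested by likelihood ratio: reduced = component + (AQ − subscale),
full = + subscale, χ² = 2Δℓ on 1 df.

The preliminary two-way repeated-measures ANOVA (ear × component) computes
each effect's F from orthonormal contrast scores of the per-subject cell
means, runs Mauchly's test per effect (first-order χ² approximation), and
applies Greenhouse–Geisser corrected degrees of freedom iff sphericity is
rejected at 0.05; ε = (tr S)²/(d·tr S²) clamped to [1/d, 1], with the
interaction's contrast space built as the Kronecker product of the main
effects' contrasts. F values are verified against statsmodels' `AnovaRM`
and ε/Mauchly against pingouin's one-way implementations in tests.
Multicollinearity is screened with VIF = 1/(1−R²_j); Welch's
unequal-variance t and Pearson correlations cover the remaining
preliminary checks.

## The synthetic generator

The generator exists so every stage has a known ground truth; it emulates
the structure of the recordings, not their biophysics.

**Waveform templates.** Deterministic, with canonical literature peak
latencies (config-exposed constants, since the modeled recordings publish
none): click waves I/III/V at 1.7/3.9/5.7 ms over a −5…20 ms epoch;
/da/-evoked V (6.6 ms), A (7.5), C (18.5), a sustained portion at a
constant f₀ = 100 Hz plus one harmonic over ≈18–44 ms whose troughs
D–E–F are spaced exactly 1/f₀ = 10 ms apart, and an offset trough O at
48 ms, over a −5…55 ms epoch. Sampling rate defaults to 20 kHz. The real
/da/ token's f₀ trajectory is a falling/rising contour in natural stimuli;
the constant-f₀ stand-in means the 18-ms FFR window does not hold an
integer number of periods, which the detector's nearest-bin logic absorbs.

**Trial-level degradation.** Per sweep: multiplicative amplitude factor
N(1, amp_cv²), latency jitter N(0, jitter_sd²) applied by resampling the
template with linear interpolation (band-limited shifting is unnecessary
at these SNRs), additive Gaussian noise (band-limited to 100–3000 Hz by
default and rescaled to an exact stationary SD; filtfilt edge transients
are kept outside the epoch by padding), a polarity-signed 100-Hz sinusoid
gated to the stimulus duration (the artifact the balanced subaveraging
must cancel), and with probability `artifact_rate` a 45–90 μV excursion
guaranteed to trip the ±35 μV rejection. The default noise SD of 2.5 μV
was calibrated once so that, at the full 1500-sweeps-per-buffer averaging
depth after filtering, mean subaverage stability lands in the ≈0.85–0.93
range typical of school-age recordings (jitter_sd 0.05 ms, amp_cv 0.05,
artifact_rate 0.02). One deliberate departure from the published
descriptive ordering: the generator's click stability is *lowest* rather
than highest, because the single-polarity click split halves the
subaverage depth and the click template carries little variance in its
short 1–8 ms window; matching the empirical click advantage would require
fitting template amplitudes to data this package does not ship.

**Cohort level.** Fisher-z stability is generated directly from the
random-intercept model: Zr_ij = β₀ + offset_j + β_AQ·AQ_i + b_i + e_ij.
Defaults inject the reference fixed effects (intercept 0.43, offsets
click +0.76 / full −0.38 / onset +0.24 / FFR −0.15 / offset −0.47 —
summing to zero — and β_AQ = −0.023) with AQ ~ N(21.6, 12.5²) clipped to
[0, 50]. participant_sd = 0.54 and residual_sd = 0.65 were chosen once so
that the generated data's variance decomposition reproduces marginal /
conditional R² of ≈ 0.29 / 0.58; note the injected intercept and slope
imply a lower mean Zr than the descriptive r range above — the cohort
generator reproduces the *inferential* structure, not the descriptive
table, and the two are not mutually consistent in the reference values
themselves. SRS-2 T-scores are generated with correlation 0.88 to AQ;
subscales are an integer split of the total respecting the 0–10 ceilings.

**What passing tests do not show.** The generator is linear, Gaussian, and
stationary: no myogenic/ocular artifact structure, no drifting electrode
impedance, no f₀ contour, no rate- or level-dependent morphology change,
and the trait→stability link is exactly linear with homoscedastic noise.
Passing recovery and calibration tests therefore demonstrates correctness
of the *procedure*, not robustness to the full messiness of scalp
recordings.

## Problem sizes and numerical choices

Test and acceptance runs use scaled problem sizes chosen to keep the whole
suite in the low minutes while leaving every statistical check
well-powered: 200 Monte-Carlo replicates at the full n = 3000 subaverage
size for the attenuation oracle, 1000 noise-only replicates for detector
calibration, 100 simulated 200-participant cohorts for coverage, and
scaled-down sweep counts (60–120 accepted sweeps per buffer) in the
pipeline smoke tests. Seeds are explicit everywhere; the same seed yields
byte-identical pipeline outputs.

Known limitations: Satterthwaite dfs are exact only as the information
approximation allows near variance boundaries; the spectral test assumes a
locally flat noise floor across its flanking bins; the sweep-store format
is package-defined (no vendor binary ingestion); and no peak-picking of
waves I–V is provided or intended.
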