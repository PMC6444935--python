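# Methods

`devconn` characterises how band-limited oscillatory power and
phase-synchrony networks change with age. This note documents the models
and procedures the package implements, the choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Connectivity model

Parcellated signals are band-pass filtered into the canonical bands
(theta 4–7 Hz, alpha 8–14 Hz, beta 15–30 Hz, gamma 31–80 Hz) with a
4th-order Butterworth applied forward–backward. Zero-phase filtering is
a requirement, not a taste: the connectivity estimator works on
instantaneous phases, and a causal filter's group delay would bias them.

Connectivity is the **weighted phase lag index (wPLI)**. For analytic
signals z_x(t), z_y(t) (Hilbert transform of the mean-centred,
band-filtered signals) and instantaneous cross-spectrum
S(t) = z_x(t)·conj(z_y(t)),

    wPLI = |Σ_t Im S(t)| / Σ_t |Im S(t)| ∈ [0, 1].

Observations are time samples within a trial; per-trial values are
mean-averaged into one adjacency entry per region pair, band and
subject. Zero-lag coupling makes Im S identically zero; the estimator
returns 0 by convention there (a logged decision — the PLI family is
deliberately blind to instantaneously mixed, e.g. volume-conducted,
signals). The plain estimator is used, not the debiased squared
variant. No edge samples are trimmed after the Hilbert transform by
default.

Graph summaries: **node strength** is the row sum of the adjacency
(diagonal excluded). **Global efficiency** is the mean of 1/d(i,j) over
ordered off-diagonal pairs, where d is the all-pairs shortest-path
closure of the length matrix length = 1/weight (zero weight → infinite
length; disconnected pairs contribute efficiency 0). Shortest paths run
through Dijkstra (scipy's csgraph); tests assert equality with an
independent Floyd–Warshall. Metrics are computed on the full weighted
matrices — no thresholding or binarisation.

## Spectral branch

Per-trial PSDs are estimated on mean-centred signals with Welch's
method and averaged across trials. Segmentation defaults to the
conventional eight segments with 50 % overlap and a Hamming taper
(`nperseg = floor(N/4.5)`); length, overlap and taper are parameters.
Band power is the arithmetic mean of PSD bins with
f_lo ≤ f ≤ f_hi (closed on both edges — a documented convention).
Regional band power is Pearson-correlated with age across subjects;
significance uses the r-scale threshold implied by a t cutoff,

    r_thr(n, t) = t / sqrt((n − 2) + t²),

e.g. r_thr(324, 3.5) ≈ 0.19. The correlation maps are thresholded
per-parcel at t_crit (default 3.5) rather than FDR-corrected; t_crit is
a parameter. Zero-variance parcels yield NaN r with a warning — never a
silent 0.

## Trajectory fitting

Three curve families are fitted to a metric y against age x:

    linear        y = a₁x + a₂
    quadratic     y = b₁x² + b₂x + b₃
    logarithmic   y = c₁·log10(c₂x + c₃) + c₄

The logarithmic family is over-parameterised —
c₁·log10(c₂x + c₃) + c₄ = c₁·log10(x + c₃/c₂) + (c₄ + c₁·log10 c₂) —
so only the fitted curve is identifiable, not the coefficient vector.
The fit is solved by variable projection over the single identifiable
offset r = c₃/c₂: a 60-point geometric grid of candidate offsets (dense
near the singular end, stretching into the near-linear large-r regime)
followed by bounded 1-D refinement, with c₁ and c₄ solved linearly at
each r. Coefficients are reported as (c₁, 1, r, c₄). The offset is
constrained so the curve stays positive-argument down to the floor of
the youngest age in the evaluation domain — this covers both held-out
subjects younger than any training subject and the integer-year
gradient grid.

**Model selection** is repeated split-half cross-validation (default
1,000 iterations): subjects are randomly split into equal Fit and Test
groups (Fit takes the extra subject when n is odd), all three models are
estimated on Fit, and each is scored on Test by the mean absolute
deviation between predictions and observations. Scoring held-out data
with Fit-estimated coefficients (rather than refitting on Test) is the
standard cross-validation reading; refitting would make the two halves
symmetric and the procedure circular. The kind with the lowest *median*
test residual across iterations wins; the median protects against a few
catastrophic splits and removes the advantage of flexible models.
Near-exact ties (within 1e-9 relative to the data scale, as happens for
exactly nested models on noise-free data) go to the model with fewer
coefficients. Failed fits contribute an infinite residual for that
iteration and kind. Splits are applied to indices after a canonical
(age, value) sort, so selection is invariant to subject order.

**Inference**: the selected kind is refitted on the full data and its
regression F statistic computed against the intercept-only model,
F = ((TSS − RSS)/(k − 1)) / (RSS/(n − k)), with k the coefficient count
(2/3/4; the logarithmic family is charged k = 4 as parameterised). The
null distribution comes from refitting the same kind after randomly
shuffling ages (default 15,000 permutations);
p = #{F_null ≥ F_obs}/N, upper tail, no +1 smoothing, so p = 0 is
reportable at 1/N resolution. For the polynomial kinds the shuffled-age
refit is computed exactly via the orthogonality of permutation matrices
(RSS(y ~ P·X) = RSS(Pᵀy ~ X)), which collapses all permutations into
one multi-RHS least-squares solve; the logarithmic kind is refitted per
permutation. A test asserts the shortcut equals the literal refit.
Strength p-values are controlled with Benjamini–Hochberg FDR at
q = 0.05 across parcels within each band; global efficiency (one test
per band) is reported at its raw permutation p.

**Descriptive outputs** per fitted curve: the analytic per-year
gradient (a₁; 2b₁x + b₂; c₁c₂/((c₂x + c₃)·ln 10)) on the integer-year
grid spanning the cohort, and the model SD — the population standard
deviation of predicted values over that grid, a one-number summary of
how much the metric changes across the developmental span.

A stability analysis reruns the whole selection after randomly
subsampling the larger sex to match the smaller (default 100 repeats)
and reports per-kind selection frequencies.

## Confound control

Younger subjects lose more trials to artefact, so trial count would
otherwise correlate with age. `balance_trials` computes the rounded
mean trial count among subjects younger than a cutoff (default 11
years) and randomly reduces every subject above that count to exactly
it, preserving trial order and values. Subject inclusion uses a strict
`n_trials > 5` reading.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth: per band, every parcel receives an independent
narrowband source (white noise band-filtered, standardised to unit SD)
scaled by an age-dependent amplitude trend; for each configured coupled
pair the second parcel's band content is the mixture
k·delayed(source₁) + (1 − k)·own source, where the fractional-sample
delay realises the configured phase lag (default π/4) at the band's
centre frequency and k(age) follows a configured linear, quadratic or
logarithmic trajectory clipped to [0, 1]; broadband Gaussian noise is
added everywhere. Narrowband-noise carriers (not sinusoids) give the
wPLI realistic phase jitter instead of degenerate 0/1 values.

Default conditions: 10-s trials at 600 Hz, 20 trials per subject, ages
uniform on 6–45 years (uniform sampling maximises leverage for curve
recovery; the true cohort density is a free parameter), broadband noise
SD 3 against unit-SD sources. That noise level keeps the estimator in
its responsive mid-range: measured wPLI runs from ~0.2 for uncoupled
pairs (the null level at 20 trials × 10 s — narrowband autocorrelation
leaves roughly one independent phase observation per cycle, so the null
is well above zero) to ~0.95 at full mixing. The k→wPLI transfer
saturates above k ≈ 0.7; the ready-made ground truths therefore keep
k(age) inside ~0.1–0.6, where the transfer is close enough to linear
that the configured trajectory shape survives into the measured
connectivity. Age-dependent trial attrition is available as a separate
operation so the balancing stage has something real to correct.

What the generator does **not** emulate: sensor-space physics, source
leakage/volume conduction (couplings are genuinely phase-lagged),
cardiac/ocular artefacts, head movement, 1/f background spectra, or the
skewed age density of real developmental cohorts. Passing end-to-end
tests therefore demonstrate that the pipeline recovers known structure
from data satisfying its assumptions — not that real recordings satisfy
those assumptions.

## Problem sizes and numerical conventions

The test and acceptance workloads use a desk-scale fixture — 30
subjects, 10 parcels, 20 trials, 2 bands, 200 CV iterations, 1,000
permutations — chosen as the package's own default experiment size;
full-size runs (hundreds of subjects, 90 parcels, 4 bands, 1,000 CV,
15,000 permutations) are configuration changes only. Percentile edge
extraction uses the nearest-rank convention with strict exceedance
(ties at the threshold are excluded). All stochastic stages draw named
child seeds from one master seed via seed sequences, making every run
bit-reproducible from its manifest; iteration counts are config keys.

## Known limitations

- The logarithmic coefficient vector is reported in its canonical
  (c₂ = 1) gauge; coefficient-level comparisons across software that
  fixes a different gauge are meaningless, curve-level ones are fine.
- The permutation shortcut for polynomial kinds is exact, but the
  logarithmic null refits inherit the grid-plus-refinement optimiser;
  an occasional local-minimum miss inflates a null RSS slightly, which
  is conservative for the p-value.
- The wPLI null level depends on trial length, trial count and band
  width; comparisons across bands share a null only approximately.
- With ~4 subjects expected under age 11 in a 30-subject uniform
  cohort, the childhood bend of log trajectories is sparsely sampled;
  quadratic fits occasionally win the selection on individual
  replicates. This is a property of small cohorts, not of the
  selection rule.
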