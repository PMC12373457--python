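# Methods

This note documents the models implemented in rhythmap, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Tapping: phases, resultant vectors, composite

Tap times are converted to phases relative to the beat grid. Each tap is
assigned to its **nearest beat**; the phase is 360°·(tap − beat)/IOI, where
the local IOI is the interval from the assigned beat to its successor (the
last beat reuses its predecessor's interval, since music grids may have
variable tempo). Phases are wrapped to (−180°, 180°]; a tap exactly midway
between two beats is assigned to the earlier beat, giving +180° rather than
−180°, which keeps the output deterministic and consistent with the stated
range. Whether phases should be referenced to the nearest or the preceding
beat is a genuine convention choice; nearest-beat is the package's default
because it treats anticipation and lagging symmetrically. Taps before the
first or after the last beat are assigned to the boundary interval rather
than discarded — every tap contributes.

Before analysis, isochronous trials drop their first two taps (startup
transients) and music trials keep only taps after the 11 s guide metronome
ends (strict inequality: a tap exactly at 11.0 s is discarded).

A trial's summary is the mean resultant vector of its phases: R is the
modulus and θ the argument of n⁻¹ Σ e^{iφ_k}. The Rayleigh uniformity p uses
the small-sample approximation p = exp(√(1 + 4n + 4(n² − S²)) − (1 + 2n))
with S = nR, accurate down to very small n (unit tests cross-check it against
pingouin). With R below 1e−12 the direction is undefined and flagged.

The two repetitions of each music clip are averaged with a **scalar mean for
R and a circular mean for θ** (direction of the mean of the two unit
vectors). Averaging the raw resultant vectors instead would couple the
averaged angle to the two R values; the scalar/circular split keeps the two
components independent, and the choice is recorded in the summary's metadata
note. If only one repetition is usable it is carried forward with a
provenance note.

The participant composite averages 18 components over the nine stimuli:
180·R (length rescaled to the angle's 0–180 scale) and −|θ|. An undefined
direction (chance tapper) contributes the worst-case −180, so random tapping
is not rewarded with a missing angle; the composite therefore spans exactly
[−90, 90].

## Beat extraction from annotations

Consensus beat grids are recovered from multi-annotator tap series by pooling
all taps and evaluating a Gaussian kernel density (kernel SD 20 ms, the
"kernel width"; grid step 1 ms, required ≤ bandwidth/4 so peaks are
resolved). Beats are the density's local maxima above a prominence floor of
0.1 × the density maximum, at least 250 ms apart (half the period of a
240 BPM beat, the fastest plausible). Both thresholds are exposed as
parameters since the appropriate values vary by clip; plateau peaks resolve
to the plateau midpoint for determinism. A flat density yields an empty beat
list with a warning rather than an error.

## Beat Alignment Test scoring

Sessions contain 9 on-beat, 9 off-beat and 3 unscored tempo-shifted filler
trials; fillers sit at fixed 1-indexed positions (5, 12, 19 by default — the
original fixed positions are unpublished, so they are configurable). Orders
are rejection-sampled until no clip repeats back to back and no condition
(filler counted as its own condition) runs three in a row.

Scoring: hits are on-beat trials judged aligned, false alarms off-beat trials
judged aligned. Rates of exactly 1 and 0 are replaced by 0.99 and 0.01 —
only at the extremes, not a log-linear correction. d′ = z(H) − z(F);
c = −(z(H) + z(F))/2 (the standard formula; only d′ and c are named in the
scoring convention, the bias formula is the field default); accuracy is
percent correct over the 18 scored trials.

The synthetic responder inverts this model: it answers "aligned" with
probability Φ(d′/2 − c) on on-beat and Φ(−d′/2 − c) on off-beat trials. Note
that with only 9 trials per condition the extreme-rate rule makes the
*estimator* upward-biased for large d′ (the exact enumeration gives
E[d̂′] = 2.38 at true d′ = 2); the tests assert agreement with that exact
expectation rather than pretending the 9-trial estimator is unbiased.

## Crawford–Howell single-case inference

t = (x★ − m̄)/(s·√((n+1)/n)) with df = n − 1, one-tailed on the lower
(deficit) tail; impairment requires p < α **and** a score below the
normative mean. α defaults to 0.02, the conservative cutoff recommended for
small normative samples; simulation in the test suite confirms the empirical
type-I error at normative n = 28 stays within [0.015, 0.025] over 10⁵ null
cases. Normative exclusions are by explicit id list only — no automatic
outlier rule is applied, since the original exclusion criterion (visual
inspection) cannot be formalized. Power against cases 3 SD below the norm is
≈ 0.78 at these settings (exact noncentral-t value, verified by simulation);
single-case designs at n = 28 simply do not reach 95% power at α = 0.02.

## Voxel-based lesion-symptom mapping

* **Smoothing:** binary masks are convolved with a Gaussian of
  σ = FWHM/(2√(2 ln 2)) per axis (default FWHM 8 mm), zero-padded, turning
  lesion status into a continuous regressor. Coverage is always computed on
  the *binary* masks: a voxel enters the analysis only if ≥ 5 patients have
  an actual lesion there. Setting `fwhm_mm=0` regresses on binary masks.
* **GLM:** at each coverage voxel, behavior ~ intercept + lesion value +
  total lesion volume (always included). The t statistic for the lesion
  coefficient is computed by Frisch–Waugh residualization — algebraically
  identical to full OLS with df = n − 3 (verified to 1e−10 against
  statsmodels) — which reduces each permutation to one matrix–vector
  product. Voxels whose lesion regressor is collinear with the covariates
  are dropped with a log entry.
* **Sign convention:** positive t always means damage associates with worse
  behavior. The default outcome is the dichotomized impairment indicator
  (1 = impaired); a continuous higher-is-better score is declared with
  `behavior_direction="score"`, which flips the sign.
* **Cluster correction:** the observed t map is thresholded at one-tailed
  voxelwise p < 0.01 (t quantile at df = n − 3); suprathreshold voxels are
  labeled with 26-connectivity by default (6/18/26 configurable — the
  convention of the original analysis code is unknown). Each permutation
  shuffles the behavior vector across patients while lesions and their
  volume covariate stay attached to their patients, and records the maximum
  cluster extent. Corrected p = (1 + #{null ≥ observed})/(1 + n_perm), so
  the smallest attainable p is 1/(1 + n_perm) and p is never zero. Clusters
  with corrected p < 0.05 (right-tailed) are significant; sizes are
  reported in mm³ and centers of mass in world coordinates via the affine.

Family-wise error was measured at 200 null cohorts (20³ grid, 30 patients,
1000 permutations — sizes chosen so the full calibration runs in under a
minute): observed FWER 0.035–0.08 across seeds around the nominal 0.05, and
a planted critical region with strong coupling is recovered as the top
cluster at the minimum attainable corrected p with its center of mass inside
the region.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the analysis assumes:

* **Stimuli:** 3 isochronous sequences of 60 tones at IOIs 600/450/750 ms;
  6 music clips of 30 s with an 11 s guide metronome, two repetitions each.
  Music grids are surrogate isochronous-at-tempo grids (tempi drawn
  uniformly in 80–140 BPM unless supplied) — the real clips' tempo curves
  are not modeled, so tempo-tracking behavior is untested.
* **Tappers:** von Mises phases around a mean asynchrony (uniform for chance
  tappers), with per-beat misses, Poisson spurious taps, and optional
  random-walk phase drift. Each entity draws from an RNG stream keyed by
  (seed, participant, trial), so outputs are bitwise reproducible under
  partial re-runs.
* **Lesions:** spherical binary lesions with radii spanning 8–47 mm (sphere
  volumes ≈ 2.1–435 cm³, the range reported for the study cohort), centers
  concentrated in the middle of the grid to mimic a shared vascular
  territory; the default cohort has 33 patients, behavioral baseline 63.7
  (the control mean) with noise SD 10, and the score drops by `effect_size`
  per unit proportion of a planted critical region lesioned.

Not emulated: audio, tap-onset detection from recordings, real lesion
geometry (spheres rather than vascular territories), spatial normalization
error, and any correlation structure between demographics and behavior.
Passing tests therefore demonstrate that the *analysis* is correct and
calibrated under its own assumptions, not that those assumptions hold in any
particular real data set.

## Problem sizes in the test and acceptance runs

Calibration suites use scaled-down but statistically meaningful sizes chosen
as the package's own test conditions: 10⁵ null single cases; 2000 Rayleigh
trials; 200 seeds per (κ, phase) cell at 58 taps; 200 null VLSM cohorts on a
20³ grid with 30 patients and 1000 permutations. The full pipeline default
remains 10,000 permutations.

## Known limitations

* The composite treats leading and lagging tappers identically (|θ|); finer
  tap-timing phenotypes (drift, period matching, tap-to-tap intervals) are
  out of scope.
* The BAT generator models alignment judgments only, not reaction times or
  the tempo-shifted filler acoustics.
* VLSM here is mass-univariate; multivariate lesion-symptom methods are not
  implemented.
* Beat-extraction thresholds are global per clip; clips whose inter-beat
  interval is shorter than `min_separation_ms` will have beats clipped (by
  design, documented in the peak-picker).
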