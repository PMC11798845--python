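# Methods

This note documents the models, numerical choices and limitations behind
`ceusflow`.  It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script.

## Replenishment kinetics and fitting

The per-pixel signal model is piecewise: steady-state plateau `O + A`
before the destruction window, residual `O` during it, and the
mono-exponential refill `O + A(1 − e^{−β(t−t_f)})` afterwards.  This is
the canonical destruction-replenishment mean model; no bolus wash-in
alternatives (log-normal, lagged-normal) are implemented, and rise-time /
time-to-peak parameters from bolus kinetics are out of scope.

Fitting uses bounded (nonnegative) trust-region nonlinear least squares on
the post-flash segment only.  Initialization: `O₀` = post-flash minimum,
`A₀` = 95th-percentile intensity minus `O₀`, `β₀` = ln 2 over the time to
half plateau; iteration stops when the relative parameter step falls below
1e-8 or after 500 iterations.  The optimizer is deterministic (no random
restarts) so identical inputs give identical fits.  A flat post-flash
segment (zero total sum of squares) cannot define `R²` and is returned
non-converged, hence excluded.  The reliability gate excludes fits with
post-flash `R² < 0.70`; the boundary value 0.70 itself is kept.

Parameter definitions — MFV `= A·β` (initial wash-in slope, au/s), transit
time `= 1/β` (s), MBF `= A²·β` (au²/s) — are a declared convention: they
are the only simple assignments consistent with the reported units and
with reading MBF as a blood-volume proxy divided by the transit time.
Absolute arbitrary-unit values are acquisition-dependent; rates and ratios
are the meaningful quantities.

On noiseless curves the fit recovers generator parameters to better than
1e-4 relative (tested over 200 draws with `A ∈ [0.1, 20]`,
`β ∈ [0.05, 5]`).  At 5% multiplicative noise the median MFV bias is below
5%, and the excluded fraction is non-decreasing in the noise level.

Replicate aggregation takes the component-wise median of MFV, transit time
and MBF over the non-excluded replicates of an exam-region; an exam-region
with no surviving replicate is missing, not zero.  Note that component-wise
medians of an odd replicate set may select components from different
replicates, so the exact identity `MBF = MFV²·TT` is guaranteed at the
replicate level but not after aggregation.

## Cine handling

Clips are multi-page TIFF stacks with a plain-text `key=value` sidecar
(`frame_interval_s`, `pixel_spacing_mm`, optional `flash_end_index`).
Pages are written in the array's own floating-point precision, so round
trips are bit-exact for both 32-bit and 64-bit clips.

Pixel coordinates are 0-based with pixel centers at `(i + 0.5) × spacing`;
circular ROIs include pixels whose centers lie within the radius
(center-in-circle, verifiable by brute-force lattice counting).  Flash
detection returns the metadata index when present; otherwise it takes the
last frame of the global-minimum run of the whole-frame mean — intensity is
minimal throughout destruction and rises at replenishment onset — and
requires that minimum to fall below 50% of the preceding mean, so a clip
without a destruction event is reported as such rather than silently
mis-segmented.  With a nonzero residual offset and heavy noise the
single-minimum frame can fall anywhere in the destruction window; callers
with such data should carry `flash_end_index` in the metadata.

Motion correction, inter-replicate registration and anatomical
segmentation are out of scope.

## Synthetic study generator

The generator emulates the structure of the cohort: 9 hypoxic and 6
normoxic animals, 1-3 exams per animal on distinct days within days 2-13
on circuit, triplicate cine acquisitions per exam, three ROIs (whole
brain, central/thalamic disc, peripheral parenchymal disc, the discs 5 mm
in diameter).  Group-by-region kinetic medians default to the published
median MFV and transit time per region, converted to `A = MFV·TT` and
`β = 1/TT`.  MBF is then determined (`A²β`) and not independently
configurable: sample medians of a nonlinear function of `A` and `β` need
not match any separately reported MBF summary, and the generator does not
pretend otherwise.

Biological variability is log-normal with median one: `dispersion` is the
marginal log-scale SD of each kinetic parameter, split 80% between animals
(shared across a lamb's exams) and 20% between exams.  The default 0.3
yields exam-level coefficients of variation near 30% per parameter, a
realistic scale for small-animal perfusion measurements; with
`dispersion=0` every animal sits exactly on the group medians.  At these
group sizes the sampling error of a group median is substantial: the
configured hypoxic-below-normoxic whole-brain MFV ordering is reproduced
in about 90% of cohorts, and recovered group medians can deviate from the
configured values by ~25% in a single cohort — passing tests therefore
demonstrate pipeline correctness, not small-cohort precision.

Acquisition noise is i.i.d. multiplicative log-normal with unit mean
(log-scale SD `noise_sigma`, default 0.05 for cohort clips) — a simple
positive, scale-proportional stand-in for speckle.  It does not model
spatially correlated speckle, attenuation, beam geometry or microbubble
physics, so detector-level artifacts are outside what the tests cover.

The rendered whole-brain ROI is a large ellipse minus the two focal discs.
This keeps each measured region kinetically homogeneous; including the
discs would mix their slow, high-amplitude exponentials (≈20% of the
summed amplitude) into the whole-brain curve and bias its fitted transit
time upward by tens of percent, conflating generator geometry with
pipeline accuracy.

Doppler envelopes are raised cosines `EDV + (PSV−EDV)(1+cos 2πft)/2`
sampled over whole cardiac cycles, so PSV/EDV/TAMV have closed forms and
the pulsatility index is exact.  Cardiac tables draw daily LVCO, RVCO,
circuit flow and oxygen delivery around group medians (hypoxic 320/460/221/15.6,
normoxic 290/460/278/21.6 mL/kg/min) with the same log-normal effect
structure; the LVCO/RVCO split is the package's own choice, set so that
combined output is higher and circuit flow and shunt fraction lower in the
hypoxic group, consistent with the reported directions.

## Group statistics

Observations are exam-level and treated as independent (1-3 exams per
animal); no mixed-effects modelling is attempted, matching the summary
tables the pipeline reproduces.  The Mann-Whitney U statistic comes from
midranks; p-values use the tie-corrected normal approximation with a 0.5
continuity correction, replaced by the exact permutation distribution when
the pooled sample has at most 10 tie-free observations.  Quantiles
(medians, IQRs) use the linear-interpolation rule.  Benjamini-Hochberg
adjustment is applied within each analysis family — the 9-test
median-comparison table, each stratum's table, the 6-test contrast family,
the correlation family — mirroring per-table presentation of adjusted
p-values rather than one global correction.

## Crossmatch test

Distances are Euclidean on pooled z-scores (sample SD, ddof 1), making the
test invariant to affine maps applied jointly to all points — necessary
because MFV (au/s) and transit time (s) are incommensurable.  A
zero-variance coordinate is dropped with a warning.  The minimum-weight
perfect matching is found by the blossom algorithm (networkx); for an odd
pool a ghost point at zero distance to all others is appended and its
partner left unmatched.  The null pmf is computed exactly (including the
odd-N singleton variant) and checked against its closed-form mean
`n0·n1/(N−1)` for all even pools up to N = 30.  The p-value is one-sided
(few cross-matches ⇒ distributions differ).

Two caveats are inherent to the exact test.  First, it is discrete: at
n0 = n1 = 10 the largest attainable size below nominal 0.05 is 0.0014, so
empirical type-I calibration is only informative at pool sizes whose
achievable size is near nominal — the calibration test uses n0 = n1 = 16,
where the achievable size is 0.0475 (computed analytically from the null
pmf).  Second, when both coordinates take exactly two balanced values the
pooled standardization equalizes within- and cross-group gaps and the
optimal matching is tied; tests avoid such degenerate configurations.

A per-group quadratic regression `TT = c0 + c1·V + c2·V²` (ordinary least
squares on `(1, V, V²)`) summarizes the empirical MFV-transit-time
relationship; the fitted coefficients are descriptive and are not compared
against any external values.

## Hemodynamics

`CCO = LVCO + RVCO`; `LVCO:RVCO` requires positive RVCO (flagged NaN
otherwise); shunt fraction is circuit flow over CCO, clipped to 1 with a
warning if measured circuit flow exceeds combined output.  The
pulsatility index uses the time-averaged maximum-velocity envelope (the
standard obstetric convention) over an integer number of cycles.
Cardiac-perfusion pairing joins on exact animal and day; exams without a
same-day cardiac row are dropped and counted, not imputed.

## Problem sizes

Default cine clips are 64 × 64 pixels at 0.5 mm pitch, 15 Hz, with 1 s
baseline, 3 s destruction and 15 s imaging (285 frames); cohort clips are
rendered in 32-bit floats.  These sizes keep a full cohort simulation and
analysis (≈90 clips, ≈260 fits) in the seconds range on one CPU while
leaving every kinetic time constant well resolved (the slowest configured
rate, β ≈ 0.26 1/s, still reaches 98% of plateau within the imaging
window).  Monte-Carlo checks use 100-1000 replicates depending on the
statistic; exhaustive enumeration oracles (matchings, permutations) run at
N ≤ 10.

## Known limitations

- Arbitrary-unit amplitudes make absolute MFV/MBF values
  acquisition-specific; only within-study contrasts are meaningful.
- The generator's noise and geometry are deliberately simple; passing
  tests validate the estimation and statistics chain, not robustness to
  real acquisition artifacts (motion, attenuation, partial destruction).
- Exam-level pooling ignores within-animal correlation, as do the summary
  tables it reproduces; p-values should be read accordingly.
- The crossmatch test is conservative at small samples due to
  discreteness.
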