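# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the validation suite shows.

## Subject-level pipeline

Stages run in a fixed order: initial-frame discard → spatial smoothing →
nuisance regression → temporal band-pass → motion metrics → censoring →
seed correlation → Fisher z.  The orchestrator (`run_subject`) enforces
this order and the QC sidecar records what was removed.

* **Frame discard** (default n = 5): the leading frames precede
  steady-state magnetisation; the generator plants a decaying intensity
  transient there so that skipping the discard is detectable.
* **Smoothing**: isotropic Gaussian, FWHM 4 mm (σ = FWHM/2.3548,
  converted to voxels via the affine), reflect boundary handling.
* **Nuisance regression**: per-voxel OLS with intercept on 12 named
  regressors — whole-brain, white-matter and ventricular mean signals,
  their backward-difference derivatives (first element 0), and the six
  rigid-body parameters.  Motion-parameter derivatives are off by
  default (a documented switch adds them).  The design is checked for
  rank; collinear columns are named in the error.
* **Band-pass**: second-order Butterworth run forward and backward
  (`sosfiltfilt`, effective 4th order, zero phase) over 0.009–0.08 Hz.
  Zero phase matters because correlations are timing-sensitive.
  Measured response: ≥ 99% amplitude at 0.04 Hz, ≤ 1% at 0.2 Hz
  (steady-state, away from record edges).
* **Motion metrics**: FD uses frame-to-frame differences of all six
  parameters, rotations scaled by r = 50 mm; the printed-formula variant
  without deltas on rotations would make FD nonzero for a perfectly
  still head held at an angle, so the framewise (difference) reading is
  used.  DVARS takes the square root (it is a root mean square), and the
  series is first rescaled so the within-brain grand mean is 100, making
  a unit difference exactly 1% BOLD — the threshold's unit.  DVARS is
  computed on the smoothed series *before* nuisance regression, because
  the % scale is undefined on mean-zero residuals.  Both metrics are 0
  at the first frame by convention (backward differences are undefined
  there).
* **Censoring**: a frame is dropped iff FD > 0.5 mm or DVARS > 0.5%
  (strict inequalities).  Censored frames are deleted at the correlation
  stage, not interpolated; filtering therefore sees an uninterrupted
  time axis, and the interaction between filtering and later deletion is
  a known, documented approximation.  A subject with fewer than 30 kept
  frames (configurable) is rejected rather than silently correlated.
* **Correlation / Fisher z**: seed time course is the unweighted spatial
  mean over the seed mask; Pearson correlation per brain voxel over kept
  frames; zero-variance voxels map to r = 0 (counted in a warning) so
  group maps stay finite; seed-internal voxels are not excluded and sit
  near r = 1.  z = arctanh(r) after clipping |r| to 1 − 1e−7.

## Group inference

All group statistics operate voxelwise on stacks of subject z maps:
one-sample t (df n−1), paired t (one-sample on differences; subject ids
must match), pooled-variance two-sample t (df n₁+n₂−2; pooled rather
than Welch, matching the SPM-era convention), and simple linear
regression on age (slope t, df n−2, with subgroup selection for the
men-only/women-only analyses).  Site is not a covariate by default.
t maps convert to Z by probability matching, Z = Φ⁻¹(F_t(t; df)),
symmetric in sign, capped at |Z| = 40 where tail probabilities
underflow; tables print peaks beyond |Z| = 8 as the token "Inf".

**Smoothness** is estimated from standardised residual maps: the
variance of spatial first differences per axis, de-biased for the
discrete lattice via λ = −2·ln(1 − var/2) (exact under a Gaussian
autocorrelation), then FWHM = √(4 ln 2 / λ), floored at 1 voxel.
RESEL counts come from exact lattice counting of points, edges, faces
and cubes of the mask, so non-box masks are handled correctly.

**Voxel-level FWE** takes the sharpest of three valid thresholds:
(i) the random-field threshold solving E[EC](u) = α with the field's own
EC densities (Student-t densities when df is known; they reduce to the
Gaussian densities as df → ∞); (ii) Bonferroni over the mask's voxels;
(iii) a discrete-local-maxima bound — the expected number of lattice
local maxima above u, evaluated in closed form through Owen's T function
from the lag-1 autocorrelation implied by the estimated FWHM.  The third
bound matters because continuous random-field theory is measurably
conservative when the field is only 2–3 voxels smooth, which is exactly
the regime of 8 mm-smooth maps on a 3 mm grid; the global maximum is
always a discrete local maximum, so the bound is valid, and it
approaches the continuous E[EC] as smoothness grows.  The validation
suite recomputes the empirical voxel-FWE rate on 500 null cohorts
(n = 20, 30×36×30 grid) and checks it against the binomial 95% band
around the nominal 0.05.

**Cluster-level FWE** forms clusters at voxel p < 0.001 (the field's own
quantile — the t quantile for a t map), labels them with 18-connectivity
(faces + edges, the dominant SPM convention; 6 and 26 available), and
assigns each the classical extent-distribution corrected p:
P(extent ≥ k) = exp(−β·k^(2/3)) in resel units with β matched to the
expected cluster count (field-specific EC densities) and expected
suprathreshold volume; corrected p = 1 − exp(−E[m]·P(n ≥ k)).  Both
tails are processed by negating the map.  The same Monte-Carlo
calibration covers the cluster-FWE rate.  Using Gaussian EC densities on
probability-converted t maps instead (an alternative the design space
allowed) proved markedly conservative in that calibration at low df and
was rejected in favour of the field's own densities.

**Slope comparison**: within each sex, z ~ age by OLS; the difference of
slopes is tested with pooled residual variance s² =
(RSS₁+RSS₂)/(n₁+n₂−4), SE = √(s²(1/Sxx₁+1/Sxx₂)), df = n₁+n₂−4 — the
two-separate-lines formulation, algebraically identical to the
age-by-sex interaction t in a full four-parameter model (the test suite
checks this).  The battery is Bonferroni-corrected: α = 0.05/n_tests,
with n_tests = 12 for the canonical region list bundled under
`midfc/data/` (3 VTA + 9 SNc men-only age-effect clusters).

## The synthetic cohort generator

The generator emulates the structure of a pooled multi-site rsFC study;
it does **not** simulate anatomy, slice timing, multi-echo effects or
nonlinear drifts (non-goals).

* **Grid**: 3 mm isotropic voxels on a 30×36×30 MNI-like box — cluster
  volumes in the emulated study are all multiples of 27 mm³, implying
  3 mm voxels.  Seeds are two disjoint compact blobs (≈16 voxels each)
  in the inferior-medial region; tissue labels (brain ellipsoid,
  white-matter shell, central ventricle) are generator-emitted, standing
  in for segmentation.
* **Site table**: five sites with scan lengths {225, 215, 215, 135, 295}
  frames and TR {2, 2.18, 2.2, 2, 2} s; ages uniform on [18, 49], sex
  Bernoulli with configurable male fraction (the emulated study's two
  inconsistent male counts are deliberately not reproduced).
* **Signal model**: all neural components are Gaussian processes made by
  filtering white noise into 0.009–0.08 Hz (so the analysis band-pass
  does not destroy planted effects), with filter edges trimmed (40
  frames each side) to keep the kept segment stationary.  Seed voxels
  share a latent time course (the two seeds' latents correlate at 0.5);
  target voxels follow ρ·s + √(1−ρ²)·e with
  ρ = base_ρ + β_age·(age − age_ref) + β_sex·[male] (sex-specific age
  slopes available).  Effects are planted on the **correlation** scale;
  inference operates on z, where the slope is β_age/(1−ρ²) by the delta
  method.  Infeasible ρ outside (−1,1) raises, or clips with a warning
  when configured.
* **Noise**: the voxelwise fluctuation field is given an 8 mm spatial
  correlation (band-limited white noise smoothed spatially, then
  renormalised per voxel).  This is the realistic regime — and it is
  load-bearing: with spatially *independent* voxel noise, the 4 mm
  analysis smoothing would average the noise down while the shared
  latent adds coherently, inflating recovered correlations well above
  their planted values.  Recovery is measured on the target region's
  interior (eroded by one voxel): smoothing partial-volumes the boundary
  voxels with surrounding effect-free tissue, diluting them by design
  rather than by pipeline error.  Thermal (white) noise of 0.05% BOLD is
  added on top.
* **Nuisance structure**: global, white-matter and ventricular
  components at 1× the neural amplitude; the global component occupies
  its own slow band (0.009–0.03 Hz), reflecting respiration/drift
  dominance — this also keeps its coherent frame-to-frame excursions
  well under the DVARS limit so that scrubbing removes exactly the
  constructed spikes.
* **Motion**: a slow random walk (median FD ≈ 0.02 mm) plus planted
  spikes — a persistent translation step of 0.7–1.8 mm at the spike
  frame with a proportional global intensity step (0.5% BOLD per mm).
  FD flags every spike; DVARS flags the larger ones, so the two metrics
  overlap without being identical, and their union is exactly the spike
  set.
* **Scaling**: baseline 1000 with a grand-mean-100 rescale for DVARS, so
  1 intensity unit = 0.1% BOLD; the initial transient is 1.5% BOLD with
  a 1.5-frame time constant.
* **Randomness**: one master seed; per-subject streams derive from
  SHA-256 of the subject id, so any subject regenerates identically
  regardless of cohort order, and identical (record, design, seed)
  triples are bit-identical.

A second, map-level generator (`simulate_zmap_cohort`) produces subject
z maps directly — planted mean plus a stationary smooth Gaussian field
(periodic boundaries) with noise sd 0.1 (bundling ≈ 0.07 sampling error
of z at T ≈ 220 with between-subject variation) and 2.7-voxel FWHM,
the smoothness measured on z maps from the full BOLD pipeline.  The
Monte-Carlo calibration and power experiments run at this level; the
full pipeline's fidelity is validated separately.  Consequently, passing
calibration does not certify the generator's BOLD realism — only that
the inference machinery is calibrated for maps with the pipeline's
smoothness — and recovery results say nothing about artifacts the
generator omits (slice timing, distortion, physiological cycles).

## Validation experiment sizes

`midfc.validation` fixes the problem sizes used by the test suite and
the acceptance script: 500 null cohorts of 20 subjects for FWE
calibration; 50 repeats of 60-subject cohorts (half male, male-only
age slope 0.01/year on the correlation scale) for recovery; 50 subjects
per planted correlation (0.3 and 0.6) through the full BOLD pipeline for
fidelity.  All are deterministic given the seed.

## Known limitations

* GRF cluster inference remains approximate on a lattice; the empirical
  rate recomputed by the validation suite sits within Monte-Carlo error
  of nominal, but the extent distribution is an asymptotic result.
* Deleting censored frames after filtering (the classical ordering) is
  inconsistent for heavily censored subjects; the 30-kept-frame floor
  bounds the damage.
* The side code ("L"/"R"/"L/R") uses a ±2 mm midline band and a
  span-the-midline rule; other conventions exist and the emulated
  study's own rule is not documented.
* Anatomical labels are pass-through text; no atlas is bundled.
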