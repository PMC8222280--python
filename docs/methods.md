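# Methods note

`radlung` quantifies radiation-induced lung injury from longitudinal CT in
two complementary ways — contrast-based Hounsfield-unit (HU) change in
isodose bins, and ventilation loss from breathing-deformation Jacobians —
and ships a synthetic thorax generator whose ground truth encodes the
response model, so every analysis stage can be validated end to end
without patient data.

## 1. Measurement model

### 1.1 Dose-binned HU change

The irradiated lung is partitioned into 10 Gy-wide physical-dose bins
(default edges 5, 15, …, up to just above the prescription; interval
`[lo, hi)`, top bin closed).  Bins smaller than 30 cc are excluded with a
warning — small contours make the mean HU statistically unstable.  Each
bin is represented by its midpoint dose and converted to the equieffective
dose in 2 Gy fractions,

    EQD2 = D · (d + α/β) / (2 + α/β),   α/β = 3 Gy,

with `d` the *prescription* per-fraction dose (total prescription / number
of fractions).  Under this convention a 50 Gy / 5 fx course maps the 5 and
15 Gy bin edges to 13 and 39 Gy EQD2; the alternative (`bin_fraction`)
convention, where `d = D / n_fx` for the bin's own dose, is available but
not the default because it is not what the bin-edge conversions above
correspond to.

Percent HU change between the pre-RT and post-RT epoch of a contour is

    ΔHU% = (HU_post − HU_pre) / |HU_pre| · 100   ("magnitude" convention),

so densification of aerated (negative-HU) lung reads positive.  The
`literal` convention (signed denominator) is available for comparison.
Baselines come from the first, pre-contrast frame of a dynamic
contrast-enhanced series (swine-style protocol) or from exhale-phase
volumes averaged over repeat acquisitions (human-style protocol); the
in-vessel measurement is the peak of the mean-HU time curve.

Controls: each dose-bin contour is reflected across the mid-sagittal plane
(halfway between the lung centroids along the left–right axis) and
intersected with the contralateral lung.  A control receiving ≥ 5 Gy is an
error, not a warning — it would silently bias the null reference.

Cohort statistics per bin: paired two-tailed t test of pre vs post,
Kolmogorov–Smirnov normality check on the standardized paired differences,
and a Bonferroni-adjusted threshold α/m with m the number of bins tested.

### 1.2 Vessel segmentation

1. Temporal maximum-intensity projection (MIP) over all frames captures
   each voxel's peak enhancement regardless of bolus timing.
2. The pre-contrast in-lung HU histogram (5 HU bins over [−1100, 300] HU,
   3-bin moving-average smoothing) is bimodal: aerated parenchyma near
   −850 HU, blood/soft tissue near +40 HU.  The two tallest local maxima
   at least 100 HU apart are the modes; a candidate mode must also reach
   1% of the tallest peak so a handful of outlier voxels cannot pose as a
   mode.
3. The upper mode's full width at half maximum is measured by linear
   interpolation of the half-maximum crossings and converted to a standard
   deviation via FWHM = 2.35 σ.  The vessel threshold is mode2 + 2σ; any
   in-lung MIP voxel strictly above it is vessel, and parenchyma is the
   lung with vessels subtracted (optional dilation of the vessel mask
   guards against partial-volume rims).

### 1.3 Ventilation via Jacobian ratios

For a breathing displacement field u (mm), J = det(I + ∇u) is the local
volume-change factor, computed with spacing-aware central differences
(one-sided at grid boundaries).  Longitudinal change is the voxel-wise
ratio J_post / J_pre; a voxel at or below 0.95 (a ≥ 5% loss of expansion)
counts as damaged.  Voxels where either Jacobian is non-positive (folding)
are marked with a negative sentinel and excluded from both numerator and
denominator.  Breathing phases across epochs are matched by equivalent
tidal volume: the inhale/exhale pair whose lung-volume difference is
closest to a target tidal volume, ties broken toward the pair containing
the end-exhale phase.

### 1.4 Cross-cohort comparison

Cohorts treated under different fractionations are compared on the EQD2
axis.  The swine-protocol linear dose response (ΔHU% vs EQD2) is evaluated
at the human bins' EQD2 values ("adjusted" dataset), and human per-bin
ΔHU% is regressed on those predictions; a slope near 1 means the reference
response transfers to the compared timepoint.  The vessel-coupling
analysis regresses per-bin in-vessel peak ΔHU% on out-of-vessel ΔHU% and
reports the correlation between the out-of-vessel increase and the
magnitude of the in-vessel reduction.

## 2. Synthetic thorax generator

The generator produces a 96×96×64 voxel grid at 2 mm isotropic spacing
containing two ellipsoidal lungs (semi-axes 36×55×45 mm, centers ±46 mm
from grid center along x; the right lung is irradiated), a random vessel
tree per lung (60 segments, 8 seeded at the lung center; radii
1.5–3.5 mm), and Gaussian acquisition noise (σ = 40 HU by default).
Tissue means are −850 HU (parenchyma) and +40 HU (vessel).

**Dose.** Dose falls off piecewise-linearly in an ellipsoidal (lung-shaped)
radius, with knots placed at volume quantiles so that every 10 Gy bin in
the irradiated lung holds the same target volume (45 cc by default, above
the 30 cc floor by construction).  The contralateral lung receives 0 Gy.

**HU response.**  Out-of-vessel gain per bin is x_b = f_t · 0.167 · EQD2_b
percent, where f_t is the timepoint factor (reference protocol 3-month
f = 1; human-protocol presets 0.785 / 0.588 / 0.955 at 3 / 6 / 12 months).
In-vessel peak enhancement starts from a gamma-variate bolus (amplitude
400 HU, arrival 9 s, shape 3, scale 2.5 s, 30 frames at 1.5 s — the frame
grid hits the analytic peak exactly) and is reduced per bin by a systemic
component (15% of the bolus) plus a leakage component linear in x_b with
slope −0.87 (% in-vessel per % out-of-vessel) across all irradiated bins.
A conservation ledger accounts the in-vessel deficit beyond the systemic
part as the leak pool and distributes it over bins above a 25 Gy physical
onset in proportion to their response and parenchymal volume, verifying
that leaked-out contrast never exceeds the measured in-vessel deficit.

**Damage and breathing.**  Each irradiated bin gets a damaged fraction
drawn uniformly from [0.40, 0.50] (dose-flat by design), realized as
spatially coherent blobs via exact-count thresholding of a smoothed noise
field.  Breathing displacement is axial (u_z) and is constructed by
solving the discrete central-difference recurrence so that the *measured*
Jacobian equals the target field exactly: J_pre ∈ [1.11, 1.19] inside the
lung, and J_post = 0.90 · J_pre on damaged voxels (1.0 elsewhere), so the
Jacobian ratio recovers damage fractions exactly.  Both epochs share the
breathing random stream: the post field is the pre field modulated by
damage, not an independent draw.

## 3. Parameter table

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| grid shape / spacing | 96×96×64 @ 2 mm | vox / mm | smallest grid with six ≥30 cc bins and resolvable vessels |
| lung semi-axes | 36, 55, 45 | mm | ≈ 0.9 L per lung at desk scale |
| μ parenchyma / vessel | −850 / +40 | HU | aerated lung and blood attenuation |
| acquisition noise σ | 40 | HU | sets realistic mode widths in the histogram |
| bolus amplitude / arrival / shape / scale | 400 HU / 9 s / 3 / 2.5 s | — | first-pass enhancement; peak lands on frame 11 |
| frames / interval / pre-contrast | 30 / 1.5 s / 4 | — | covers wash-in and wash-out |
| dose bin width / floor / control limit | 10 Gy / 30 cc / 5 Gy | — | binning convention of the analysis |
| α/β | 3 | Gy | late-responding lung tissue |
| reference slope | 0.167 | %/Gy EQD2 | encoded dose response |
| timepoint factors (human preset) | 0.785 / 0.588 / 0.955 | — | 3 / 6 / 12-month response relative to reference |
| systemic peak reduction | 0.15 | — | dose-independent in-vessel loss |
| leak coupling slope | −0.87 | % per % | in- vs out-of-vessel coupling |
| leak onset | 25 | Gy physical | dose above which leakage is accounted |
| damaged fraction range | 0.40–0.50 | — | center of the plausible 0.30–0.60 band |
| Jacobian damage threshold | 0.95 | — | inclusive, "0.95 or lower" |
| FWHM/σ | 2.35 | — | fixed conversion used throughout |

## 4. Numerical and design choices

- All randomness flows through `numpy.random.SeedSequence`; a subject is a
  pure function of (config, seed), with separately spawned anatomy,
  response, breathing and noise streams.  A `noise_seed` override
  regenerates only the acquisition noise, enabling repeat-scan
  experiments on fixed anatomy.
- The in-vessel coupling is linear in the out-of-vessel response across
  *all* irradiated bins; the 25 Gy onset enters only the conservation
  bookkeeping.  A kinked (flat-below-onset) model would not reproduce the
  encoded coupling slope when fit over the full bin range.
- Jacobians use `np.gradient` (central differences, one-sided at
  boundaries); the generator's displacement construction makes the
  discrete Jacobian exact rather than approximately matching a continuous
  target, eliminating discretization bias from recovery tests.
- Statistics come from `scipy.stats` (`ttest_rel`, `kstest`, `linregress`,
  `pearsonr`); file I/O uses NIfTI via `nibabel` with a JSON sidecar for
  dynamic-series timing.

## 5. What the generator does and does not emulate

Emulated: bimodal in-lung histograms, first-pass bolus kinetics, linear
EQD2 dose response with timepoint scaling, in-/out-of-vessel coupling with
contrast conservation, dose-flat ventilation damage, mirrored
uncontaminated controls, repeat-scan noise.

Not emulated: cardiac/respiratory motion artifacts, beam-hardening and
scanner-dependent HU calibration, anatomical variability beyond ellipsoids
and random vessel trees, deformable-registration error (displacement
fields are known, not estimated), perfusion heterogeneity.

## 6. Limitations

Statistics measured on real cohort scans — per-timepoint correlation
values, heat maps, and any number that depends on true anatomical and
physiological variability — cannot be reproduced from synthetic data at
desk scale.  This package validates the *pipeline* (does each stage
recover what the generator encoded?) rather than the *clinical findings*;
the presets encode published-scale effect sizes, and recovery tolerances
(±10% on slopes, correlation floors) reflect generator noise, not clinical
uncertainty.  Registration is assumed perfect: displacement fields are
inputs, and errors from estimating them on real image pairs are out of
scope.
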