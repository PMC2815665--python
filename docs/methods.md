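# Methods

This note records the models, numerical choices and limitations behind
`rotred`, in the order data flows through the pipeline.

## Conventions

Right-handed lab frame; lengths in mm, reciprocal space in 1/Å, angles
in degrees.  The incident wavevector **s0** points source → crystal with
|s0| = 1/λ; a diffracted wavevector **S1** has the same modulus and the
scattering vector is **p\*** = **S1** − **s0**.  The spindle rotates by
the right-hand rule about the unit axis **m2**; the continuous frame
coordinate z maps to φ = φ₀ + z·Δφ, so frame *f* (1-based in files)
covers z ∈ [f−1, f].  Detector pixels are (x fast, y slow) with centres
on integers, 0-based in memory and 1-based in files.  Both Ewald-sphere
crossings of every reciprocal-lattice point are generated as separate
predictions.

## Synthetic data

The generator is the ground-truth oracle for every stage, so its realism
budget is spent where the pipeline is sensitive:

* True intensities are Wilson-distributed (exponential, mean 8000 counts
  by default) with a B-factor falloff (default 15 Å²), constant on the
  symmetry classes of a chosen space group so merging statistics vanish
  on noise-free data.
* Each reflection deposits counts as a separable Gaussian: the rocking
  profile (σ_M degrees about the diffracting angle φ_c, split across
  frames by the error-function integral over each frame's φ interval)
  times an isotropic detector footprint whose width follows from the
  divergence σ_D at the crystal-to-detector distance.
* Recorded counts carry the Lorentz-polarization modulation (I/rlp with
  rlp = |ζ|/P): slow Ewald crossings near the rotation axis accumulate
  more counts, exactly what the correction stage later divides out.
  Without this modulation the LP correction would *introduce* scatter
  between symmetry mates of synthetic data.
* Poisson background with configurable gain g (emulated as g·Poisson(μ/g)),
  a circular sensitive face (imaging-plate-like; corners record dark
  current only), an optional beamstop shadow, ice rings, alien spots and
  per-frame exponential dose decay.  Spots whose footprint would be
  clipped by a dead region are neither rendered nor listed in the
  manifest, so manifest intensities are always fully recorded.
* Regeneration with the same seed is bit-identical.

Default study conditions: 256×256 pixels of 0.3 mm at 96 mm and λ = 1 Å
(≈ 22° of scattering angle at the face edge, d ≈ 2.6 Å), cells of
14–24 Å, Δφ = 1° over 30–45 frames, σ_M = 0.2°, σ_D = 0.3°, background
20 counts/pixel/frame.  Small cells keep neighbouring reflections
separated by ~16 px against an integration domain of ~11 px — the same
spots-per-detector-area regime as a real crystal on a large detector,
scaled to desk size.  What the generator does *not* emulate: oblique-
incidence (Kahn) footprint distortion, point-spread tails, detector
saturation physics beyond a hard overload clamp, and anisotropic
mosaicity.  Passing tests therefore demonstrate the correctness of the
algorithms under the stated model, not detector-specific calibration.

## Calibration tables

GAIN is the local variance over the local mean-above-dark in a
(2·NBX+1)(2·NBY+1) box (default 11×11), with iterated 2.5σ trimming and
a two-pixel dilation of the excluded set to remove spot tails; the
variance shrinkage of the one-sided trim is undone analytically
(truncated-normal factor 0.9556).  Shadow detection in the background
sum: trusted pixels below blank + 3·sqrt(gain·blank) are shaded.  The
ABS plateau estimator is the mode of a 256-bin histogram over the
20 %-trimmed value range, smoothed over nbins/16 bins; the plateau is
normalized to exactly 10 000.  Untrusted pixels carry −3 and masking is
monotone across XYCORR → INIT → DEFPIX.

## Spot finding

Strong pixels exceed the two-pass local box background by
STRONG_PIXEL·sqrt(gain·background) (the first pass excludes candidates
found with the BACKGROUND_PIXEL constant).  Spots are 6-connected
(face-adjacent) components in (x, y, z), accepted with ≥ 3 strong pixels
and a centroid within SPOT_MAXIMUM-CENTROID (3 px) of the strongest
member — the guard against ice-ring arcs.  Assembly is invariant to
pixel input order; capping to the strongest pixels breaks ties
lexicographically by (z, y, x).

## Autoindexing

Difference vectors of the ~400 strongest reciprocal-lattice vectors are
canonicalized to a hemisphere and binned in a 64³ histogram whose
half-width adapts to the data (3.5× the 2nd percentile of pairwise
lengths); SEPMIN and the smoothing radius default to 0.3× and 0.1× that
scale.  The basis triple minimizes the population-weighted integrality
deviation with a mild small-magnitude preference (guarding against sub-
and super-lattice bases).  Cells are Niggli-reduced by the Křivý–Gruber
iteration with relative ε = 10⁻⁵ and epsilon-aware sign classification
(a near-zero scalar product is treated as zero, which keeps boundary
settings deterministic).

The 44 lattice characters are encoded as (number, Bravais type, integer
transform, sign class).  A character's quality is the metric violation
of its transformed conventional cell — percent length mismatches plus
angle deviations in degrees, plus a penalty when the reduced scalar
products violate the character's sign class — so quality 0 means the
International Tables conditions hold exactly.  The likelihood column
1/(1+q) is an explicitly heuristic monotone map.  Round-trip tests over
all fourteen Bravais types (conventional → primitive → random unimodular
setting → reduce → classify) validate table and transforms.

Local indexing: a k-nearest-neighbour graph (k = 12) over the ≤ 3000
strongest spots; edge reliability is the product over the three indices
of a triangular kernel of half-width ε (INDEX_ERROR) on the
distance-to-integer of the pair difference, damped by
1/(1+(|m|/φ)²) (INDEX_MAGNITUDE); the maximum-reliability spanning
forest (Kruskal) defines subtrees and indices propagate from the
strongest node of the largest subtree.

Two measurement biases matter at Δφ = 1°: (i) rocking centroids snap
toward frame centres; z values are de-biased by inverting the
phase-compression curve at a rocking width estimated from the phase
spread; (ii) weak spots' centroids carry threshold-quantisation noise,
so geometry refinement uses the brighter half of the indexed spots
(indexing itself uses all).  Refinement is Levenberg–Marquardt on
(x, y, 0.5·z) residuals with numerical Jacobians, parameter classes
{CELL, ORIENTATION, BEAM, DISTANCE, ORGXY, AXIS}, and never returns a
model worse than its input.  The index-origin search scores each offset
|h₀|,|k₀|,|l₀| ≤ 1 by positional rms plus 0.05·(beam-centre shift in
pixels).  The run succeeds when ≥ 70 % of the spots are explained within
MAXIMUM_ERROR_OF_SPOT_POSITION (3 px, 3 frames).

## Integration

The profile grid is 9×9×9 voxels spanning (±δ_D, ±δ_D, ±δ_M) in the
per-reflection frame (angular offsets along e1 = S1×s0 and e2 = S1×e1,
plus the spindle offset φ−φ_c).  δ = 8σ by default, the midpoint of the
customary 6–10 band.  Two numerical choices keep observation and
template consistent:

* each pixel's counts are distributed over five sub-steps of its frame's
  φ interval, weighted by the predicted rocking density — otherwise each
  observation is a near-delta at its own sub-frame phase while templates
  are phase-averaged, and the fit collapses;
* pixels are split 2×2 before trilinear deposition (anti-aliasing of
  footprints that are narrow compared with the voxel).

Counts are collected within 0.8 of the domain radius (> 6σ_D) to keep
neighbouring reflections' tails out.  Reflections whose peak area
(half the collection radius plus two pixels) touches untrusted pixels
or the detector edge, or whose reciprocal vector lies within ζ < 0.1 of
the rotation axis (extreme Lorentz factors), are discarded outright —
a partially shadowed or near-spindle observation cannot be measured
reliably.  Templates are accumulated as
signed background-subtracted grids (noise cancels; clipping happens once
at the end), normalized by the signed total, per nine detector regions
per DELPHI batch; regions with fewer than 10 strong contributors borrow
the global template.  The fit solves counts = I·p + b·w by weighted
least squares in two passes, the second weighted by the fitted model
rather than the observed counts (removing the attenuation bias of
noise-correlated weights).  Because the fit is a per-voxel regression
against a template normalized over all voxels, it estimates the full
intensity directly; partiality (the recorded profile fraction) gates
acceptance via MINPK (default 75 %) instead of rescaling.

σ_D/σ_M auto-estimation uses the strongest ~200 spots: footprint second
moments from the peak frame (with the threshold-truncation shrinkage of
a 2D Gaussian undone analytically) and the sideband fraction of the
three frames around the peak, fitted against its phase-conditioned
calibration curve.  The rocking width is identifiable only when
σ_M/Δφ ≳ 0.4; below that the estimate saturates high and the (larger)
integration domain remains safe.  Batch width is the smallest whole
number of frames covering 2δ_M + Δφ.

## Correction and symmetry

Accepted reflections (MINPK, data range, resolution windows, ice-ring
exclusions, overload, REMOVE list — tallied per cause) are divided by
Lorentz (1/|ζ|), polarization (two-component dipole factor; reduces to
(1+cos²2θ)/2 unpolarized), air transmission and sensor efficiency.

The space-group proposal enumerates every lattice character consistent
with the cell metric (MAX_CELL_AXIS_ERROR 3 %, MAX_CELL_ANGLE_ERROR 2°)
and, per Bravais type, the enantiomorph-free candidates without screw
axes.  All candidates are judged on the same records, corrected once
for decay and detector-face modulation under the triclinic hypothesis
(so radiation damage does not masquerade as broken symmetry and no
candidate benefits from hypothesis-specific overfitting).  The real
per-observation error — integration model error included — is
calibrated from the scatter of Friedel pairs, which are equivalent
under every hypothesis, and mapped onto each candidate's class
structure as the R_meas expected of an intact symmetry
(E|I−⟨I⟩| = √(2/π)·σ·√((n−1)/n) per member).  A candidate is acceptable
with ≥ MIN_RFL_Rmeas (50) observations in classes with mates and a
measured R_meas within MAX_FAC_Rmeas (2.0) of that expectation; among
acceptable candidates the fewest unique reflections — the highest
merging symmetry — wins, and failing everything the triclinic
hypothesis is returned with a warning.  Users override with
SPACE_GROUP_NUMBER / UNIT_CELL_CONSTANTS.  Distinguishing a group from
its subgroups requires the cross-linking mates of a reasonably complete
sweep: on narrow wedges the undersampled higher symmetry can remain
statistically indistinguishable (and is then preferred, as the fewest
unique reflections), so the symmetry-recovery study uses 90° sweeps.

Scaling alternates class means with per-bin multiplicative factors
(Fox–Holmes-style least squares, relative tolerance 10⁻⁶, ≤ 100
iterations, mean-log-zero gauge per family): DECAY over rotation-batch ×
resolution bins, MODULATION over a 4×4 face grid, ABSORPTION over 13
face zones (a central disc plus 12 sectors) × batches; adjacent
underpopulated bins merge until every factor rests on
REFLECTIONS/CORRECTION_FACTOR (30) observations.  The same solver backs
the multi-dataset scaler.

The error model v(I) = a[v₀(I) + b·I²] is fitted to class sample
variances in ~10 equal-count intensity bins by an alternating scheme:
the slope b from precision-weighted per-bin estimates (weak bins carry
almost no slope information), the level a from bins where the counting
term still dominates — a joint linear fit is unstable because the two
regressors are nearly collinear on steeply falling intensity
distributions.  Misfits are expelled greedily (worst deviation from the
weighted mean of the remaining mates first, threshold
WFAC1·sqrt(v(I)+var(mean))) so one deviant cannot drag its mates over
the threshold; they keep their values with σ sign-flipped and are
excluded from all reported statistics.  Completeness compares unique
classes against full enumeration of the resolution shell; Wilson
outliers are |z| > 4 on log-intensity within shells.

## Multi-dataset scaling and conversion

All input sets of all output groups enter one joint scaling problem
(shared scale across output files); Friedel pairs separate in the
correction classes only when STRICT_ABSORPTION_CORRECTION and not
FRIEDEL'S_LAW.  Merged σ is the larger of the inverse-variance
propagation and the sample scatter of the contributors.  Zero-dose
extrapolation fits I(dose) = I₀ + s·dose per unique class of one
crystal (dose proxied linearly by frame number) and removes s·dose from
each observation; classes with < 3 observations are left unchanged and
flagged.

French–Wilson conversion integrates the posterior of F = √J under the
Wilson prior (acentric exponential, centric half-normal in J) with a
Normal(I, σ_I) likelihood, by 128-point Gauss–Legendre quadrature in
F-space over the likelihood support [I−8σ, I+8σ]∩[0,∞) — the F-space
substitution removes the centric J→0 singularity and the adaptive
support keeps the relative quadrature error far below 10⁻³ (verified
against 200 000-point trapezoid oracles).  Σ comes from 20 equal-count
resolution shells of the data.  Centricity is decided by symmetry-
operator enumeration (h → −h).

## Problem sizes

The test-suite stacks are 256×256 px with 150–450 reflections over
30–60 frames; the acceptance study reduces twenty random cells
(triclinic to cubic) blind and the symmetry study twenty stacks with
known groups, injected decay and counting noise.  These sizes keep the
whole suite and the acceptance script within a few minutes on one CPU
while leaving every algorithmic path exercised.

## Known limitations

Single panel, planar detector, monochromatic beam, single lattice; no
screw-axis determination (axial intensities and would-be absences are
reported for inspection); σ_M estimation saturates in the sub-frame
regime; the lattice-character "likelihood" is a heuristic map of the
metric penalty, not a probability.
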