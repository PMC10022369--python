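# Methods

## Scope and data model

The pipeline starts where manual work ends: electrode tips have been
localized (an ellipse fit to the tract at its tip, giving a 3D center),
and neuron somata have been traced as ordered closed 2D contours in every
confocal z-plane where they appear. A traced neuron is a
`NeuronScaffold`; everything downstream (volume, centroid, CSSI,
distances) derives from it. The coordinate frame is x = medial/lateral,
y = anterior/posterior, z = dorsal→ventral increasing from the slice top
at z = 0; all distances are in µm.

## Morphometrics

**Volume and centroid.** A voxel belongs to a soma when its center falls
inside the traced contour of that plane (even-odd rule; voxel centers sit
at (i + ½)·dx). Volume is the interior-voxel count times the voxel
volume; the centroid is the mean of interior voxel centers. On analytic
ellipsoids the error is set by voxelization and decreases monotonically
under grid refinement (≈1.3% at 0.81 × 0.81 × 3 µm voxels for a
2.9 × 10³ µm³ soma, ≈0.1% at 0.202 × 0.202 × 0.5 µm).

**CSSI.** The cell shape strain index 2(b − a)/(b + a) is computed from a
direct least-squares conic fit, constrained to an ellipse (Halir–Flusser
formulation), of the contour in the plane of greatest cross-sectional
area. Area ties break toward the more dorsal plane (the tie-break is a
package choice; it only matters for exactly symmetric synthetic input).
CSSI is scale-invariant and insensitive to whether axes or semi-axes are
supplied; the package stores semi-axes.

**Boundary-cut exclusion.** A soma is excluded when its greatest-area
plane is the first or last plane of the slice (within half a z-step of a
slice boundary): the mid-body then lay outside the section and volume and
CSSI would be underestimates. This operationalizes what is otherwise a
human judgment about "the middle of the soma" being lost; it
intentionally errs toward exclusion for a hemisphere clipped exactly at
its equator.

## Spatial statistics

Distances are 3D Euclidean from tip center to soma centroid. Each fiber's
*tracing radius* is min(50 µm, tip depth below the slice top); a fiber
contributes to the k-th position summary only when it has at least k
neurons inside its radius — if it has fewer, the true k-th neighbor may
lie beyond the (possibly reduced) radius and the position was simply not
measured. Distance ties break by neuron id for determinism.

The hypothetical-fiber grid is an axis-aligned 12.5 µm lattice centered
on the volume centroid, keeping points at least 50 µm from the volume
border and outside every soma. For traced scaffolds, soma membership is
tested against the contour polygon at the point's nearest z-plane; for
synthetic populations, against the analytic ellipsoid in 3D (the two
agree to within the z-step). In the 300 µm-diameter × 300 µm control
cylinder this yields ≈2.9–3.0 × 10³ points, depending on how many lattice
sites fall inside somata. Grid anchoring (centered vs corner-anchored)
was not specified in the source procedure; the centered choice changes
the count by a few percent and the distance means negligibly.

The closed-form mean k-th nearest-neighbor distance of a homogeneous
Poisson process, Γ(k + 1/3)/Γ(k)·(4πλ/3)^(−1/3), validates the
simulation path: without the in-soma exclusion the simulated grid means
sit on the closed form to within Monte-Carlo error (tested at 3 SEs
across 30 population replicates). The in-soma exclusion removes exactly
the grid points closest to a centroid and therefore biases the 1st-NN
mean up by ~0.7–1 µm at these soma sizes; the same mechanism is visible
in the measured control value (16.2 µm) sitting above the closed form
(15.9 µm).

## Glial profiling

Profiles are measured in the tip's own z-plane with in-plane distances,
in 10 µm rings bounded by lanes: strips perpendicular to the
total-least-squares electrode axis, centered on each tip, of width equal
to the minimum inter-tip pitch. Lane-boundary pixels go to the tip with
the nearer axis projection, ties to the lower fiber id, so lanes are
disjoint by construction. Ring means are divided by the plane background
(mean over pixels 300–310 µm from the nearest reference: the tip itself,
or the tract center for planes dorsal to a tip), making the ratio
invariant to acquisition gain. Rings with no pixels report NaN, never 0.
Planes that caught the top/bottom of the slice are excluded via a
user-supplied valid-z range; automatic detection is out of scope. Lanes
are not clipped perpendicular to the axis; bins end where pixels end.
Group comparisons use per-bin two-sided pooled-variance t-tests at
α = 0.05 with no multiple-testing correction (matching the source
procedure; the report notes this).

## Point-source model

V_pp(r) = I_pp/(4πσr) with the fixed unit convention
V[µV] = I[nA]·10³/(4π·σ[S/m]·r[µm]); σ defaults to 0.27 S/m (literature
cortical conductivity). The model treats a firing neuron as a point
current source at its soma centroid, in an isotropic medium, with
identical spiking output across neurons — so amplitude depends on
distance alone.

Fitting: with σ fixed the model is linear in I_pp and the least-squares
solution is closed-form (Σ V·x / Σ x², x = 10³/(4πσr)); a dense 1-D
grid-search oracle confirms it in tests. The joint (I_pp, σ) fit uses
`scipy.optimize.least_squares` from the documented initialization
(10 nA, 0.27 S/m); since V depends only on I_pp/σ this fit is
structurally non-identifiable, so the package reports the converged pair
*and* the identifiable ratio, and the ratio is what tests assert.

Discriminability: with predicted amplitudes V(k) at the mean rank-k
neuron positions, d_k = V(k) − V(k+1); for a noise threshold θ the
boundary rank is the smallest k with d_j < θ for all j ≥ k. The
thresholds are plain µV values (defaults 15 and 10). Note a deliberate
unit looseness inherited from the comparison being emulated: peak–peak
amplitude differences are compared against noise levels quoted in
µV_rms. Waveform scaling multiplies unit peak–peak spikes by V(r_k);
peak–peak is measured over the full stored window with no re-alignment,
so a mean of time-shifted spikes has peak–peak below the predicted value.

## Synthetic tissue generator

The generator's defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| density | 3.5e4/0.82 ≈ 4.27e4 mm⁻³ | healthy layer-V neuron density implied by the implant measurement (3.5e4 mm⁻³ at 82% retention) |
| mean_volume ± sd | 2.9e3 ± 1.3e3 µm³ (implant 2.3e3 ± 1.5e3) | soma volume, log-normal matched to mean/SD (only mean ± SD are reported; log-normal keeps volumes positive with the right first two moments) |
| cssi_mean ± sd | 0.25 ± 0.12 (near-tip 0.53 ± 0.22) | CSSI, truncated normal on [0, 1.8] |
| density_scale | 0.82 (implant) | thinning of the healthy density |
| exclusion_radius | 8 µm (implant) | peri-tip displacement radius |
| slice thickness | 300 µm | cryosection thickness |
| sampling rate | 24 414.1 Hz | spike waveform sampling |

Somas are triaxial ellipsoids: the axial semi-axis equals the
sphere-equivalent radius (3V/4π)^(1/3) and the in-plane pair splits by
the ratio k = (2 + CSSI)/(2 − CSSI) inverted from the CSSI definition,
with uniform random in-plane orientation.

**Peri-tip displacement.** The implant site shows ~0 neurons within
10 µm of a tip yet an essentially Poisson count within 50 µm, which
implies displacement rather than deletion. Centroids drawn inside the
exclusion radius R are pushed radially outward (from the nearest tip)
to a uniform radius in [R, R + 5 µm], conserving the total count
exactly. R is exposed in the config because no mechanism or radius is
reported; the default is 8 µm, and the near-zero 10 µm count is
reproduced with R = 10 µm (with R = 8 µm a small fraction of displaced
somata lands at 8–10 µm).

**Distance-dependent CSSI.** The implant CSSI mean declines linearly from
0.53 at the tip to the contralateral 0.25 at 162 µm (the reported
regression crossing), and the SD declines from 0.22 to 0.12 over the
same range so the far field recovers the contralateral distribution.
With a fixed SD of 0.22 the zero-truncation alone would inflate the
far-field mean to ~0.30. A consequence of imposing the *local* mean
0.53 at r = 0 is that the population mean over the whole 0–50 µm sphere
is ~0.47–0.49, slightly below the 0.53 summary statistic measured over
that sphere; the generator prioritizes the regression geometry over the
sphere average.

**Glial stacks** program intensity baseline·(1 + (peak_ratio − 1)·
exp(−d/decay_length)) plus Gaussian noise, with d the distance to the
nearest tract line (dorsal to a tip) or tip center (at/below it).
Defaults: GFAP-like decay 60 µm and IBA1-like 18 µm, chosen so the
ratio-versus-distance curve stays detectably above 1 to roughly 200 µm
and 60 µm respectively, the reported elevation extents.

**Spike clusters** scale a biphasic unit peak–peak template (48 samples,
~2 ms at 24 414.1 Hz) to predict_vpp at each tip's k-th nearest neuron
distance, plus Gaussian amplitude noise (default SD 10 µV, a typical
carbon-fiber baseline noise level). Raw voltage traces and spike times
are not simulated — the model's constant-output assumption makes
amplitudes sufficient.

**Randomness.** Every generator takes one integer seed, split via
`numpy.random.SeedSequence.spawn` into independent child streams
(placement, shape, orientation, displacement/noise), and is
bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: confocal texture, staining variability and
segmentation error; dendrites/axons; anisotropic or layer-dependent
density; correlated soma orientations near the tract; electrode drift or
waveform shape changes with distance. Tests against the generator
validate the *pipeline arithmetic* under the study's summary statistics,
not the biology.

## Numerical choices and degenerate inputs

* Ellipse fitting requires ≥5 non-collinear points; collinear or
  non-elliptic conic solutions raise with a diagnostic.
* Voxel membership, grid soma-membership and lane ownership all have
  explicit tie rules (even-odd; nearest plane; nearer projection then
  lower fiber id) so results are deterministic.
* Position summaries return NaN with n = 0 when no fiber contributes;
  empty profile rings return NaN; a degenerate t-test (two identical
  constant samples) reports p = 1 by convention.
* KS tests default to the asymptotic p-value with an exact option for
  small n; t-tests default to pooled variance with an unequal-variance
  switch (the source analyses do not state either choice).
* Linear-fit extrapolation flags "no crossing" for ~zero slope or a
  non-positive crossing distance rather than reporting an extrapolation
  artifact.

## Problem sizes used in tests and the acceptance script

The control simulation is the study-scale cylinder (≈905 neurons,
≈2.9–3.4 × 10³ grid points) — small enough that the acceptance script's
10 replicates and the 30-replicate oracle property test run in seconds.
Implant simulations use 16 tips at the 80 µm design pitch in a
1500 × 300 × 300 µm box. Spike-fit recovery uses 12 channels × 3
clusters × 100 spikes at 10 µV amplitude noise.

## Known limitations

* The per-channel cluster amplitudes behind the reported 16.6/15.9 nA and
  (14.4 nA, 0.23 S/m) fits are not published, so those exact values
  cannot be recomputed; the fitting procedures are instead validated by
  parameter recovery on synthetic data.
* The joint (I_pp, σ) fit is non-identifiable by construction; only the
  ratio is meaningful.
* The boundary-rank definition reproduces the qualitative "4th neuron on
  the boundary" statement; other reasonable definitions (first single
  sub-threshold gap) differ on non-monotone inputs.
* Glial profiling evaluates rings only in the tip's own z-plane, as in
  the emulated procedure; it is not a volumetric measure.
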