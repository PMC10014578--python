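# Methods

This note documents the models, algorithms and parameter choices behind
`ooclust`, and what the synthetic benchmarks do and do not show about
real microscopy data.

## The measurement problem

In maturing mammalian oocytes, chromosomes scattered through the
germinal vesicle converge into a single cluster within roughly half an
hour of nuclear envelope breakdown (NEBD).  Quantifying this requires
(i) an objective time zero (NEBD), (ii) a scalar measure of dispersion
whose decay rate is the "clustering speed", (iii) a description of the
actin flows in the nuclear region that drive the early phase, and
(iv) proximity statistics linking kinetochores to actin structures.
Each is implemented as an independent module over calibrated
(µm / minutes) multi-channel volumes.

## Synthetic data generator

`OocyteScenario` fixes the geometry (cell and nucleus radii, blob count
and size), the kinetics (NEBD time, convergence speed), the optics
(voxel size, frame interval) and the noise; a single seed drives all
randomness, and identical scenarios are bit-identical.

**Chromatin kinetics.** Blobs are placed by dart-throwing inside the
nucleus with a minimum separation of one blob diameter (scenarios that
cannot fit are rejected).  After NEBD every centroid is scaled toward
the nucleus centre by a common factor, which makes the true largest
pairwise distance decrease *exactly* linearly at the scenario's
convergence speed — so the generative slope is available in closed form
for parameter-recovery tests.  Motion stops when all pairwise distances
fall below two chromosome radii (the "formed cluster" floor).

**Rendering.** Chromatin blobs are Gaussians whose FWHM equals the
nominal chromosome radius, matching the diffraction-blurred appearance
of chromatin and giving analytically checkable geometry; fragments are
solid spheres so their voxel-count volume is checkable against
(4/3)πr³.  The lamina is a Gaussian shell that persists and compacts
slowly after NEBD; dextran fills the cytoplasm, is excluded from the
nucleus before NEBD and reaches cytoplasmic level within two frames
after it; the membrane is a shell at the cell radius.  Noise is Poisson
on the signal (shot noise) followed by additive Gaussian read noise,
applied last.

**Calibration regimes.** Defaults mirror the two imaging regimes the
analysis targets: live time-lapse at 0.5 × 0.5 × 3 µm voxels and 5-min
frames, and a fixed/airyscan regime at 0.19 µm isotropic voxels.  Both
are overridable.

**Flow scenes.** 2D actin texture is carried by Gaussian particles
(σ = 1.5 px, density 0.05 px⁻², generated with a margin beyond the
frame so border inflow is consistent).  The scene is tiled into 32-px
patches; each patch moves toward the disc centre with probability
`actin_inward_fraction`, otherwise in a uniformly random direction, at
`actin_speed` (default 3 µm/min).  Neither the cable density nor the
coherence scale of real actin flow is constrained by a measured value;
the density was chosen to give PIV-standard seeding (≈ 0.05 particles
per pixel) and the patch size to sit just above the final interrogation
window so each window sees predominantly one motion.  Flow ground truth
is 2D, as is the PIV analysis.

**Kinetochore–actin scenes.** A bundle of crossing cylindrical cables
(radius 0.5 µm) forms one connected actin structure whose volume falls
inside the 30–1,000 µm³ surface gate.  Kinetochore contact flags are
drawn once per spot as Bernoulli(contact probability) — so the realised
contact rate is an unbiased sample — and only the positions are
resampled under the placement constraints (contacting spots on a cable,
non-contacting ones ≥ 1 µm away, ≥ 0.8 µm mutual separation).

**What the generator does not emulate:** photobleaching and
phototoxicity, optical aberrations and depth-dependent scattering,
chromosome shape (blobs are isotropic), nucleolus-associated chromatin,
3D flow, and cytoplasmic autofluorescence.  Passing the recovery tests
therefore shows that the *algorithms* are unbiased under realistic
noise and sampling, not that they are robust to every real-data
artefact.

## Segmentation

Chromatin foci: optional Gaussian pre-smoothing (default σ = 1 voxel in
xy, 0.5 in z — reflecting the axial anisotropy of live stacks), Otsu
threshold, 26-connectivity labelling, minimum-volume gate (default
0.5 µm³), intensity-weighted centroids.  Surfaces: Otsu plus an
inclusive per-component volume gate, default 30–1,000 µm³.  Spots:
difference-of-Gaussians band-pass followed by local-maximum detection;
the threshold is the larger of a robust noise floor (median + 6·MAD of
the band-passed image) and 20 % of the brightest response; with a
target count the strongest maxima are kept (all maxima, flagged, if
fewer exist).  A focus carries a kinetochore if a spot falls inside its
label region dilated by one voxel.

Lamina contour: CLAHE local contrast enhancement → Canny edges → polar
coordinates about the edge centre of mass → sector-wise outlier
rejection (drop pixels > 3·1.4826·MAD from the sector median, 10°
sectors including both neighbours) → periodic smooth fit of ρ(θ) →
outward expansion (default 1.5 µm; 2.5 µm is the documented
alternative).  The periodic fit is a truncated Fourier series whose
harmonic count (1–10) is selected by generalized cross-validation; a
Fourier basis is periodic by construction and, being a linear smoother,
makes GCV exact and cheap.  On a thick lamina band the Canny step
yields both flanks of the ridge and the outlier rule can favour the
(longer) outer flank, biasing the fitted radius by up to ~0.5 µm — in
the flow analysis the contour is only used (expanded) for
inside/outside vector selection, where this is immaterial.

## NEBD detection

The probe is a 10 µm-diameter sphere centred each frame on the centre
of mass of the above-Otsu chromatin signal; its mean dextran intensity
is compared with median(history) + k·sd(history) computed from *prior*
frames only (sample sd, n−1; optionally a rolling window).  Neither k
nor the minimum history length is constrained by a stated value; with
histories of fewer than ~5 frames the sd estimate is so unstable that
false triggers become common, so the defaults are **k = 6** and
**min_history = 6**, which on the synthetic regime give a ≤ 5 % false
trigger rate on stationary series and ≥ 95 % detection within ±1 frame
for influx amplitudes ≥ 5 × noise sd.  Both are exposed in config; the
trigger scan stops at the first exceeding frame, emulating an
acquisition switch (CLI exit code 2 = no event).

## PIV and circular statistics

Frames are first stabilized by subpixel phase correlation on the lamina
channel (pure translation, applied to all channels).  The displacement
field is then estimated in three passes with 64, 32 and 24-px windows
at 50 % overlap; each pass offsets its windows by the previous field
(nearest-neighbour interpolated, rounded to integers) and measures the
residual by zero-normalised cross-correlation (ZNCC) of the window
template inside a larger search region (margin = window/4).  ZNCC was
chosen over plain FFT correlation because an unnormalised peak drifts
toward high-variance patches and the overlap taper biases fractional
displacements toward integers (peak locking); template matching in
'valid' mode eliminates both.  Subpixel position comes from cubic
upsampling (×20) of the 7×7 peak neighbourhood, falling back to a
3-point Gaussian fit at map borders.  Windows are only placed where the
full search region fits inside the frame, so every emitted vector has a
symmetric displacement range.  Post-filtering is deliberately weak: a
vector is invalid only if its primary/secondary correlation peak ratio
falls below 1.05; invalid vectors are median-filled from their valid
neighbours before the next pass.  On noiseless programmed translations
of the synthetic texture the worst vector error over 50 scenes is
< 0.1 px.

Vectors inside the (expanded) lamina contour with speed ≥ 1.8 µm/min
are classified by the angle between the vector and the direction to the
nuclear centre.  Four sectors of 120° each cannot tile the circle, so
the default tiling is inward [−60°, 60°), outward [120°, 240°) and two
60° sideways sectors; the overlapping strict-120° variant is available
behind a flag.  Under this tiling an isotropic field yields an inward
fraction of 1/3.  The circular mean is the resultant direction; its
95 % CI uses the circular-dispersion approximation
(± asin(1.96·√(δ̂/n))) when the sample is large and concentrated enough
(n ≥ 8, resultant length > 0.25, argument < 1), and otherwise a seeded
bootstrap (2,000 resamples).  Antipodally balanced samples report an
undefined mean.

## Colocalization

Spot-to-surface distances use a Euclidean distance transform of the
complement mask in calibrated space (0 inside the surface), sampled at
the voxel containing each spot — agreeing with brute-force
nearest-voxel search to within half a voxel diagonal.  The mirrored
control reflects spot coordinates about the volume mid-plane
(x′ = extent − x with extent = (n−1)·voxel, an exact involution on
voxel centres).  No numeric cutoff defines "interacting" in visual
scoring; the default is **0.25 µm**, approximately the lateral airyscan
resolution at which a contact becomes unresolvable, echoed in all
outputs.  The expected random overlap of two independent
classifications is the product of their fractions.  ROI crops have a
fixed physical size (default 10 µm cube); automatic placement maximises
the distance from the nucleus mask and image border.

## Clustering kinetics conventions

Distances are vertex-based by default (all labelled voxels — the
discrete analogue of isosurface vertices), with an intensity-weighted
centroid fallback for coarse data.  Speeds are the per-frame mean of
−ΔD/Δt over consecutive-frame midpoints in a half-open window
[start, end), positive while converging; a regression-slope variant is
available (the two agree exactly on linear series).  Reporting windows
default to 0–30 and 30–50 min post-NEBD; NEBD is time zero.  An
interval containing fewer than two frames is an error.  Convex hull
volumes use Qhull; degenerate (coplanar) sets report 0.  The fragment
size gate is strict: volume < 30 µm³ is "small", ≥ 30 µm³ "large".
Chromatin around the nucleolus has no automatic exclusion rule; an
optional user-supplied exclusion mask fills that role.

## Numerical and scale choices

Benchmark sizes were chosen so the full suite runs comfortably on one
CPU: recovery studies use 20 oocytes (the reported per-oocyte sd of the
recovered clustering speed is ≈ 0.03 µm/min, so the mean is determined
to ~1.5 %), detector rate studies 100 series of 12 frames at a reduced
geometry (14 µm cell), and oracle batteries 50 seeded instances per
operation.  With the live-regime 3 µm z-step, single-frame distance
read-outs carry ±1–2 µm of voxelization noise; the speed estimator is
robust to this because the mean of finite differences telescopes to the
endpoints and averages across oocytes.

## Known limitations

* PIV is 2D and first-order (window offsetting, not full image
  deformation); strong rotation or shear within a window is averaged.
* The lamina fit assumes a star-convex nucleus about the edge centre of
  mass.
* Kinetochore assignment to foci assumes spots lie within one voxel of
  their focus; heavily blurred axial geometry can miss assignments.
* The synthetic study conditions are favourable in one respect: objects
  are isotropic and backgrounds flat, so Otsu thresholds are stable.
  Real chromatin requires per-dataset tuning of the smoothing sigma and
  minimum-volume gate, which are exposed in `SegmentationSettings`.
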