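# Methods

`atriaflow` estimates left- and right-atrial volumes from a single
non-gated, first-pass dynamic cardiac PET scan (resting ¹⁵O-water
protocol), together with the parametric images the segmentation is built
on: bolus arrival time, first-pass area, and the kinetic maps MBF, PTF,
V_A and V_RV.  This note documents the model, the numerical choices, and
what the synthetic phantom does and does not establish.

## First-pass parametric images

Every voxel's time-activity curve (TAC) C(t) is reduced to its first-pass
bolus transit.  The transit segment is found by locating the global
maximum within a 120 s search window and extending in both directions
until the curve drops below 10% of the maximum, a local minimum below
half-maximum is reached (recirculation cut), or the window ends.  The
first sub-threshold frame at each end is kept unless the stop was the
recirculation minimum: a frame stores the *average* of the curve, so the
frame in which the bolus arrives usually sits below the 10% line while
holding real onset area; dropping it deflates the AUC of early-arriving
chambers (whose rise falls inside the long first frame) relative to the
LV reference and would bias their segmented volume low.

Two scalars summarise the segment:

* arrival time `t_mid = Σ tᵢ Cᵢ Δᵢ / Σ Cᵢ Δᵢ` with frame mid-times tᵢ and
  durations Δᵢ — duration weighting makes the centroid invariant to the
  strongly non-uniform framing (1×10, 8×5, 4×10, 2×15, 3×20, 2×30,
  2×60 s; 22 frames, 6 min);
* area `AUC = Σ Cᵢ Δᵢ`, proportional to local blood volume for blood
  voxels.

AUC is normalised so the LV blood pool reads 1 (reference: the first-pass
area of the LV-cavity mean TAC).  The blood pool is then the region with
normalised AUC > 2/3 and t_mid < 1.5 min.  Voxels with no detectable peak
(maximum below 5× the late-frame background) carry NaN and are excluded
from every mask.

## Input functions by cluster analysis

Candidate voxels (detected peaks with raw AUC above the 75th percentile)
are clustered with k-means (k = 6) on amplitude-normalised TAC shape,
seeded k-means++ initialisation on canonically ordered voxels so the
result is reproducible and order-independent.  The venous input C_RV is
the earliest-peaking high-AUC cluster (right heart); the arterial input
C_A is the highest-AUC cluster peaking ≥ 4 s later, with near-AUC ties
(within 10%) broken toward the *latest* peak so the left atrium — same
blood, ~3 s earlier — is never mistaken for the LV/aorta.  Both input
TACs average only the hottest quartile of member voxels: rim voxels are
partial-volume-diluted and carry blurred-in myocardial washout in their
tail, which otherwise biases MBF upward by several percent.

The lung timing reference t_lungs (needed by the left-atrial gate) is the
first-pass centroid of the cluster with intermediate AUC (0.15–0.5 of the
arterial AUC) lying strictly between the venous and arterial centroids;
if no cluster qualifies, the midpoint of the two centroids is used and
flagged.

## Kinetic model

The single-tissue compartment model for ¹⁵O-water:

    C_T(t) = PTF·MBF·C_A(t) ⊗ exp(−MBF/V_T · t) + V_A·C_A(t) + V_RV·C_RV(t)

with V_T fixed at 0.91 mL/g, MBF in mL·g⁻¹·min⁻¹ (divided by 60 inside
the exponent and the leading factor), PTF the perfusable tissue fraction
(g/mL) and V_A/V_RV arterial and right-ventricular blood fractions.

Fitting uses the basis-function formulation: for each MBF on a log-spaced
grid (200 points over 0.1–5.0 mL·g⁻¹·min⁻¹) the convolution is
precomputed once, leaving the 3-coefficient linear model
θ = (PTF·MBF, V_A, V_RV) solved per voxel by duration-weighted
non-negative least squares.  With three coefficients the NNLS optimum is
found exactly by enumerating the 2³ active sets, which vectorises over
hundreds of thousands of voxels; RSS ties on the grid break toward the
smaller MBF.  The 200-point grid (≈2% spacing) keeps the fit within 1% of
a free nonlinear least-squares solution in RSS and within grid resolution
(≤2%) in parameters on noise-free data; refining the grid can only help.

Convolutions run by trapezoidal accumulation on a uniform 1 s grid —
exact to well under 0.1% for these kinetics, with no transform-length
pitfalls.  Frame-sampled input functions are lifted to the fine grid by
linear interpolation at frame mid-times plus two fixed-point corrections
that force the reconstructed curve's frame averages to match the measured
frames; without this re-sharpening the flattened bolus peak biases MBF by
roughly +7%.

## Ventricular segmentation

The heart's long axis is the principal eigenvector of the second-moment
tensor of the LV blood pool, identified among high-V_A (≥0.6) connected
components as *the blood pool wrapped in muscle*: the component whose
2-voxel rim has the highest mean PTF.  (Size and timing are ambiguous
discriminators — a dilated atrium can out-volume the LV cavity and the
aorta shares its arrival time — but only ventricles have a perfusable
wall at PET resolution.)  A one-voxel erosion severs thin partial-volume
bridges between pools before labelling.  All maps are rigidly resampled
into a short-axis grid (+z basal, i.e. toward the remaining arterial
blood).

Per short-axis slice, 36 radial PTF profiles emanate from the slice
centroid of the cavity marker (V_A for the LV, V_RV for the RV).  The
wall is the nearest prominent PTF ridge beyond the cavity edge — nearest,
because septal profiles also cross the other ventricle's wall — with
inner/outer edges at half-maximum, capped at 10 mm half-thickness, and
the union of wall samples is morphologically closed.  This profiling is a
deliberately simplified re-creation of the published method chain, whose
exact criteria are not part of this codebase; every parameter is exposed
in `ChamberConfig`.

Cavities follow the resolution-margin rule: blood voxels inside the
per-slice-filled myocardial ring at least 1.3 cm (twice an assumed 6.5 mm
FWHM) from any myocardial voxel, by anisotropy-aware Euclidean distance
transform.  The cavity TACs yield t_LV, t_RV, AUC_LV, AUC_RV; AUC_LV
becomes the definitive normalisation reference (a provisional
normalisation to the arterial-cluster AUC bootstraps the blood mask
before the ventricles exist).

## Atrial segmentation

Left atrium: blood-mask voxels minus everything arriving later than
t_LV + two heartbeats (heart rate is a config parameter, default 60 bpm —
the acquisition described here carries no ECG), minus everything arriving
before the lungs, minus the filled interior of the segmented left
ventricle (myocardium plus enclosed blood, dilated one voxel — removing
only the margin-eroded cavity would leave a shell of ventricular blood in
the candidate).  The LV outflow tract axis — the line from the LV-cavity
centroid through the basal-most cavity slice centroid — is extrapolated
as a cylinder whose radius grows from 5 mm in 1 mm steps until the
candidate splits into ≥2 components of ≥5 mL; the component with the
lowest median t_mid is the LA, the rest is aorta.  If no split is
achieved by 30 mm the whole candidate is returned as LA and flagged.

Right atrium: the mirrored rule gated on t_RV (no lung gate — the right
heart fills before the lungs), minus the right ventricle's filled
interior and the left-heart labels.  Scanning axial slices from the
superior end, a run of ≥3 consecutive slices whose candidate
cross-section is small (< 4 cm²) and circular (4πA/P² > 0.6) is labelled
superior vena cava and removed; the largest remaining component is the
RA.  The 4 cm² area bound reflects a normal SVC cross-section (~3 cm²); a
looser bound would classify several slices of the tapering atrial roof as
tube.

Volumes are voxel count × voxel volume — mean (non-gated) volumes over
the scan, not end-systolic or end-diastolic ones.  BSA indexing uses
Du Bois (0.007184·w^0.425·h^0.725).

## Repeatability statistics

For paired test–retest values: RPC = 2·SD(differences) (sample SD),
CoV = SD(differences)/grand mean × 100, Bland–Altman limits
mean ± 1.96 SD, and the two-way mixed single-score ICC.  The consistency
form (MS_R − MS_E)/(MS_R + (k−1)MS_E) is the default reading of "two-way
mixed, single score"; the absolute-agreement form is computed alongside
since the convention is often left unstated.

## The synthetic phantom

The phantom emulates the acquisition the method targets: a 6-min scan in
the 22-frame schedule above, bolus transit SVC → RA → RV → lungs → LA →
LV → aorta with distinct arrival delays, gamma-variate first-pass curves
`A·((t−t0)/(αβ))^α·e^(α−(t−t0)/β)` (closed-form centroid t0 + β(α+1),
enabling analytic tests) with a recirculation tail (15% amplitude, +30 s,
doubled dispersion), and myocardial shells following the forward kinetic
model above (LV wall: MBF 0.9, PTF 0.60, V_A 0.15, V_RV 0.05; RV wall:
MBF 0.9, PTF 0.55, V_A 0.05, V_RV 0.20).

Geometry (96³ grid, 2 mm voxels, 192 mm FOV; any grid with the same FOV
scales): prolate ventricular cavities (LV ≈ 55 mL, RV ≈ 57 mL) with 10
and 6 mm walls, atria sized to the diseased cohorts this method was
developed in (LAV ≈ 70 mL, RAV ≈ 84 mL, i.e. indexed volumes near the
reported cohort medians at BSA ≈ 1.9 m²), a 25°-tilted ascending aorta
leaving the LV outflow tract, an SVC tube entering the RA roof, and
paired lung ellipsoids at ~30% of blood AUC.  A configurable global
rotation exercises the reorientation.  Resolution is emulated by an
isotropic Gaussian PSF of 5 mm FWHM — representative of the
reconstructed resolution of current clinical scanners; the more
conservative 6.5 mm figure is retained where it matters to the method,
in the 1.3 cm cavity margin.  Noise is multiplicative Gaussian with
SD ∝ √(value/frame duration), a simple surrogate reproducing the
variance decrease with frame length; it is not a claim about
reconstructed-PET noise texture (no spatial correlation, no
attenuation-dependent variance).

What passing tests show — and don't.  The phantom establishes that the
chain of rules is implemented correctly and is stable under voxel noise,
resolution blur, atrial size changes and orientation changes.  It does
not establish clinical accuracy: real data add respiratory/cardiac
motion, spatially correlated noise, anatomical variation (appendages,
pulmonary veins, valve planes) and pathology the ellipsoid-world phantom
cannot represent.  The systematic ~10–13% underestimate of atrial volume
seen on the phantom is the expected geometry of the 2/3 blood-pool
threshold clipping each chamber's partial-volume rim; on real data this
bias folds into the method's calibration against reference modalities.

## Problem sizes and determinism

The default end-to-end checks run the full 96³ phantom noise-free; the
paired test–retest experiment uses 20 subject pairs at 64³/3 mm (same
FOV) with default noise — repeatability metrics are precision statements
and are insensitive to the coarser grid.  Every stochastic step (noise
generation, k-means seeding, voxel subsampling in tests) is driven by an
explicit seed; identical spec and seed reproduce outputs bit-for-bit.

## Known limitations

* Mean (non-gated) atrial volumes only; minimal/maximal volumes and
  emptying fraction are out of reach without gating.
* The circumferential profiling and the LVOT/SVC rules are documented
  stand-ins for unpublished details of the original tooling, exposed as
  configuration rather than claimed as re-implementations.
* The heart rate entering the two-heartbeat gate is a configuration
  default (60 bpm), not measured from data.
* No attenuation/scatter simulation, no motion, no DICOM ingestion.
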