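# Methods

This note documents the models, numerical choices and limitations behind
`lysomorph`. It covers the three measurement families the package
implements: slice-wise lysosome membrane morphometrics, β-sheet registry
trajectory statistics, and fluorescence quantification.

## Slice-wise membrane morphometrics

### Input model

Input volumes are integer-labeled MRC2014 segmentations (as produced by
membrane-segmentation tools), handled internally in `(z, y, x)` order with
0-based pixel-centred coordinates. Label 0 is background; each positive label
is one membrane object. Physical sizes come from the map header (Å, stored
as nm). The pixel-unit filters assume isotropic in-plane pixels; this
assumption is recorded in the run manifest. Voxel anisotropy along z does not
enter any 2D computation.

### Centerline extraction

Each slice mask is thinned to a unit-width centerline (`skimage.morphology.thin`,
a Zhang–Suen-style iterative thinning). The skeleton pixels form a graph with
8-connectivity. The centerline is the longest geodesic (endpoint-to-endpoint)
path of that graph; branches off it are treated as thinning spurs and pruned.
Traversal starts at the endpoint nearest the image border — segmented
membranes are routinely truncated by the field of view, so the border end is
the natural arc origin. Skeletons without endpoints (closed loops) are cut
open at the pixel nearest the border and flagged; all contours are then
treated as open arcs. When several connected components survive thinning, the
largest is kept and a warning recorded. Contours of fewer than 4 points are
degenerate for a cubic fit; they are logged and count as invalid slices for
z-coverage.

### Spline fit and curvature

A smoothing cubic B-spline (`scipy.interpolate.splprep`) is fitted to each
ordered contour and sampled at 200 uniformly spaced parameter values. The
smoothing value is `s = (m − √(2m)) · σ̂²`, where `m` is the number of contour
points and `σ̂²` a per-point jitter-variance estimate computed from third
differences of the ordered coordinates (`σ̂² = E[(Δ³x)² + (Δ³y)²]/20`). Third
differences annihilate locally cubic trends, so the estimate vanishes for
noise-free contours (the spline then interpolates, which is required for
curvature accuracy at the 2% level) and converges to the pixel-jitter
variance for thinned skeletons (≈0.3–0.5 px), where it licenses smoothing at
the noise scale. A scale based on nearest-neighbour spacing was rejected:
point spacing is ≈1 px regardless of noise, and 1 px of licensed smoothing
residual distorts curvature of R = 10–50 px arcs by 10–35%.

Signed curvature is evaluated analytically at every sample from the spline
derivatives, κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}, in px⁻¹. Samples with
vanishing parametric speed yield NaN, never ±∞. The traversal orientation of
an open arc is arbitrary, so summaries report |κ|. Arc length is the length
of the 200-sample polyline; at these curvatures the discretization error is
below 0.1%. Perimeter equals arc length; bounding box, aspect ratio and
centroid are computed over the 200 samples. Arcs shorter than 50 px are
excluded ("below 50" read strictly, so exactly 50 px is retained; the
boundary is configurable).

Accuracy note: for noise-free contours, curvature error is dominated by the
interpolation error of the cubic spline, which at R = 10 px requires point
spacing ≈0.5 px to stay below 2%; thinned skeletons provide ≈1–1.4 px
spacing, where per-sample curvature errors of 10–30% remain (the ellipse
stage, not the curvature profile, carries the quantitative shape estimates
for such inputs).

### Ellipse fitting

Two stages. (1) The direct least-squares conic fit of Fitzgibbon et al.
(stable split-design formulation), whose constraint 4AC − B² > 0 guarantees
an ellipse; points are centred before the scatter matrices are built.
(2) Orthogonal distance regression on the five geometric parameters
(cx, cy, a, b, θ): Levenberg–Marquardt on the exact perpendicular distances,
with the analytic Jacobian given by the envelope theorem. The perpendicular
foot point is found by solving Eberly's scalar root equation
`(ax/(u+a²−b²))² + (by/u)² = 1` with Newton iteration from the lower bracket
`u₀ = by`; the root function is convex and decreasing, so convergence is
global and monotone for every query point, inside or outside (verified
against a dense-polyline oracle to 1e−6 px). Convergence is declared at
relative objective change < 1e−10 or 200 iterations; non-convergence is
flagged and the best iterate kept. The refinement never increases the sum of
squared perpendicular distances: if LM fails to improve, the initialization
is returned.

Fit quality: RMSE of the perpendicular residuals and
`R² = 1 − Σdᵢ²/Σ‖pᵢ − p̄‖²` (orthogonal residual scatter over total point
scatter about the centroid — well defined for orthogonal regression, ≈1 for
good fits). θ is canonical in [0, π), a ≥ b always.

### Bootstrap and confidence

Semi-axis uncertainty comes from a percentile bootstrap: 500 iterations,
each resampling the 200 spline sample points with replacement and repeating
the full two-stage fit; the 95% CI is the 2.5th/97.5th percentile pair.
Resampling uses a fixed seed (default 42, configurable) and is bit-identical
across runs; per-object seeds are derived from the master seed and object
label via `SeedSequence`, so objects can be processed in any order or
concurrently with identical output. Failed iterations are skipped and
counted; above 20% failures the CI is flagged unreliable.

Confidence tiers use the mean slice R² together with z-coverage
(valid slices / inclusive z-extent of occupied slices): High requires
R² > 0.5 and coverage > 0.7, Medium R² > 0.3 and coverage > 0.5, else Low.
Thresholds are strict inequalities. Per-object summaries report the mean
over valid slices of π·a·b (converted to nm²), mean spline arc length in nm,
and the equivalent diameter `2√(mean_area/π)` (the diameter of the circle
with the object's mean cross-section area — the conventional definition,
adopted here as the package's convention). Low-confidence objects can be
excluded from statistical comparisons by a flag.

### Group statistics

Condition comparisons are gated by normality: Shapiro–Wilk at α = 0.05 on
each group; Welch's t-test (unequal variances — the safer default for an
unspecified "independent samples t-test"; the pooled variant is available)
when both pass, otherwise a two-sided Mann–Whitney U test. Cohen's d uses
the pooled-SD denominator and is always reported. All metric comparisons
within one condition pair form one Benjamini–Hochberg family
(`statsmodels` `fdr_bh` behind the module surface). Liposome leakage is
normalized pointwise between the liposome-only control (0%) and the Triton
X-100 maximum (100%); values outside [0, 100] are reported raw.

## Trajectory statistics

Hydrogen bonds follow the DSSP electrostatic model: for every donor N–H and
acceptor C=O pair, E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol
(distances in Å, the prefactor is the classical 0.084·332 dipole–dipole
coupling), accepted when E < −0.5 kcal/mol. Same-residue and
adjacent-peptide-bond pairs are excluded per the DSSP convention. Distances
use the minimum-image convention in orthorhombic boxes. When explicit amide
hydrogens are absent they are reconstructed 1.01 Å from N opposite the
preceding residue's C=O (DSSP's own fallback); reconstruction can be
disabled, in which case missing hydrogens raise an error naming the
residues. Each accepted (donor, acceptor) pair is counted once.

Registry classification applies only to inter-monomer bonds: a donor at
residue i is in-register parallel when the acceptor is residue i − 1 in
another monomer, antiparallel when it is residue L + 1 − i. For hexapeptides
(L = 6) both rules map donor 4 to acceptor 3; that pairing is ambiguous and
excluded, leaving 4 admissible parallel and 5 antiparallel bonds per
interface. The 4:5 imbalance motivates the 0.8 weight in the parallel sheet
fraction f_p = n_p/(n_p + 0.8·n_ap + 1); the +1 keeps the ratio defined for
bond-free frames (f_p ∈ [0, 1), equal to 0 at (0,0)). Same-index
cross-monomer pairings (possible for odd L) are not admissible under either
rule and are tagged "other". f_p is evaluated every 10 ns by default; all
other trajectory metrics every frame (1 ns in the production setting).

RMSD: trajectories are unwrapped (consecutive-frame displacements folded
into the minimum image, so no atom jumps more than half a box edge), each
frame is rigid-body aligned on the t = 0 reference by unweighted Kabsch
superposition of the backbone atoms, and RMSD is computed over backbone
atoms, with an optional exclusion set for atoms that corrupt the alignment
(e.g. a peptide that detached and re-entered across the boundary).

Insertion depth is the z-distance between the mass-weighted protein centre
of mass and the (unweighted, single-element) phosphorus centre of mass.
Pore persistence is the count of water oxygens within 0.5 nm (closed
interval — "within" read inclusively; the boundary has measure zero but is
fixed for determinism) of the phosphorus CoM in z.

## Image quantification

Maximum z-projections are elementwise maxima. Puncta counting binarizes the
projection at one shared threshold per experiment, labels 8-connected
components (matching the originating tooling's default), retains components
strictly larger than 15 px, and assigns each retained punctum to the cell
mask containing its centroid (components straddling masks follow their
centroid; centroids outside all masks go to an explicit "unassigned"
bucket). Manders coefficients are classic (threshold 0) by default with
optional explicit thresholds; auto-threshold variants of the original
plugin are not reproduced, and both thresholded and classic readings are
available.

## Synthetic data

The generators define the package's test conditions and are deterministic
per seed.

* **Ellipsoid shells** — a voxel is foreground iff its centre's
  gradient-normalized ellipsoidal radius (a first-order Euclidean distance
  to the surface) is within half the shell thickness (default 4 px, a
  realistic membrane-mask thickness at ≈1 nm voxels). Truth records carry
  the analytic per-slice ellipse (a(z), b(z), centre, orientation, area)
  before jitter, dropout or angular clipping are applied. Clipping removes
  an azimuthal wedge from every slice to force open arcs, emulating
  field-of-view truncation. Not emulated: tomographic missing-wedge
  anisotropy, CTF, segmentation false merges — so passing phantom tests
  validates the geometry pipeline, not robustness to those artefacts.
* **β-sheets** — idealized backbone geometry (3.4 Å rise, 4.8 Å strand
  spacing, ±1.7 Å in-register stagger, N–H and C=O groups pointing at the
  partner strand). The construction makes the intended pairs — and only
  those — pass the DSSP criterion (intended-pair energies ≈ −1.5 kcal/mol,
  nearest unintended ≈ −0.17). The geometric bond set of an in-register
  parallel interface necessarily includes the ambiguous (4 → 3) bond; it is
  present in the truth pair list and excluded by classification, exactly as
  in the counting rules (hence n_p = 4, f_p = 0.8 for a static 2-monomer
  parallel sheet). No force-field realism is claimed.
* **Membrane slabs** — phosphorus z-values in mirror pairs about the slab
  centre (CoM exact), waters placed strictly inside/outside the 0.5 nm
  window.
* **Blob images** — connected components grown to exact pixel areas with a
  2 px moat so 8-connected labeling cannot merge them.
* **Group samples / leakage traces** — known family, location shift and
  analytic effect size; leakage traces saturate below a known bound.

## Problem sizes

Default test and validation scales, chosen to probe each property at
adequate power while keeping the suite quick to run: 50 random arcs for
ellipse recovery; 100 phantoms × 500 bootstrap iterations for CI coverage;
one 115×115×95 px noise-free ellipsoid (semi-axes 55/50/45 px) for the
end-to-end oracle; exhaustive BH enumeration for all p-multisets of length
≤ 6 on a 0.05 grid; 100 seeded replicates for test routing.

## Known limitations

* Anisotropic in-plane pixels are not supported (assumed isotropic; recorded
  in the manifest).
* The z-coverage denominator is the inclusive span of slices containing any
  object voxel; for thick shells the polar cap slices (which cannot yield a
  ≥50 px arc) therefore depress coverage slightly — visible in phantom runs
  as coverage ≈0.9 rather than 1.0 for full ellipsoids.
* The per-object bootstrap CI is computed for one representative retained
  slice, not per slice (the per-slice loop is available in the library).
* Only orthorhombic boxes are handled in the trajectory metrics.
* 3D surface curvature (curvedness), membrane thickness line scans and
  inter-organelle distances are out of scope (external surface-morphometrics
  tooling); this package's curvature is the 2D slice-contour κ.
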