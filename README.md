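# lysomorph

Quantitative analysis of lysosomal membrane damage by intralysosomal
amyloid: slice-wise morphometrics of segmented lysosome membranes from
cryo-ET, β-sheet registry statistics for peptide-fibril MD trajectories, and
the accompanying fluorescence quantifications (puncta, colocalization,
liposome leakage). It is aimed at groups analysing membrane segmentations
and short-peptide aggregation simulations who need the full measurement
chain — geometry, uncertainty, and gated statistics — reproducible from a
single seed.

## What it computes

**Membrane morphometrics.** Labeled MRC segmentation volumes are processed
slice by slice along z: each cross-section mask is thinned to a one-pixel
centerline, ordered into an open arc, and fitted with a smoothing cubic
B-spline sampled at 200 parameter values. Per slice the pipeline reports the
perimeter (spline arc length), bounding box, centroid, and the analytic
signed curvature

κ = (x′y″ − y′x″) / (x′² + y′²)^{3/2},

then fits a 2D ellipse in two stages — Fitzgibbon direct least squares
followed by orthogonal-distance (true perpendicular residual)
Levenberg–Marquardt refinement — with R², RMSE, and 95% bootstrap
confidence intervals for the semi-axes (500 resamples, fixed seed). Arcs
below 50 px are excluded. Objects aggregate to mean ellipse area, mean
perimeter, equivalent diameter 2√(area/π), and a confidence tier (High:
R² > 0.5 and z-coverage > 70%; Medium: R² > 0.3 and coverage > 50%; Low
otherwise). Group comparisons are Shapiro–Wilk-gated (Welch t vs
Mann–Whitney U, α = 0.05) with Cohen's d and Benjamini–Hochberg FDR
correction.

**Trajectory statistics.** Backbone hydrogen bonds by the DSSP
(Kabsch–Sander) energy criterion (E < −0.5 kcal/mol, minimum-image), and
their in-register registry classes for hexapeptide monomers: donor residue
i to acceptor i−1 in another monomer is parallel, to L+1−i antiparallel;
the ambiguous (4 → 3) pairing is excluded, leaving 4 parallel and 5
antiparallel admissible bonds per interface. The weighted parallel sheet
fraction is

f_p = n_p / (n_p + 0.8·n_ap + 1),

sampled every 10 ns by default. Also: PBC-unwrapped, Kabsch-aligned
backbone RMSD versus t = 0; fibril insertion depth (protein CoM z minus
phosphorus CoM z); and the pore-water count (water oxygens within 0.5 nm in
z of the phosphorus CoM).

**Image quantification.** Maximum z-projections; puncta counts per manually
drawn cell mask with one shared threshold and a strict >15 px particle
filter; Manders colocalization coefficients M1/M2; and the liposome leakage
percentage (F_sample − F_control)/(F_Triton − F_control) × 100.

A `synthetic` module generates ground-truthed inputs for every stage
(voxelized ellipsoid shells with analytic slice ellipses, ideal β-sheet
backbones, membrane slabs, blob images, leakage traces), so the whole
package builds and tests without any external data.

## Worked example

```python
from lysomorph import synthetic, pipeline

spec = synthetic.PhantomSpec(semi_axes=(40, 35, 30), shell_thickness=4,
                             clip_fraction=0.2, jitter_sigma=0.3, seed=7)
vol, truth = synthetic.make_ellipsoid_shell_volume(spec)
res = pipeline.run_morphometrics(vol, pipeline.RunConfig())
print(res["per_object"].round(3).to_string(index=False))
```

prints (abridged):

```
object_label  n_valid_slices  z_extent  z_coverage  mean_r2  mean_ellipse_area_nm2  equivalent_diameter_nm confidence  a_ci_lo  a_ci_hi
           1              59        65       0.908    0.999               2962.095                  61.412       High   34.540   34.701
```

The phantom is an ellipsoidal membrane shell (semi-axes 40/35/30 px, 1 nm
voxels) with 20% of each contour clipped away and 0.3 px boundary jitter.
59 of the 65 occupied z-slices yield valid arcs (z-coverage 0.91 — the polar
caps cannot form a ≥50 px arc), the mean fitted ellipse area of 2962 nm² sits
within 1% of the analytic cross-section mean of 2981 nm², and the bootstrap
CI brackets the median slice's semi-major axis. The tier is High since
R² > 0.5 and coverage > 70%.

For a trajectory frame holding one parallel and one antiparallel sheet
interface:

```python
from lysomorph import synthetic, trajectory
frame, _ = synthetic.make_ideal_beta_sheet("mixed", 3)
s = trajectory.compute_sheet_order_series([frame])
print(s.n_p[0], s.n_ap[0], round(s.f_p[0], 4))   # 4 5 0.4444
```

— the four admissible parallel bonds, five antiparallel, and
f_p = 4/(4 + 0.8·5 + 1).

A `lysomorph` CLI exposes each stage (`simulate-phantom`, `morphometrics`,
`compare`, `sheet-order`, `rmsd`, `insertion`, `pore-water`, `puncta`,
`manders`, `leakage`); all outputs are TSV/JSON with a run manifest
recording every parameter and per-object disposition.

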