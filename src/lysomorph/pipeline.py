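"""End-to-end orchestration: volume -> contours -> ellipses -> statistics.

``run_morphometrics`` processes every labeled object of a segmentation
volume slice by slice (skeletonize, order, spline, length filter, two-stage
ellipse fit, bootstrap) and aggregates per-object summaries;
``run_comparison`` runs the normality-gated group comparisons over summary
tables. Failures are isolated per object — one bad object never aborts a
run — and every disposition is recorded in the run manifest.

All stage parameters live in :class:`RunConfig` with the defaults of the
analysis this package implements (min arc 50 px, 200 spline samples, 500
bootstrap iterations, seed 42, alpha 0.05). Per-object bootstrap seeds are
derived deterministically from the master seed and the object label, so
objects may be processed in any order (or concurrently) with byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contours, ellipses, stats, volume_io


@dataclass
class RunConfig:
    """All stage parameters of a morphometrics/comparison run."""

    min_arc_px: float = contours.MIN_ARC_PX
    n_samples: int = contours.N_SPLINE_SAMPLES
    n_boot: int = ellipses.DEFAULT_N_BOOT
    seed: int = ellipses.DEFAULT_SEED
    alpha: float = stats.ALPHA_NORMALITY
    min_size_px: int = 15
    slab_half_width_nm: float = 0.5
    fp_stride_ns: float = 10.0
    strict_thresholds: bool = True
    exclude_low_confidence: bool = False
    bootstrap: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def object_seed(master_seed: int, label: int) -> int:
    """Deterministic per-object bootstrap seed below 2^31."""
    return int(np.random.SeedSequence([master_seed, label]).generate_state(1)[0]
               % (2**31 - 1))


def process_slice(
    mask: np.ndarray, z_index: int, config: RunConfig
) -> tuple[dict, ellipses.EllipseFit | None, np.ndarray | None]:
    """One slice through the full contour + ellipse stage.

    Returns a per-slice record (always), the ellipse fit and the spline
    samples (both None when the slice is rejected).
    """
    rec = {
        "z_index": z_index,
        "n_points": 0,
        "arc_length_px": np.nan,
        "perimeter_px": np.nan,
        "bbox_w": np.nan,
        "bbox_h": np.nan,
        "aspect_ratio": np.nan,
        "centroid_x": np.nan,
        "centroid_y": np.nan,
        "abs_mean_kappa": np.nan,
        "abs_max_kappa": np.nan,
        "was_closed": False,
        "ellipse_a_px": np.nan,
        "ellipse_b_px": np.nan,
        "ellipse_area_px2": np.nan,
        "r_squared": np.nan,
        "rmse_px": np.nan,
        "retained": False,
        "rejection_reason": "",
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            skel = contours.skeletonize_slice(mask)
            contour = contours.order_skeleton_points(skel, mask.shape, z_index)
            rec["n_points"] = len(contour)
            rec["was_closed"] = contour.was_closed
            spline = contours.fit_spline(contour, config.n_samples)
    except contours.ContourRejected as exc:
        rec["rejection_reason"] = exc.reason
        return rec, None, None
    metrics = contours.slice_shape_metrics(spline)
    kappa = contours.signed_curvature(spline)
    rec.update(
        arc_length_px=spline.arc_length_px,
        perimeter_px=metrics["perimeter_px"],
        bbox_w=metrics["bbox_w"],
        bbox_h=metrics["bbox_h"],
        aspect_ratio=metrics["aspect_ratio"],
        centroid_x=metrics["centroid"][0],
        centroid_y=metrics["centroid"][1],
        abs_mean_kappa=kappa.abs_mean,
        abs_max_kappa=kappa.abs_max,
    )
    if not contours.passes_length_filter(
        spline, config.min_arc_px, config.strict_thresholds
    ):
        rec["rejection_reason"] = "arc_too_short"
        return rec, None, None
    try:
        fit = ellipses.fit_ellipse(spline.samples)
    except ellipses.EllipseFitError as exc:
        rec["rejection_reason"] = f"ellipse_fit_failed: {exc}"
        return rec, None, None
    rec.update(
        ellipse_a_px=fit.params.a,
        ellipse_b_px=fit.params.b,
        ellipse_area_px2=fit.params.area,
        r_squared=fit.r_squared,
        rmse_px=fit.rmse,
        retained=True,
    )
    return rec, fit, spline.samples


def run_morphometrics(
    vol: volume_io.LabeledVolume, config: RunConfig | None = None
) -> dict:
    """Full morphometrics run over every labeled object of a volume.

    Returns a dict with ``per_slice`` and ``per_object`` DataFrames and a
    ``manifest`` recording parameters and per-object dispositions.
    """
    config = config or RunConfig()
    slice_rows: list[dict] = []
    object_rows: list[dict] = []
    dispositions: dict[int, str] = {}
    for label in sorted(vol.labels):
        stack = volume_io.extract_object_slices(vol, label)
        fits: list[tuple[ellipses.EllipseFit, float]] = []
        fit_samples: list[np.ndarray] = []
        for z, mask in stack.slices:
            rec, fit, samples = process_slice(mask, z, config)
            rec["object_label"] = label
            slice_rows.append(rec)
            if fit is not None:
                fits.append((fit, rec["arc_length_px"]))
                fit_samples.append(samples)
        if not fits:
            dispositions[label] = "dropped: no valid slices"
            continue
        summary = ellipses.summarize_object(
            fits, label, stack.z_extent, vol.in_plane_voxel_nm
        )
        row = dataclasses.asdict(summary)
        if config.bootstrap and fit_samples:
            # CI for the median-semi-axis slice, seeded per object
            mid = int(np.argsort([f.params.a for f, _ in fits])[len(fits) // 2])
            pts = fit_samples[mid]
            seed = object_seed(config.seed, label)
            try:
                ci = ellipses.bootstrap_ellipse_ci(pts, config.n_boot, seed)
                row.update(
                    a_ci_lo=ci.lo_a, a_ci_hi=ci.hi_a,
                    b_ci_lo=ci.lo_b, b_ci_hi=ci.hi_b,
                    ci_seed=seed, n_boot=ci.n_boot,
                )
            except ellipses.EllipseFitError:
                row.update(a_ci_lo=np.nan, a_ci_hi=np.nan,
                           b_ci_lo=np.nan, b_ci_hi=np.nan,
                           ci_seed=seed, n_boot=config.n_boot)
        object_rows.append(row)
        dispositions[label] = f"retained: {summary.confidence}"
    per_slice = pd.DataFrame(slice_rows)
    per_object = pd.DataFrame(object_rows)
    manifest = {
        "parameters": config.to_dict(),
        "n_objects": len(vol.labels),
        "dispositions": {str(k): v for k, v in dispositions.items()},
        "in_plane_isotropy_assumed": True,
    }
    return {"per_slice": per_slice, "per_object": per_object, "manifest": manifest}


DEFAULT_METRICS = (
    "mean_ellipse_area_nm2",
    "mean_perimeter_nm",
    "equivalent_diameter_nm",
)


def run_comparison(
    per_object: pd.DataFrame,
    condition_col: str = "condition",
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Pairwise gated comparisons of object metrics between conditions.

    For every pair of conditions, each metric is compared with the
    Shapiro-Wilk-gated two-sample scheme; the metric family within one
    condition pair is BH-adjusted together. Objects with Low confidence are
    excluded when ``config.exclude_low_confidence`` is set. Metrics with
    fewer than 3 objects per group are skipped with a reason row.
    """
    config = config or RunConfig()
    df = per_object
    if config.exclude_low_confidence and "confidence" in df.columns:
        df = df[df["confidence"] != "Low"]
    conditions = sorted(df[condition_col].unique())
    rows = []
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1:]:
            family: list[stats.GroupComparison] = []
            skipped = []
            for metric in metrics:
                x = df.loc[df[condition_col] == c1, metric].dropna().to_numpy()
                y = df.loc[df[condition_col] == c2, metric].dropna().to_numpy()
                try:
                    family.append(
                        stats.compare_groups(x, y, config.alpha, metric_name=metric)
                    )
                except ValueError as exc:
                    skipped.append((metric, str(exc)))
            stats.adjust_comparisons(family)
            for c in family:
                rows.append({
                    "condition_1": c1, "condition_2": c2,
                    "metric": c.metric_name, "n1": c.n1, "n2": c.n2,
                    "normal1": c.normal1, "normal2": c.normal2,
                    "test_used": c.test_used, "statistic": c.statistic,
                    "p_value": c.p_value, "p_adjusted": c.p_adjusted,
                    "cohens_d": c.cohens_d, "skipped_reason": "",
                })
            for metric, reason in skipped:
                rows.append({
                    "condition_1": c1, "condition_2": c2, "metric": metric,
                    "n1": np.nan, "n2": np.nan, "normal1": None, "normal2": None,
                    "test_used": "", "statistic": np.nan, "p_value": np.nan,
                    "p_adjusted": np.nan, "cohens_d": np.nan,
                    "skipped_reason": reason,
                })
    return pd.DataFrame(rows)


def write_tables(result: dict, out_dir: str) -> None:
    """Write per-slice/per-object TSVs and the manifest JSON."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    result["per_slice"].to_csv(
        os.path.join(out_dir, "per_slice.tsv"), sep="\t", index=False
    )
    result["per_object"].to_csv(
        os.path.join(out_dir, "per_object.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result["manifest"], fh, indent=1)
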