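"""Fluorescence image quantification: puncta counts and Manders colocalization.

Puncta counting mirrors the batch thresholding workflow: maximum z-projection,
one shared intensity threshold per experiment, 8-connected components, and a
strict size filter — only particles larger than 15 pixels count as puncta.
Each punctum is assigned to the cell mask containing its centroid.

Manders coefficients are computed on maximum-intensity projections:
``M1 = sum(a_i over pixels with b_i > thr_b) / sum(a_i)`` restricted to
``a_i > thr_a`` (and M2 with roles swapped). Thresholds default to 0
(classic Manders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

#: strict particle-size filter: retained particles have area > this (px)
MIN_PUNCTA_SIZE_PX = 15


@dataclass
class PunctaResult:
    cell_id: int
    n_puncta: int
    particle_sizes: list[int]


def max_z_projection(stack: np.ndarray) -> np.ndarray:
    """Elementwise maximum across the z-axis of a (z, y, x) stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need a non-empty (z, y, x) stack")
    return stack.max(axis=0)


def count_puncta(
    image: np.ndarray,
    cell_masks: np.ndarray,
    threshold: float,
    min_size_px: int = MIN_PUNCTA_SIZE_PX,
    strict: bool = True,
) -> list[PunctaResult]:
    """Size-filtered puncta counts per labeled cell mask.

    The image is binarized at ``threshold`` (the same value is meant to be
    shared across a batch), connected components are extracted with
    8-connectivity, components with area larger than ``min_size_px`` are
    retained (strictly larger by default), and each retained component is
    assigned to the cell mask containing its centroid. Components whose
    centroid falls outside every mask land in the cell_id 0 ("unassigned")
    bucket, reported only when non-empty.
    """
    image = np.asarray(image)
    cell_masks = np.asarray(cell_masks)
    if image.shape != cell_masks.shape:
        raise ValueError("image and cell_masks must have the same shape")
    binary = image > threshold
    comps = cc_label(binary, connectivity=2)
    counts: dict[int, list[int]] = {
        int(c): [] for c in np.unique(cell_masks) if c > 0
    }
    unassigned: list[int] = []
    for prop in regionprops(comps):
        area = int(prop.area)
        retained = area > min_size_px if strict else area >= min_size_px
        if not retained:
            continue
        cy, cx = prop.centroid
        cell = int(cell_masks[int(round(cy)), int(round(cx))])
        if cell > 0:
            counts[cell].append(area)
        else:
            unassigned.append(area)
    results = [
        PunctaResult(cell_id=cid, n_puncta=len(sizes), particle_sizes=sizes)
        for cid, sizes in sorted(counts.items())
    ]
    if unassigned:
        results.append(
            PunctaResult(cell_id=0, n_puncta=len(unassigned), particle_sizes=unassigned)
        )
    return results


def manders_coefficients(
    a: np.ndarray,
    b: np.ndarray,
    thr_a: float = 0.0,
    thr_b: float = 0.0,
) -> tuple[float, float]:
    """Manders colocalization coefficients (M1, M2) of two channels.

    M1 is the fraction of channel-a intensity (over pixels with a > thr_a)
    lying where channel b exceeds thr_b; M2 swaps the roles. A zero
    denominator yields NaN for that coefficient.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    sel_a = a > thr_a
    sel_b = b > thr_b
    denom1 = a[sel_a].sum()
    denom2 = b[sel_b].sum()
    m1 = float(a[sel_a & sel_b].sum() / denom1) if denom1 > 0 else float("nan")
    m2 = float(b[sel_a & sel_b].sum() / denom2) if denom2 > 0 else float("nan")
    return m1, m2


def thresholded_area_and_density(
    image: np.ndarray, threshold: float
) -> tuple[int, float]:
    """Convenience: area (px) and integrated density of above-threshold ROIs."""
    image = np.asarray(image, dtype=float)
    roi = image > threshold
    return int(roi.sum()), float(image[roi].sum())
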