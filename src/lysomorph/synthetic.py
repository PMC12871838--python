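"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is deterministic given its spec and seed, and returns a truth
record sufficient to compute the expected pipeline outputs without re-deriving
geometry:

* voxelized ellipsoidal membrane shells with analytic per-slice cross-section
  ellipses, optional boundary jitter, dropout and angular clipping (open arcs);
* idealized parallel/antiparallel/mixed beta-sheet backbones of hexapeptide
  monomers whose intended hydrogen bonds — and only those — satisfy the DSSP
  energy criterion;
* slab membranes with water oxygens placed inside/outside the pore window;
* blob images with exact particle areas and labeled cell masks;
* leakage traces with known bounds and two-group samples with known effect
  size and distribution family.

The beta-sheet builder uses idealized geometry (3.4 A rise per residue,
4.8 A inter-strand spacing, in-register stagger) rather than force-field
minimization; bond realism is limited to the electrostatic criterion firing
on the intended donor/acceptor pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .trajectory import (
    AMBIGUOUS,
    ANTIPARALLEL,
    PARALLEL,
    HBondRecord,
    MembraneFrame,
    PeptideFrame,
    classify_registry,
)
from .volume_io import LabeledVolume

# idealized beta-strand geometry, Angstrom
STRAND_RISE_A = 3.4
STRAND_SPACING_A = 4.8
NH_LENGTH_A = 1.0
CO_LENGTH_A = 1.23
C_OFFSET_A = 1.7


@dataclass
class PhantomSpec:
    """Ellipsoidal membrane-shell phantom parameters (pixels / nm)."""

    semi_axes: tuple[float, float, float] = (40.0, 30.0, 20.0)  # a >= b >= c, px
    center: tuple[float, float, float] | None = None  # (z, y, x), px
    orientation: float = 0.0  # in-plane rotation, radians
    shell_thickness: float = 4.0  # px
    voxel_size_nm: float = 1.0
    jitter_sigma: float = 0.0  # boundary jitter, px
    dropout_rate: float = 0.0  # salt-and-pepper rate on shell voxels
    clip_fraction: float = 0.0  # angular fraction of each slice removed
    label: int = 1
    seed: int = 0
    margin: int = 6  # empty border, px

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > self.shell_thickness / 2):
            raise ValueError("require a >= b >= c > shell_thickness/2")
        if not 0 <= self.clip_fraction < 1:
            raise ValueError("clip_fraction must lie in [0, 1)")
        if self.shell_thickness < 1:
            raise ValueError("shell thinner than 1 voxel")


def make_ellipsoid_shell_volume(spec: PhantomSpec) -> tuple[LabeledVolume, dict]:
    """Voxelized ellipsoidal membrane shell plus analytic slice truth.

    A voxel is foreground iff its center's Euclidean distance to the
    ellipsoid surface (gradient-normalized ellipsoidal radius) is within
    ``shell_thickness / 2``. Jitter, dropout and angular clipping are applied
    after the truth record is taken. Cross-sections at height dz from the
    center are ellipses with semi-axes ``a sqrt(1 - (dz/c)^2)`` (same for b),
    rotated by ``orientation``.
    """
    a, b, c = spec.semi_axes
    rng = np.random.default_rng(spec.seed)
    nz = int(np.ceil(2 * c)) + 2 * spec.margin + 1
    ny = int(np.ceil(2 * max(a, b))) + 2 * spec.margin + 1
    nx = ny
    cz, cy, cx = spec.center or ((nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    dz, dy, dx = zz - cz, yy - cy, xx - cx
    # rotate in-plane coordinates into the ellipsoid frame
    ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2)
    grad = (
        np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2 + (dz / c**2) ** 2)
        / np.where(rho == 0, 1.0, rho)
    )
    surf_dist = np.abs(rho - 1.0) / np.where(grad == 0, 1.0, grad)
    if spec.jitter_sigma > 0:
        surf_dist = surf_dist + rng.normal(0, spec.jitter_sigma, surf_dist.shape)
    shell = surf_dist <= spec.shell_thickness / 2
    shell &= rho > 0
    # truth before degradation
    slices = []
    for z in range(nz):
        frac = 1.0 - ((z - cz) / c) ** 2
        if frac <= 0:
            continue
        scale = np.sqrt(frac)
        slices.append(
            {
                "z": z,
                "a_px": a * scale,
                "b_px": b * scale,
                "theta": spec.orientation,
                "center_xy": (cx, cy),
                "area_px2": np.pi * a * b * frac,
            }
        )
    if spec.clip_fraction > 0:
        phi = np.arctan2(v, u)
        phi0 = rng.uniform(-np.pi, np.pi)
        width = 2 * np.pi * spec.clip_fraction
        dphi = (phi - phi0 + np.pi) % (2 * np.pi) - np.pi
        shell &= np.abs(dphi) > width / 2
    if spec.dropout_rate > 0:
        shell &= rng.random(shell.shape) > spec.dropout_rate
    vol = LabeledVolume(
        voxels=np.where(shell, spec.label, 0).astype(np.int32),
        voxel_size=np.full(3, spec.voxel_size_nm),
        metadata={"phantom_seed": spec.seed},
    )
    truth = {
        "label": spec.label,
        "semi_axes_px": (a, b, c),
        "center_zyx": (cz, cy, cx),
        "orientation": spec.orientation,
        "voxel_size_nm": spec.voxel_size_nm,
        "mean_cross_section_area_px2": float(
            np.mean([s["area_px2"] for s in slices])
        ),
        "slices": slices,
    }
    return vol, truth


def make_ideal_beta_sheet(
    arrangement: str = "parallel",
    n_monomers: int = 2,
    monomer_length: int = 6,
    box_nm: float = 10.0,
    time_ns: float = 0.0,
) -> tuple[PeptideFrame, dict]:
    """Idealized in-register beta-sheet backbone of short peptide monomers.

    Strands run along x at 4.8 A spacing in y; each strand donates its amide
    hydrogens to the carbonyls of the strand below, staggered so exactly the
    in-register pairings satisfy the DSSP criterion. ``arrangement`` is
    "parallel", "antiparallel", or "mixed" (alternating interface types,
    starting parallel). The truth record lists every geometric (donor,
    acceptor) pair and the registry-classified counts; note the ambiguous
    in-register pairing (residue 4 donor to residue 3 acceptor for
    hexapeptides) is geometrically present but excluded from the counts.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if arrangement not in ("parallel", "antiparallel", "mixed"):
        raise ValueError(f"unknown arrangement: {arrangement}")
    lng = monomer_length
    ori = [1] * n_monomers
    offs = [0.0] * n_monomers
    kinds = []
    for m in range(1, n_monomers):
        if arrangement == "parallel":
            kind = "p"
        elif arrangement == "antiparallel":
            kind = "ap"
        else:
            kind = "p" if m % 2 == 1 else "ap"
        kinds.append(kind)
        if kind == "p":
            ori[m] = ori[m - 1]
            offs[m] = offs[m - 1] - C_OFFSET_A * ori[m - 1]
        else:
            ori[m] = -ori[m - 1]
            offs[m] = offs[m - 1] + C_OFFSET_A * ori[m - 1]
    positions, roles, monomer_id, residue_index = [], [], [], []
    for m in range(n_monomers):
        y = STRAND_SPACING_A * m
        for k in range(1, lng + 1):
            x_n = offs[m] + STRAND_RISE_A * (k if ori[m] > 0 else lng + 1 - k)
            x_c = x_n + C_OFFSET_A * ori[m]
            for role, xyz in (
                ("N", (x_n, y, 0.0)),
                ("H", (x_n, y - NH_LENGTH_A, 0.0)),
                ("C", (x_c, y, 0.0)),
                ("O", (x_c, y + CO_LENGTH_A, 0.0)),
                ("CA", (x_n + 0.8 * ori[m], y, 0.5)),
            ):
                positions.append(xyz)
                roles.append(role)
                monomer_id.append(m)
                residue_index.append(k)
    pos = np.asarray(positions) / 10.0  # A -> nm
    pos += box_nm / 2 - pos.mean(axis=0)  # center in the box
    frame = PeptideFrame(
        positions=pos,
        roles=np.array(roles),
        monomer_id=np.array(monomer_id),
        residue_index=np.array(residue_index),
        monomer_length=lng,
        box=np.full(3, float(box_nm)),
        time_ns=time_ns,
    )
    pairs = []
    counts = {PARALLEL: 0, ANTIPARALLEL: 0, AMBIGUOUS: 0}
    for m in range(1, n_monomers):
        for i in range(1, lng + 1):
            j = i - 1 if kinds[m - 1] == "p" else lng + 1 - i
            if not 1 <= j <= lng:
                continue
            pairs.append(((m, i), (m - 1, j)))
            cls = classify_registry(
                HBondRecord(donor=(m, i), acceptor=(m - 1, j), energy=-1.0), lng
            )
            if cls in counts:
                counts[cls] += 1
    truth = {
        "arrangement": arrangement,
        "n_monomers": n_monomers,
        "monomer_length": lng,
        "pairs": pairs,
        "n_parallel": counts[PARALLEL],
        "n_antiparallel": counts[ANTIPARALLEL],
        "n_ambiguous": counts[AMBIGUOUS],
    }
    return frame, truth


def make_membrane_frame(
    n_phosphorus: int = 100,
    slab_z_nm: float = 5.0,
    n_waters_inside: int = 0,
    n_waters_outside: int = 0,
    box_nm: tuple[float, float, float] = (10.0, 10.0, 12.0),
    half_width_nm: float = 0.5,
    seed: int = 0,
) -> tuple[MembraneFrame, dict]:
    """Slab membrane with exactly-known pore-water occupancy.

    Phosphorus z-coordinates are placed in mirror pairs about ``slab_z_nm``
    (leaflet offset ~2 nm), so their CoM equals the slab center exactly.
    ``n_waters_inside`` oxygens fall strictly within ``half_width_nm`` of the
    slab center and the rest strictly outside.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box_nm, dtype=float)
    if n_phosphorus < 2:
        raise ValueError("need at least 2 phosphorus atoms")
    outer = slab_z_nm + half_width_nm + 0.2 + 1.5
    if outer >= box[2] or slab_z_nm - 2.2 <= 0:
        raise ValueError("box too small for the requested slab")
    half = n_phosphorus // 2
    offsets = rng.uniform(1.8, 2.2, half)
    p_z = np.concatenate([slab_z_nm + offsets, slab_z_nm - offsets])
    if n_phosphorus % 2:
        p_z = np.append(p_z, slab_z_nm)
    inside = slab_z_nm + rng.uniform(
        -half_width_nm * 0.98, half_width_nm * 0.98, n_waters_inside
    )
    out_off = rng.uniform(half_width_nm + 0.2, half_width_nm + 1.5, n_waters_outside)
    out_sign = rng.choice([-1.0, 1.0], n_waters_outside)
    outside = slab_z_nm + out_sign * out_off
    frame = MembraneFrame(
        phosphorus_z=p_z,
        water_oxygen_z=np.concatenate([inside, outside]),
        box=box,
    )
    truth = {
        "slab_z_nm": slab_z_nm,
        "n_waters_inside": n_waters_inside,
        "n_waters_outside": n_waters_outside,
        "half_width_nm": half_width_nm,
    }
    return frame, truth


def make_puncta_image(
    blob_areas,
    cell_masks: np.ndarray | None = None,
    shape: tuple[int, int] = (128, 128),
    intensity: float = 100.0,
    min_size_px: int = 15,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Blob image with exact particle areas plus labeled cell masks.

    ``blob_areas`` is either a flat list of pixel areas (all placed in cell 1)
    or a list of ``(cell_id, area)`` pairs. Blobs are grown as connected
    components of exactly the requested area and kept >= 2 px apart so
    8-connected labeling cannot merge them. The truth record counts, per
    cell, the blobs strictly larger than ``min_size_px``.
    """
    rng = np.random.default_rng(seed)
    if cell_masks is None:
        cell_masks = np.ones(shape, dtype=int)
    cell_masks = np.asarray(cell_masks)
    shape = cell_masks.shape
    blobs = [
        (1, int(a)) if np.isscalar(a) else (int(a[0]), int(a[1]))
        for a in blob_areas
    ]
    image = np.zeros(shape, dtype=float)
    forbidden = np.zeros(shape, dtype=bool)
    truth_counts: dict[int, int] = {
        int(c): 0 for c in np.unique(cell_masks) if c > 0
    }
    for cell, area in blobs:
        placed = False
        cell_pix = np.argwhere(cell_masks == cell)
        if len(cell_pix) == 0:
            raise ValueError(f"cell {cell} not present in masks")
        for _ in range(max_tries):
            sy, sx = cell_pix[rng.integers(len(cell_pix))]
            blob = _grow_blob((sy, sx), area, shape, forbidden, rng)
            if blob is None:
                continue
            ys, xs = zip(*blob)
            cy, cx = int(round(np.mean(ys))), int(round(np.mean(xs)))
            if cell_masks[cy, cx] != cell:
                continue
            image[ys, xs] = intensity
            for (y, x) in blob:  # blob plus a 2-px moat
                forbidden[
                    max(y - 2, 0) : y + 3, max(x - 2, 0) : x + 3
                ] = True
            if area > min_size_px:
                truth_counts[cell] += 1
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place blob of area {area}")
    truth = {"counts_per_cell": truth_counts, "min_size_px": min_size_px}
    return image, cell_masks, truth


def _grow_blob(start, area, shape, forbidden, rng):
    """Grow a connected pixel set of exactly ``area`` avoiding forbidden pixels."""
    if forbidden[start]:
        return None
    blob = [start]
    members = {start}
    frontier = [start]
    while len(blob) < area:
        if not frontier:
            return None
        y, x = frontier[rng.integers(len(frontier))]
        nbrs = [
            (y + dy, x + dx)
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= y + dy < shape[0]
            and 0 <= x + dx < shape[1]
            and (y + dy, x + dx) not in members
            and not forbidden[y + dy, x + dx]
        ]
        if not nbrs:
            frontier.remove((y, x))
            continue
        nxt = nbrs[rng.integers(len(nbrs))]
        blob.append(nxt)
        members.add(nxt)
        frontier.append(nxt)
    return blob


def make_group_samples(
    dist1: str = "normal",
    dist2: str = "normal",
    n: int = 30,
    effect_size: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two reproducible samples with known families and location shift.

    Distributions: "normal" (sd 1), "cauchy", "lognormal". For
    normal/normal the analytic Cohen's d equals ``effect_size``.
    """
    rng = np.random.default_rng(seed)

    def draw(name, loc):
        if name == "normal":
            return rng.normal(loc, 1.0, n)
        if name == "cauchy":
            return loc + rng.standard_cauchy(n)
        if name == "lognormal":
            return loc + rng.lognormal(0.0, 1.0, n)
        raise ValueError(f"unknown distribution: {name}")

    x = draw(dist1, effect_size)
    y = draw(dist2, 0.0)
    truth = {
        "dist1": dist1,
        "dist2": dist2,
        "analytic_d": effect_size if dist1 == dist2 == "normal" else None,
        "normal1": dist1 == "normal",
        "normal2": dist2 == "normal",
    }
    return x, y, truth


def make_leakage_trace(
    n_points: int = 60,
    leak_level: float = 0.75,
    f0: float = 100.0,
    fmax: float = 1000.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Plate-reader-like fluorescence traces with known leakage bounds.

    The sample trace rises exponentially toward ``leak_level`` of the
    detergent maximum; control and Triton traces are flat at ``f0`` and
    ``fmax``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float)
    frac = leak_level * (1 - np.exp(-t / max(n_points / 4, 1)))
    sample = f0 + frac * (fmax - f0) + rng.normal(0, noise, n_points)
    trace = {
        "time": t,
        "f_sample": sample,
        "f_control": np.full(n_points, f0),
        "f_triton": np.full(n_points, fmax),
    }
    truth = {"leak_level_percent": leak_level * 100.0}
    return trace, truth


# ---------------------------------------------------------------------------
# file writers (MRC/PDB/TIFF + JSON truth sidecars)
# ---------------------------------------------------------------------------

def write_phantom(vol: LabeledVolume, truth: dict, path_mrc: str) -> None:
    from .volume_io import write_labeled_volume

    write_labeled_volume(vol, path_mrc)
    with open(str(path_mrc) + ".truth.json", "w") as fh:
        json.dump(truth, fh, default=_jsonable, indent=1)


def write_sheet_pdb(frame: PeptideFrame, truth: dict, path_pdb: str) -> None:
    """Write a peptide frame as PDB (Angstrom) with a JSON truth sidecar."""
    import warnings

    import MDAnalysis as mda

    n = len(frame.positions)
    res_key = list(zip(frame.monomer_id, frame.residue_index))
    unique_res = sorted(set(res_key))
    res_of_atom = np.array([unique_res.index(k) for k in res_key])
    seg_of_res = np.array([k[0] for k in unique_res])
    u = mda.Universe.empty(
        n,
        n_residues=len(unique_res),
        n_segments=int(frame.monomer_id.max()) + 1,
        atom_resindex=res_of_atom,
        residue_segindex=seg_of_res,
        trajectory=True,
    )
    names = {"N": "N", "H": "H", "C": "C", "O": "O", "CA": "CA"}
    u.add_TopologyAttr("names", [names.get(str(r), "CB") for r in frame.roles])
    u.add_TopologyAttr("resids", [k[1] for k in unique_res])
    u.add_TopologyAttr("resnames", ["LEU"] * len(unique_res))
    u.add_TopologyAttr(
        "segids", [chr(ord("A") + s % 26) for s in range(int(frame.monomer_id.max()) + 1)]
    )
    u.atoms.positions = frame.positions * 10.0
    if frame.box is not None:
        u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path_pdb))
    with open(str(path_pdb) + ".truth.json", "w") as fh:
        json.dump(truth, fh, default=_jsonable, indent=1)


def write_puncta_tiff(image: np.ndarray, masks: np.ndarray, truth: dict, path_tiff: str) -> None:
    import tifffile

    tifffile.imwrite(str(path_tiff), image.astype(np.float32))
    tifffile.imwrite(str(path_tiff) + ".masks.tiff", masks.astype(np.int32))
    with open(str(path_tiff) + ".truth.json", "w") as fh:
        json.dump(truth, fh, default=_jsonable, indent=1)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
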