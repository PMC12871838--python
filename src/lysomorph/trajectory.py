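"""MD trajectory statistics for hexapeptide fibrils at membranes.

Implements the bespoke trajectory measures used to characterize (LL)3OMe
fibril formation and membrane insertion:

* backbone hydrogen bonds by the DSSP (Kabsch-Sander) electrostatic
  criterion, ``E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` kcal/mol with
  distances in Angstrom, accepted when ``E < -0.5``;
* in-register parallel/antiparallel registry classification of inter-monomer
  bonds: a donor N-H of residue i pairs with the acceptor C=O of residue
  ``i - 1`` (parallel) or ``L + 1 - i`` (antiparallel) in another monomer;
  the pairing where both rules coincide (residue 4 donor to residue 3
  acceptor for L = 6) is ambiguous and excluded, leaving 4 admissible
  parallel and 5 antiparallel bonds per interface for hexapeptides;
* the weighted parallel sheet fraction
  ``f_p = n_p / (n_p + 0.8 n_ap + 1)`` (the 0.8 corrects the 4:5 imbalance,
  the +1 avoids division by zero);
* periodic-boundary unwrapping, rigid-body alignment and backbone RMSD
  against the t = 0 configuration;
* fibril insertion depth (protein CoM z minus phosphorus CoM z) and the
  pore-water count (water oxygens within 0.5 nm in z of the phosphorus CoM).

All positions are in nm; boxes are orthorhombic. Default analysis strides
are 1 ns, except f_p which is evaluated every 10 ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Kabsch-Sander dipole coupling constant, kcal/mol * Angstrom
KS_PREFACTOR = 27.888
#: H-bond acceptance threshold, kcal/mol
KS_CUTOFF = -0.5
#: reconstructed amide N-H bond length, nm
NH_BOND_NM = 0.101
#: pore slab half-width, nm
PORE_HALF_WIDTH_NM = 0.5
#: default f_p sampling stride, ns
FP_STRIDE_NS = 10.0

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"
AMBIGUOUS = "excluded_ambiguous"
OTHER = "other"


@dataclass
class PeptideFrame:
    """Backbone atoms of peptide monomers in a periodic box.

    Per-atom arrays: ``positions`` (n, 3) in nm, ``roles`` in
    {"N", "H", "C", "O", "CA", "side"} (C/O are the carbonyl pair),
    ``monomer_id`` and 1-based ``residue_index`` within each monomer.
    """

    positions: np.ndarray
    roles: np.ndarray
    monomer_id: np.ndarray
    residue_index: np.ndarray
    monomer_length: int = 6
    box: np.ndarray | None = None
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles)
        self.monomer_id = np.asarray(self.monomer_id, dtype=int)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.residue_index.size and (
            self.residue_index.min() < 1
            or self.residue_index.max() > self.monomer_length
        ):
            raise ValueError("residue_index must lie in [1, monomer_length]")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


@dataclass
class HBondRecord:
    donor: tuple[int, int]      # (monomer_id, residue i) of the N-H
    acceptor: tuple[int, int]   # (monomer_id, residue j) of the C=O
    energy: float               # kcal/mol
    registry_class: str = OTHER


@dataclass
class SheetOrderSeries:
    """Time series of registry-classified H-bond counts and f_p."""

    time_ns: np.ndarray
    n_p: np.ndarray
    n_ap: np.ndarray
    f_p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.f_p = np.array(
            [parallel_fraction(p, ap) for p, ap in zip(self.n_p, self.n_ap)]
        )


@dataclass
class MembraneFrame:
    """Geometry needed for insertion-depth and pore-water metrics (nm)."""

    phosphorus_z: np.ndarray
    water_oxygen_z: np.ndarray
    protein_positions: np.ndarray | None = None
    protein_masses: np.ndarray | None = None
    box: np.ndarray | None = None
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.phosphorus_z = np.asarray(self.phosphorus_z, dtype=float)
        self.water_oxygen_z = np.asarray(self.water_oxygen_z, dtype=float)
        if self.phosphorus_z.size == 0:
            raise ValueError("membrane metrics need a non-empty phosphorus set")


# ---------------------------------------------------------------------------
# hydrogen bonds and registry
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def _residue_table(frame: PeptideFrame) -> dict:
    table: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for k, role in enumerate(frame.roles):
        if role in ("N", "H", "C", "O"):
            key = (int(frame.monomer_id[k]), int(frame.residue_index[k]))
            table.setdefault(key, {})[str(role)] = frame.positions[k]
    return table


def _reconstruct_h(table: dict, key: tuple[int, int]) -> np.ndarray | None:
    """DSSP fallback amide hydrogen: 1.01 A from N opposite the preceding C=O."""
    mono, res = key
    prev = table.get((mono, res - 1))
    if prev is None or "C" not in prev or "O" not in prev:
        return None
    n = table[key]["N"]
    direction = prev["C"] - prev["O"]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return None
    return n + direction / norm * NH_BOND_NM


def kabsch_sander_energy(
    n: np.ndarray,
    h: np.ndarray,
    c: np.ndarray,
    o: np.ndarray,
    box: np.ndarray | None = None,
) -> float:
    """Electrostatic H-bond energy of an (N-H, C=O) pair, kcal/mol.

    Distances are evaluated under the minimum-image convention when a box is
    given; positions in nm are converted to Angstrom inside the formula.
    """
    def dist(p, q):
        return float(np.linalg.norm(_min_image(p - q, box))) * 10.0

    return KS_PREFACTOR * (
        1.0 / dist(o, n) + 1.0 / dist(c, h) - 1.0 / dist(o, h) - 1.0 / dist(c, n)
    )


def detect_backbone_hbonds(
    frame: PeptideFrame, reconstruct_h: bool = True
) -> list[HBondRecord]:
    """All backbone H-bonds satisfying the DSSP criterion (E < -0.5 kcal/mol).

    Every donor (N-H of one residue) is tested against every acceptor (C=O of
    another), excluding the self-residue pair and the adjacent peptide-bond
    pair (acceptor = donor's preceding residue in the same monomer), per the
    DSSP convention. Records are classified by the in-register registry rules.
    """
    table = _residue_table(frame)
    donors = []
    missing = []
    for key, atoms in table.items():
        if "N" not in atoms:
            continue
        h = atoms.get("H")
        if h is None:
            if reconstruct_h:
                h = _reconstruct_h(table, key)
            if h is None:
                missing.append(key)
                continue
        donors.append((key, atoms["N"], h))
    if missing and not reconstruct_h:
        raise ValueError(f"missing amide hydrogens for residues: {sorted(missing)}")
    acceptors = [
        (key, atoms["C"], atoms["O"])
        for key, atoms in table.items()
        if "C" in atoms and "O" in atoms
    ]
    bonds: list[HBondRecord] = []
    for (dk, n, h) in donors:
        for (ak, c, o) in acceptors:
            if dk[0] == ak[0] and ak[1] in (dk[1], dk[1] - 1):
                continue  # self residue / adjacent peptide bond
            e = kabsch_sander_energy(n, h, c, o, frame.box)
            if e < KS_CUTOFF:
                rec = HBondRecord(donor=dk, acceptor=ak, energy=e)
                rec.registry_class = classify_registry(rec, frame.monomer_length)
                bonds.append(rec)
    return bonds


def classify_registry(bond: HBondRecord, monomer_length: int = 6) -> str:
    """In-register registry class of one inter-monomer H-bond.

    Parallel: acceptor residue ``j = i - 1``; antiparallel:
    ``j = L + 1 - i``. A pairing matched by both rules is ambiguous and
    excluded from the counts; same-residue-index cross-monomer pairings and
    intra-monomer bonds are tagged "other".
    """
    if bond.donor[0] == bond.acceptor[0]:
        return OTHER
    i, j = bond.donor[1], bond.acceptor[1]
    lng = monomer_length
    is_par = j == i - 1
    is_anti = j == lng + 1 - i and j != i
    if is_par and is_anti:
        return AMBIGUOUS
    if is_par:
        return PARALLEL
    if is_anti:
        return ANTIPARALLEL
    return OTHER


def count_admissible_pairings(monomer_length: int = 6) -> tuple[int, int]:
    """Admissible (parallel, antiparallel) in-register pairings per interface.

    Enumerates donor residues i = 1..L under each registry rule, discarding
    acceptors outside [1, L], self-index pairings, and the ambiguous pairing
    matched by both rules. For hexapeptides this yields (4, 5).
    """
    lng = int(monomer_length)
    if lng < 1:
        raise ValueError("monomer_length must be >= 1")
    n_p = n_ap = 0
    for i in range(1, lng + 1):
        for j, cls in (
            (i - 1, PARALLEL),
            (lng + 1 - i, ANTIPARALLEL),
        ):
            if not 1 <= j <= lng:
                continue
            got = classify_registry(
                HBondRecord(donor=(0, i), acceptor=(1, j), energy=-1.0), lng
            )
            if got == PARALLEL and cls == PARALLEL:
                n_p += 1
            elif got == ANTIPARALLEL and cls == ANTIPARALLEL:
                n_ap += 1
    return n_p, n_ap


def parallel_fraction(n_p: int, n_ap: int) -> float:
    """Weighted parallel sheet fraction ``n_p / (n_p + 0.8 n_ap + 1)``."""
    if n_p < 0 or n_ap < 0:
        raise ValueError("bond counts must be non-negative")
    return n_p / (n_p + 0.8 * n_ap + 1.0)


def compute_sheet_order_series(
    frames: list[PeptideFrame], stride_ns: float = FP_STRIDE_NS
) -> SheetOrderSeries:
    """Registry-classified H-bond counts and f_p at a fixed time stride.

    Frames are sampled at ``stride_ns`` intervals from the first frame's
    time; a stride longer than the trajectory yields a single-frame series.
    """
    if not frames:
        raise ValueError("empty trajectory")
    frames = sorted(frames, key=lambda f: f.time_ns)
    times, n_p, n_ap = [], [], []
    next_t = frames[0].time_ns
    for f in frames:
        if f.time_ns + 1e-9 < next_t:
            continue
        bonds = detect_backbone_hbonds(f)
        classes = [b.registry_class for b in bonds]
        times.append(f.time_ns)
        n_p.append(classes.count(PARALLEL))
        n_ap.append(classes.count(ANTIPARALLEL))
        next_t = f.time_ns + stride_ns
    return SheetOrderSeries(
        time_ns=np.array(times), n_p=np.array(n_p), n_ap=np.array(n_ap)
    )


# ---------------------------------------------------------------------------
# RMSD, insertion depth, pore waters
# ---------------------------------------------------------------------------

def unwrap_trajectory(positions: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Remove periodic-boundary jumps from a (T, n, 3) coordinate series.

    After unwrapping, no atom moves more than half a box edge between
    consecutive frames.
    """
    positions = np.asarray(positions, dtype=float)
    boxes = np.broadcast_to(np.asarray(boxes, dtype=float), positions.shape[:1] + (3,))
    out = positions.copy()
    for t in range(1, len(out)):
        step = positions[t] - out[t - 1]
        step -= boxes[t] * np.round(step / boxes[t])
        out[t] = out[t - 1] + step
    return out


def kabsch_align(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition of ``mobile`` onto ``ref``."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return (mobile - mc) @ rot + rc


def unwrap_and_align(
    positions: np.ndarray,
    boxes: np.ndarray | None = None,
    align_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Unwrap a (T, n, 3) trajectory and align each frame on frame 0.

    ``align_indices`` selects the atoms used for the superposition (backbone
    atoms, typically); the fitted transform is applied to all atoms.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3:
        raise ValueError("positions must have shape (T, n, 3)")
    if boxes is not None:
        positions = unwrap_trajectory(positions, boxes)
    idx = np.arange(positions.shape[1]) if align_indices is None else np.asarray(
        align_indices
    )
    ref = positions[0]
    out = positions.copy()
    for t in range(1, len(positions)):
        sub = positions[t][idx]
        mc = sub.mean(axis=0)
        rc = ref[idx].mean(axis=0)
        h = (sub - mc).T @ (ref[idx] - rc)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out[t] = (positions[t] - mc) @ rot + rc
    return out


def backbone_rmsd(
    positions: np.ndarray,
    ref: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) of an aligned (T, n, 3) trajectory vs frame 0.

    ``exclude`` removes an atom subset from the average (e.g. a peptide that
    detached and rejoined across the periodic boundary).
    """
    positions = np.asarray(positions, dtype=float)
    if ref is None:
        ref = positions[0]
    keep = np.ones(positions.shape[1], dtype=bool)
    if exclude is not None:
        keep[np.asarray(exclude)] = False
    if not keep.any():
        raise ValueError("empty atom selection for RMSD")
    diff = positions[:, keep, :] - ref[keep]
    return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))


def insertion_depth(frame: MembraneFrame) -> float:
    """Signed z-distance (nm) of the protein CoM from the phosphorus CoM.

    The protein CoM is mass-weighted; the phosphorus CoM is unweighted
    (single element). Positive values place the protein above the membrane
    mid-plane defined by the phosphorus atoms.
    """
    if frame.protein_positions is None or len(frame.protein_positions) == 0:
        raise ValueError("insertion depth needs a non-empty protein set")
    pos = np.asarray(frame.protein_positions, dtype=float)
    masses = (
        np.ones(len(pos))
        if frame.protein_masses is None
        else np.asarray(frame.protein_masses, dtype=float)
    )
    z_protein = float(np.average(pos[:, 2], weights=masses))
    return z_protein - float(frame.phosphorus_z.mean())


def pore_water_count(
    frame: MembraneFrame, half_width_nm: float = PORE_HALF_WIDTH_NM
) -> int:
    """Water oxygens within ``half_width_nm`` (closed interval) in z of the
    phosphorus CoM — the persistent-pore proxy."""
    z_mem = float(frame.phosphorus_z.mean())
    return int(np.sum(np.abs(frame.water_oxygen_z - z_mem) <= half_width_nm))


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

DEFAULT_ROLE_MAP = {
    "N": "N",
    "H": "H",
    "HN": "H",
    "C": "C",
    "O": "O",
    "CA": "CA",
}


def load_peptide_frames(
    structure_path: str,
    trajectory_path: str | None = None,
    role_map: dict | None = None,
    monomer_length: int = 6,
) -> list[PeptideFrame]:
    """Read PDB (+ optional XTC/DCD-class trajectory) into PeptideFrames.

    Atom roles come from ``role_map`` (atom name -> role, defaulting to the
    standard backbone names); monomers are segments/chains; residue indices
    are renumbered 1..L within each monomer. MDAnalysis positions (Angstrom)
    are converted to nm.
    """
    import MDAnalysis as mda

    role_map = role_map or DEFAULT_ROLE_MAP
    u = (
        mda.Universe(structure_path, trajectory_path)
        if trajectory_path
        else mda.Universe(structure_path)
    )
    roles = np.array([role_map.get(nm, "side") for nm in u.atoms.names])
    monomer_id = u.atoms.segindices.astype(int)
    residue_index = np.empty(len(u.atoms), dtype=int)
    for seg in np.unique(monomer_id):
        sel = monomer_id == seg
        resids = u.atoms.resids[sel]
        residue_index[sel] = resids - resids.min() + 1
    frames = []
    for ts in u.trajectory:
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = ts.dimensions[:3] / 10.0
        frames.append(
            PeptideFrame(
                positions=ts.positions / 10.0,
                roles=roles,
                monomer_id=monomer_id,
                residue_index=residue_index,
                monomer_length=monomer_length,
                box=box,
                time_ns=float(ts.time) / 1000.0,  # ps -> ns
            )
        )
    return frames


def load_frames_csv(path: str, monomer_length: int = 6) -> list[PeptideFrame]:
    """Read plain per-frame coordinate tables (test/interchange format).

    Columns: time_ns, monomer, residue, role, x, y, z [, box_x, box_y, box_z],
    positions in nm.
    """
    import pandas as pd

    df = pd.read_csv(path)
    frames = []
    for t, g in df.groupby("time_ns", sort=True):
        box = None
        if {"box_x", "box_y", "box_z"}.issubset(g.columns):
            box = g[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(float)
        frames.append(
            PeptideFrame(
                positions=g[["x", "y", "z"]].to_numpy(float),
                roles=g["role"].to_numpy(),
                monomer_id=g["monomer"].to_numpy(int),
                residue_index=g["residue"].to_numpy(int),
                monomer_length=monomer_length,
                box=box,
                time_ns=float(t),
            )
        )
    return frames
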