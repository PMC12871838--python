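import numpy as np
import pytest

from lysomorph import synthetic, trajectory as tj


def ideal_pair(r_on_a=2.9):
    """A near-linear N-H...O=C geometry with a given O..N distance (Angstrom),
    returned in nm."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([0.0, -1.0, 0.0])
    o = np.array([0.0, -r_on_a, 0.0])
    c = np.array([0.0, -r_on_a - 1.23, 0.0])
    return n / 10, h / 10, c / 10, o / 10


class TestKabschSander:
    def test_close_pair_accepted(self):
        n, h, c, o = ideal_pair(2.9)
        e = tj.kabsch_sander_energy(n, h, c, o)
        assert e < tj.KS_CUTOFF

    def test_distant_pair_rejected(self):
        n, h, c, o = ideal_pair(6.0)
        e = tj.kabsch_sander_energy(n, h, c, o)
        assert abs(e) < 0.5

    def test_direct_formula_value(self):
        """Hand-evaluated formula on constructed coordinates."""
        n, h, c, o = ideal_pair(2.9)
        r_on, r_ch, r_oh, r_cn = 2.9, 2.9 + 1.23 - 1.0, 2.9 - 1.0, 2.9 + 1.23
        expected = 27.888 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        assert tj.kabsch_sander_energy(n, h, c, o) == pytest.approx(expected)

    def test_minimum_image_wrapping_invariance(self):
        frame, _ = synthetic.make_ideal_beta_sheet("parallel", 2)
        base = {(b.donor, b.acceptor) for b in tj.detect_backbone_hbonds(frame)}
        wrapped = tj.PeptideFrame(
            positions=frame.positions + frame.box * np.array([1.0, 0.0, 0.0]),
            roles=frame.roles,
            monomer_id=frame.monomer_id,
            residue_index=frame.residue_index,
            monomer_length=frame.monomer_length,
            box=frame.box,
        )
        # shift half the atoms by one box vector: min-image must restore bonds
        pos = frame.positions.copy()
        pos[::2] += frame.box
        half = tj.PeptideFrame(
            positions=pos, roles=frame.roles, monomer_id=frame.monomer_id,
            residue_index=frame.residue_index, box=frame.box,
        )
        for fr in (wrapped, half):
            assert {(b.donor, b.acceptor) for b in tj.detect_backbone_hbonds(fr)} == base

    def test_isolated_monomer_has_no_intermonomer_bonds(self):
        frame, _ = synthetic.make_ideal_beta_sheet("parallel", 2)
        keep = frame.monomer_id == 0
        single = tj.PeptideFrame(
            positions=frame.positions[keep],
            roles=frame.roles[keep],
            monomer_id=frame.monomer_id[keep],
            residue_index=frame.residue_index[keep],
            box=frame.box,
        )
        bonds = tj.detect_backbone_hbonds(single)
        assert all(b.donor[0] == b.acceptor[0] for b in bonds)
        assert bonds == []  # extended strand: no intra bonds either

    def test_missing_hydrogen_reconstruction(self):
        frame, truth = synthetic.make_ideal_beta_sheet("antiparallel", 2)
        keep = frame.roles != "H"
        stripped = tj.PeptideFrame(
            positions=frame.positions[keep],
            roles=frame.roles[keep],
            monomer_id=frame.monomer_id[keep],
            residue_index=frame.residue_index[keep],
            box=frame.box,
        )
        with pytest.raises(ValueError, match="missing amide hydrogens"):
            tj.detect_backbone_hbonds(stripped, reconstruct_h=False)
        bonds = tj.detect_backbone_hbonds(stripped, reconstruct_h=True)
        assert len(bonds) > 0  # reconstructed H still finds sheet bonds


class TestRegistry:
    @pytest.mark.parametrize(
        "i,j,expected",
        [
            (3, 2, tj.PARALLEL),
            (2, 5, tj.ANTIPARALLEL),
            (4, 3, tj.AMBIGUOUS),
            (2, 2, tj.OTHER),
            (1, 6, tj.ANTIPARALLEL),
            (6, 5, tj.PARALLEL),
        ],
    )
    def test_rule_table_hexapeptide(self, i, j, expected):
        bond = tj.HBondRecord(donor=(0, i), acceptor=(1, j), energy=-1.0)
        assert tj.classify_registry(bond, 6) == expected

    def test_same_monomer_is_other(self):
        bond = tj.HBondRecord(donor=(0, 3), acceptor=(0, 2), energy=-1.0)
        assert tj.classify_registry(bond, 6) == tj.OTHER

    @pytest.mark.parametrize("length", range(2, 9))
    def test_truth_table_enumeration(self, length):
        """Exhaustive oracle over all (i, j) in [1, L]^2: re-derive the class
        directly from the registry rules."""
        for i in range(1, length + 1):
            for j in range(1, length + 1):
                par = j == i - 1
                anti = j == length + 1 - i and j != i
                if par and anti:
                    expected = tj.AMBIGUOUS
                elif par:
                    expected = tj.PARALLEL
                elif anti:
                    expected = tj.ANTIPARALLEL
                else:
                    expected = tj.OTHER
                bond = tj.HBondRecord(donor=(0, i), acceptor=(1, j), energy=-1.0)
                assert tj.classify_registry(bond, length) == expected

    def test_admissible_counts_hexapeptide(self):
        assert tj.count_admissible_pairings(6) == (4, 5)

    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_admissible_counts_match_enumeration(self, length):
        n_p = n_ap = 0
        for i in range(1, length + 1):
            jp, ja = i - 1, length + 1 - i
            amb = jp == ja
            if 1 <= jp <= length and not amb:
                n_p += 1
            if 1 <= ja <= length and not amb and ja != i:
                n_ap += 1
        assert tj.count_admissible_pairings(length) == (n_p, n_ap)


class TestParallelFraction:
    @pytest.mark.parametrize("np_,nap,expected", [(0, 0, 0.0), (4, 0, 0.8), (0, 5, 0.0)])
    def test_examples(self, np_, nap, expected):
        assert tj.parallel_fraction(np_, nap) == pytest.approx(expected)

    def test_monotonicity_and_bounds(self):
        for n_ap in range(0, 12):
            vals = [tj.parallel_fraction(n_p, n_ap) for n_p in range(0, 30)]
            assert all(0 <= v < 1 for v in vals)
            assert (np.diff(vals) > 0).all()
        for n_p in range(1, 12):
            vals = [tj.parallel_fraction(n_p, n_ap) for n_ap in range(0, 30)]
            assert (np.diff(vals) < 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tj.parallel_fraction(-1, 0)


class TestSheetSeries:
    def test_static_parallel_sheet(self):
        frames = [
            synthetic.make_ideal_beta_sheet("parallel", 2, time_ns=10.0 * k)[0]
            for k in range(5)
        ]
        series = tj.compute_sheet_order_series(frames, stride_ns=10.0)
        assert len(series.time_ns) == 5
        assert (series.n_p == 4).all()
        assert np.allclose(series.f_p, 0.8)

    def test_static_antiparallel_sheet(self):
        frames = [synthetic.make_ideal_beta_sheet("antiparallel", 2)[0]]
        series = tj.compute_sheet_order_series(frames)
        assert series.n_p[0] == 0 and series.n_ap[0] == 5
        assert series.f_p[0] == 0.0

    def test_mixed_interfaces_are_additive(self):
        frames = [synthetic.make_ideal_beta_sheet("mixed", 3)[0]]
        series = tj.compute_sheet_order_series(frames)
        assert series.n_p[0] == 4 and series.n_ap[0] == 5

    def test_stride_subsampling(self):
        frames = [
            synthetic.make_ideal_beta_sheet("parallel", 2, time_ns=float(k))[0]
            for k in range(25)
        ]
        series = tj.compute_sheet_order_series(frames, stride_ns=10.0)
        assert list(series.time_ns) == [0.0, 10.0, 20.0]

    def test_stride_longer_than_trajectory(self):
        frames = [synthetic.make_ideal_beta_sheet("parallel", 2, time_ns=1.0)[0]]
        series = tj.compute_sheet_order_series(frames, stride_ns=1000.0)
        assert len(series.time_ns) == 1


class TestRMSDPipeline:
    def test_unwrap_inserted_jump(self, rng):
        box = np.array([5.0, 5.0, 5.0])
        base = rng.uniform(1, 4, (8, 3))
        drift = np.array([0.02, 0.0, 0.01])
        pos = np.stack([base + k * drift for k in range(20)])
        pos[10:] += np.array([box[0], 0.0, 0.0])  # artificial +Lx jump
        unwrapped = tj.unwrap_trajectory(pos, box)
        steps = np.abs(np.diff(unwrapped, axis=0))
        assert steps.max() < box.min() / 2
        assert np.allclose(unwrapped[-1], base + 19 * drift, atol=1e-12)

    def test_identity_trajectory(self, rng):
        pos = np.stack([rng.uniform(0, 5, (10, 3))] * 4)
        aligned = tj.unwrap_and_align(pos)
        assert np.allclose(aligned, pos)
        assert np.allclose(tj.backbone_rmsd(aligned), 0.0, atol=1e-12)

    def test_rigid_motion_removed(self, rng):
        ref = rng.uniform(0, 3, (12, 3))
        frames = [ref]
        for phi, shift in [(0.4, [1, 0, 0]), (1.1, [0, 2, -1])]:
            rot = np.array(
                [
                    [np.cos(phi), -np.sin(phi), 0],
                    [np.sin(phi), np.cos(phi), 0],
                    [0, 0, 1],
                ]
            )
            frames.append(ref @ rot.T + shift)
        aligned = tj.unwrap_and_align(np.stack(frames))
        rmsd = tj.backbone_rmsd(aligned)
        assert np.all(rmsd < 1e-6)

    def test_uniform_shift_rmsd_closed_form(self, rng):
        ref = rng.uniform(0, 3, (50, 3))
        shifted = ref + np.array([0.25, 0.0, 0.0])
        rmsd = tj.backbone_rmsd(np.stack([ref, shifted]))
        assert rmsd[1] == pytest.approx(0.25)

    def test_gaussian_perturbation_expectation(self, rng):
        """Isotropic sigma-noise on each coordinate gives RMSD ~ sigma*sqrt(3)."""
        sigma = 0.05
        ref = rng.uniform(0, 5, (1000, 3))
        noisy = ref + rng.normal(0, sigma, ref.shape)
        rmsd = tj.backbone_rmsd(np.stack([ref, noisy]))
        assert rmsd[1] == pytest.approx(sigma * np.sqrt(3), rel=0.1)

    def test_exclusion_subset(self, rng):
        ref = rng.uniform(0, 3, (10, 3))
        moved = ref.copy()
        moved[0] += 5.0  # one outlier atom
        rmsd_all = tj.backbone_rmsd(np.stack([ref, moved]))
        rmsd_excl = tj.backbone_rmsd(np.stack([ref, moved]), exclude=[0])
        assert rmsd_excl[1] == pytest.approx(0.0, abs=1e-12)
        assert rmsd_all[1] > 1.0
        with pytest.raises(ValueError, match="empty"):
            tj.backbone_rmsd(np.stack([ref, moved]), exclude=list(range(10)))


class TestMembraneMetrics:
    def test_insertion_examples(self):
        frame = tj.MembraneFrame(
            phosphorus_z=np.array([1.0, 1.0]),
            water_oxygen_z=np.array([]),
            protein_positions=np.array([[0, 0, 0.0], [0, 0, 4.0]]),
        )
        assert tj.insertion_depth(frame) == pytest.approx(1.0)  # CoM 2 - P 1
        frame2 = tj.MembraneFrame(
            phosphorus_z=np.array([5.0, 5.0]),
            water_oxygen_z=np.array([]),
            protein_positions=np.array([[0, 0, 5.0]]),
        )
        assert tj.insertion_depth(frame2) == 0.0

    def test_mass_weighting(self):
        frame = tj.MembraneFrame(
            phosphorus_z=np.array([0.0, 0.0]),
            water_oxygen_z=np.array([]),
            protein_positions=np.array([[0, 0, 0.0], [0, 0, 3.0]]),
            protein_masses=np.array([1.0, 2.0]),
        )
        assert tj.insertion_depth(frame) == pytest.approx(2.0)

    def test_pore_water_constructed_counts(self):
        frame, truth = synthetic.make_membrane_frame(
            n_phosphorus=100, slab_z_nm=5.0, n_waters_inside=7,
            n_waters_outside=13, seed=4,
        )
        assert tj.pore_water_count(frame) == 7

    def test_no_waters(self):
        frame, _ = synthetic.make_membrane_frame(100, 5.0, 0, 0, seed=1)
        assert tj.pore_water_count(frame) == 0

    def test_boundary_is_inclusive(self):
        frame = tj.MembraneFrame(
            phosphorus_z=np.array([3.0, 7.0]),  # CoM exactly 5.0
            water_oxygen_z=np.array([5.5, 4.5, 5.5001, 4.4999]),
        )
        assert tj.pore_water_count(frame) == 2

    def test_rigid_z_translation_invariance(self):
        frame, _ = synthetic.make_membrane_frame(50, 5.0, 5, 9, seed=2)
        shifted = tj.MembraneFrame(
            phosphorus_z=frame.phosphorus_z + 1.0,
            water_oxygen_z=frame.water_oxygen_z + 1.0,
        )
        assert tj.pore_water_count(shifted) == tj.pore_water_count(frame)


class TestFileRoundtrip:
    def test_sheet_pdb_roundtrip_preserves_bonds(self, tmp_path):
        frame, truth = synthetic.make_ideal_beta_sheet("parallel", 3)
        path = tmp_path / "sheet.pdb"
        synthetic.write_sheet_pdb(frame, truth, str(path))
        frames = tj.load_peptide_frames(str(path))
        assert len(frames) == 1
        back = frames[0]
        bonds = tj.detect_backbone_hbonds(back)
        assert {(b.donor, b.acceptor) for b in bonds} == {
            (tuple(d), tuple(a)) for d, a in truth["pairs"]
        }
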