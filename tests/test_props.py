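"""Structural property calculators against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mdflex.errors import DegenerateGeometryError, MDFlexError, ValidationError
from mdflex.model import AnalysisConfig, Trajectory
from mdflex.props import (
    StructuralPropertyTable,
    assign_secondary_structure,
    build_native_pairs,
    compare_tables,
    kabsch_superpose_rmsd,
    native_contact_count,
    property_table,
    radius_of_gyration,
    shrake_rupley_sasa,
)

from conftest import peptide_system


class TestKabsch:
    def test_identical_coordinates_zero_rmsd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(20, 3)) * 5
        rot37 = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        mobile = ref @ rot37.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose_rmsd(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_tetrahedron_matches_rotation_search_oracle(self):
        # regular tetrahedron with one vertex displaced by 1 A
        ref = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        mobile = ref.copy()
        mobile[0] += np.array([1.0, 0.0, 0.0])

        def cost(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = mobile @ rot.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        # independent numerical search over rigid transforms, multi-start
        best = np.inf
        rng = np.random.default_rng(2)
        for _ in range(40):
            x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(size=3)])
            res = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            best = min(best, res.fun)
        _, _, rmsd = kabsch_superpose_rmsd(mobile, ref)
        assert rmsd == pytest.approx(best, abs=1e-3)
        assert rmsd <= best + 1e-9  # Kabsch attains the global minimum

    def test_fit_never_increases_rmsd(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(15, 3)) * 4
        mobile = ref + rng.normal(size=(15, 3))
        _, _, fitted = kabsch_superpose_rmsd(mobile, ref)
        raw = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
        assert fitted <= raw + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose_rmsd(line + 1.0, line)


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        frame = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1.0)

    def test_circle(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        frame = np.column_stack([3 * np.cos(theta), 3 * np.sin(theta), 0 * theta])
        assert radius_of_gyration(frame) == pytest.approx(3.0)

    def test_weighted_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        frame = rng.normal(size=(100, 3)) * 7
        masses = rng.uniform(1, 16, size=100)
        com = (masses[:, None] * frame).sum(axis=0) / masses.sum()
        expected = np.sqrt(
            (masses * np.sum((frame - com) ** 2, axis=1)).sum() / masses.sum()
        )
        got = radius_of_gyration(frame, np.arange(100), masses)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            radius_of_gyration(np.zeros((3, 3)), np.array([], dtype=int))


class TestNativeContacts:
    def test_reference_frame_counts_all_pairs(self, helix15):
        pairs = build_native_pairs(helix15, 6.0)
        count = native_contact_count(helix15.reference_coordinates, pairs, 6.0)
        assert count == len(pairs)

    def test_expansion_breaks_all_contacts(self, helix15):
        pairs = build_native_pairs(helix15, 6.0)
        centroid = helix15.reference_coordinates.mean(axis=0)
        blown = centroid + 10.0 * (helix15.reference_coordinates - centroid)
        assert native_contact_count(blown, pairs, 6.0) == 0

    def test_rotation_invariance(self, helix15):
        pairs = build_native_pairs(helix15, 6.0)
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = helix15.reference_coordinates @ rot.T + 5.0
        assert native_contact_count(moved, pairs, 6.0) == len(pairs)

    def test_matches_brute_force_on_random_frame(self, helix15):
        pairs = build_native_pairs(helix15, 6.0)
        rng = np.random.default_rng(5)
        frame = helix15.reference_coordinates + rng.normal(
            size=helix15.reference_coordinates.shape
        )
        brute = sum(
            1 for i, j in pairs if np.linalg.norm(frame[i] - frame[j]) < 6.0
        )
        assert native_contact_count(frame, pairs, 6.0) == brute

    def test_pair_list_is_strict_inequality_heavy_interresidue(self, helix15):
        pairs = build_native_pairs(helix15, 6.0)
        ref = helix15.reference_coordinates
        resid = helix15.residue_indices
        for i, j in pairs:
            assert not helix15.atoms[i].is_hydrogen
            assert resid[i] != resid[j]
            assert np.linalg.norm(ref[i] - ref[j]) < 6.0

    def test_missing_pairs_informative_error(self):
        with pytest.raises(MDFlexError, match="build_native_pairs"):
            native_contact_count(np.zeros((3, 3)), None)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.5]), 1.4, 960)
        analytic = 4 * np.pi * 2.9**2
        assert area[0] == pytest.approx(analytic, rel=0.01)

    def test_distant_spheres_additive(self):
        frames = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        radii = np.array([1.5, 1.8])
        total = shrake_rupley_sasa(frames, radii, 1.4, 960).sum()
        isolated = sum(
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]), 1.4, 960)[0]
            for r in radii
        )
        assert total == pytest.approx(isolated, rel=1e-6)

    def test_fused_spheres_match_monte_carlo(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.5, 1.5])
        probe = 1.4
        total = shrake_rupley_sasa(frame, radii, probe, 960).sum()
        rng = np.random.default_rng(6)
        acc = radii + probe
        mc_total = 0.0
        for i in range(2):
            pts = rng.normal(size=(1_000_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = frame[i] + acc[i] * pts
            j = 1 - i
            exposed = np.linalg.norm(pts - frame[j], axis=1) >= acc[j]
            mc_total += exposed.mean() * 4 * np.pi * acc[i] ** 2
        assert total == pytest.approx(mc_total, rel=0.02)

    def test_matches_mdtraj_on_helix(self, helix15):
        md = pytest.importorskip("mdtraj")
        top = md.Topology()
        chain = top.add_chain()
        residues = {}
        for a in helix15.atoms:
            if a.residue_index not in residues:
                residues[a.residue_index] = top.add_residue("SER", chain)
            top.add_atom(
                a.name, md.element.Element.getBySymbol(a.element),
                residues[a.residue_index],
            )
        xyz = helix15.reference_coordinates[None] / 10.0  # A -> nm
        traj = md.Trajectory(xyz, top)
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)
        ref_total = ref[0].sum() * 100.0  # nm^2 -> A^2
        ours = shrake_rupley_sasa(
            helix15.reference_coordinates, helix15.vdw_radii, 1.4, 960
        ).sum()
        assert ours == pytest.approx(ref_total, rel=0.01)

    def test_approach_never_increases_total(self):
        radii = np.array([1.5, 1.5])
        prev = np.inf
        for d in (8.0, 6.0, 4.0, 3.0, 2.0, 1.0):
            frame = np.array([[0.0, 0, 0], [d, 0, 0]])
            total = shrake_rupley_sasa(frame, radii, 1.4, 480).sum()
            assert total <= prev + 1e-9
            prev = total


class TestSecondaryStructure:
    def test_ideal_helix_core_is_helical(self, helix15):
        labels = assign_secondary_structure(
            helix15.reference_coordinates, helix15
        )
        # i -> i+4 amide pattern oracle: donor N(i+4) within reach of O(i)
        ref = helix15.reference_coordinates
        turns = []
        for i in range(11):
            o = helix15.atom_index(i, "O")
            n = helix15.atom_index(i + 4, "N")
            turns.append(np.linalg.norm(ref[o] - ref[n]) < 3.5)
        assert all(turns)
        # two consecutive turns cover residues 2..13 (1-based) at least
        for r in range(1, 13):
            assert labels[r] == "H", f"residue {r}: {labels}"
        assert labels[0] != "H"

    def test_extended_chain_all_coil(self, extended12):
        labels = assign_secondary_structure(
            extended12.reference_coordinates, extended12
        )
        assert labels == ["C"] * 12

    def test_antiparallel_hairpin_strand_interiors(self, hairpin):
        from mdflex.props import _backbone_hbond_matrix

        hb = _backbone_hbond_matrix(hairpin.reference_coordinates, hairpin)
        inter = hb[:6, 6:].sum() + hb[6:, :6].sum()
        assert inter >= 3  # genuine cross-strand amide bonds exist
        labels = assign_secondary_structure(
            hairpin.reference_coordinates, hairpin
        )
        # bridge-pattern oracle marks the paired interiors as strand
        assert labels.count("E") >= 6
        for r in (2, 3, 8, 9):
            assert labels[r] == "E", f"residue {r}: {labels}"

    def test_labels_partition_residues(self, helix15, hairpin):
        for system in (helix15, hairpin):
            labels = assign_secondary_structure(
                system.reference_coordinates, system
            )
            assert len(labels) == system.n_residues
            assert set(labels) <= {"H", "G", "E", "T", "C"}

    def test_short_chain_warns_all_coil(self):
        system = peptide_system(2, -120.0, 120.0)
        with pytest.warns(UserWarning):
            labels = assign_secondary_structure(
                system.reference_coordinates, system
            )
        assert labels == ["C", "C"]


class TestPropertyTableArithmetic:
    def test_printed_rmsd_percent_change(self):
        # cold-solvent -> warm-solvent comparison on published table means
        a = StructuralPropertyTable(label="P180/S180", rmsd_mean=0.62)
        b = StructuralPropertyTable(label="P180/S300", rmsd_mean=0.90)
        (delta,) = [d for d in compare_tables(a, b) if d.property_name == "rmsd"]
        assert delta.percent_change == pytest.approx(45.2, abs=0.05)

    def test_identical_tables_zero_deltas(self):
        a = StructuralPropertyTable(
            label="x", rmsd_mean=1.0, sasa_mean=100.0, nnc_mean=50, rg_mean=16.0
        )
        for d in compare_tables(a, a):
            assert d.percent_change == 0.0 and d.fold_change == 0.0

    def test_tmsf_fold_change(self):
        a = StructuralPropertyTable(label="P300/S180", tmsf=0.64 * 100)
        b = StructuralPropertyTable(label="P300/S300", tmsf=2.97 * 100)
        (delta,) = [d for d in compare_tables(a, b) if d.property_name == "tmsf"]
        assert delta.fold_change == pytest.approx(3.64, abs=0.005)

    def test_zero_baseline_rejected(self):
        a = StructuralPropertyTable(label="a", rmsd_mean=0.0)
        b = StructuralPropertyTable(label="b", rmsd_mean=1.0)
        with pytest.raises(MDFlexError, match="zero baseline"):
            compare_tables(a, b)

    def test_property_table_on_static_trajectory(self, helix15):
        frames = np.repeat(helix15.reference_coordinates[None], 3, axis=0)
        traj = Trajectory(helix15, frames, 10.0 * (1 + np.arange(3)))
        config = AnalysisConfig(sasa_points_per_atom=60)
        table = property_table(traj, config, label="static")
        assert table.rmsd_mean == pytest.approx(0.0, abs=1e-9)
        assert table.rmsd_sd == pytest.approx(0.0, abs=1e-9)
        assert table.nnc_mean == len(helix15.native_pairs)
        assert table.sse_helix_mean >= 10
        assert table.sasa_mean > 0
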