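"""Hydrogen-bond detection and occupancy bookkeeping."""

import numpy as np
import pytest

from mdflex.errors import ValidationError
from mdflex.hbonds import (
    classify_pair,
    detect_hbonds_frame,
    hbond_statistics,
    implied_static_mean,
)
from mdflex.model import ATOMIC_MASSES, VDW_RADII, Atom, System, Trajectory
from mdflex.pdbio import assign_donors_acceptors
from mdflex.synth import HBondSchedule, ScheduledBond, gen_toy_protein_solvent


def _cloud_system(n_donors, n_acceptors, seed, box=None):
    """Random cloud of N-H donors and O acceptors, no covalent contacts."""
    rng = np.random.default_rng(seed)
    side = 18.0 if box is None else box[0]
    heavy = []
    while len(heavy) < n_donors + n_acceptors:
        p = rng.uniform(0, side, size=3)
        if all(np.linalg.norm(p - q) >= 2.3 for q in heavy):
            heavy.append(p)
    atoms, coords = [], []
    for i in range(n_donors):
        n_pos = heavy[i]
        h_dir = rng.normal(size=3)
        h_dir /= np.linalg.norm(h_dir)
        atoms.append(Atom(index=len(atoms), name="N", element="N",
                          residue_index=i, residue_name="GLY",
                          is_mainchain=True, vdw_radius=VDW_RADII["N"],
                          mass=ATOMIC_MASSES["N"]))
        coords.append(n_pos)
        atoms.append(Atom(index=len(atoms), name="H", element="H",
                          residue_index=i, residue_name="GLY",
                          is_mainchain=True, is_hydrogen=True,
                          vdw_radius=VDW_RADII["H"], mass=ATOMIC_MASSES["H"]))
        coords.append(n_pos + h_dir)
    for i in range(n_acceptors):
        atoms.append(Atom(index=len(atoms), name="O", element="O",
                          residue_index=n_donors + i, residue_name="GLY",
                          is_mainchain=True, vdw_radius=VDW_RADII["O"],
                          mass=ATOMIC_MASSES["O"]))
        coords.append(heavy[n_donors + i])
    system = System(atoms, np.asarray(coords))
    assign_donors_acceptors(system)
    return system


def _brute_force(frame, system, cutoff=3.5, angle=120.0, box=None):
    """All-triples reference detector (distance + angle only)."""
    from mdflex.model import minimum_image

    out = set()
    for d in system.atoms:
        if not d.donor_flag:
            continue
        for h in d.attached_hydrogens:
            for a in system.atoms:
                if not a.acceptor_flag or a.index == d.index:
                    continue
                dv = minimum_image(frame[a.index] - frame[d.index], box)
                if np.linalg.norm(dv) > cutoff:
                    continue
                v1 = minimum_image(frame[d.index] - frame[h], box)
                v2 = minimum_image(frame[a.index] - frame[h], box)
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle:
                    out.add((d.index, h, a.index))
    return out


class TestDetector:
    def test_collinear_bond_detected(self):
        system = _cloud_system(1, 1, seed=0)
        frame = system.reference_coordinates.copy()
        n, h, o = 0, 1, 2
        direction = frame[h] - frame[n]
        frame[o] = frame[n] + 2.9 * direction
        bonds = detect_hbonds_frame(frame, system)
        assert [(b.donor, b.hydrogen, b.acceptor) for b in bonds] == [(n, h, o)]

    def test_distance_fail_not_detected(self):
        system = _cloud_system(1, 1, seed=0)
        frame = system.reference_coordinates.copy()
        direction = frame[1] - frame[0]
        frame[2] = frame[0] + 3.6 * direction  # perfect angle, too far
        assert detect_hbonds_frame(frame, system) == []

    def test_angle_fail_not_detected(self):
        system = _cloud_system(1, 1, seed=0)
        frame = system.reference_coordinates.copy()
        direction = frame[1] - frame[0]
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        frame[2] = frame[0] + 2.0 * perp  # close but ~90 deg at H
        assert detect_hbonds_frame(frame, system) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        system = _cloud_system(25, 25, seed=seed)
        rng = np.random.default_rng(100 + seed)
        for _ in range(10):
            frame = system.reference_coordinates + rng.normal(
                scale=0.5, size=system.reference_coordinates.shape
            )
            got = {(b.donor, b.hydrogen, b.acceptor)
                   for b in detect_hbonds_frame(frame, system)}
            assert got == _brute_force(frame, system)

    def test_periodic_minimum_image(self):
        box = np.array([20.0, 20.0, 20.0])
        system = _cloud_system(1, 1, seed=1, box=box)
        frame = system.reference_coordinates.copy()
        frame[0] = np.array([0.5, 10.0, 10.0])
        frame[1] = frame[0] - np.array([1.0, 0.0, 0.0])   # H towards -x
        frame[2] = np.array([17.6, 10.0, 10.0])           # 2.9 A across the wall
        got = {(b.donor, b.hydrogen, b.acceptor)
               for b in detect_hbonds_frame(frame, system, box=box)}
        assert got == {(0, 1, 2)}
        assert got == _brute_force(frame, system, box=box)

    def test_deterministic_ordering(self):
        system = _cloud_system(10, 10, seed=3)
        frame = system.reference_coordinates
        bonds = detect_hbonds_frame(frame, system)
        keys = [(b.donor, b.hydrogen, b.acceptor) for b in bonds]
        assert keys == sorted(keys)


class TestClassification:
    def test_class_from_flags(self, scheduled_toy):
        system, _, schedule = scheduled_toy
        for b in schedule.bonds:
            assert classify_pair(system, b.donor, b.acceptor) == b.class_label

    def test_mainchain_sidechain_combinations(self):
        atoms = []
        coords = []
        spec = [
            ("N", "N", True, True), ("O", "O", True, True),     # mainchain pair
            ("OG", "O", True, False), ("OW", "O", False, False),
        ]
        for i, (name, element, solute, mainchain) in enumerate(spec):
            atoms.append(Atom(index=i, name=name, element=element,
                              residue_index=i, residue_name="X",
                              is_solute=solute, is_mainchain=mainchain,
                              vdw_radius=1.5, mass=14.0))
            coords.append([3.0 * i, 0.0, 0.0])
        system = System(atoms, np.array(coords))
        assert classify_pair(system, 0, 1) == "M-M"
        assert classify_pair(system, 0, 2) == "M-S"
        assert classify_pair(system, 2, 2) == "S-S"
        assert classify_pair(system, 0, 3) == "M-solv"
        assert classify_pair(system, 2, 3) == "S-solv"
        assert classify_pair(system, 3, 3) == "solv-solv"


def _scheduled_stats(persistencies, n_frames=200, seed=0):
    """Toy trajectory whose bonds hit the requested persistencies exactly."""
    n = len(persistencies)
    system, _, _ = gen_toy_protein_solvent(
        3 * n + 4, "extended", 0, schedule="auto", n_frames=1, n_bonds=0,
        seed=seed,
    )
    bonds = []
    for k, pct in enumerate(persistencies):
        donor = system.atom_index(2 + 3 * k, "N")
        h = system.atoms[donor].attached_hydrogens[0]
        acceptor = system.atom_index(3 + 3 * k, "OG")
        mask = np.zeros(n_frames, dtype=bool)
        mask[: int(round(pct / 100 * n_frames))] = True
        bonds.append(ScheduledBond(donor, h, acceptor, "M-S", mask))
    schedule = HBondSchedule(bonds)
    system, traj, schedule = gen_toy_protein_solvent(
        3 * n + 4, "extended", 0, schedule=schedule, seed=seed
    )
    return hbond_statistics(traj, scope="intra-protein")


class TestStatistics:
    def test_single_persistent_bond(self):
        stats = _scheduled_stats([100.0])
        assert stats.static_mean == pytest.approx(1.0)
        assert stats.dynamic_count == 1
        assert list(stats.persistency.values()) == [pytest.approx(100.0)]

    def test_scripted_persistencies(self):
        stats = _scheduled_stats([100.0, 50.0, 10.0])
        assert stats.static_mean == pytest.approx(1.6)
        assert stats.dynamic_count == 3
        assert stats.mean_persistency == pytest.approx(160.0 / 3)

    def test_persistency_identity_exact(self, scheduled_toy):
        _, traj, _ = scheduled_toy
        stats = hbond_statistics(traj, scope="intra-protein")
        total = sum(stats.persistency.values()) / 100.0
        assert total == pytest.approx(stats.static_mean, rel=1e-12)

    def test_scope_partition_against_schedule(self, scheduled_toy):
        system, traj, schedule = scheduled_toy
        intra = hbond_statistics(traj, scope="intra-protein")
        solv = hbond_statistics(traj, scope="protein-solvent")
        n_intra = sum(
            1 for b in schedule.bonds if b.class_label in ("M-M", "M-S", "S-S")
        )
        n_solv = len(schedule.bonds) - n_intra
        assert intra.dynamic_count == n_intra
        assert solv.dynamic_count == n_solv
        assert sum(intra.class_counts.values()) == intra.dynamic_count
        assert sum(
            intra.class_mean_persistency[c] * intra.class_counts[c]
            for c in intra.class_counts
        ) / 100.0 == pytest.approx(intra.static_mean, rel=1e-12)

    def test_dynamic_count_monotone_in_prefix_length(self, scheduled_toy):
        system, traj, _ = scheduled_toy
        prev = 0
        for n in (20, 60, 120, 200):
            sub = Trajectory(system, traj.frames[:n], traj.times[:n])
            count = hbond_statistics(sub, scope="intra-protein").dynamic_count
            assert count >= prev
            prev = count

    def test_protein_solvent_scope_needs_solvent(self, helix15):
        frames = np.repeat(helix15.reference_coordinates[None], 2, axis=0)
        traj = Trajectory(helix15, frames, [10.0, 20.0])
        with pytest.raises(ValidationError, match="solvent"):
            hbond_statistics(traj, scope="protein-solvent")

    def test_implied_static_mean_identity(self):
        # identity static = dynamic x mean persistency / 100
        assert implied_static_mean(3, 160.0 / 3) == pytest.approx(1.6)
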