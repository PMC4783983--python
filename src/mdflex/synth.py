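"""Synthetic trajectories and toy protein–solvent systems with known truth.

Every analysis stage in this package is exercised against data generated
here: Gaussian-mode trajectories with a planted covariance, random walks
(the diffusion-like signal that cosine-content flags), two-state Markov
hopping with a known free-energy difference, and a kinematic toy
peptide/water system whose hydrogen bonds follow a scripted schedule
exactly.

The toy systems carry no energetics whatsoever: geometry is built from
ideal internal coordinates (N–CA 1.46 Å, CA–C 1.52 Å, C–N 1.33 Å, ω = 180°;
helix φ = −57°, ψ = −47°; extended φ = −120°, ψ = 120°) and scheduled bonds
are realised by moving the acceptor (a side-chain hydroxyl oxygen or a water
oxygen) along the donor's D–H ray: 2.9 Å from the donor on "on" frames
(satisfying both criteria), 3.8 Å on "off" frames (violating the 3.5 Å
distance cutoff by 0.3 Å).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .hbonds import classify_pair
from .model import Atom, System, Trajectory

_ON_DISTANCE = 2.9   # Å, donor-acceptor on "on" frames
_OFF_DISTANCE = 3.8  # Å, = cutoff + 0.3 margin on "off" frames

# ideal peptide internal coordinates, Å / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.46, 1.52, 1.33, 1.23, 1.00
_B_CA_CB, _B_CB_OG, _B_OG_HG = 1.53, 1.42, 0.96
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 121.0

GEOMETRIES = {"helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}


@dataclass
class PlantedMode:
    """One planted covariance mode: a unit 3N-vector and its variance (Å²)."""

    eigenvector: np.ndarray
    eigenvalue: float

    def __post_init__(self) -> None:
        self.eigenvector = np.asarray(self.eigenvector, dtype=float).ravel()
        norm = np.linalg.norm(self.eigenvector)
        if abs(norm - 1.0) > 1e-10:
            raise ValidationError(f"mode eigenvector norm {norm} != 1")
        if self.eigenvalue < 0:
            raise ValidationError("mode eigenvalue must be >= 0")


@dataclass
class ScheduledBond:
    donor: int
    hydrogen: int
    acceptor: int
    class_label: str
    mask: np.ndarray  # boolean, one entry per frame


@dataclass
class HBondSchedule:
    """Ground-truth hydrogen-bond presence bitmasks over frames."""

    bonds: list[ScheduledBond]

    @property
    def n_frames(self) -> int:
        return len(self.bonds[0].mask) if self.bonds else 0

    def __post_init__(self) -> None:
        for b in self.bonds:
            b.mask = np.asarray(b.mask, dtype=bool)
        lengths = {len(b.mask) for b in self.bonds}
        if len(lengths) > 1:
            raise ValidationError("all schedule bitmasks must have equal length")

    def frame_set(self, f: int) -> set[tuple[int, int, int]]:
        return {
            (b.donor, b.hydrogen, b.acceptor) for b in self.bonds if b.mask[f]
        }


def gen_gaussian_mode_trajectory(
    system: System,
    modes: list[PlantedMode],
    n_frames: int,
    seed: int = 0,
    dt_ps: float = 10.0,
) -> Trajectory:
    """Reference structure plus independent Gaussian motion along planted modes.

    Frame t = reference + sum_k z_k(t) v_k with z_k ~ N(0, lambda_k) i.i.d.
    per frame, so the population covariance is exactly
    sum_k lambda_k v_k v_k^T.
    """
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    for i, mi in enumerate(modes):
        for mj in modes[i + 1:]:
            if abs(float(mi.eigenvector @ mj.eigenvector)) > 1e-8:
                raise ValidationError("planted modes must be mutually orthogonal")
    rng = np.random.default_rng(seed)
    ref = system.reference_coordinates.reshape(-1)
    frames = np.tile(ref, (n_frames, 1))
    for mode in modes:
        z = rng.normal(0.0, np.sqrt(mode.eigenvalue), size=n_frames)
        frames += z[:, None] * mode.eigenvector[None, :]
    frames = frames.reshape(n_frames, system.n_atoms, 3)
    times = dt_ps * (1.0 + np.arange(n_frames))
    return Trajectory(system, frames, times)


def orthogonal_modes(
    system: System, eigenvalues, seed: int = 0
) -> list[PlantedMode]:
    """Random planted modes orthogonal to the rigid-body subspace.

    Least-squares fitting removes global translations and infinitesimal
    rotations from a trajectory, so planted modes with components in that
    6-dimensional subspace would be partially destroyed by the fit.  This
    helper projects random directions out of the rigid-body subspace (built
    around the reference centroid) and orthonormalises them.
    """
    rng = np.random.default_rng(seed)
    ref = system.reference_coordinates
    n = system.n_atoms
    centered = ref - ref.mean(axis=0)
    basis = []
    for axis in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, axis] = 1.0
        basis.append(v.ravel())
    for axis in range(3):  # infinitesimal rotations about the centroid
        e = np.zeros(3)
        e[axis] = 1.0
        basis.append(np.cross(e, centered).ravel())
    modes = []
    for lam in eigenvalues:
        v = rng.normal(size=3 * n)
        for b in basis:
            nb = np.linalg.norm(b)
            if nb > 0:
                v -= (v @ b) / (nb * nb) * b
        for m in modes:
            v -= (v @ m.eigenvector) * m.eigenvector
        v /= np.linalg.norm(v)
        modes.append(PlantedMode(v, lam))
    return modes


def gen_random_walk(
    n_dims: int, step_sd: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Cumulative sum of i.i.d. N(0, step_sd²) steps; shape (n_frames, n_dims).

    MSD at lag m is m·step_sd²·n_dims in expectation.  step_sd = 0 produces
    a constant (all-zero) series.
    """
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    if step_sd < 0:
        raise ValidationError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(n_frames, n_dims))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def gen_two_state(
    delta_F: float,
    kT: float = 1.0,
    hop_prob: float = 0.1,
    n_frames: int = 10000,
    seed: int = 0,
    centers: tuple[float, float] = (-1.0, 1.0),
    jitter: float | None = None,
) -> np.ndarray:
    """Two-state Markov hopping with stationary ratio p_B/p_A = exp(−ΔF).

    ΔF is in units of kT.  Transitions are Metropolis moves: a switch is
    attempted with probability ``hop_prob`` and accepted with probability
    min(1, exp(∓ΔF)), which satisfies detailed balance.  The emitted series
    is the occupied state's centre plus Gaussian jitter of width
    0.05·|centre separation| (unless overridden).
    """
    if not (0.0 < hop_prob < 1.0):
        raise ValidationError("hop_prob must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if jitter is None:
        jitter = 0.05 * abs(centers[1] - centers[0])
    p_a_to_b = hop_prob * min(1.0, np.exp(-delta_F))
    p_b_to_a = hop_prob * min(1.0, np.exp(delta_F))
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=int)
    state = 0
    for t in range(n_frames):
        thresh = p_a_to_b if state == 0 else p_b_to_a
        if u[t] < thresh:
            state = 1 - state
        states[t] = state
    series = np.asarray(centers)[states] + rng.normal(0.0, jitter, size=n_frames)
    return series


# ---------------------------------------------------------------------------
# toy peptide / solvent construction
# ---------------------------------------------------------------------------


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position D with |CD|=bond, angle(B,C,D), torsion(A,B,C,D)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_peptide(n_residues: int, phi: float, psi: float):
    """Ideal-geometry peptide; returns (atom specs, coordinates).

    Each residue carries N, H (except the first), CA, CB, OG, HG, C, O —
    a serine-like template whose hydroxyl serves as side-chain donor and
    acceptor for scheduled bonds.
    """
    bb = {}  # (res, name) -> coord
    bb[(0, "N")] = np.array([0.0, 0.0, 0.0])
    bb[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    bb[(0, "C")] = _place(
        np.array([0.0, 1.0, 0.0]), bb[(0, "N")], bb[(0, "CA")],
        _B_CA_C, _A_N_CA_C, psi + 120.0,  # arbitrary but fixed orientation
    )
    for i in range(1, n_residues):
        bb[(i, "N")] = _place(
            bb[(i - 1, "N")], bb[(i - 1, "CA")], bb[(i - 1, "C")],
            _B_C_N, _A_CA_C_N, psi,
        )
        bb[(i, "CA")] = _place(
            bb[(i - 1, "CA")], bb[(i - 1, "C")], bb[(i, "N")],
            _B_N_CA, _A_C_N_CA, 180.0,
        )
        bb[(i, "C")] = _place(
            bb[(i - 1, "C")], bb[(i, "N")], bb[(i, "CA")],
            _B_CA_C, _A_N_CA_C, phi,
        )
    atoms = []
    coords = []
    for i in range(n_residues):
        n, ca, c = bb[(i, "N")], bb[(i, "CA")], bb[(i, "C")]
        res_atoms = [("N", "N", n)]
        if i > 0:
            u = ca - n
            v = bb[(i - 1, "C")] - n
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            hdir = -(u + v)
            hdir /= np.linalg.norm(hdir)
            res_atoms.append(("H", "H", n + _B_N_H * hdir))
        res_atoms.append(("CA", "C", ca))
        # side chain: CB out of the backbone plane, hydroxyl OG-HG on a stalk
        u_n = (n - ca) / np.linalg.norm(n - ca)
        u_c = (c - ca) / np.linalg.norm(c - ca)
        perp = np.cross(u_n, u_c)
        perp /= np.linalg.norm(perp)
        cb_dir = -(u_n + u_c) + 1.1 * perp
        cb_dir /= np.linalg.norm(cb_dir)
        cb = ca + _B_CA_CB * cb_dir
        og = cb + _B_CB_OG * cb_dir
        hg = og + _B_OG_HG * cb_dir
        res_atoms += [("CB", "C", cb), ("OG", "O", og), ("HG", "H", hg)]
        res_atoms.append(("C", "C", c))
        # carbonyl O, anti to the next N about the CA-C axis
        o = _place(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        res_atoms.append(("O", "O", o))
        for name, element, pos in res_atoms:
            atoms.append((i, name, element))
            coords.append(pos)
    return atoms, np.asarray(coords)


def gen_toy_protein_solvent(
    n_residues: int,
    geometry: str = "extended",
    n_waters: int = 0,
    schedule: HBondSchedule | str = "auto",
    seed: int = 0,
    n_frames: int = 100,
    n_bonds: int = 6,
    shell_fraction: float = 0.5,
    shell_distance: float = 4.0,
    bulk_distance: float = 12.0,
    dt_ps: float = 10.0,
):
    """Build a toy peptide + water system whose H-bonds follow a schedule.

    Returns ``(system, trajectory, schedule)``.  With ``schedule="auto"`` a
    random schedule of ``n_bonds`` bonds over ``n_frames`` frames is
    generated (donors: mainchain amides or side-chain hydroxyls; acceptors:
    distant side-chain hydroxyls or water oxygens).  Waters not used by the
    schedule are placed on a hydration shell (``shell_distance`` from the
    nearest protein atom; inside the hydration cutoff but outside H-bond
    range) and in the far field (``bulk_distance`` or farther).

    Water molecules are represented by their oxygen site only (acceptor,
    never donor); the generator is kinematic, not energetic.
    """
    if geometry not in GEOMETRIES:
        raise ValidationError(f"geometry must be one of {sorted(GEOMETRIES)}")
    phi, psi = GEOMETRIES[geometry]
    rng = np.random.default_rng(seed)
    atom_specs, coords = _build_peptide(n_residues, phi, psi)

    atoms: list[Atom] = []
    from .model import ATOMIC_MASSES, VDW_RADII

    for idx, (res, name, element) in enumerate(atom_specs):
        atoms.append(
            Atom(
                index=idx,
                name=name,
                element=element,
                residue_index=res,
                residue_name="SER",
                is_solute=True,
                is_mainchain=name in ("N", "H", "CA", "C", "O"),
                is_hydrogen=element == "H",
                vdw_radius=VDW_RADII[element],
                mass=ATOMIC_MASSES[element],
            )
        )
    n_protein = len(atoms)
    protein_coords = coords.copy()

    heavy_coords = protein_coords[
        [i for i, (_, _, e) in enumerate(atom_specs) if e != "H"]
    ]
    water_coords = _place_waters(
        rng, protein_coords, heavy_coords, n_waters, shell_fraction,
        shell_distance, bulk_distance,
    )
    all_coords = (
        np.vstack([protein_coords, water_coords]) if n_waters else protein_coords
    )
    for w in range(n_waters):
        atoms.append(
            Atom(
                index=n_protein + w,
                name="OW",
                element="O",
                residue_index=n_residues + w,
                residue_name="SOL",
                is_solute=False,
                is_mainchain=False,
                is_hydrogen=False,
                vdw_radius=VDW_RADII["O"],
                mass=18.015,
            )
        )
    system = System(atoms, all_coords)
    from .pdbio import assign_donors_acceptors

    assign_donors_acceptors(system)

    if schedule == "auto":
        schedule = _auto_schedule(
            rng, system, n_residues, n_waters, n_protein, n_frames, n_bonds
        )
    _validate_schedule(system, schedule)
    n_frames = schedule.n_frames if schedule.bonds else n_frames

    frames = np.tile(all_coords, (n_frames, 1, 1))
    name_of = {a.index: a.name for a in system.atoms}
    for bond in schedule.bonds:
        d_pos = all_coords[bond.donor]
        h_pos = all_coords[bond.hydrogen]
        ray = h_pos - d_pos
        ray /= np.linalg.norm(ray)
        on_pos = d_pos + _ON_DISTANCE * ray
        off_pos = d_pos + _OFF_DISTANCE * ray
        acc = bond.acceptor
        for f in range(n_frames):
            pos = on_pos if bond.mask[f] else off_pos
            frames[f, acc] = pos
            if name_of[acc] == "OG":  # carry the hydroxyl hydrogen along
                hg = acc + 1
                frames[f, hg] = pos + _B_OG_HG * ray
    times = dt_ps * (1.0 + np.arange(n_frames))
    traj = Trajectory(system, frames, times)
    return system, traj, schedule


def _place_waters(rng, protein_coords, heavy_coords, n_waters, shell_fraction,
                  shell_distance, bulk_distance):
    if n_waters == 0:
        return np.zeros((0, 3))
    from scipy.spatial import cKDTree

    # shell membership is judged against protein heavy atoms, so anchor
    # shell waters to heavy atoms and measure clearance against them
    tree_all = cKDTree(protein_coords)
    heavy_tree = cKDTree(heavy_coords)
    centroid = protein_coords.mean(axis=0)
    extent = float(np.max(np.linalg.norm(protein_coords - centroid, axis=1)))
    n_shell = int(round(shell_fraction * n_waters))
    placed: list[np.ndarray] = []

    def separated(candidate):
        return all(np.linalg.norm(candidate - p) >= 3.9 for p in placed)

    for w in range(n_waters):
        want_shell = w < n_shell
        for _ in range(2000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if want_shell:
                anchor = heavy_tree.data[rng.integers(len(heavy_tree.data))]
                candidate = anchor + shell_distance * direction
                d_heavy = heavy_tree.query(candidate)[0]
                d_all = tree_all.query(candidate)[0]
                if (shell_distance * 0.975 <= d_heavy <= shell_distance * 1.1
                        and d_all >= 3.0 and separated(candidate)):
                    placed.append(candidate)
                    break
            else:
                radius = extent + bulk_distance + 8.0 * rng.random()
                candidate = centroid + radius * direction
                if tree_all.query(candidate)[0] >= bulk_distance and separated(
                    candidate
                ):
                    placed.append(candidate)
                    break
        else:
            raise ValidationError("could not place waters without clashes")
    return np.asarray(placed)


def _auto_schedule(rng, system, n_residues, n_waters, n_protein,
                   n_frames, n_bonds):
    donors_pool = []  # candidate (donor residue)
    for r in range(2, n_residues - 1, 3):
        donors_pool.append(r)
    if not donors_pool:
        raise ValidationError("n_residues too small for an auto schedule")
    bonds: list[ScheduledBond] = []
    used_acceptors: set[int] = set()
    water_cursor = 0
    acceptor_res_pool = [r for r in range(n_residues) if r not in donors_pool]
    rng.shuffle(acceptor_res_pool)
    for k in range(min(n_bonds, len(donors_pool))):
        res = donors_pool[k]
        if rng.random() < 0.5:
            d = system.atom_index(res, "N")
        else:
            d = system.atom_index(res, "OG")
        h = system.atoms[d].attached_hydrogens[0]
        use_water = n_waters > water_cursor and rng.random() < 0.5
        if use_water:
            a = n_protein + water_cursor
            water_cursor += 1
        else:
            while acceptor_res_pool:
                cand = system.atom_index(acceptor_res_pool.pop(), "OG")
                if cand not in used_acceptors and cand != d:
                    a = cand
                    break
            else:
                continue
        used_acceptors.add(a)
        mask = rng.random(n_frames) < rng.uniform(0.2, 0.9)
        if not mask.any():
            mask[rng.integers(n_frames)] = True
        bonds.append(
            ScheduledBond(d, h, a, classify_pair(system, d, a), mask)
        )
    return HBondSchedule(bonds)


def _validate_schedule(system: System, schedule: HBondSchedule) -> None:
    seen_acceptors: set[int] = set()
    for b in schedule.bonds:
        atom_d = system.atoms[b.donor]
        atom_a = system.atoms[b.acceptor]
        if not atom_d.donor_flag or b.hydrogen not in atom_d.attached_hydrogens:
            raise ValidationError(
                f"schedule bond donor {b.donor} is not a donor with hydrogen "
                f"{b.hydrogen}"
            )
        if not atom_a.acceptor_flag:
            raise ValidationError(
                f"schedule bond acceptor {b.acceptor} is not an acceptor"
            )
        if b.acceptor in seen_acceptors:
            raise ValidationError(
                f"acceptor {b.acceptor} is used by more than one scheduled bond"
            )
        seen_acceptors.add(b.acceptor)
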