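"""Domain types shared by every analysis module.

Conventions: all lengths are in Angstrom (Å), times in picoseconds, masses in
amu.  Atom and residue indices are 0-based and contiguous; residue numbering
from input files is preserved for display only and never used for indexing.
Mean-square quantities (eigenvalues, TMSF) are carried in Å² and can be
converted to nm² with :data:`A2_PER_NM2` (1 nm² = 100 Å²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: conversion factor between Å² and nm²
A2_PER_NM2 = 100.0

#: Boltzmann constant in kJ/(mol·K)
KB_KJ_PER_MOL_K = 0.0083144626

#: mainchain (backbone) atom names; everything else in a residue is side chain
MAINCHAIN_NAMES = frozenset(
    {"N", "H", "H1", "H2", "H3", "CA", "HA", "C", "O", "OXT"}
)

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})

#: residue names recognised as monatomic ions (retained but not solute)
ION_RESNAMES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "CA", "NA+", "CL-", "K+", "MG2", "CAL"}
)

#: Bondi van der Waals radii by element, Å
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38,
}
DEFAULT_MASS = 12.011


@dataclass
class Atom:
    """A single atom with the role flags used by the analyses.

    ``is_mainchain`` implies ``is_solute``; ``attached_hydrogens`` lists the
    indices of covalently bound hydrogens of the same residue (used by the
    hydrogen-bond donor geometry).
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    is_solute: bool = True
    is_mainchain: bool = False
    is_hydrogen: bool = False
    vdw_radius: float = DEFAULT_VDW_RADIUS
    mass: float = DEFAULT_MASS
    donor_flag: bool = False
    acceptor_flag: bool = False
    attached_hydrogens: list[int] = field(default_factory=list)
    residue_number: int | None = None  # author numbering, display only
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.is_mainchain and not self.is_solute:
            raise ValidationError(
                f"atom {self.index} ({self.name}): is_mainchain implies is_solute"
            )


class System:
    """Topology plus reference coordinates.

    Parameters
    ----------
    atoms : list of Atom
    reference_coordinates : (N, 3) array, Å
    native_pairs : optional (P, 2) integer array of reference atom pairs
    """

    def __init__(self, atoms, reference_coordinates, native_pairs=None):
        self.atoms = list(atoms)
        ref = np.asarray(reference_coordinates, dtype=float)
        if ref.ndim != 2 or ref.shape != (len(self.atoms), 3):
            raise ValidationError(
                f"reference_coordinates shape {ref.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(ref)):
            raise ValidationError("reference coordinates must be finite")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValidationError(
                    f"atom indices must be contiguous; atom {i} has index {a.index}"
                )
        self.reference_coordinates = ref
        if native_pairs is not None:
            native_pairs = np.asarray(native_pairs, dtype=int)
            if native_pairs.size and (
                native_pairs.min() < 0 or native_pairs.max() >= len(self.atoms)
            ):
                raise ValidationError("native_pairs indices out of range")
        self.native_pairs = native_pairs
        self._flag_cache: dict[str, np.ndarray] = {}

    # -- cached per-atom flag arrays ------------------------------------
    def _flags(self, attr: str) -> np.ndarray:
        if attr not in self._flag_cache:
            self._flag_cache[attr] = np.array(
                [getattr(a, attr) for a in self.atoms]
            )
        return self._flag_cache[attr]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return 1 + max(a.residue_index for a in self.atoms) if self.atoms else 0

    @property
    def is_solute(self) -> np.ndarray:
        return self._flags("is_solute")

    @property
    def is_mainchain(self) -> np.ndarray:
        return self._flags("is_mainchain")

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self._flags("is_hydrogen")

    @property
    def donor_flag(self) -> np.ndarray:
        return self._flags("donor_flag")

    @property
    def acceptor_flag(self) -> np.ndarray:
        return self._flags("acceptor_flag")

    @property
    def masses(self) -> np.ndarray:
        return self._flags("mass").astype(float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._flags("vdw_radius").astype(float)

    @property
    def residue_indices(self) -> np.ndarray:
        return self._flags("residue_index").astype(int)

    def is_water(self) -> np.ndarray:
        return np.array([a.residue_name in WATER_RESNAMES for a in self.atoms])

    def atom_index(self, residue_index: int, name: str) -> int | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a.index
        return None


class Trajectory:
    """Time-ordered coordinate frames over one :class:`System`.

    ``frames`` is (F, N, 3) in Å, ``times`` (F,) strictly increasing in ps,
    ``box`` either None or (F, 3) orthorhombic box lengths in Å.
    """

    def __init__(self, system: System, frames, times, box=None, metadata=None):
        frames = np.asarray(frames, dtype=float)
        times = np.asarray(times, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != system.n_atoms or frames.shape[2] != 3:
            raise ValidationError(
                f"frames shape {frames.shape} incompatible with "
                f"{system.n_atoms} atoms"
            )
        if frames.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if times.shape != (frames.shape[0],):
            raise ValidationError("times length must equal number of frames")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(frames)):
            raise ValidationError("coordinates must be finite")
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape == (3,):
                box = np.tile(box, (frames.shape[0], 1))
            if box.shape != (frames.shape[0], 3):
                raise ValidationError("box must be (F, 3) or (3,)")
        self.system = system
        self.frames = frames
        self.times = times
        self.box = box
        self.metadata = dict(metadata) if metadata else {}

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (median of successive differences)."""
        if self.n_frames < 2:
            raise ValidationError("dt undefined for a single frame")
        return float(np.median(np.diff(self.times)))


@dataclass
class AnalysisConfig:
    """Analysis cutoffs and conditions.

    Defaults follow common practice for protein trajectory analysis: a
    hydrogen bond requires donor–acceptor distance ≤ 3.5 Å and
    donor–hydrogen–acceptor angle ≥ 120°; a native contact is an atom pair
    closer than 6 Å in the reference structure; SASA uses a 1.4 Å water
    probe; the first hydration shell ends 4.5 Å from protein heavy atoms.
    """

    hb_distance_cutoff: float = 3.5     # Å
    hb_angle_cutoff: float = 120.0      # degrees at the hydrogen
    native_contact_cutoff: float = 6.0  # Å
    sasa_probe_radius: float = 1.4      # Å
    sasa_points_per_atom: int = 960
    hydration_cutoff: float = 4.5       # Å
    surface_sasa_threshold: float = 0.5  # Å² per atom, defines "surface"
    temperature: float = 300.0          # K
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "hb_distance_cutoff", "native_contact_cutoff",
            "sasa_probe_radius", "hydration_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 < self.hb_angle_cutoff <= 180.0):
            raise ValidationError("hb_angle_cutoff must be in (0, 180]")
        if self.sasa_points_per_atom < 60:
            raise ValidationError("sasa_points_per_atom must be >= 60")

    @property
    def kT(self) -> float:
        """Thermal energy kB·T in kJ/mol."""
        return KB_KJ_PER_MOL_K * self.temperature


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``box`` is a length-3 array of orthorhombic box lengths or None (no
    periodicity).
    """
    if box is None:
        return vectors
    return vectors - box * np.round(vectors / box)
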