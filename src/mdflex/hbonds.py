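"""Hydrogen-bond detection and trajectory bookkeeping.

A hydrogen bond is recorded for a (donor, hydrogen, acceptor) triple when the
donor–acceptor distance is at most ``hb_distance_cutoff`` (default 3.5 Å,
inclusive) and the donor–hydrogen–acceptor angle at the hydrogen is at least
``hb_angle_cutoff`` (default 120°, inclusive).  Pairs that are covalently
bonded or share a covalent neighbour (1-2 and 1-3 pairs) are excluded.

Over a trajectory three summary statistics are kept, mirroring the standard
occupancy bookkeeping of MD hydrogen-bond tools:

* the *static* number — the per-frame bond count averaged over frames;
* the *dynamic* number — the count of distinct triples seen in >= 1 frame;
* the *persistency* of each bond — the percentage of frames it exists in.

These satisfy the exact identity  sum_i persistency_i / 100 = static_mean.
Bond identity is the full (donor, hydrogen, acceptor) triple: two hydrogens
of one donor bonding the same acceptor count as two dynamic bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import AnalysisConfig, System, Trajectory, minimum_image
from .pdbio import infer_mainchain_nh

#: side-chain N/O names treated as donors even without an explicit hydrogen
#: (distance-only fallback)
SIDECHAIN_DONOR_NAMES = frozenset(
    {"OG", "OG1", "OH", "NE", "NH1", "NH2", "ND1", "NE2", "NZ", "ND2", "SG"}
)

CLASS_MM = "M-M"
CLASS_MS = "M-S"
CLASS_SS = "S-S"
CLASS_MSOLV = "M-solv"
CLASS_SSOLV = "S-solv"
CLASS_SOLVSOLV = "solv-solv"


@dataclass(frozen=True, order=True)
class HBond:
    """One hydrogen bond; ``hydrogen`` is -1 for distance-only detections."""

    donor: int
    hydrogen: int
    acceptor: int
    class_label: str = field(compare=False, default="")


def classify_pair(system: System, donor: int, acceptor: int) -> str:
    """Class label of a bond from the solute/mainchain flags of its partners.

    Intra-protein bonds are M-M / M-S / S-S by the mainchain flags of both
    partners; protein–solvent bonds are M-solv / S-solv by the protein
    partner's flag.
    """
    da, aa = system.atoms[donor], system.atoms[acceptor]
    if da.is_solute and aa.is_solute:
        if da.is_mainchain and aa.is_mainchain:
            return CLASS_MM
        if da.is_mainchain or aa.is_mainchain:
            return CLASS_MS
        return CLASS_SS
    if not da.is_solute and not aa.is_solute:
        return CLASS_SOLVSOLV
    protein = da if da.is_solute else aa
    return CLASS_MSOLV if protein.is_mainchain else CLASS_SSOLV


def _covalent_neighbors(system: System) -> list[set[int]]:
    """Covalent neighbour sets inferred from reference-coordinate distances."""
    cached = getattr(system, "_covalent_neighbors", None)
    if cached is not None:
        return cached
    ref = system.reference_coordinates
    hyd = system.is_hydrogen
    tree = cKDTree(ref)
    neighbors: list[set[int]] = [set() for _ in range(system.n_atoms)]
    for i, j in tree.query_pairs(1.9):
        cut = 1.25 if (hyd[i] or hyd[j]) else 1.9
        if hyd[i] and hyd[j]:
            continue
        if np.linalg.norm(ref[i] - ref[j]) < cut:
            neighbors[i].add(j)
            neighbors[j].add(i)
    system._covalent_neighbors = neighbors
    return neighbors


def _excluded(neighbors: list[set[int]], d: int, a: int) -> bool:
    if a in neighbors[d]:
        return True
    return bool(neighbors[d] & neighbors[a])


def detect_hbonds_frame(
    frame: np.ndarray,
    system: System,
    config: AnalysisConfig | None = None,
    box: np.ndarray | None = None,
    infer_hydrogens: bool = True,
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame.

    Returns bonds sorted by (donor, hydrogen, acceptor).  Donors are N/O
    atoms with attached hydrogens; mainchain nitrogens lacking one get a
    geometrically inferred amide hydrogen, and known side-chain donor names
    without hydrogens fall back to the distance-only criterion (with a
    warning) unless ``infer_hydrogens`` is False, in which case hydrogen-less
    donors raise :class:`ValidationError`.
    """
    config = config or AnalysisConfig()
    frame = np.asarray(frame, dtype=float)
    neighbors = _covalent_neighbors(system)
    d_cut = config.hb_distance_cutoff
    cos_cut = np.cos(np.deg2rad(config.hb_angle_cutoff))

    # donor list: (donor index, hydrogen index or -1, hydrogen position or None)
    donors: list[tuple[int, int, np.ndarray | None]] = []
    inferred = None
    for a in system.atoms:
        if a.element not in ("N", "O"):
            continue
        if a.attached_hydrogens:
            for h in a.attached_hydrogens:
                donors.append((a.index, h, frame[h]))
        elif a.name == "N" and a.is_solute:
            if not infer_hydrogens:
                raise ValidationError(
                    f"donor {a.index} has no hydrogen and inference is disabled"
                )
            if inferred is None:
                inferred = infer_mainchain_nh(system, frame)
            if a.index in inferred:
                donors.append((a.index, -1, inferred[a.index]))
        elif a.name in SIDECHAIN_DONOR_NAMES:
            if not infer_hydrogens:
                raise ValidationError(
                    f"donor {a.index} has no hydrogen and inference is disabled"
                )
            warnings.warn(
                f"donor atom {a.index} ({a.name}) has no hydrogen; "
                "using distance-only criterion",
                stacklevel=2,
            )
            donors.append((a.index, -1, None))

    acceptor_idx = np.flatnonzero(system.acceptor_flag)
    if len(acceptor_idx) == 0 or not donors:
        return []
    apos = frame[acceptor_idx]
    box_row = None
    if box is not None:
        box_row = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(apos, box_row), boxsize=box_row)
    else:
        tree = cKDTree(apos)

    out: list[HBond] = []
    for d, h, hpos in donors:
        dpos = frame[d]
        query = np.mod(dpos, box_row) if box_row is not None else dpos
        for local in tree.query_ball_point(query, d_cut):
            a = int(acceptor_idx[local])
            if a == d or _excluded(neighbors, d, a):
                continue
            dvec = minimum_image(frame[a] - dpos, box_row)
            if np.linalg.norm(dvec) > d_cut:
                continue
            if hpos is not None:
                v1 = minimum_image(dpos - hpos, box_row)
                v2 = minimum_image(frame[a] - hpos, box_row)
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cos_angle = float(np.dot(v1, v2)) / denom
                if cos_angle > cos_cut:  # angle below cutoff
                    continue
            out.append(HBond(d, h, a, classify_pair(system, d, a)))
    out.sort()
    return out


@dataclass
class HBondStats:
    """Trajectory-level hydrogen-bond statistics for one scope."""

    scope: str
    n_frames: int
    static_mean: float
    static_sd: float
    dynamic_count: int
    persistency: dict[HBond, float]          # percent of frames, per bond
    mean_persistency: float                  # percent, averaged over bonds
    class_counts: dict[str, int]
    class_mean_persistency: dict[str, float]
    per_frame_counts: np.ndarray = None

    def to_frame(self):
        """Per-bond persistency as a pandas DataFrame."""
        import pandas as pd

        rows = [
            (b.donor, b.hydrogen, b.acceptor, b.class_label, p)
            for b, p in sorted(self.persistency.items())
        ]
        return pd.DataFrame(
            rows, columns=["donor", "hydrogen", "acceptor", "class", "persistency_pct"]
        )


_SCOPES = ("intra-protein", "protein-solvent")


def hbond_statistics(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    scope: str = "intra-protein",
) -> HBondStats:
    """Static/dynamic/persistency statistics over a trajectory.

    ``scope`` selects intra-protein bonds (both partners solute) or
    protein–solvent bonds (exactly one partner solute); water–water bonds
    are never counted.
    """
    if scope not in _SCOPES:
        raise ValidationError(f"scope must be one of {_SCOPES}")
    system = traj.system
    if scope == "protein-solvent" and bool(np.all(system.is_solute)):
        raise ValidationError("protein-solvent scope requires solvent atoms")
    config = config or AnalysisConfig()
    solute = system.is_solute

    registry: dict[HBond, int] = {}
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        bonds = detect_hbonds_frame(traj.frames[f], system, config, box=box)
        for b in bonds:
            both_solute = solute[b.donor] and solute[b.acceptor]
            if scope == "intra-protein" and not both_solute:
                continue
            if scope == "protein-solvent" and (
                both_solute or (not solute[b.donor] and not solute[b.acceptor])
            ):
                continue
            registry[b] = registry.get(b, 0) + 1
            counts[f] += 1

    persistency = {b: 100.0 * n / traj.n_frames for b, n in registry.items()}
    class_counts: dict[str, int] = {}
    class_p: dict[str, list[float]] = {}
    for b, p in persistency.items():
        class_counts[b.class_label] = class_counts.get(b.class_label, 0) + 1
        class_p.setdefault(b.class_label, []).append(p)
    return HBondStats(
        scope=scope,
        n_frames=traj.n_frames,
        static_mean=float(counts.mean()),
        static_sd=float(counts.std()),
        dynamic_count=len(persistency),
        persistency=persistency,
        mean_persistency=(
            float(np.mean(list(persistency.values()))) if persistency else 0.0
        ),
        class_counts=class_counts,
        class_mean_persistency={c: float(np.mean(v)) for c, v in class_p.items()},
        per_frame_counts=counts,
    )


def implied_static_mean(dynamic_count: int, mean_persistency_pct: float) -> float:
    """Static mean implied by the persistency identity.

    Rearranges  static_mean = sum_i persistency_i/100
              = dynamic_count * mean_persistency/100.
    """
    return dynamic_count * mean_persistency_pct / 100.0
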