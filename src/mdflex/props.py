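"""Structural property calculators and table comparison arithmetic.

Covers the per-frame quantities typically tabulated for a protein
trajectory — backbone RMSD to the starting structure, total SASA, number of
native contacts (NNC), radius of gyration, secondary-structure residue
counts — plus the percent-change / fold-change arithmetic used to compare
conditions:

    percent_change = 100 * (b - a) / a
    fold_change    = (b - a) / a        (a 3.64-fold *increase*)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, MDFlexError, ValidationError
from .model import AnalysisConfig, System, Trajectory
from .select import select_atoms

BACKBONE_RMSD_NAMES = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose_rmsd(mobile, reference, selection=None):
    """Optimal rigid-body superposition (Kabsch) and the resulting RMSD.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    selected atoms.  The rotation is proper (det = +1).  A collinear or
    < 3-point selection raises :class:`DegenerateGeometryError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atoms")
    x = mobile[sel]
    y = reference[sel]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    if np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise DegenerateGeometryError("selection is collinear or degenerate")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def fit_frames(frames, reference, selection=None):
    """Superpose every frame onto ``reference`` over ``selection``.

    Returns the fitted (F, N, 3) array; the transform is computed on the
    selection and applied to all atoms.
    """
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        rot, trans, _ = kabsch_superpose_rmsd(frames[f], reference, selection)
        out[f] = frames[f] @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# scalar per-frame properties
# ---------------------------------------------------------------------------

def radius_of_gyration(frame, selection=None, masses=None) -> float:
    """Mass-weighted radius of gyration in Å (geometric if masses is None)."""
    frame = np.asarray(frame, dtype=float)
    sel = np.arange(len(frame)) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValidationError("empty selection")
    r = frame[sel]
    m = np.ones(sel.size) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValidationError("total mass must be > 0")
    com = (m[:, None] * r).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((r - com) ** 2, axis=1)).sum() / total))


def build_native_pairs(system: System, cutoff: float = 6.0) -> np.ndarray:
    """Native contact pairs from the reference structure.

    All solute heavy-atom pairs i < j in different residues closer than
    ``cutoff`` (strict) in the reference coordinates.
    """
    heavy = np.flatnonzero(system.is_solute & ~system.is_hydrogen)
    ref = system.reference_coordinates[heavy]
    resid = system.residue_indices[heavy]
    tree = cKDTree(ref)
    pairs = []
    for i, j in tree.query_pairs(cutoff):
        if resid[i] == resid[j]:
            continue
        if np.linalg.norm(ref[i] - ref[j]) < cutoff:
            pairs.append((heavy[min(i, j)], heavy[max(i, j)]))
    pairs.sort()
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def native_contact_count(frame, native_pairs, cutoff: float = 6.0) -> int:
    """Count native pairs closer than ``cutoff`` (strict) in ``frame``."""
    if native_pairs is None:
        raise MDFlexError(
            "native_pairs not built; call build_native_pairs on the reference"
        )
    native_pairs = np.asarray(native_pairs)
    if native_pairs.size == 0:
        return 0
    frame = np.asarray(frame, dtype=float)
    d = np.linalg.norm(frame[native_pairs[:, 0]] - frame[native_pairs[:, 1]], axis=1)
    return int(np.count_nonzero(d < cutoff))


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(frame, radii, probe: float = 1.4, n_points: int = 960):
    """Per-atom solvent-accessible surface area (Shrake–Rupley), Å².

    Each atom's solvent-accessible sphere (radius r_i + probe) is sampled
    with a deterministic golden-spiral point set; a point is exposed when no
    other atom's accessible sphere covers it.  Per-atom area =
    exposed fraction × 4π(r_i + probe)².
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValidationError("radii must be > 0")
    if n_points < 60:
        raise ValidationError("n_points must be >= 60")
    n = len(frame)
    sphere = _golden_spiral(n_points)
    acc = radii + probe
    tree = cKDTree(frame)
    areas = np.zeros(n)
    max_acc = acc.max()
    for i in range(n):
        pts = frame[i] + acc[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(frame[i], acc[i] + max_acc):
            if j == i:
                continue
            d = np.linalg.norm(pts - frame[j], axis=1)
            exposed &= d >= acc[j]
        areas[i] = exposed.mean() * 4.0 * np.pi * acc[i] ** 2
    return areas


# ---------------------------------------------------------------------------
# secondary structure (minimal DSSP)
# ---------------------------------------------------------------------------

_KS_COUPLING = 332.0 * 0.42 * 0.20  # kcal/mol·Å, Kabsch–Sander constant
_KS_CUTOFF = -0.5  # kcal/mol


def _backbone_hbond_matrix(frame, system: System) -> np.ndarray:
    """hb[i, j] True when the C=O of residue i accepts from the N–H of j."""
    n_res = system.n_residues
    atom = system.atom_index
    N = {r: atom(r, "N") for r in range(n_res)}
    CA = {r: atom(r, "CA") for r in range(n_res)}
    C = {r: atom(r, "C") for r in range(n_res)}
    O = {r: atom(r, "O") for r in range(n_res)}
    H: dict[int, np.ndarray | None] = {}
    for r in range(n_res):
        h_idx = atom(r, "H")
        if h_idx is not None:
            H[r] = frame[h_idx]
        elif r > 0 and None not in (N[r], C[r - 1], O[r - 1]):
            # DSSP convention: N-H anti-parallel to the previous C=O
            d = frame[C[r - 1]] - frame[O[r - 1]]
            H[r] = frame[N[r]] + d / np.linalg.norm(d)
        else:
            H[r] = None
    hb = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        if None in (C[i], O[i]):
            continue
        for j in range(n_res):
            if abs(i - j) < 2 or N[j] is None or H[j] is None:
                continue
            r_on = np.linalg.norm(frame[O[i]] - frame[N[j]])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(frame[C[i]] - H[j])
            r_oh = np.linalg.norm(frame[O[i]] - H[j])
            r_cn = np.linalg.norm(frame[C[i]] - frame[N[j]])
            energy = _KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            hb[i, j] = energy < _KS_CUTOFF
    return hb


def assign_secondary_structure(frame, system: System) -> list[str]:
    """Per-residue labels in {H, G, E, T, C} from backbone hydrogen bonds.

    A Kabsch–Sander backbone H-bond i→j (acceptor C=O of i, donor N–H of j)
    exists when the electrostatic energy is below −0.5 kcal/mol.  Two
    consecutive i→i+4 turns make an α-helix (H), two consecutive i→i+3
    turns a 3₁₀ helix (G), bridge patterns make strand (E), isolated turns
    T, and everything else coil (C).  Priority H > E > G > T.
    """
    n_res = system.n_residues
    if n_res < 3:
        import warnings

        warnings.warn("chain shorter than 3 residues; all coil", stacklevel=2)
        return ["C"] * n_res
    hb = _backbone_hbond_matrix(np.asarray(frame, dtype=float), system)

    turn4 = np.array([hb[i, i + 4] if i + 4 < n_res else False for i in range(n_res)])
    turn3 = np.array([hb[i, i + 3] if i + 3 < n_res else False for i in range(n_res)])

    labels = np.array(["C"] * n_res, dtype="<U1")

    # turns first (lowest priority), from any isolated i->i+3 / i->i+4 bond
    for i in range(n_res):
        if turn4[i]:
            labels[i + 1: i + 4] = np.where(
                labels[i + 1: i + 4] == "C", "T", labels[i + 1: i + 4]
            )
        if turn3[i]:
            labels[i + 1: i + 3] = np.where(
                labels[i + 1: i + 3] == "C", "T", labels[i + 1: i + 3]
            )

    # 3-10 helix: two consecutive i->i+3 turns cover residues i+1..i+3
    for i in range(n_res - 1):
        if turn3[i] and turn3[i + 1]:
            labels[i + 1: i + 4] = "G"

    # strand: parallel / antiparallel bridges
    bridge = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(1, n_res - 1):
            if abs(i - j) < 3:
                continue
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (
                hb[j - 1, i] and hb[i, j + 1]
            )
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or anti:
                bridge[i] = True
                bridge[j] = True
    labels[bridge] = "E"

    # alpha helix (highest priority): two consecutive i->i+4 turns
    for i in range(n_res - 1):
        if turn4[i] and turn4[i + 1]:
            labels[i + 1: i + 5] = "H"

    return list(labels)


# ---------------------------------------------------------------------------
# trajectory-level table + comparison arithmetic
# ---------------------------------------------------------------------------

@dataclass
class StructuralPropertyTable:
    """Per-trajectory means and standard deviations of the table properties."""

    label: str
    rmsd_mean: float = np.nan
    rmsd_sd: float = 0.0
    sasa_mean: float = np.nan
    sasa_sd: float = 0.0
    nnc_mean: float = np.nan
    nnc_sd: float = 0.0
    rg_mean: float = np.nan
    rg_sd: float = 0.0
    sse_helix_mean: float = np.nan
    sse_helix_sd: float = 0.0
    sse_sheet_mean: float = np.nan
    sse_sheet_sd: float = 0.0
    sse_turn_mean: float = np.nan
    sse_turn_sd: float = 0.0
    tmsf: float = np.nan  # Å²; optional, filled when ED has been run

    @property
    def sse_total_mean(self) -> float:
        return self.sse_helix_mean + self.sse_sheet_mean + self.sse_turn_mean

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PropertyDelta:
    """Relative change of one property between two conditions."""

    property_name: str
    from_label: str
    to_label: str
    percent_change: float
    fold_change: float


def property_table(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    label: str = "",
    compute_sasa: bool = True,
    compute_sse: bool = True,
) -> StructuralPropertyTable:
    """Frame-averaged structural properties of a trajectory.

    RMSD is the backbone (N, CA, C, O) deviation from the reference
    structure after Kabsch fitting; Rg is mass-weighted over solute atoms;
    NNC recounts the reference-derived native pairs; SASA is summed over
    solute heavy atoms; SSE counts use the minimal DSSP labels with
    helix = H + G, sheet = E, turn = T.
    """
    config = config or AnalysisConfig()
    system = traj.system
    backbone = select_atoms(
        system, "name " + " ".join(BACKBONE_RMSD_NAMES) + " and solute"
    )
    solute = np.flatnonzero(system.is_solute)
    heavy_solute = np.flatnonzero(system.is_solute & ~system.is_hydrogen)
    if system.native_pairs is None:
        system.native_pairs = build_native_pairs(
            system, config.native_contact_cutoff
        )
    ref = system.reference_coordinates
    masses = system.masses[solute]
    radii = system.vdw_radii[heavy_solute]

    rmsd = np.empty(traj.n_frames)
    rg = np.empty(traj.n_frames)
    nnc = np.empty(traj.n_frames)
    sasa = np.full(traj.n_frames, np.nan)
    helix = np.full(traj.n_frames, np.nan)
    sheet = np.full(traj.n_frames, np.nan)
    turn = np.full(traj.n_frames, np.nan)
    for f, frame in enumerate(traj.frames):
        _, _, rmsd[f] = kabsch_superpose_rmsd(frame, ref, backbone)
        rg[f] = radius_of_gyration(frame, solute, masses)
        nnc[f] = native_contact_count(
            frame, system.native_pairs, config.native_contact_cutoff
        )
        if compute_sasa:
            sasa[f] = shrake_rupley_sasa(
                frame[heavy_solute], radii, config.sasa_probe_radius,
                config.sasa_points_per_atom,
            ).sum()
        if compute_sse:
            labels = assign_secondary_structure(frame, system)
            helix[f] = labels.count("H") + labels.count("G")
            sheet[f] = labels.count("E")
            turn[f] = labels.count("T")

    def ms(x):
        return (float(np.nanmean(x)), float(np.nanstd(x))) if not np.all(
            np.isnan(x)
        ) else (np.nan, 0.0)

    vals = {}
    for name, series in [
        ("rmsd", rmsd), ("sasa", sasa), ("nnc", nnc), ("rg", rg),
        ("sse_helix", helix), ("sse_sheet", sheet), ("sse_turn", turn),
    ]:
        vals[f"{name}_mean"], vals[f"{name}_sd"] = ms(series)
    return StructuralPropertyTable(label=label, **vals)


_COMPARED_PROPERTIES = ("rmsd", "sasa", "nnc", "rg", "sse", "tmsf")


def compare_tables(a: StructuralPropertyTable, b: StructuralPropertyTable):
    """Percent and fold changes from table ``a`` to table ``b``.

    The SSE change is computed on the total helix + sheet + turn residue
    count.  Properties that are NaN in either table are skipped; a zero
    ``a``-value with nonzero ``b`` raises.
    """
    deltas = []
    for prop in _COMPARED_PROPERTIES:
        if prop == "sse":
            va, vb = a.sse_total_mean, b.sse_total_mean
        elif prop == "tmsf":
            va, vb = a.tmsf, b.tmsf
        else:
            va, vb = getattr(a, f"{prop}_mean"), getattr(b, f"{prop}_mean")
        if np.isnan(va) or np.isnan(vb):
            continue
        if va == 0:
            if vb != 0:
                raise MDFlexError(
                    f"{prop}: percent change undefined for zero baseline"
                )
            continue
        rel = (vb - va) / va
        deltas.append(
            PropertyDelta(prop, a.label, b.label, 100.0 * rel, rel)
        )
    return deltas


def tables_to_csv(tables: list[StructuralPropertyTable]) -> str:
    """Serialise property tables to CSV (one row per condition label)."""
    import pandas as pd

    return pd.DataFrame([t.to_dict() for t in tables]).to_csv(index=False)
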