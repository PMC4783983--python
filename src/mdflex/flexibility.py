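"""Per-residue RMSF and flexibility as a function of burial depth.

RMSF_i = sqrt(<|r_i(t) − <r_i>|²>) after fitting every frame to a reference.
The burial-depth profile bins residues by the distance from their Cα (on
the trajectory mean structure) to the nearest solvent-exposed atom, where
"exposed" means per-atom SASA above a small threshold (default 0.5 Å²,
probe 1.4 Å); surface residues have depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import AnalysisConfig, Trajectory
from .props import fit_frames, shrake_rupley_sasa
from .select import select_atoms


@dataclass
class FlexibilityProfile:
    residue_indices: np.ndarray   # residues carrying a Cα
    rmsf: np.ndarray              # Å, per residue
    depth: np.ndarray             # Å, per residue
    depth_bin_edges: np.ndarray   # (n_bins + 1,)
    depth_profile: np.ndarray     # mean RMSF per bin; NaN where empty
    bin_occupancy: np.ndarray     # residues per bin
    bin_of_residue: np.ndarray    # bin index per residue


def per_residue_rmsf(
    traj: Trajectory, selection=None, fit_reference=None
) -> tuple[np.ndarray, np.ndarray]:
    """Cα RMSF per residue after superposition.

    Returns ``(residue_indices, rmsf)``.  ``selection`` defaults to solute
    Cα atoms and must contain at most one atom per residue.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs >= 2 frames")
    system = traj.system
    if selection is None:
        selection = select_atoms(system, "name CA and solute")
    selection = np.asarray(selection, dtype=int)
    if fit_reference is None:
        fit_reference = system.reference_coordinates
    fitted = fit_frames(traj.frames, fit_reference, selection)[:, selection, :]
    mean = fitted.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    residues = system.residue_indices[selection]
    if len(np.unique(residues)) != len(residues):
        raise ValidationError("selection must contain one atom per residue")
    return residues, rmsf


def rmsf_depth_profile(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    n_bins: int = 5,
    selection=None,
) -> FlexibilityProfile:
    """Mean RMSF as a function of burial depth on the mean structure.

    Depth is measured once, on the trajectory mean structure (after
    fitting): the distance from each residue's Cα to the nearest
    solvent-exposed heavy atom.  Residues are binned into ``n_bins``
    equal-width depth bins; empty bins are reported as NaN, never zero.
    """
    config = config or AnalysisConfig()
    system = traj.system
    if selection is None:
        selection = select_atoms(system, "name CA and solute")
    residues, rmsf = per_residue_rmsf(traj, selection)

    fitted = fit_frames(
        traj.frames, system.reference_coordinates, np.asarray(selection)
    )
    mean_structure = fitted.mean(axis=0)
    heavy = np.flatnonzero(system.is_solute & ~system.is_hydrogen)
    sasa = shrake_rupley_sasa(
        mean_structure[heavy], system.vdw_radii[heavy],
        config.sasa_probe_radius, config.sasa_points_per_atom,
    )
    surface = heavy[sasa > config.surface_sasa_threshold]
    if surface.size == 0:
        raise ValidationError("no surface atoms found (threshold too high?)")
    tree = cKDTree(mean_structure[surface])
    ca_pos = mean_structure[np.asarray(selection)]
    depth, _ = tree.query(ca_pos)

    max_depth = depth.max()
    edges = np.linspace(0.0, max_depth if max_depth > 0 else 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(depth, edges[1:-1]), 0, n_bins - 1)
    profile = np.full(n_bins, np.nan)
    occupancy = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = bin_of == b
        occupancy[b] = mask.sum()
        if occupancy[b]:
            profile[b] = rmsf[mask].mean()
    return FlexibilityProfile(
        residue_indices=residues,
        rmsf=rmsf,
        depth=depth,
        depth_bin_edges=edges,
        depth_profile=profile,
        bin_occupancy=occupancy,
        bin_of_residue=bin_of,
    )
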