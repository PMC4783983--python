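"""Solvent mean-square displacement and hydration-shell classification.

MSD(τ) is averaged over molecules and sliding time origins after unwrapping
coordinates across periodic images (minimum-image displacement
accumulation).  Freely diffusing water gives a linear MSD with slope
2·d·D; structurally arrested (glass-like) water shows an initial rise
followed by a plateau.  Waters are classed "hydration" when their oxygen
lies within a cutoff (default 4.5 Å) of any protein heavy atom, else
"bulk".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import AnalysisConfig, System, Trajectory, minimum_image


@dataclass
class MSDCurve:
    lag_times: np.ndarray           # ps
    msd: np.ndarray                 # Å²
    subset: str                     # {"hydration", "bulk", "all"}
    diffusion_coefficient: float    # Å²/ps, from the linear fit window
    n_dims: int = 3


def _unwrap(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Continuous coordinates for ``selection`` across periodic images."""
    pos = traj.frames[:, selection, :]
    if traj.box is None:
        return pos.copy()
    out = np.empty_like(pos)
    out[0] = pos[0]
    for f in range(1, traj.n_frames):
        step = minimum_image(pos[f] - pos[f - 1], traj.box[f])
        out[f] = out[f - 1] + step
    return out


def unwrap_msd(
    traj: Trajectory,
    selection,
    max_lag: int,
    fit_window: tuple[int, int] | None = None,
    subset: str = "all",
) -> MSDCurve:
    """MSD over sliding time origins, plus a diffusion-coefficient fit.

    ``max_lag`` counts frames and must be below the trajectory length.
    D = slope / (2·3) from a straight-line fit of MSD(τ) over
    ``fit_window`` (lag-index range, default the upper half of the lags).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValidationError("empty selection")
    if max_lag >= traj.n_frames:
        raise ValidationError("max_lag must be < number of frames")
    coords = _unwrap(traj, selection)
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    for m in lags[1:]:
        disp = coords[m:] - coords[:-m]
        msd[m] = np.mean(np.sum(disp ** 2, axis=2))
    dt = traj.dt
    lag_times = lags * dt
    if fit_window is None:
        fit_window = (max(1, max_lag // 2), max_lag)
    lo, hi = fit_window
    slope = np.polyfit(lag_times[lo:hi + 1], msd[lo:hi + 1], 1)[0]
    return MSDCurve(
        lag_times=lag_times, msd=msd, subset=subset,
        diffusion_coefficient=float(slope / 6.0),
    )


def water_oxygen_indices(system: System) -> np.ndarray:
    """Indices of water oxygen atoms (one per water molecule)."""
    idx = [
        a.index
        for a in system.atoms
        if not a.is_solute and a.element == "O" and a.residue_name in
        ("HOH", "SOL", "WAT")
    ]
    return np.asarray(idx, dtype=int)


def classify_hydration(
    frame, system: System, cutoff: float = 4.5, box=None
) -> tuple[np.ndarray, np.ndarray]:
    """Partition water molecules into hydration shell and bulk.

    A water is "hydration" iff its oxygen is within ``cutoff`` of any
    protein heavy atom (minimum image when a box is given).  Returns
    ``(hydration_oxygens, bulk_oxygens)`` — an exhaustive, exclusive
    partition of the water oxygen indices.
    """
    waters = water_oxygen_indices(system)
    if waters.size == 0:
        raise ValidationError("system contains no water molecules")
    frame = np.asarray(frame, dtype=float)
    protein = np.flatnonzero(system.is_solute & ~system.is_hydrogen)
    ppos = frame[protein]
    wpos = frame[waters]
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(ppos, box), boxsize=box)
        d, _ = tree.query(np.mod(wpos, box))
    else:
        tree = cKDTree(ppos)
        d, _ = tree.query(wpos)
    hyd = d <= cutoff
    return waters[hyd], waters[~hyd]


def hydration_bulk_msd(
    traj: Trajectory,
    max_lag: int,
    config: AnalysisConfig | None = None,
    mode: str = "per-origin",
    fit_window: tuple[int, int] | None = None,
) -> dict[str, MSDCurve]:
    """Hydration-shell vs bulk MSD curves (plus the joint "all" curve).

    With ``mode="per-origin"`` each time origin classifies waters afresh
    (waters may change shell between origins); ``mode="initial"`` fixes the
    class at the first frame.  The occupancy-weighted average of the two
    subset curves equals the joint curve by construction.
    """
    if mode not in ("per-origin", "initial"):
        raise ValidationError("mode must be 'per-origin' or 'initial'")
    config = config or AnalysisConfig()
    system = traj.system
    waters = water_oxygen_indices(system)
    if waters.size == 0:
        raise ValidationError("system contains no water molecules")
    if max_lag >= traj.n_frames:
        raise ValidationError("max_lag must be < number of frames")
    coords = _unwrap(traj, waters)
    pos_of = {w: i for i, w in enumerate(waters)}

    sums = {"hydration": np.zeros(max_lag + 1), "bulk": np.zeros(max_lag + 1)}
    counts = {"hydration": np.zeros(max_lag + 1), "bulk": np.zeros(max_lag + 1)}
    box0 = traj.box[0] if traj.box is not None else None
    if mode == "initial":
        hyd0, _ = classify_hydration(
            traj.frames[0], system, config.hydration_cutoff, box0
        )
        hyd_mask0 = np.isin(waters, hyd0)
    for t0 in range(traj.n_frames - 1):
        if mode == "per-origin":
            box = traj.box[t0] if traj.box is not None else None
            hyd, _ = classify_hydration(
                traj.frames[t0], system, config.hydration_cutoff, box
            )
            hyd_mask = np.isin(waters, hyd)
        else:
            hyd_mask = hyd_mask0
        top = min(max_lag, traj.n_frames - 1 - t0)
        disp = coords[t0 + 1: t0 + top + 1] - coords[t0]
        sq = np.sum(disp ** 2, axis=2)  # (top, n_waters)
        for label, mask in (("hydration", hyd_mask), ("bulk", ~hyd_mask)):
            if mask.any():
                sums[label][1: top + 1] += sq[:, mask].sum(axis=1)
                counts[label][1: top + 1] += mask.sum()
    dt = traj.dt
    lag_times = np.arange(max_lag + 1) * dt
    out: dict[str, MSDCurve] = {}
    joint_sum = sums["hydration"] + sums["bulk"]
    joint_count = counts["hydration"] + counts["bulk"]
    for label in ("hydration", "bulk"):
        with np.errstate(invalid="ignore"):
            msd = np.where(counts[label] > 0, sums[label] / np.maximum(counts[label], 1), 0.0)
        out[label] = _fit_curve(lag_times, msd, label, fit_window, max_lag)
    joint = np.where(joint_count > 0, joint_sum / np.maximum(joint_count, 1), 0.0)
    out["all"] = _fit_curve(lag_times, joint, "all", fit_window, max_lag)
    return out


def _fit_curve(lag_times, msd, label, fit_window, max_lag):
    if fit_window is None:
        fit_window = (max(1, max_lag // 2), max_lag)
    lo, hi = fit_window
    slope = np.polyfit(lag_times[lo:hi + 1], msd[lo:hi + 1], 1)[0]
    return MSDCurve(lag_times=lag_times, msd=msd, subset=label,
                    diffusion_coefficient=float(slope / 6.0))
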