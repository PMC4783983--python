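"""Essential dynamics: covariance eigendecomposition of atomic fluctuations.

Every frame is least-squares fitted to a reference (by default the starting
structure) on the analysis selection, then the 3n × 3n Cartesian covariance

    C = < (x - <x>) (x - <x>)^T >        (population normalisation, 1/F)

is diagonalised.  Eigenvectors are collective motion directions, eigenvalues
their variances (Å²); the total mean-square fluctuation (TMSF) is the trace,
i.e. the sum of eigenvalues.  No mass weighting is applied — the intended
selection is the Cα set.

The cosine content of a projection p(t) on eigenvector k,

    c_k = (2/T) ( ∫ cos(kπt/T) p(t) dt )²  /  ∫ p(t)² dt,

is a sampling-convergence diagnostic: values near 1 mean the projection
resembles a half-period cosine, the hallmark of random diffusion
(unconverged sampling); values near 0 indicate converged sampling.

Combined ED concatenates two trajectories fitted to a common reference and
diagonalises the joint covariance; per-half projection means and
mean-square displacements (about the combined mean) quantify conformational
shifts between the two simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import A2_PER_NM2, Trajectory
from .props import fit_frames

__all__ = [
    "EDResult", "ProjectionStats", "ed_decompose", "project",
    "projection_extremes", "cosine_content", "combined_ed",
]


@dataclass
class EDResult:
    """Eigendecomposition of the fitted-fluctuation covariance."""

    selection: np.ndarray          # atom indices the ED was computed on
    fit_reference: np.ndarray      # (n, 3) reference used for fitting
    mean_structure: np.ndarray     # (n, 3) mean of the fitted selection
    eigenvectors: np.ndarray       # (3n, 3n), columns, descending eigenvalue
    eigenvalues: np.ndarray        # (3n,), Å², descending, >= 0

    @property
    def eigenvalues_nm2(self) -> np.ndarray:
        return self.eigenvalues / A2_PER_NM2

    @property
    def tmsf(self) -> float:
        """Total mean-square fluctuation in Å² (trace of the covariance)."""
        return float(self.eigenvalues.sum())

    @property
    def tmsf_nm2(self) -> float:
        return self.tmsf / A2_PER_NM2


@dataclass
class ProjectionStats:
    """Per-half projection statistics from a combined-ED analysis."""

    n_vectors: int
    means: np.ndarray          # (2, K) per-half projection means, Å
    msds: np.ndarray           # (2, K) per-half mean square displacement, Å²
    histograms: list           # per k: (edges, counts_half_A, counts_half_B)
    cosine_contents: np.ndarray  # (K,) of the full combined projection


def _fitted_selection(traj: Trajectory, selection, fit_reference):
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ValidationError("ED selection needs >= 3 atoms")
    if fit_reference is None:
        fit_reference = traj.system.reference_coordinates
    fitted = fit_frames(traj.frames, fit_reference, selection)
    return fitted[:, selection, :], np.asarray(fit_reference, dtype=float)


def ed_decompose(
    traj: Trajectory, selection, fit_reference=None
) -> EDResult:
    """Diagonalise the covariance of fitted atomic fluctuations.

    ``fit_reference`` defaults to the system's reference (starting)
    structure.  Eigenvalues are sorted descending and clipped at 0;
    each eigenvector's largest-magnitude component is made positive
    (deterministic sign convention).
    """
    if traj.n_frames < 2:
        raise ValidationError("ED needs >= 2 frames")
    coords, ref = _fitted_selection(traj, selection, fit_reference)
    x = coords.reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    dx = x - mean
    cov = (dx.T @ dx) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        imax = np.argmax(np.abs(evecs[:, k]))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return EDResult(
        selection=np.asarray(selection, dtype=int),
        fit_reference=ref,
        mean_structure=mean.reshape(-1, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
    )


def project(traj: Trajectory, ed: EDResult, k: int) -> np.ndarray:
    """Projection time series p_k(t) = v_k · (x_fit(t) − <x>), Å."""
    if not (0 <= k < ed.eigenvectors.shape[1]):
        raise IndexError(f"eigenvector index {k} out of range")
    coords, _ = _fitted_selection(traj, ed.selection, ed.fit_reference)
    dx = coords.reshape(traj.n_frames, -1) - ed.mean_structure.reshape(-1)
    return dx @ ed.eigenvectors[:, k]


def projection_extremes(
    traj: Trajectory, ed: EDResult, k: int, n_interpolants: int = 0
):
    """Frames attaining min/max projection on eigenvector k, plus linear
    Cartesian interpolants between them.

    Returns ``(frame_min_index, frame_max_index, structures)`` where
    ``structures`` is an (n_interpolants + 2, N, 3) array running from the
    minimum-projection frame to the maximum-projection frame.
    """
    p = project(traj, ed, k)
    i_min = int(np.argmin(p))
    i_max = int(np.argmax(p))
    fitted = fit_frames(traj.frames, ed.fit_reference, ed.selection)
    a, b = fitted[i_min], fitted[i_max]
    ts = np.linspace(0.0, 1.0, n_interpolants + 2)
    structures = np.array([(1 - t) * a + t * b for t in ts])
    return i_min, i_max, structures


def cosine_content(series: np.ndarray, k: int = 1) -> float:
    """Cosine content c_k ∈ [0, 1] of a projection series.

    Mean-centres the series internally and discretises the defining
    integrals with the trapezoid rule.  An all-zero (constant) series has
    no defined cosine content and raises :class:`ValidationError`.
    """
    p = np.asarray(series, dtype=float)
    if p.ndim != 1 or p.size < 4:
        raise ValidationError("series must be 1-D with >= 4 samples")
    if k < 1:
        raise ValidationError("k must be >= 1")
    p = p - p.mean()
    denom_int = np.trapezoid(p * p, dx=1.0)
    if denom_int == 0:
        raise ValidationError("cosine content undefined for a constant series")
    t = np.linspace(0.0, 1.0, p.size)  # scale cancels in the ratio
    cos_kt = np.cos(k * np.pi * t)
    num = np.trapezoid(cos_kt * p, dx=1.0)
    c = 2.0 / (p.size - 1) * num * num / denom_int
    return float(min(max(c, 0.0), 1.0))


def combined_ed(
    trajA: Trajectory,
    trajB: Trajectory,
    selection,
    fit_reference=None,
    n_vectors: int = 30,
    n_bins: int = 50,
):
    """ED of the concatenation of two trajectories plus per-half statistics.

    Both trajectories are fitted to a common reference (default: trajA's
    starting reference).  For each of the first ``n_vectors`` combined
    eigenvectors the per-half projection mean and mean square displacement
    msd_h(k) = < p_k² >_h are computed with projections centred on the
    *combined* mean, so the MSD captures both the conformational shift
    between halves and the fluctuation within each half.
    """
    if trajA.n_atoms != trajB.n_atoms:
        raise ValidationError("trajectories must share one atom set")
    if fit_reference is None:
        fit_reference = trajA.system.reference_coordinates
    frames = np.concatenate([trajA.frames, trajB.frames], axis=0)
    dt = trajA.dt if trajA.n_frames > 1 else 1.0
    times = dt * (1.0 + np.arange(len(frames)))
    joint = Trajectory(trajA.system, frames, times)
    ed = ed_decompose(joint, selection, fit_reference)

    n_vectors = min(n_vectors, ed.eigenvectors.shape[1])
    nA = trajA.n_frames
    means = np.empty((2, n_vectors))
    msds = np.empty((2, n_vectors))
    histograms = []
    ccs = np.empty(n_vectors)
    for k in range(n_vectors):
        p = project(joint, ed, k)
        pA, pB = p[:nA], p[nA:]
        means[0, k], means[1, k] = pA.mean(), pB.mean()
        msds[0, k], msds[1, k] = np.mean(pA ** 2), np.mean(pB ** 2)
        edges = np.histogram_bin_edges(p, bins=n_bins)
        histograms.append(
            (edges, np.histogram(pA, bins=edges, density=True)[0],
             np.histogram(pB, bins=edges, density=True)[0])
        )
        ccs[k] = cosine_content(p, 1)
    stats = ProjectionStats(
        n_vectors=n_vectors, means=means, msds=msds,
        histograms=histograms, cosine_contents=ccs,
    )
    return ed, stats
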