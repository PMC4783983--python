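"""Free-energy landscapes: histogram inversion and well-tempered metadynamics.

Two reconstruction routes are provided:

* Boltzmann inversion of a sampled collective-variable (CV) histogram,
  F_b = −kT · ln(n_b / n_max), with empty bins masked (not set to zero);

* a toy overdamped-Langevin sampler on analytic 1-D/2-D potentials plus a
  well-tempered metadynamics engine.  At each deposition a Gaussian hill of
  width σ and height w = w₀ · exp(−V_bias(s) / ((γ−1) kT)) is added at the
  current CV value; the free-energy estimate is
  F̂(s) = −γ/(γ−1) · V_bias(s) + C with C fixed so min F̂ = 0.

Default metadynamics parameters follow common practice for eigenvector-
projection CVs: initial hill height 0.4 kJ/mol deposited every 2 ps, hill
width 0.35 nm, bias factor 10.  The bias potential and its gradient are
kept on a grid (bin width σ/5) so per-step cost is O(1) in the number of
hills; the grid-interpolation error is far below the hill height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrationError, ValidationError
from .model import KB_KJ_PER_MOL_K


@dataclass
class FreeEnergySurface:
    """Gridded free energy over one or two CVs, minimum shifted to zero."""

    cv_grid: np.ndarray | tuple        # bin centres; tuple of two axes in 2-D
    free_energy: np.ndarray            # kJ/mol (or caller units); NaN = unvisited
    kT: float
    mask: np.ndarray = None            # True where the bin is empty

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.isnan(self.free_energy)

    @property
    def occupied_min(self) -> float:
        return float(np.nanmin(self.free_energy))

    @property
    def occupied_max(self) -> float:
        return float(np.nanmax(self.free_energy))


@dataclass
class MetadynamicsParams:
    """Well-tempered metadynamics parameters.

    ``hill_height`` (w₀) and temperatures are in kJ/mol and K; ``hill_width``
    and the CV itself share one unit (nm for eigenvector projections);
    ``stride_ps`` is the deposition period and ``dt_ps`` the integrator step.
    """

    hill_height: float = 0.4    # kJ/mol
    hill_width: float = 0.35    # CV units
    stride_ps: float = 2.0      # deposition period
    bias_factor: float = 10.0   # gamma, dimensionless
    temperature: float = 300.0  # K
    run_length_ns: float = 10.0
    dt_ps: float = 0.002
    friction: float = 1.0       # kJ/mol·ps per CV-unit² (overdamped)

    def __post_init__(self):
        if self.bias_factor <= 1.0:
            raise ValidationError("bias_factor must be > 1")
        for name in ("hill_height", "hill_width", "stride_ps", "dt_ps",
                     "friction"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def kT(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    @property
    def n_steps(self) -> int:
        return int(round(self.run_length_ns * 1000.0 / self.dt_ps))

    @property
    def stride_steps(self) -> int:
        return max(1, int(round(self.stride_ps / self.dt_ps)))


def histogram_fel(samples, bins, kT: float, range=None) -> FreeEnergySurface:
    """Boltzmann-invert a CV histogram into a free-energy surface.

    ``samples`` is (n,) for a 1-D CV or (n, 2) for two CVs.  Occupied bins
    get F = −kT ln(n_b / n_max) (so the most populated bin is 0); empty
    bins are NaN and flagged in ``mask``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("no samples")
    if samples.ndim == 1:
        counts, edges = np.histogram(samples, bins=bins, range=range)
        centers = 0.5 * (edges[:-1] + edges[1:])
        grid = centers
    elif samples.ndim == 2 and samples.shape[1] == 2:
        counts, ex, ey = np.histogram2d(
            samples[:, 0], samples[:, 1], bins=bins, range=range
        )
        grid = (0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]))
    else:
        raise ValidationError("samples must be (n,) or (n, 2)")
    counts = counts.astype(float)
    nmax = counts.max()
    if nmax == 0:
        raise ValidationError("histogram has no occupied bin")
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(counts / nmax)
    fe[counts == 0] = np.nan
    return FreeEnergySurface(cv_grid=grid, free_energy=fe, kT=kT)


def langevin_sample(
    grad,
    kT: float,
    friction: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
    s0=0.0,
    guard: float = 1e4,
) -> np.ndarray:
    """Overdamped (Euler–Maruyama) Langevin sampling of exp(−U/kT).

    ``grad(s)`` returns ∇U at the CV value s (scalar or length-d vector).
    Update: s ← s − (∇U/friction)·dt + sqrt(2·kT·dt/friction)·ξ.
    Divergence beyond ``guard`` raises :class:`IntegrationError`.
    Statistics depend on U only through its gradient, so constants added
    to U are irrelevant.
    """
    rng = np.random.default_rng(seed)
    s = np.atleast_1d(np.asarray(s0, dtype=float)).copy()
    d = s.size
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    out = np.empty((n_steps, d))
    noise = rng.standard_normal((n_steps, d)) * noise_scale
    for t in range(n_steps):
        g = np.atleast_1d(np.asarray(grad(s if d > 1 else s[0]), dtype=float))
        s = s - (g / friction) * dt + noise[t]
        if np.any(np.abs(s) > guard):
            raise IntegrationError(
                f"Langevin integration diverged at step {t} (dt={dt}); "
                "reduce dt or soften the potential"
            )
        out[t] = s
    return out[:, 0] if d == 1 else out


def wt_metadynamics(
    potential_grad,
    params: MetadynamicsParams,
    seed: int = 0,
    cv_range: tuple[float, float] = (-3.0, 3.0),
    s0: float = 0.0,
    average_fraction: float = 0.5,
):
    """1-D well-tempered metadynamics on an analytic potential.

    ``potential_grad(s)`` is dU/ds in kJ/mol per CV unit.  Returns
    ``(hill_log, fes)`` where ``hill_log`` is a list of
    ``(time_ps, center, height)`` and ``fes`` the bias-derived estimate
    F̂ = −γ/(γ−1)·V_bias shifted to min 0 on the deposition grid.  To damp
    the hill-scale ripple of the instantaneous bias, V_bias is
    time-averaged over the final ``average_fraction`` of depositions (the
    uniform late-time growth of the well-tempered bias only adds a
    constant, which the min-shift removes); set ``average_fraction=0`` for
    the raw final-bias estimate.

    The γ → ∞ limit reduces to standard metadynamics (constant hill
    heights); heights at a revisited region decay as the accumulated bias
    grows — the well-tempered convergence mechanism.
    """
    kT = params.kT
    gamma = params.bias_factor
    sigma = params.hill_width
    w0 = params.hill_height
    dt = params.dt_ps
    friction = params.friction
    lo, hi = cv_range

    n_grid = int(np.ceil((hi - lo) / (sigma / 5.0))) + 1
    grid = np.linspace(lo, hi, n_grid)
    dg = grid[1] - grid[0]
    v_bias = np.zeros(n_grid)
    dv_bias = np.zeros(n_grid)  # dV/ds on the grid

    rng = np.random.default_rng(seed)
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    stride = params.stride_steps
    n_steps = params.n_steps
    s = float(s0)
    hills: list[tuple[float, float, float]] = []
    guard_lo, guard_hi = lo - 5 * sigma, hi + 5 * sigma
    n_depositions = n_steps // stride
    avg_start = int((1.0 - average_fraction) * n_depositions)
    v_avg = np.zeros(n_grid)
    n_avg = 0
    # vectorised per-block noise; the inner loop stays scalar for speed
    noise = rng.standard_normal(n_steps) * noise_scale
    inv_friction_dt = dt / friction
    for t in range(n_steps):
        # linear interpolation of the bias gradient
        if s <= lo:
            fb = dv_bias[0]
        elif s >= hi:
            fb = dv_bias[-1]
        else:
            u = (s - lo) / dg
            i = int(u)
            w = u - i
            fb = dv_bias[i] * (1.0 - w) + dv_bias[i + 1] * w
        g = potential_grad(s) + fb
        s = s - g * inv_friction_dt + noise[t]
        if not (guard_lo < s < guard_hi):
            raise IntegrationError(
                f"metadynamics walker left the CV range at step {t}"
            )
        if (t + 1) % stride == 0:
            # current bias at s (linear interpolation)
            u = np.clip((s - lo) / dg, 0, n_grid - 1 - 1e-9)
            i = int(u)
            w = u - i
            vb_here = v_bias[i] * (1.0 - w) + v_bias[i + 1] * w
            height = w0 * np.exp(-vb_here / ((gamma - 1.0) * kT))
            z = (grid - s) / sigma
            gauss = height * np.exp(-0.5 * z * z)
            v_bias += gauss
            dv_bias += gauss * (-(grid - s) / sigma ** 2)
            hills.append(((t + 1) * dt, s, float(height)))
            if len(hills) > avg_start:
                v_avg += v_bias
                n_avg += 1

    v_est = v_avg / n_avg if n_avg else v_bias
    fe = -(gamma / (gamma - 1.0)) * v_est
    fe -= fe.min()
    return hills, FreeEnergySurface(cv_grid=grid, free_energy=fe, kT=kT,
                                    mask=np.zeros(n_grid, dtype=bool))


def reweighted_histogram_fel(
    samples, v_bias_at_samples, bins, kT: float, range=None
) -> FreeEnergySurface:
    """Histogram FEL with metadynamics umbrella weights exp(V_bias/kT)."""
    samples = np.asarray(samples, dtype=float)
    w = np.exp(np.asarray(v_bias_at_samples) / kT)
    counts, edges = np.histogram(samples, bins=bins, range=range, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nmax = counts.max()
    if nmax == 0:
        raise ValidationError("histogram has no occupied bin")
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(counts / nmax)
    fe[counts == 0] = np.nan
    return FreeEnergySurface(cv_grid=centers, free_energy=fe, kT=kT)


def double_well(barrier: float, separation: float = 2.0):
    """Symmetric quartic double well with minima at ±separation/2.

    U(s) = barrier · ((s/a)² − 1)² with a = separation/2, so U(±a) = 0 and
    U(0) = barrier.  Returns ``(U, grad)`` callables.
    """
    a = separation / 2.0

    def u(s):
        z = (s / a) ** 2 - 1.0
        return barrier * z * z

    def g(s):
        return 4.0 * barrier * s / a ** 2 * ((s / a) ** 2 - 1.0)

    return u, g


def barrier_height(fes: FreeEnergySurface, split: float = 0.0) -> float:
    """Barrier of a 1-D double-well estimate: F at the top between the wells
    minus the mean of the two well minima."""
    grid = np.asarray(fes.cv_grid)
    fe = fes.free_energy
    left = fe[grid < split]
    right = fe[grid >= split]
    if left.size == 0 or right.size == 0:
        raise ValidationError("split leaves an empty side")
    f_left = np.nanmin(left)
    f_right = np.nanmin(right)
    i_lo = np.nanargmin(left)
    i_hi = np.nanargmin(right) + left.size
    top = np.nanmax(fe[i_lo:i_hi + 1])
    return float(top - 0.5 * (f_left + f_right))
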