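# Methods

This note documents the models and numerical procedures mdflex implements,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish about real data.

## Units and conventions

Lengths are in Å, times in ps, masses in amu, energies in kJ/mol
(`kB = 0.0083145 kJ/mol/K`). Mean-square quantities (eigenvalues, TMSF)
are carried in Å² and additionally exposed in nm² (1 nm² = 100 Å²), the
unit conventionally used for TMSF. Atom and residue indices are 0-based
and contiguous; author residue numbering from PDB files is preserved for
display only. Metadynamics collective variables (CVs) are treated in nm —
the conventional unit for eigenvector-projection CVs — while all other
geometry is in Å; the conversion is explicit at the module boundary.

## Structure model and atom roles

The PDB reader interprets only coordinate records and assigns role flags:

- *solvent*: residue names HOH/SOL/WAT; monatomic ions (NA, CL, CA, MG, …)
  are retained but flagged not-solute.
- *mainchain*: atom names N, H (H1–H3), CA, HA, C, O, OXT; everything
  else in a solute residue is side chain. This is the common backbone
  convention.
- *donor/acceptor*: every N and O is an acceptor; an N or O with a
  covalently attached hydrogen (same residue, < 1.25 Å) is a donor. No
  force-field typing is attempted. When hydrogens are absent, mainchain
  amide hydrogens are constructed geometrically (1.0 Å from N along the
  negative bisector of N→CA and N→C(prev)); side-chain donor names
  (OG, OH, NZ, …) without hydrogens fall back to a distance-only
  criterion with a warning. Whether reference hydrogen-bond tools
  inferred or required such hydrogens is not documented anywhere we know
  of; the fallback is our choice and is flagged at run time.
- van der Waals radii are element-based Bondi values (C 1.70, N 1.55,
  O 1.52, S 1.80, H 1.20 Å).

Alternate locations keep the first occurrence; insertion codes are kept
verbatim. The TRJF v1 fixture format is a plain-text trajectory container
(header + per-frame coordinate blocks at 9 significant digits) chosen so
fixtures remain inspectable and diffable.

## Hydrogen bonds

A bond is a (donor, hydrogen, acceptor) triple with donor–acceptor
distance ≤ 3.5 Å **and** donor–hydrogen–acceptor angle at the hydrogen
≥ 120°. Both bounds are inclusive ("maximum distance", "minimum angle").
Pairs that are covalently bonded or share a covalent neighbour (1-2 and
1-3 pairs, inferred from reference-coordinate distances) are excluded;
without the 1-3 exclusion every peptide bond would contribute a
chemically impossible N(i+1)–H···O(i) pair. Minimum-image distances are
used when a periodic box is present.

Bond identity is the full triple, so two hydrogens of one donor bonding
one acceptor are two distinct dynamic bonds — the bookkeeping used by the
standard trajectory tools. Over a trajectory:

- static mean = per-frame count averaged over frames,
- dynamic count = number of distinct triples seen at least once,
- persistency(bond) = 100 × (frames containing the bond) / F.

These definitions satisfy `Σ persistency/100 = static_mean` as an exact
identity, which the test suite asserts to machine precision. Published
tables of this kind approximately exhibit the identity; some rows deviate
beyond rounding (suggesting a different averaging or triple-identity
convention), and we deliberately do not reproduce that deviation.
Class labels (M–M, M–S, S–S intra-protein; M–solv, S–solv by the protein
partner) derive solely from the solute/mainchain flags; water–water bonds
are never counted.

## Structural properties

- **RMSD**: Kabsch superposition (SVD with determinant correction) on the
  backbone N, CA, C, O selection against the starting structure. The
  choice to include O is documented here because reference tools differ;
  a custom selection can be passed.
- **Rg**: mass-weighted by default (the common default), geometric on
  request.
- **Native contacts**: all solute heavy-atom pairs in different residues
  closer than 6 Å (strict) in the reference; recounted per frame with the
  same strict cutoff. Intra-residue pairs are excluded — they never break
  and only add a constant. An all-contacts mode is intentionally not the
  default: the tabulated quantity is *native* contacts.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points/atom, probe 1.4 Å). The quadrature error on an
  isolated sphere is ≪ 1%; the test suite also cross-checks a fused-sphere
  case against a 10⁶-point Monte-Carlo surface sample.
- **Secondary structure**: a minimal Kabsch–Sander assignment. Backbone
  amide H positions use the DSSP convention (anti-parallel to the
  preceding C=O) when explicit hydrogens are absent. Hydrogen-bond energy
  E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond if
  E < −0.5. Two consecutive i→i+4 turns make H, two consecutive i→i+3
  turns make G, parallel/antiparallel bridge patterns make E, isolated
  turns make T, priority H > E > G > T. Helix counts report H+G together
  (3₁₀ grouped with α), sheet = E, turn = T. π-helices, bends and isolated
  β-bridges are out of scope. Where the run-end convention is ambiguous
  (an ideal N-residue helix labels residues 2..N−1), tests assert the
  convention-independent core.
- **Comparison arithmetic**: `percent_change = 100·(b−a)/a` and
  `fold_change = (b−a)/a` (a "3.64-fold increase" means b = 4.64·a is
  *not* implied; the increase itself is 3.64×a). The secondary-structure
  percent change is computed on the helix+sheet+turn total.

## Essential dynamics

Frames are least-squares fitted to the *starting structure* on the
analysis selection (fitting to the iterated trajectory mean is available
as an option but not the default, to match the RMSD reference
convention), then the 3n×3n Cartesian covariance with population
normalisation 1/F is diagonalised with a dense symmetric eigensolver.
No mass weighting: the intended selection is Cα-only, where mass
weighting is a constant. Signs are fixed by making each eigenvector's
largest-magnitude component positive. Dense diagonalisation is adequate
to n ≈ 2000 selected atoms.

The projection of frame t on eigenvector k is
`p_k(t) = v_kᵀ(x_fit(t) − ⟨x⟩)`; its variance equals λ_k by construction
(asserted to 1e−6 relative). Projection extremes are the frames attaining
min/max p_k; interpolants between them are linear in Cartesian space and
visualise the mode, not a transition pathway.

**Cosine content** is discretised with the trapezoid rule on a unit time
grid; the time scale cancels in the ratio. A constant series has an
undefined cosine content and raises rather than returning 0, because 0
means "converged" — the opposite of what a degenerate input should claim.

**Combined ED** concatenates two trajectories fitted to one common
reference and diagonalises the joint covariance. Per-half projection
means and MSDs (`msd_h(k) = ⟨p_k²⟩_h`) are computed about the *combined*
mean: a common origin is what makes the MSD sensitive to the
conformational shift between the halves as well as to the fluctuation
within each half. This convention is a documented choice — the quantity
is not precisely defined in the literature that uses it.

**Planted-mode validation**: the generator draws i.i.d. Gaussian
amplitudes along orthonormal 3n-vectors, so the population covariance is
known exactly. Because least-squares fitting annihilates the 6-dimensional
rigid-body subspace, validation modes are drawn orthogonal to it
(`orthogonal_modes`); with 10⁴ frames, eigenvalues are recovered within a
few percent and eigenvector overlaps exceed 0.99.

## Flexibility profiles

RMSF_i = sqrt(⟨|r_i(t) − ⟨r_i⟩|²⟩) on fitted frames; Σ_i RMSF_i² equals
the TMSF of the same selection and fit (trace identity, asserted).
Burial depth is measured once on the trajectory mean structure: surface
atoms are heavy atoms with per-atom SASA > 0.5 Å² (probe 1.4 Å), and a
residue's depth is the distance from its Cα to the nearest surface atom
(0 for surface residues). Residues are binned into equal-width depth
bins; empty bins are reported as missing (NaN), never as zero. The
SASA-threshold + nearest-surface-atom construction is a stand-in for the
unspecified "distance to the protein surface" of the figures it mirrors;
both the threshold and per-frame averaging are configurable.

## Free-energy landscapes

Histogram inversion: `F_b = −kT·ln(n_b/n_max)` on occupied bins, empty
bins masked. On Gaussian samples the fitted curvature recovers kT/σ²
within 10% at 10⁵ samples; on two-state samples the well-depth difference
recovers −kT·ln(p_B/p_A) — these closed forms are the oracles.

The sampler is overdamped Euler–Maruyama:
`s ← s − (∇U/γ_f)·dt + sqrt(2 kT dt/γ_f)·ξ`. Stability requires
dt ≲ 0.1·γ_f/max|U″|; divergence beyond a guard radius raises an error
naming dt. Well-tempered metadynamics deposits Gaussian hills of width σ
every τ ps with height `w = w₀·exp(−V_bias(s)/((γ−1)kT))`; the estimate
is `F̂ = −γ/(γ−1)·V_bias + C`, min-shifted to 0. Defaults follow common
practice (w₀ = 0.4 kJ/mol, σ = 0.35 nm, τ = 2 ps, γ = 10). The bias and
its gradient live on a grid of bin width σ/5 and are updated locally at
each deposition, so per-step cost is O(1) in the number of hills; the
interpolation error is far below w₀. To damp the hill-scale ripple of
the instantaneous bias, the returned estimate time-averages V_bias over
the final half of depositions (the uniform late-time growth adds only a
constant). A reweighted-histogram estimator (weights exp(V_bias/kT)) is
also provided; a WHAM-based reconstruction is not, as both standard
estimators agree on the 1-D analytic benchmarks used here.

Benchmark choices: the barrier-recovery benchmark uses a quartic double
well with minima at ±1 nm and a 5 kT barrier; the hill width is set to
0.1 nm because the thermal well width sqrt(kT/U″) ≈ 0.16 nm must be
resolved by the hills for an unbiased estimate — with the 0.35 nm default
the wells are over-smoothed and the barrier overestimated by ~8%. Runs of
4 ns (2×10⁶ steps) average the recovered barrier to within a few percent
over 5 seeds.

## Solvent dynamics

Coordinates are unwrapped by accumulating minimum-image displacements
between consecutive frames, then
`MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩` over molecules and all sliding time
origins; D = slope/(2·3) over a fit window defaulting to the upper half
of the lag range. Closed-form oracles: ballistic motion (v²τ²), random
walks (3mσ²), and an Ornstein–Uhlenbeck particle whose plateau is
6 kT/κ. Hydration water is any molecule whose oxygen lies within 4.5 Å
(a conventional first-shell bound, configurable) of a protein heavy
atom; membership is assigned per time origin by default ("initial-frame"
class is available), and the occupancy-weighted average of the subset
curves reproduces the joint curve exactly under the fixed-class mode.

## Replica management

Replicas of one condition are joined after discarding frames with
time ≤ 1 ns (the conventional equilibration discard; an RMSD-plateau
detector is provided but off by default). The joined time axis is
relabelled continuously; a provenance table maps each joined frame to its
replica and original time. Six 15-ns replicas saved every 10 ps with a
1-ns discard join to 8400 frames spanning 84 ns. Order-free statistics
(ED spectra, hydrogen-bond statistics, RMSF) are invariant to replica
order, which the suite asserts by permutation.

## Synthetic data: what it does and does not show

The generators are kinematic, not physical. The toy peptide uses ideal
internal coordinates (N–CA 1.46, CA–C 1.52, C–N 1.33 Å, ω = 180°; helix
φ/ψ = −57°/−47°, extended −120°/120°) with a serine-like hydroxyl stalk
per residue; scheduled hydrogen bonds are realised by *moving the
acceptor* (a hydroxyl oxygen or a water oxygen) along the donor's D–H
ray — 2.9 Å on "on" frames, 3.8 Å on "off" frames, violating the
distance criterion by a 0.3 Å margin so threshold ties cannot occur.
Waters are single-oxygen sites placed on a 4.0 Å shell (inside the
hydration cutoff, outside hydrogen-bond range) and in the far field
(≥ 12 Å); there is no water model and no energetics. Schedulable bond
classes are those whose acceptor can move freely (M–S, S–S, M–solv,
S–solv); mainchain–mainchain bonds arise only from genuine backbone
geometry (the helix template) and their classification is unit-tested on
hand-built systems. The two-state generator is a Metropolis chain whose
stationary ratio exp(−ΔF) is exact, with Gaussian jitter of width 5% of
the state separation so histogram wells stay resolvable.

Passing these suites therefore establishes that the estimators implement
their definitions correctly and recover planted parameters at the stated
statistical precision. It does not establish robustness to force-field
artefacts, to correlated noise with realistic spectra, to water
reorientational kinetics, or to the sampling inadequacy of real
nanosecond trajectories — the convergence diagnostics (cosine content,
per-half MSDs) are the tools this package provides for that judgement on
real data.

## Problem sizes in the default runs

The test suite and the acceptance script size their simulations for a
single CPU: 10⁴-frame planted-mode trajectories (20-residue toy
peptides), 100-frame/30-bond schedules for the detector equality check,
10⁵-sample histograms, 4-ns metadynamics runs (2×10⁶ steps) at 5 seeds,
4×10⁵-step Langevin runs and 10⁴-step random walks. These sizes were
chosen so every statistical tolerance has comfortable headroom at the
stated precision.
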