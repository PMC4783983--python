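# mdflex

Trajectory analysis for protein flexibility studies: essential dynamics,
hydrogen-bond persistency bookkeeping, structural property tables,
RMSF/burial-depth profiles, free-energy landscapes and solvent mobility —
with a synthetic-trajectory generator that plants known ground truth for
every analysis stage.

## The scientific problem

Whether a protein is flexible or rigid is governed as much by its solvent
as by the protein itself: simulations that couple the protein and the
water bath to different thermostats (e.g. protein at 300 K in 180 K water,
written P300/S180) show that solvent temperature dominates protein
flexibility. Establishing that claim from molecular-dynamics trajectories
requires a specific analysis toolchain, which this package implements as a
reusable, tested library:

- **Essential dynamics (ED)** — PCA of the Cα fluctuation covariance after
  least-squares fitting to the starting structure,
  `C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩`. Eigenvectors are collective motion directions;
  eigenvalues their variances; the **TMSF** (total mean-square
  fluctuation) is `tr C = Σ λ_k`. Includes projections, projection
  extremes with linear interpolants, and **combined ED** of two
  concatenated trajectories with per-half projection means and MSDs.
- **Cosine content** `c_k = (2/T)(∫ cos(kπt/T) p(t) dt)² / ∫ p²(t) dt` of
  projection series, the standard convergence diagnostic (≈1 means
  diffusion-like, unconverged sampling; ≈0 means converged).
- **Hydrogen bonds** — geometric detection (donor–acceptor ≤ 3.5 Å,
  donor–H–acceptor angle ≥ 120°) with *static* (per-frame mean), *dynamic*
  (distinct bonds ever seen) and *persistency* (% of frames per bond)
  statistics, broken down into mainchain/side-chain/solvent classes.
  These satisfy `static_mean = Σ_i persistency_i / 100` exactly.
- **Structural properties** — Kabsch-fitted backbone RMSD, Shrake–Rupley
  SASA, native-contact counts (< 6 Å), radius of gyration, and a minimal
  Kabsch–Sander secondary-structure assignment; plus the percent-change
  (`100·(b−a)/a`) and fold-change (`(b−a)/a`) arithmetic used to compare
  conditions.
- **Flexibility profiles** — per-residue Cα RMSF and RMSF as a function of
  burial depth (distance from a residue's Cα to the nearest
  solvent-exposed atom).
- **Free-energy landscapes** — Boltzmann inversion of projection
  histograms, `F_b = −kT ln(n_b/n_max)`, and a 1-D overdamped-Langevin +
  well-tempered metadynamics engine on analytic collective-variable
  potentials (hill height `w = w₀·exp(−V/((γ−1)kT))`, estimate
  `F̂ = −γ/(γ−1)·V_bias`).
- **Solvent dynamics** — unwrapped mean-square displacement over sliding
  time origins with hydration-shell vs bulk classification (shell = water
  oxygen within 4.5 Å of a protein heavy atom).
- **Pipeline** — multi-replica equilibration discard and joining,
  provenance tracking, and a report bundle (CSV/TSV tables + JSON
  manifest) over labelled conditions, with a `mdflex` CLI.

The `mdflex.synth` module generates the inputs these analyses are
validated on: Gaussian-mode trajectories with planted covariances, random
walks, two-state Markov hopping with a prescribed free-energy difference,
and a kinematic toy peptide/water system whose hydrogen bonds follow a
scripted schedule exactly.

## Worked example

```python
import numpy as np
from mdflex.ed import ed_decompose, project, cosine_content
from mdflex.synth import gen_gaussian_mode_trajectory, gen_toy_protein_solvent, orthogonal_modes
from mdflex.hbonds import hbond_statistics

# 1. plant two covariance modes (4 and 1 Å^2) and recover them with ED
system, _, _ = gen_toy_protein_solvent(20, "extended", 0, "auto",
                                       n_frames=2, n_bonds=0, seed=0)
modes = orthogonal_modes(system, [4.0, 1.0], seed=1)
traj = gen_gaussian_mode_trajectory(system, modes, 10_000, seed=2)
ed = ed_decompose(traj, np.arange(system.n_atoms))
print("eigenvalues:", ed.eigenvalues[:2].round(3))   # [4.039 0.982]
print("TMSF (A^2): %.3f" % ed.tmsf)                  # 5.021
print("overlap:", abs(ed.eigenvectors[:, 0] @ modes[0].eigenvector).round(4))
                                                     # 0.9994

# 2. hydrogen-bond bookkeeping on a scheduled toy system
system, traj, schedule = gen_toy_protein_solvent(
    60, "extended", n_waters=12, schedule="auto", n_frames=100,
    n_bonds=15, seed=3)
stats = hbond_statistics(traj, scope="intra-protein")
print("static %.2f  dynamic %d  mean persistency %.1f%%"
      % (stats.static_mean, stats.dynamic_count, stats.mean_persistency))
# static 5.04  dynamic 8  mean persistency 63.0%
# identity: sum(persistency)/100 == static_mean, exactly
```

The first block shows ED recovering a planted covariance spectrum from
10,000 frames: eigenvalues within a few percent of the planted 4 and 1 Å²
and an eigenvector overlap of 0.9994. The second shows the occupancy
bookkeeping on a system whose bonds are scripted: the static mean is the
average number of bonds per frame, the dynamic count the number of
distinct bonds ever formed, and their ratio (via the mean persistency) is
an exact identity of the definitions.

A shell session with the same machinery:

```bash
mdflex --out-dir out --seed 1 synth --n-residues 30 --n-waters 10
mdflex --out-dir out ed out/toy.pdb out/toy.trjf
mdflex --out-dir out metad --barrier-kt 5
```

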