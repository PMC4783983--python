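"""Replica management and end-to-end report generation.

Multi-replica simulations of one condition are joined into a single
trajectory after discarding an equilibration prefix (default 1 ns) from
each replica; the joined time axis is relabelled to a continuous grid and a
provenance map (joined frame → replica, original time) is retained.  Order-
free statistics (ED spectra, hydrogen-bond statistics, RMSF) are invariant
to replica ordering.

Condition labels follow the "P<protein-T>/S<solvent-T>" convention, e.g.
"P300/S180" for protein at 300 K in 180 K solvent.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ed import cosine_content, ed_decompose, project
from .errors import ValidationError
from .fel import histogram_fel
from .flexibility import per_residue_rmsf
from .hbonds import hbond_statistics
from .model import AnalysisConfig, Trajectory
from .props import property_table, tables_to_csv
from .select import select_atoms


@dataclass
class ReplicaSet:
    """Replicas of one condition sharing a single System."""

    replicas: list[Trajectory]
    labels: list[str] = field(default_factory=list)
    equilibration_discard: float = 1000.0  # ps

    def __post_init__(self):
        if not self.replicas:
            raise ValidationError("ReplicaSet needs at least one replica")
        n = self.replicas[0].n_atoms
        for r in self.replicas:
            if r.n_atoms != n:
                raise ValidationError("replicas must share one atom count")
        if not self.labels:
            self.labels = [f"replica{i + 1}" for i in range(len(self.replicas))]


def join_equilibrated(rs: ReplicaSet) -> Trajectory:
    """Concatenate the equilibrated portion (time > discard) of each replica.

    The joined time axis is continuous with the original frame spacing;
    ``metadata['provenance']`` maps each joined frame to its replica label
    and original time.
    """
    frames = []
    provenance = []
    discard = rs.equilibration_discard
    for label, rep in zip(rs.labels, rs.replicas):
        keep = rep.times > discard
        if not keep.any():
            raise ValidationError(
                f"discard {discard} ps leaves no frames in replica {label!r}"
            )
        frames.append(rep.frames[keep])
        provenance.extend((label, t) for t in rep.times[keep])
    joined = np.concatenate(frames, axis=0)
    dt = rs.replicas[0].dt
    times = dt * (1.0 + np.arange(len(joined)))
    prov = pd.DataFrame(provenance, columns=["replica", "original_time_ps"])
    return Trajectory(
        rs.replicas[0].system, joined, times,
        box=None if rs.replicas[0].box is None else np.repeat(
            rs.replicas[0].box[:1], len(joined), axis=0
        ),
        metadata={"provenance": prov},
    )


def run_report(
    config: AnalysisConfig,
    replica_sets: dict[str, ReplicaSet],
    out_dir: str | os.PathLike,
    seed: int | None = None,
    n_eigenvectors: int = 10,
    fel_bins: int = 40,
) -> dict:
    """Run the full analysis pipeline for each condition and write a bundle.

    The bundle contains a structural-property CSV (one row per condition),
    per-condition hydrogen-bond CSVs, ED eigenvalue spectra, Cα RMSF
    profiles, projection-based free-energy surfaces, a JSON manifest
    (versions, seed, config hash) and a plain-text log.  Output is
    deterministic for a fixed seed; failures of one stage are recorded in
    the log and do not discard completed stages.
    """
    if not replica_sets:
        raise ValidationError("need at least one condition")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    seed = config.random_seed if seed is None else seed
    log: list[str] = []
    outputs: dict[str, str] = {}
    tables = []
    for label, rs in sorted(replica_sets.items()):
        safe = label.replace("/", "_")
        try:
            joined = join_equilibrated(rs)
            log.append(f"{label}: joined {joined.n_frames} frames")

            table = property_table(joined, config, label=label)
            tables.append(table)

            for scope, tag in (("intra-protein", "hb_intra"),
                               ("protein-solvent", "hb_solv")):
                try:
                    stats = hbond_statistics(joined, config, scope)
                except ValidationError as exc:
                    log.append(f"{label}: {tag} skipped ({exc})")
                    continue
                path = os.path.join(out_dir, f"{tag}_{safe}.csv")
                summary = pd.DataFrame(
                    [{
                        "label": label,
                        "scope": scope,
                        "static_mean": stats.static_mean,
                        "static_sd": stats.static_sd,
                        "dynamic": stats.dynamic_count,
                        "mean_persistency_pct": stats.mean_persistency,
                        **{f"n_{c}": n for c, n in sorted(stats.class_counts.items())},
                    }]
                )
                summary.to_csv(path, index=False)
                stats.to_frame().to_csv(
                    os.path.join(out_dir, f"{tag}_{safe}_bonds.tsv"),
                    sep="\t", index=False,
                )
                outputs[f"{tag}_{safe}"] = path

            ca = select_atoms(joined.system, "name CA and solute")
            ed = ed_decompose(joined, ca)
            k = min(n_eigenvectors, len(ed.eigenvalues))
            spec = pd.DataFrame({
                "eigenvector": np.arange(1, k + 1),
                "eigenvalue_A2": ed.eigenvalues[:k],
                "eigenvalue_nm2": ed.eigenvalues_nm2[:k],
            })
            path = os.path.join(out_dir, f"ed_eigenvalues_{safe}.csv")
            spec.to_csv(path, index=False)
            outputs[f"ed_{safe}"] = path
            log.append(f"{label}: TMSF {ed.tmsf:.4f} A^2")

            p1 = project(joined, ed, 0)
            if np.var(p1) > 0:
                log.append(
                    f"{label}: cosine content c1 = {cosine_content(p1, 1):.4f}"
                )
            p2 = project(joined, ed, 1)
            fes = histogram_fel(
                np.column_stack([p1, p2]), fel_bins, config.kT
            )
            gx, gy = fes.cv_grid
            fel_df = pd.DataFrame(fes.free_energy, index=gx, columns=gy)
            path = os.path.join(out_dir, f"fel_{safe}.tsv")
            fel_df.to_csv(path, sep="\t")
            outputs[f"fel_{safe}"] = path

            residues, rmsf = per_residue_rmsf(joined)
            path = os.path.join(out_dir, f"rmsf_{safe}.tsv")
            pd.DataFrame({"residue": residues, "rmsf_A": rmsf}).to_csv(
                path, sep="\t", index=False
            )
            outputs[f"rmsf_{safe}"] = path
        except Exception as exc:  # record stage failure, keep partial bundle
            log.append(f"{label}: FAILED ({type(exc).__name__}: {exc})")

    props_path = os.path.join(out_dir, "structural_properties.csv")
    with open(props_path, "w") as fh:
        fh.write(tables_to_csv(tables))
    outputs["structural_properties"] = props_path

    config_dict = {k: getattr(config, k) for k in config.__dataclass_fields__}
    manifest = {
        "package": "mdflex",
        "version": __version__,
        "seed": seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "conditions": sorted(replica_sets),
        "outputs": sorted(outputs),
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
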