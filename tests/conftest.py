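import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdflex.model import ATOMIC_MASSES, VDW_RADII, Atom, System
from mdflex.pdbio import assign_donors_acceptors
from mdflex.synth import _build_peptide, gen_toy_protein_solvent

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.675   6.719  -4.147  1.00  0.00           C
END
"""

PROTEIN_ION_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.420   0.100  1.00  0.00           O
ATOM      5  CB  GLY A   1       2.000  -0.800   1.200  1.00  0.00           C
HETATM    6 CA    CA A 301      10.000  10.000  10.000  1.00  0.00          CA
HETATM    7 CA    CA A 302      12.000  12.000  12.000  1.00  0.00          CA
ATOM      8  O   HOH A 401      20.000  20.000  20.000  1.00  0.00           O
END
"""


def peptide_system(n_residues, phi, psi, residue_offset=0, transform=None):
    """Build a System from the ideal-geometry peptide template."""
    atoms, coords = _build_peptide(n_residues, phi, psi)
    if transform is not None:
        coords = transform(coords)
    alist = []
    for idx, (res, name, element) in enumerate(atoms):
        alist.append(
            Atom(
                index=idx, name=name, element=element,
                residue_index=res + residue_offset, residue_name="SER",
                is_solute=True,
                is_mainchain=name in ("N", "H", "CA", "C", "O"),
                is_hydrogen=element == "H",
                vdw_radius=VDW_RADII[element], mass=ATOMIC_MASSES[element],
            )
        )
    system = System(alist, coords)
    assign_donors_acceptors(system)
    return system


@pytest.fixture(scope="session")
def helix15():
    return peptide_system(15, -57.0, -47.0)


@pytest.fixture(scope="session")
def extended12():
    return peptide_system(12, -120.0, 120.0)


@pytest.fixture(scope="session")
def hairpin():
    """Two antiparallel extended strands (residues 0-5 and 6-11).

    Strand B is strand A rotated 180 degrees about the hydrogen-bonding
    direction through the Calpha centroid and offset to register the
    inter-strand amide pairing.
    """
    atoms, coords = _build_peptide(6, -120.0, 120.0)
    ca = np.array([c for (r, n, e), c in zip(atoms, coords) if n == "CA"])
    e1 = ca[-1] - ca[0]
    e1 /= np.linalg.norm(e1)
    named = {(r, n): c for (r, n, e), c in zip(atoms, coords)}
    nh = named[(2, "H")] - named[(2, "N")]
    nh -= (nh @ e1) * e1
    e2 = nh / np.linalg.norm(nh)
    center = ca.mean(axis=0)
    rot = Rotation.from_rotvec(np.pi * e2).as_matrix()
    coords_b = (coords - center) @ rot.T + center + 4.0 * e2 - 2.0 * e1

    sys_a = peptide_system(6, -120.0, 120.0)
    alist = []
    for src, off, cset in ((sys_a, 0, coords), (sys_a, 6, coords_b)):
        for a in src.atoms:
            alist.append(
                Atom(
                    index=len(alist), name=a.name, element=a.element,
                    residue_index=a.residue_index + off, residue_name="SER",
                    is_solute=True, is_mainchain=a.is_mainchain,
                    is_hydrogen=a.is_hydrogen, vdw_radius=a.vdw_radius,
                    mass=a.mass,
                )
            )
    system = System(alist, np.vstack([coords, coords_b]))
    assign_donors_acceptors(system)
    return system


@pytest.fixture(scope="session")
def scheduled_toy():
    """Extended toy peptide + waters with a random 30-bond schedule."""
    return gen_toy_protein_solvent(
        95, "extended", n_waters=20, schedule="auto", seed=7,
        n_frames=200, n_bonds=30,
    )


def water_only_system(n_waters):
    """A bare collection of water oxygen sites (for MSD tests)."""
    atoms = [
        Atom(
            index=i, name="OW", element="O", residue_index=i,
            residue_name="SOL", is_solute=False, is_mainchain=False,
            is_hydrogen=False, vdw_radius=VDW_RADII["O"], mass=18.015,
        )
        for i in range(n_waters)
    ]
    return System(atoms, np.zeros((n_waters, 3)))
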