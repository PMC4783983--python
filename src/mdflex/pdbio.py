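"""PDB structure reading/writing and atom-role assignment.

Only the coordinate records (ATOM/HETATM/MODEL/ENDMDL/TER/END) are
interpreted; everything else is ignored.  Atoms keep file order, indices are
0-based.  Alternate locations: the first one encountered for a given
atom/residue is kept.  Insertion codes are preserved verbatim but never used
for indexing.

Role flags
----------
* solvent: residue names HOH/SOL/WAT and monatomic ions are ``is_solute=False``
* mainchain: atom names N, H, H1–H3, CA, HA, C, O, OXT (solute residues only)
* donor: any N or O with at least one covalently attached hydrogen
  (attachment = same residue, distance < 1.25 Å in the reference coordinates)
* acceptor: any N or O
"""

from __future__ import annotations

import numpy as np

from .errors import ParseError
from .model import (
    ATOMIC_MASSES,
    DEFAULT_MASS,
    DEFAULT_VDW_RADIUS,
    ION_RESNAMES,
    MAINCHAIN_NAMES,
    VDW_RADII,
    WATER_RESNAMES,
    Atom,
    System,
    Trajectory,
)

_H_ATTACH_CUTOFF = 1.25  # Å; X–H covalent bond upper bound


def _guess_element(name: str, resname: str) -> str:
    name = name.strip()
    if resname.strip().upper() in ION_RESNAMES and len(name) <= 2:
        return name.upper().rstrip("+-0123456789") or name.upper()
    # strip leading digits (e.g. 1HG1), then first letter is the element
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "C"
    first = stripped[0].upper()
    if first == "H" or (name and name[0].isdigit() and first == "H"):
        return "H"
    return first


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def _parse_atom_records(pdb_text: str):
    """Yield per-model lists of raw atom records."""
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated coordinate record")
            current.append(
                dict(
                    name=line[12:16].strip(),
                    altloc=line[16].strip(),
                    resname=line[17:20].strip(),
                    chain=line[21].strip() or "A",
                    resseq=line[22:26].strip(),
                    icode=line[26].strip(),
                    x=_parse_float(line[30:38], "x coordinate", lineno),
                    y=_parse_float(line[38:46], "y coordinate", lineno),
                    z=_parse_float(line[46:54], "z coordinate", lineno),
                    element=line[76:78].strip() if len(line) >= 78 else "",
                )
            )
    if current or not models:
        models.append(current)
    return models


def _build_system(records: list[dict]) -> System:
    if not records:
        raise ParseError("no ATOM/HETATM records found")
    atoms: list[Atom] = []
    coords = []
    seen_alt: set[tuple] = set()
    res_key_to_index: dict[tuple, int] = {}
    for rec in records:
        key = (rec["chain"], rec["resseq"], rec["icode"], rec["resname"], rec["name"])
        if rec["altloc"]:
            if key in seen_alt:
                continue  # keep first altloc only
            seen_alt.add(key)
        res_key = (rec["chain"], rec["resseq"], rec["icode"], rec["resname"])
        if res_key not in res_key_to_index:
            res_key_to_index[res_key] = len(res_key_to_index)
        ridx = res_key_to_index[res_key]
        element = rec["element"].upper() or _guess_element(rec["name"], rec["resname"])
        resname = rec["resname"].upper()
        is_water = resname in WATER_RESNAMES
        is_ion = resname in ION_RESNAMES
        is_solute = not (is_water or is_ion)
        is_h = element == "H"
        try:
            resnum = int(rec["resseq"])
        except ValueError:
            resnum = None
        atoms.append(
            Atom(
                index=len(atoms),
                name=rec["name"],
                element=element,
                residue_index=ridx,
                residue_name=resname,
                chain_id=rec["chain"],
                is_solute=is_solute,
                is_mainchain=is_solute and rec["name"] in MAINCHAIN_NAMES,
                is_hydrogen=is_h,
                vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                mass=ATOMIC_MASSES.get(element, DEFAULT_MASS),
                residue_number=resnum,
                insertion_code=rec["icode"],
            )
        )
        coords.append((rec["x"], rec["y"], rec["z"]))
    system = System(atoms, np.asarray(coords, dtype=float))
    assign_donors_acceptors(system)
    return system


def assign_donors_acceptors(system: System) -> None:
    """Assign donor/acceptor flags and attached hydrogens in place.

    N and O atoms are acceptors; those with a covalently attached hydrogen
    (same residue, < 1.25 Å in the reference coordinates) are also donors.
    """
    ref = system.reference_coordinates
    by_residue: dict[int, list[Atom]] = {}
    for a in system.atoms:
        by_residue.setdefault(a.residue_index, []).append(a)
    for a in system.atoms:
        a.donor_flag = False
        a.acceptor_flag = False
        a.attached_hydrogens = []
        if a.element not in ("N", "O"):
            continue
        a.acceptor_flag = True
        for b in by_residue[a.residue_index]:
            if b.is_hydrogen and np.linalg.norm(ref[b.index] - ref[a.index]) < _H_ATTACH_CUTOFF:
                a.attached_hydrogens.append(b.index)
        if a.attached_hydrogens:
            a.donor_flag = True


def parse_structure(pdb_text: str) -> System:
    """Parse PDB text into a :class:`System` (first model only)."""
    models = _parse_atom_records(pdb_text)
    return _build_system(models[0])


def read_pdb_trajectory(pdb_text: str, dt_ps: float = 10.0) -> Trajectory:
    """Parse a multi-model PDB into a Trajectory (one frame per MODEL)."""
    models = [m for m in _parse_atom_records(pdb_text) if m]
    if not models:
        raise ParseError("no ATOM/HETATM records found")
    system = _build_system(models[0])
    frames = [system.reference_coordinates]
    for i, recs in enumerate(models[1:], start=2):
        if len(recs) != system.n_atoms:
            raise ParseError(
                f"MODEL {i} has {len(recs)} atoms, expected {system.n_atoms}"
            )
        frames.append(np.array([(r["x"], r["y"], r["z"]) for r in recs]))
    frames = np.asarray(frames)
    times = dt_ps * (1.0 + np.arange(len(frames)))
    return Trajectory(system, frames, times)


def write_structure(system: System, coordinates: np.ndarray | None = None) -> str:
    """Serialise a System (or one coordinate frame of it) to PDB text."""
    coords = system.reference_coordinates if coordinates is None else coordinates
    lines = []
    for a, (x, y, z) in zip(system.atoms, coords):
        record = "ATOM  " if a.is_solute else "HETATM"
        name = a.name
        # PDB name column convention: pad 1-3 char names starting at col 14
        fname = f" {name:<3s}" if len(name) < 4 else name
        resnum = a.residue_number if a.residue_number is not None else a.residue_index + 1
        lines.append(
            f"{record}{a.index + 1:5d} {fname}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{resnum:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_trajectory(traj: Trajectory) -> str:
    """Serialise a Trajectory as a multi-model PDB."""
    parts = []
    for i in range(traj.n_frames):
        parts.append(f"MODEL {i + 1:8d}")
        body = write_structure(traj.system, traj.frames[i])
        parts.append(body.replace("\nEND\n", "\n").rstrip("\n"))
        parts.append("ENDMDL")
    parts.append("END")
    return "\n".join(parts) + "\n"


def infer_mainchain_nh(system: System, frame: np.ndarray) -> dict[int, np.ndarray]:
    """Geometrically construct amide N–H positions for donors lacking one.

    The hydrogen is placed 1.0 Å from N along the negative bisector of the
    N→CA and N→C(prev) directions (standard planar amide construction).
    Returns {nitrogen atom index: H position}; first residues of a chain and
    nitrogens with explicit hydrogens are skipped.
    """
    out: dict[int, np.ndarray] = {}
    for a in system.atoms:
        if a.name != "N" or not a.is_solute or a.attached_hydrogens:
            continue
        ca = system.atom_index(a.residue_index, "CA")
        cprev = system.atom_index(a.residue_index - 1, "C")
        if ca is None or cprev is None:
            continue
        n = frame[a.index]
        u = frame[ca] - n
        v = frame[cprev] - n
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        d = -(u + v)
        norm = np.linalg.norm(d)
        if norm < 1e-8:
            continue
        out[a.index] = n + d / norm
    return out
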