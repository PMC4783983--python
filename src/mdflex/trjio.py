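"""TRJF v1 — a plain-text trajectory fixture format.

Layout::

    natoms <N>
    nframes <F>
    dt_ps <float>
    box <bx> <by> <bz>        (or: box none)
    frame <i> time <t>
    x y z                     (N lines, Å, >= 6 significant digits)
    ...

The box, when present, is constant over the trajectory (the writer uses the
first frame's box).  Coordinates round-trip losslessly at the declared
precision (9 significant digits).
"""

from __future__ import annotations

import io
import os

import numpy as np

from .errors import TrajectoryFormatError
from .model import System, Trajectory

_PRECISION = "%.9g"


def write_trjf(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory to a TRJF v1 text file."""
    buf = io.StringIO()
    buf.write(f"natoms {traj.n_atoms}\n")
    buf.write(f"nframes {traj.n_frames}\n")
    dt = traj.dt if traj.n_frames > 1 else 1.0
    buf.write(f"dt_ps {_PRECISION % dt}\n")
    if traj.box is None:
        buf.write("box none\n")
    else:
        bx, by, bz = traj.box[0]
        buf.write(f"box {_PRECISION % bx} {_PRECISION % by} {_PRECISION % bz}\n")
    for i in range(traj.n_frames):
        buf.write(f"frame {i} time {_PRECISION % traj.times[i]}\n")
        for x, y, z in traj.frames[i]:
            buf.write(f"{_PRECISION % x} {_PRECISION % y} {_PRECISION % z}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trjf(path: str | os.PathLike, system: System) -> Trajectory:
    """Read a TRJF v1 file back into a Trajectory over ``system``.

    Raises :class:`TrajectoryFormatError` on any structural violation
    (header/payload atom-count mismatch, truncated frame) and
    :class:`ValidationError` for non-monotone times.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line():
        try:
            return next(it)
        except StopIteration:
            raise TrajectoryFormatError("unexpected end of file") from None

    def header(key):
        lineno, line = next_line()
        parts = line.split()
        if not parts or parts[0] != key:
            raise TrajectoryFormatError(f"line {lineno}: expected '{key} ...'")
        return parts[1:]

    natoms = int(header("natoms")[0])
    nframes = int(header("nframes")[0])
    header("dt_ps")
    box_fields = header("box")
    box = None if box_fields[0] == "none" else [float(v) for v in box_fields[:3]]
    if natoms != system.n_atoms:
        raise TrajectoryFormatError(
            f"header natoms {natoms} does not match system ({system.n_atoms})"
        )
    frames = np.empty((nframes, natoms, 3))
    times = np.empty(nframes)
    for f in range(nframes):
        lineno, line = next_line()
        parts = line.split()
        if len(parts) != 4 or parts[0] != "frame" or parts[2] != "time":
            raise TrajectoryFormatError(
                f"line {lineno}: expected 'frame <i> time <t>', got {line!r}"
            )
        times[f] = float(parts[3])
        for a in range(natoms):
            lineno, line = next_line()
            parts = line.split()
            if parts and parts[0] == "frame":
                raise TrajectoryFormatError(
                    f"line {lineno}: frame {f} has fewer than {natoms} atoms"
                )
            if len(parts) != 3:
                raise TrajectoryFormatError(
                    f"line {lineno}: expected 3 coordinates, got {line!r}"
                )
            frames[f, a] = [float(v) for v in parts]
    return Trajectory(system, frames, times, box=box)
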