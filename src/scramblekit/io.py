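"""Structure and trajectory readers/writers.

Supported formats:

* GRO (fixed-width Gromacs coordinate files, nm) — single- or multi-frame;
* PDB (``ATOM``/``HETATM`` records, Angstrom, converted to nm on read);
* a plain columnar trajectory TSV with one particle per row
  (``time_ps particle_id x y z box_x box_y box_z``, nm/ps).

Only orthorhombic boxes are supported; triclinic box lines raise
:class:`~scramblekit.errors.UnsupportedBoxError`.  Parse failures carry
the 1-based line number of the offending record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MembraneFrame, RoleRules, Structure
from .errors import ParameterError, ParseError, UnsupportedBoxError, ValidationError

_TRAJ_COLUMNS = ["time_ps", "particle_id", "x", "y", "z",
                 "box_x", "box_y", "box_z"]


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_box(tokens, path, lineno):
    vals = [float(t) for t in tokens]
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise UnsupportedBoxError(
                f"{path}: line {lineno}: triclinic box is not supported")
        box = np.array(vals[:3])
    else:
        raise ParseError("box line must have 3 or 9 fields",
                         path=path, line=lineno)
    if not np.all(box > 0):
        raise ParseError("box edge lengths must be positive",
                         path=path, line=lineno)
    return box


def _parse_gro_block(lines, start, path):
    """Parse one GRO frame starting at index ``start``; return
    (residue_ids, residue_names, particle_names, coords, box, time, next_index)."""
    if start >= len(lines):
        raise ParseError("unexpected end of file", path=path, line=len(lines))
    title = lines[start]
    time = None
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            time = None
    try:
        natoms = int(lines[start + 1].strip())
    except (ValueError, IndexError):
        raise ParseError("expected particle count",
                         path=path, line=start + 2) from None
    resids, resnames, names, coords = [], [], [], []
    for i in range(natoms):
        lineno = start + 3 + i  # 1-based
        try:
            line = lines[start + 2 + i]
        except IndexError:
            raise ParseError("file truncated inside frame",
                             path=path, line=len(lines)) from None
        if len(line.rstrip("\n")) < 44:
            raise ParseError("record too short for fixed-width GRO fields",
                             path=path, line=lineno)
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            xyz = [float(line[20 + 8 * k: 28 + 8 * k]) for k in range(3)]
        except ValueError as exc:
            raise ParseError(f"malformed fixed-width field ({exc})",
                             path=path, line=lineno) from None
        coords.append(xyz)
    box_index = start + 2 + natoms
    if box_index >= len(lines):
        raise ParseError("missing box line", path=path, line=len(lines))
    box = _parse_gro_box(lines[box_index].split(), path, box_index + 1)
    return (np.array(resids), np.array(resnames, dtype=object),
            np.array(names, dtype=object),
            np.array(coords, dtype=float), box, time, box_index + 1)


def read_gro(path) -> tuple[Structure, MembraneFrame]:
    """Read a single-frame GRO file (structure + coordinates).

    Roles are *not* assigned here; use :func:`read_structure` for a
    role-annotated :class:`~scramblekit.core.Structure`.
    """
    lines = Path(path).read_text().splitlines()
    resids, resnames, names, coords, box, time, nxt = _parse_gro_block(
        lines, 0, path)
    frame = MembraneFrame(time or 0.0, coords, box)
    return (resids, resnames, names), frame


def read_gro_trajectory(path) -> list[MembraneFrame]:
    """Read a multi-frame GRO file into a list of frames.

    Frame times are taken from ``t=`` in the title lines when present,
    else numbered 0, 1, 2, ... .
    """
    lines = Path(path).read_text().splitlines()
    frames: list[MembraneFrame] = []
    idx = 0
    n = 0
    while idx < len(lines) and lines[idx].strip():
        _, _, _, coords, box, time, idx = _parse_gro_block(lines, idx, path)
        frames.append(MembraneFrame(time if time is not None else float(n),
                                    coords, box))
        n += 1
    return frames


def write_gro(path, structure: Structure, frame: MembraneFrame,
              title: str = "scramblekit"):
    with open(path, "w") as fh:
        _write_gro_frame(fh, structure, frame, title)


def write_gro_trajectory(path, structure: Structure, frames, title="scramblekit"):
    with open(path, "w") as fh:
        for frame in frames:
            _write_gro_frame(fh, structure, frame,
                             f"{title} t= {frame.time:.3f}")


def _write_gro_frame(fh, structure, frame, title):
    fh.write(f"{title}\n{len(structure):d}\n")
    for i in range(len(structure)):
        x, y, z = frame.coords[i]
        fh.write(f"{int(structure.residue_ids[i]) % 100000:5d}"
                 f"{structure.residue_names[i]:<5.5s}"
                 f"{structure.particle_names[i]:>5.5s}"
                 f"{(i + 1) % 100000:5d}"
                 f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path):
    """Read ATOM/HETATM records of a PDB file; coordinates converted to nm.

    Returns the same ``(arrays, frame)`` pair as :func:`read_gro`.  The
    box comes from a ``CRYST1`` record (orthorhombic only); without one a
    generous bounding box is synthesised.
    """
    resids, resnames, names, coords = [], [], [], []
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    alpha, beta, gamma = (float(line[33:40]),
                                          float(line[40:47]),
                                          float(line[47:54]))
                except ValueError:
                    raise ParseError("malformed CRYST1 record",
                                     path=path, line=lineno) from None
                if not (abs(alpha - 90) < 1e-6 and abs(beta - 90) < 1e-6
                        and abs(gamma - 90) < 1e-6):
                    raise UnsupportedBoxError(
                        f"{path}: line {lineno}: non-orthorhombic CRYST1")
                box = np.array([a, b, c]) / 10.0
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError("ATOM record too short",
                                     path=path, line=lineno)
                try:
                    names.append(line[12:16].strip())
                    resnames.append(line[17:21].strip())
                    resids.append(int(line[22:26]))
                    coords.append([float(line[30:38]), float(line[38:46]),
                                   float(line[46:54])])
                except ValueError as exc:
                    raise ParseError(f"malformed ATOM field ({exc})",
                                     path=path, line=lineno) from None
    coords = np.array(coords, dtype=float) / 10.0  # Angstrom -> nm
    if box is None:
        span = coords.max(axis=0) - coords.min(axis=0) + 2.0 if len(coords) \
            else np.ones(3)
        box = np.maximum(span, 1.0)
    frame = MembraneFrame(0.0, coords, box)
    return (np.array(resids), np.array(resnames, dtype=object),
            np.array(names, dtype=object)), frame


# ---------------------------------------------------------------------------
# unified structure reader
# ---------------------------------------------------------------------------

def read_structure(path, format: str | None = None,
                   role_rules: RoleRules | None = None,
                   ) -> tuple[Structure, MembraneFrame]:
    """Read a GRO or PDB file and assign roles from ``role_rules``.

    ``format`` defaults to the file extension.  Residue names not
    covered by the rules raise a validation error rather than being
    silently defaulted.
    """
    if format is None:
        format = Path(path).suffix.lstrip(".").upper() or "GRO"
    format = format.upper()
    if format == "GRO":
        arrays, frame = read_gro(path)
    elif format == "PDB":
        arrays, frame = read_pdb(path)
    else:
        raise ParameterError(f"unknown structure format {format!r}")
    resids, resnames, names = arrays
    if len(resids) == 0:
        raise ParseError("no particles found", path=path)
    structure = Structure.from_particles(resids, resnames, names,
                                         rules=role_rules)
    return structure, frame


# ---------------------------------------------------------------------------
# columnar trajectory TSV
# ---------------------------------------------------------------------------

def read_trajectory_tsv(path) -> list[MembraneFrame]:
    """Read the columnar trajectory dialect into time-ordered frames.

    Columns: ``time_ps particle_id x y z box_x box_y box_z`` with ``#``
    comments.  Within a frame, rows must cover particle ids 0..n-1.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=_TRAJ_COLUMNS)
    except ValueError as exc:
        raise ParseError(f"cannot parse trajectory table ({exc})",
                         path=path) from None
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0])
        raise ParseError("non-numeric or missing field",
                         path=path, line=bad + 1)
    frames = []
    for time, grp in df.groupby("time_ps", sort=True):
        grp = grp.sort_values("particle_id")
        pids = grp["particle_id"].to_numpy()
        if not np.array_equal(pids, np.arange(len(pids))):
            raise ValidationError(
                f"frame at t={time}: particle ids are not contiguous from 0")
        box = grp[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float)
        frames.append(MembraneFrame(float(time),
                                    grp[["x", "y", "z"]].to_numpy(dtype=float),
                                    box))
    return frames


def write_trajectory_tsv(path, frames, header_lines=()):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# " + " ".join(_TRAJ_COLUMNS) + "\n")
        for frame in frames:
            bx, by, bz = frame.box
            for pid, (x, y, z) in enumerate(frame.coords):
                fh.write(f"{frame.time:.4f}\t{pid}\t{x:.6f}\t{y:.6f}\t"
                         f"{z:.6f}\t{bx:.6f}\t{by:.6f}\t{bz:.6f}\n")
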