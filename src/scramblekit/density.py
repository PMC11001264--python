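"""Replica merging, reference alignment and 3D occupancy densities.

Frames (possibly concatenated from several replicas) are rigid-body
aligned onto a protein reference via Kabsch superposition, then selected
particles (phosphates, water, ...) are binned on a regular 3D grid.
Voxel values are mean counts per voxel per frame, so
``sum(values) * n_frames`` equals the total number of selected-particle
observations when everything lies inside the grid.  Grids are exported
as OpenDX scalar fields (nm units) readable by standard viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MembraneFrame, Selection, Structure
from .errors import EmptySelectionError, ParameterError, ParseError
from .geometry import apply_transform, kabsch_superpose


def merge_replicas(*replicas) -> list[MembraneFrame]:
    """Concatenate frame lists from several replicas, order preserved."""
    out: list[MembraneFrame] = []
    for frames in replicas:
        out.extend(frames)
    return out


def align_to_reference(frames, structure: Structure,
                       reference_selection: Selection,
                       reference: MembraneFrame | None = None
                       ) -> list[MembraneFrame]:
    """Superpose every frame onto a reference via the given selection.

    The Kabsch transform is computed on ``reference_selection`` (e.g.
    protein beads) and applied to the whole frame.  The reference
    defaults to the first frame.
    """
    if len(reference_selection) == 0:
        raise EmptySelectionError("reference selection is empty")
    reference_selection.validate(structure)
    frames = list(frames)
    if reference is None:
        if not frames:
            return []
        reference = frames[0]
    ref_coords = reference_selection.coords(reference)
    aligned = []
    for frame in frames:
        rot, trans, _ = kabsch_superpose(
            reference_selection.coords(frame), ref_coords)
        aligned.append(MembraneFrame(
            frame.time, apply_transform(frame.coords, rot, trans),
            frame.box.copy()))
    return aligned


@dataclass
class DensityGrid:
    """Regular isotropic 3D grid of mean per-frame occupancy counts."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    values: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be positive")
        if self.values.shape != tuple(self.shape):
            raise ParameterError("values shape does not match grid shape")

    @property
    def total_observations(self) -> float:
        return float(self.values.sum() * self.n_frames)

    def voxel_centers(self):
        axes = [self.origin[d] + self.spacing * (np.arange(self.shape[d]) + 0.5)
                for d in range(3)]
        return axes


def density_grid(frames, structure: Structure, selection: Selection,
                 spacing: float = 0.1,
                 bounds: tuple | None = None,
                 margin: float = 0.5,
                 sigma: float = 0.0) -> DensityGrid:
    """Mean per-frame voxel occupancy of ``selection`` particles.

    Point (nearest-voxel) assignment by default; ``sigma`` > 0 smears
    each observation with an isotropic Gaussian of that width (nm) for
    visual parity with viewer-style density tools (conservation then
    holds only approximately near the grid edge).

    ``bounds`` is ((lo_x, lo_y, lo_z), (hi_x, hi_y, hi_z)); when omitted
    the grid is auto-sized to cover all selected coordinates over all
    frames plus ``margin`` nm, so auto-bounds never raise.  With
    explicit bounds an outside particle is an error, never silently
    dropped.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    frames = list(frames)
    if not frames:
        raise ParameterError("no frames")
    selection.validate(structure)
    if len(selection) == 0:
        raise EmptySelectionError("density selection is empty")
    coords = np.concatenate([selection.coords(f) for f in frames])
    if bounds is None:
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        explicit = False
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        explicit = True
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) for d in range(3))
    shape = tuple(max(s, 1) for s in shape)
    counts = np.zeros(shape, dtype=float)
    for frame in frames:
        pts = selection.coords(frame)
        idx = np.floor((pts - lo) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        if explicit and not np.all(inside):
            bad = pts[~inside][0]
            raise ParameterError(
                f"particle at {bad} lies outside explicit grid bounds")
        idx = idx[inside]
        if sigma == 0.0:
            np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
        else:
            _smear(counts, pts[inside], lo, spacing, sigma)
    return DensityGrid(lo, spacing, shape, counts / len(frames), len(frames))


def _smear(counts, pts, lo, spacing, sigma):
    """Deposit Gaussian-weighted observations (3-sigma cutoff)."""
    reach = int(np.ceil(3.0 * sigma / spacing))
    axes_shape = counts.shape
    offsets = np.arange(-reach, reach + 1)
    for p in pts:
        idx0 = np.floor((p - lo) / spacing).astype(int)
        w_axes = []
        ranges = []
        for d in range(3):
            ids = idx0[d] + offsets
            ok = (ids >= 0) & (ids < axes_shape[d])
            ids = ids[ok]
            centers = lo[d] + spacing * (ids + 0.5)
            w_axes.append(np.exp(-0.5 * ((centers - p[d]) / sigma) ** 2))
            ranges.append(ids)
        w = (w_axes[0][:, None, None] * w_axes[1][None, :, None]
             * w_axes[2][None, None, :])
        s = w.sum()
        if s > 0:
            counts[np.ix_(ranges[0], ranges[1], ranges[2])] += w / s


# ---------------------------------------------------------------------------
# OpenDX I/O
# ---------------------------------------------------------------------------

def export_dx(grid: DensityGrid, path):
    """Write the grid as an OpenDX scalar field (nm units, z fastest)."""
    nx, ny, nz = grid.shape
    vals = grid.values.reshape(-1)  # C order: z fastest, matching DX
    with open(path, "w") as fh:
        fh.write("# OpenDX density written by scramblekit (units: nm)\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6g} {:.6g} {:.6g}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6g} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6g} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{vals.size} data follows\n")
        for start in range(0, vals.size, 3):
            chunk = vals[start:start + 3]
            fh.write(" ".join(f"{v:.6g}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`export_dx`."""
    shape = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                shape = tuple(int(t) for t in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(t) for t in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(t) for t in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
            elif n_items is not None and len(values) < n_items:
                try:
                    values.extend(float(t) for t in s.split())
                except ValueError:
                    if s.startswith(("attribute", "object", "component")):
                        continue
                    raise ParseError("malformed data line",
                                     path=path, line=lineno) from None
    if shape is None or origin is None or len(deltas) < 3 or n_items is None:
        raise ParseError("incomplete OpenDX header", path=path)
    d = np.array(deltas)
    spac = d[0][0]
    if not (abs(d[1][1] - spac) < 1e-9 and abs(d[2][2] - spac) < 1e-9):
        raise ParseError("anisotropic spacing is not supported", path=path)
    vals = np.array(values[:n_items]).reshape(shape)
    return DensityGrid(origin, float(spac), shape, vals, n_frames=1)
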