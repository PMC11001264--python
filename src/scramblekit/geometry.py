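"""Periodic-boundary geometry, membrane centering and Kabsch RMSD."""

from __future__ import annotations

import numpy as np

from .core import MembraneFrame, Selection, Structure
from .errors import DegenerateGeometryError, EmptySelectionError, ValidationError


def minimum_image_xy(dxy: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to xy displacement vectors."""
    dxy = np.asarray(dxy, dtype=float)
    return dxy - box[:2] * np.round(dxy / box[:2])


def unwrap_z(z: np.ndarray, box_z: float) -> np.ndarray:
    """Shift each z by multiples of the box height so the set is contiguous.

    Values are taken in input order; each is placed within +-box_z/2 of
    the running median of the values placed so far.  This reconstructs a
    bilayer split across the periodic z boundary before its center is
    averaged.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    placed: list[float] = []
    for i, zi in enumerate(z):
        if placed:
            ref = float(np.median(placed))
            zi = zi - box_z * np.round((zi - ref) / box_z)
        out[i] = zi
        placed.append(zi)
    return out


def membrane_midplane(frame: MembraneFrame, structure: Structure,
                      wrap: bool = True) -> float:
    """Global membrane center: mean z of all lipid phosphate beads.

    With ``wrap=True`` (default) phosphates are first made contiguous
    across the periodic z boundary (see :func:`unwrap_z`).
    """
    hg = structure.headgroup_ids
    if len(hg) < 2:
        raise EmptySelectionError(
            "membrane midplane needs at least 2 lipid headgroups")
    z = frame.coords[hg, 2]
    if wrap:
        z = unwrap_z(z, frame.box[2])
    return float(np.mean(z))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the least-squares
    deviation from ``reference``.  The rotation is proper
    (determinant +1); reflections are never returned.

    Raises :class:`DegenerateGeometryError` for n < 3 or (near-)collinear
    point sets, where the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError(
            f"coordinate sets differ in shape: {mobile.shape} vs "
            f"{reference.shape}")
    n = mobile.shape[0]
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("coordinates must have shape (n, 3)")
    if n < 3:
        raise DegenerateGeometryError(
            f"superposition needs at least 3 points, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    p = mobile - mc
    q = reference - rc
    # collinearity check: a unique rotation needs >= 2 non-degenerate
    # principal directions in both sets
    for label, x in (("mobile", p), ("reference", q)):
        s = np.linalg.svd(x, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-12):
            raise DegenerateGeometryError(
                f"{label} coordinates are (near-)collinear; rotation is "
                "not unique")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd_timeseries(frames, reference: MembraneFrame, selection: Selection,
                    structure: Structure | None = None) -> np.ndarray:
    """Per-frame RMSD (nm) after Kabsch superposition on ``selection``.

    Returns an array of shape (n_frames, 2) with columns (time_ps, rmsd).
    Pairing is positional within the selection; the same topology is
    assumed across frames.
    """
    if structure is not None:
        selection.validate(structure)
    ref = selection.coords(reference)
    out = np.empty((len(frames), 2))
    for i, frame in enumerate(frames):
        _, _, rmsd = kabsch_superpose(selection.coords(frame), ref)
        out[i] = (frame.time, rmsd)
    return out
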