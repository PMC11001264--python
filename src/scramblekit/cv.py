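"""The flip-flop collective variable and bias potentials.

The reaction coordinate is the *oriented* z-distance between a tracked
lipid's phosphate bead and the local membrane center of mass, where the
local center is averaged over lipid particles inside a vertical cylinder
(radius 2.0 nm for proteinless membranes, 3.0 nm with protein) whose
axis passes through the phosphate.  Positive values mean the phosphate
sits above the local center.

Bias potentials cover the harmonic umbrella restraint and the
flat-bottom xy-plane restraint used to keep the tracked lipid near the
scrambling pathway (reference distance 2.5 nm, k = 500 kJ/mol/nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MembraneFrame, Selection, Structure
from .errors import EmptyCylinderError, ParameterError, ValidationError
from .geometry import minimum_image_xy


@dataclass
class CylinderCVSpec:
    """Geometry of the local-membrane-center cylinder.

    ``membrane_selection`` lists the lipid particles contributing to the
    local center (all lipid beads of all lipids except the tracked one,
    by default — build with :func:`make_cv_spec`).  ``switch_width`` > 0
    replaces the hard radial cutoff with a cosine taper of that width
    just inside the radius (sensitivity option; default hard cutoff).
    """

    radius: float
    tracked_lipid: int
    membrane_selection: Selection
    switch_width: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("cylinder radius must be positive")
        if self.switch_width < 0 or self.switch_width >= self.radius:
            raise ParameterError("switch width must be in [0, radius)")


def make_cv_spec(structure: Structure, tracked_lipid: int,
                 radius: float = 3.0, switch_width: float = 0.0
                 ) -> CylinderCVSpec:
    """Build the CV spec for a tracked lipid residue.

    The membrane selection is every particle of every *other* lipid
    (headgroups and tails); the tracked lipid is excluded so it cannot
    bias its own reference.
    """
    lipid = structure.roles == "lipid"
    not_tracked = structure.residue_ids != tracked_lipid
    ids = structure.particle_ids[lipid & not_tracked]
    if len(ids) == 0:
        raise ValidationError("no membrane particles besides tracked lipid")
    return CylinderCVSpec(radius, tracked_lipid,
                          Selection("membrane", ids), switch_width)


def _cylinder_weights(frame: MembraneFrame, spec: CylinderCVSpec,
                      phosphate_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = spec.membrane_selection.particle_ids
    dxy = frame.coords[ids, :2] - phosphate_xy
    r = np.linalg.norm(minimum_image_xy(dxy, frame.box), axis=1)
    if spec.switch_width == 0.0:
        w = (r <= spec.radius).astype(float)
    else:
        inner = spec.radius - spec.switch_width
        w = np.zeros_like(r)
        w[r <= inner] = 1.0
        taper = (r > inner) & (r <= spec.radius)
        w[taper] = 0.5 * (1.0 + np.cos(
            np.pi * (r[taper] - inner) / spec.switch_width))
    return ids, w


def local_membrane_center(frame: MembraneFrame, spec: CylinderCVSpec,
                          structure: Structure) -> float:
    """Mean z of membrane particles inside the cylinder around the phosphate.

    Uniform particle weighting with a hard radius cutoff (minimum image
    in xy).  Raises :class:`EmptyCylinderError` when no particle falls
    inside — the caller may widen the radius.
    """
    phos = structure.headgroup_of(spec.tracked_lipid)
    ids, w = _cylinder_weights(frame, spec, frame.coords[phos, :2])
    wsum = w.sum()
    if wsum <= 0:
        raise EmptyCylinderError(
            f"no membrane particle within {spec.radius} nm of lipid "
            f"{spec.tracked_lipid}'s phosphate in xy")
    return float(np.sum(w * frame.coords[ids, 2]) / wsum)


def oriented_cv(frame: MembraneFrame, spec: CylinderCVSpec,
                structure: Structure) -> float:
    """Signed z-distance of the tracked phosphate to the local center."""
    phos = structure.headgroup_of(spec.tracked_lipid)
    return float(frame.coords[phos, 2]
                 - local_membrane_center(frame, spec, structure))


def cv_timeseries(frames, spec: CylinderCVSpec, structure: Structure
                  ) -> np.ndarray:
    """(time, cv) pairs for a frame sequence; shape (n_frames, 2)."""
    out = np.empty((len(frames), 2))
    for i, frame in enumerate(frames):
        out[i] = (frame.time, oriented_cv(frame, spec, structure))
    return out


def xyz_distance_cv(frame: MembraneFrame, particle_id: int,
                    selection: Selection) -> float:
    """3D distance between a particle and a selection's center of mass.

    Utility coordinate (used in steered-pulling setups to drag a
    phosphorus away from a helix); minimum image in all three axes.
    """
    com = selection.coords(frame).mean(axis=0)
    d = frame.coords[particle_id] - com
    d -= frame.box * np.round(d / frame.box)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# bias potentials
# ---------------------------------------------------------------------------

@dataclass
class BiasSpec:
    """Harmonic umbrella bias or flat-bottom xy restraint.

    harmonic:        U(s)  = k/2 (s - center)^2
    flat_bottom_xy:  U(d)  = 0 for d <= center, else k/2 (d - center)^2,
                     where d is an xy-plane distance to ``anchor``.
    Units: center nm, k kJ/mol/nm^2.
    """

    kind: str
    center: float
    k: float
    anchor: int | None = None

    def __post_init__(self):
        if self.kind not in ("harmonic", "flat_bottom_xy"):
            raise ParameterError(f"unknown bias kind {self.kind!r}")
        if self.k < 0:
            raise ParameterError("force constant must be non-negative")


def bias_energy(value: float, spec: BiasSpec) -> float:
    """Bias energy (kJ/mol) at a CV value (harmonic) or xy distance
    (flat-bottom)."""
    value = np.asarray(value, dtype=float)
    if spec.kind == "harmonic":
        e = 0.5 * spec.k * (value - spec.center) ** 2
    else:
        excess = np.maximum(value - spec.center, 0.0)
        e = 0.5 * spec.k * excess ** 2
    return float(e) if e.ndim == 0 else e


def flat_bottom_xy_distance(frame: MembraneFrame, particle_id: int,
                            anchor_id: int) -> float:
    """xy-plane minimum-image distance between a particle and its anchor."""
    dxy = frame.coords[particle_id, :2] - frame.coords[anchor_id, :2]
    return float(np.linalg.norm(minimum_image_xy(dxy, frame.box)))
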