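"""Core data model: particles, roles, frames and selections.

A :class:`Structure` is the static topology of the system — particle and
residue identities plus a coarse *role* (lipid / protein / water / ion)
assigned from the residue name via user-supplied rules.  A
:class:`MembraneFrame` is one snapshot of coordinates with an
orthorhombic box.  A :class:`Selection` is an ordered list of particle
indices; order matters because RMSD pairing is positional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, ParameterError, ValidationError

ROLES = ("lipid", "protein", "water", "ion")

#: residue-name -> role rules covering common Martini / CHARMM naming.
DEFAULT_ROLE_RULES: dict[str, str] = {
    # lipids
    "POPC": "lipid", "POPE": "lipid", "POPS": "lipid", "DOPC": "lipid",
    "DPPC": "lipid", "DOPE": "lipid", "CDL2": "lipid", "LIP": "lipid",
    # water
    "W": "water", "PW": "water", "WF": "water", "SOL": "water",
    "TIP3": "water", "HOH": "water",
    # ions
    "NA": "ion", "NA+": "ion", "CL": "ion", "CL-": "ion", "ION": "ion",
    "K": "ion", "K+": "ion", "SOD": "ion", "CLA": "ion",
    # amino acids (3-letter) -> protein
    **{aa: "protein" for aa in (
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "HSD", "HSE", "HSP", "PROT",
    )},
}

#: particle names recognised as the lipid headgroup reference (phosphate).
DEFAULT_HEADGROUP_PATTERN = r"PO4|P"


@dataclass(frozen=True)
class RoleRules:
    """Residue-name -> role mapping plus the headgroup particle pattern.

    ``headgroup_pattern`` is a regular expression matched (fully) against
    particle names of lipid residues to find the per-lipid phosphate
    reference bead.
    """

    residue_roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_RULES))
    headgroup_pattern: str = DEFAULT_HEADGROUP_PATTERN

    def role_of(self, residue_name: str) -> str | None:
        return self.residue_roles.get(residue_name)

    def is_headgroup(self, particle_name: str) -> bool:
        return re.fullmatch(self.headgroup_pattern, particle_name) is not None


class Structure:
    """Static topology: ids, residues, particle names and roles.

    Particle ids are contiguous integers from 0.  Every lipid residue
    must contain exactly one headgroup (phosphate) reference particle.
    """

    def __init__(self, residue_ids, residue_names, particle_names, roles,
                 headgroup_mask=None):
        self.residue_ids = np.asarray(residue_ids, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.particle_names = np.asarray(particle_names, dtype=object)
        self.roles = np.asarray(roles, dtype=object)
        n = len(self.residue_ids)
        if not (len(self.residue_names) == len(self.particle_names)
                == len(self.roles) == n):
            raise ValidationError("per-particle arrays have unequal lengths")
        self.particle_ids = np.arange(n, dtype=np.int64)
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")
        if headgroup_mask is None:
            headgroup_mask = np.zeros(n, dtype=bool)
        self.headgroup_mask = np.asarray(headgroup_mask, dtype=bool)
        self._validate_headgroups()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_particles(cls, residue_ids, residue_names, particle_names,
                       rules: RoleRules | None = None) -> "Structure":
        """Assign roles and headgroups from :class:`RoleRules`.

        Residue names not covered by the rules raise a
        :class:`ValidationError` — never a silent default.
        """
        rules = rules or RoleRules()
        residue_names = np.asarray(residue_names, dtype=object)
        particle_names = np.asarray(particle_names, dtype=object)
        roles = np.empty(len(residue_names), dtype=object)
        unassigned = set()
        for i, rn in enumerate(residue_names):
            role = rules.role_of(rn)
            if role is None:
                unassigned.add(rn)
            roles[i] = role
        if unassigned:
            raise ValidationError(
                "unassigned roles for residue names: "
                f"{sorted(unassigned)}; extend the role rules")
        hg = np.array([roles[i] == "lipid" and rules.is_headgroup(pn)
                       for i, pn in enumerate(particle_names)], dtype=bool)
        return cls(residue_ids, residue_names, particle_names, roles, hg)

    def _validate_headgroups(self):
        lipid = self.roles == "lipid"
        for rid in np.unique(self.residue_ids[lipid]):
            n_hg = int(np.sum(self.headgroup_mask
                              & (self.residue_ids == rid)))
            if n_hg != 1:
                raise ValidationError(
                    f"lipid residue {rid} has {n_hg} headgroup reference "
                    "particles; exactly one is required")
        if np.any(self.headgroup_mask & ~lipid):
            raise ValidationError("headgroup flagged on a non-lipid particle")

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.particle_ids)

    @property
    def n_particles(self) -> int:
        return len(self)

    @property
    def headgroup_ids(self) -> np.ndarray:
        """Particle ids of lipid phosphate reference beads."""
        return self.particle_ids[self.headgroup_mask]

    @property
    def lipid_residue_ids(self) -> np.ndarray:
        return np.unique(self.residue_ids[self.roles == "lipid"])

    def select_role(self, role: str, name: str | None = None) -> "Selection":
        if role not in ROLES:
            raise ParameterError(f"unknown role {role!r}")
        ids = self.particle_ids[self.roles == role]
        return Selection(name or role, ids)

    def select_names(self, particle_names, name: str = "named") -> "Selection":
        wanted = set(np.atleast_1d(particle_names))
        mask = np.array([pn in wanted for pn in self.particle_names])
        return Selection(name, self.particle_ids[mask])

    def select_residue_ranges(self, ranges, particle_names=None,
                              name: str = "ranges") -> "Selection":
        """Particles whose residue id falls in any inclusive (lo, hi) range.

        Used e.g. for the cavity-helix residue windows; optionally
        restricted to given particle names (e.g. backbone atoms).
        """
        mask = np.zeros(len(self), dtype=bool)
        for lo, hi in ranges:
            mask |= (self.residue_ids >= lo) & (self.residue_ids <= hi)
        if particle_names is not None:
            wanted = set(np.atleast_1d(particle_names))
            mask &= np.array([pn in wanted for pn in self.particle_names])
        return Selection(name, self.particle_ids[mask])

    def headgroup_of(self, lipid_residue_id: int) -> int:
        mask = self.headgroup_mask & (self.residue_ids == lipid_residue_id)
        ids = self.particle_ids[mask]
        if len(ids) == 0:
            raise EmptySelectionError(
                f"residue {lipid_residue_id} has no headgroup particle")
        return int(ids[0])


@dataclass
class MembraneFrame:
    """One snapshot: time (ps), coords (n, 3) in nm, orthorhombic box (3,)."""

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must have shape (n, 3)")
        if self.box.shape != (3,):
            raise ValidationError("box must be a 3-vector of edge lengths")
        if not np.all(self.box > 0):
            raise ValidationError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")

    def copy(self) -> "MembraneFrame":
        return MembraneFrame(self.time, self.coords.copy(), self.box.copy())


@dataclass(frozen=True)
class Selection:
    """Named, ordered particle-id list (order defines RMSD pairing)."""

    name: str
    particle_ids: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.particle_ids, dtype=np.int64)
        object.__setattr__(self, "particle_ids", ids)
        if ids.ndim != 1:
            raise ValidationError("particle_ids must be 1-D")
        if len(np.unique(ids)) != len(ids):
            raise ValidationError(f"selection {self.name!r} has duplicates")

    def __len__(self) -> int:
        return len(self.particle_ids)

    def validate(self, structure: Structure):
        if len(self) and (self.particle_ids.min() < 0
                          or self.particle_ids.max() >= len(structure)):
            raise ValidationError(
                f"selection {self.name!r} has ids outside the structure")

    def coords(self, frame: MembraneFrame) -> np.ndarray:
        return frame.coords[self.particle_ids]
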