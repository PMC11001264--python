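"""Shared fixtures: tiny structures and frames built programmatically."""

import numpy as np
import pytest

from scramblekit import MembraneFrame, Structure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY_SYSTEM = [
    # (resid, resname, particle name, x, y, z) in nm
    (1, "POPC", "PO4", 1.0, 2.0, 3.0),
    (2, "W", "W", 4.0, 4.0, 4.0),
    (3, "NA", "NA", 0.5, 0.5, 0.5),
]


@pytest.fixture
def tiny_gro(tmp_path):
    """3-particle GRO file: one POPC PO4 bead, one water, one ion."""
    lines = ["tiny membrane t= 0.0", f"{len(TINY_SYSTEM):5d}"]
    for i, (rid, rn, pn, x, y, z) in enumerate(TINY_SYSTEM):
        lines.append(f"{rid:5d}{rn:<5s}{pn:>5s}{i + 1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{10.0:10.5f}{10.0:10.5f}{8.0:10.5f}")
    path = tmp_path / "tiny.gro"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_pdb(tmp_path):
    """Same content as tiny_gro, expressed as a PDB (Angstrom)."""
    lines = ["CRYST1  100.000  100.000   80.000  90.00  90.00  90.00 P 1"]
    for i, (rid, rn, pn, x, y, z) in enumerate(TINY_SYSTEM):
        lines.append(f"ATOM  {i + 1:5d} {pn:<4s} {rn:<4s}A{rid:4d}    "
                     f"{x * 10:8.3f}{y * 10:8.3f}{z * 10:8.3f}"
                     f"  1.00  0.00")
    lines.append("END")
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def flat_bilayer():
    """20 phosphates at z = 5 +- 2 in a 10x10x8 box: ideal two-leaflet slab."""
    n_per_leaf = 10
    resids, resnames, names, coords = [], [], [], []
    for i in range(2 * n_per_leaf):
        resids.append(i + 1)
        resnames.append("POPC")
        names.append("PO4")
        z = 7.0 if i < n_per_leaf else 3.0
        coords.append([i % 5 + 0.5, i // 5 % 2 * 5 + 2.0, z])
    structure = Structure.from_particles(resids, resnames, names)
    frame = MembraneFrame(0.0, np.array(coords), np.array([10.0, 10.0, 8.0]))
    return structure, frame
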