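"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library code paths they check: the RMSD
oracle searches rotation space numerically instead of using the SVD
solution, and the cylinder oracle is a direct O(N) loop.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from scramblekit.errors import EmptyCylinderError


def brute_force_min_rmsd(mobile, reference, n_starts=60, seed=0):
    """Minimum RMSD over rotations via quaternion-grid multistart plus
    Nelder-Mead refinement."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for quat in rng.normal(size=(n_starts, 4)):
        rv = Rotation.from_quat(quat / np.linalg.norm(quat)).as_rotvec()
        res = minimize(rmsd_of, rv, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


def brute_force_center(frame, structure, spec):
    """Direct loop: uniform mean z of membrane particles whose
    minimum-image xy distance to the tracked phosphate <= radius."""
    phos = structure.headgroup_of(spec.tracked_lipid)
    pxy = frame.coords[phos, :2]
    zs = []
    for pid in spec.membrane_selection.particle_ids:
        d = frame.coords[pid, :2] - pxy
        d = d - frame.box[:2] * np.round(d / frame.box[:2])
        if np.hypot(*d) <= spec.radius:
            zs.append(frame.coords[pid, 2])
    if not zs:
        raise EmptyCylinderError("empty")
    return float(np.mean(zs))
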