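"""Ground-truth generators for pipeline validation without MD.

Three generators make every analysis stage testable against known
truth:

* :func:`simulate_flipflop` — overdamped (Brownian) Langevin dynamics of
  lipid CV coordinates over an analytic bilayer PMF, with a ledger of
  every leaflet crossing at the output stride;
* :func:`simulate_umbrella_set` — *exact* Boltzmann samples from each
  umbrella window's biased stationary density via inverse-transform
  sampling on a fine grid (i.i.d., no autocorrelation, no equilibration
  artifacts — a WHAM recovery failure therefore indicts the solver, not
  the data);
* :func:`build_membrane_fixture` — static two-leaflet bead membranes
  with optional tails, protein blob, water, and scripted flip-flop
  events for leaflet / CV / density / RMSD tests.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .core import MembraneFrame, Structure
from .errors import ParameterError, ValidationError
from .scrambling import DOWN_TO_UP, UP_TO_DOWN
from .wham import UmbrellaWindow


# ---------------------------------------------------------------------------
# analytic PMFs
# ---------------------------------------------------------------------------

@dataclass
class PMFSpec:
    """Analytic flip-flop PMF driving the generators.

    The quartic double well

        F(s) = barrier * (1 - (s/z0)^2)^2   for |s| <= z0, flat 0 beyond

    has wells F = 0 at s = +-z0 (the phosphate levels of the two
    leaflets, default 1.9 nm) and F(0) = barrier.  Barrier presets of
    interest: 62/83/92 kJ/mol (membrane-only coarse-grained and
    atomistic profiles) and 7/15/16 kJ/mol (protein-assisted ones).
    ``tabulated`` PMFs interpolate user (s, F) pairs.
    """

    form: str = "quartic_double_well"
    barrier: float = 62.0
    well_position: float = 1.9
    table: np.ndarray | None = None

    def __post_init__(self):
        if self.form not in ("quartic_double_well", "tabulated"):
            raise ParameterError(f"unknown PMF form {self.form!r}")
        if self.form == "quartic_double_well":
            if self.barrier < 0:
                raise ParameterError("barrier must be non-negative")
            if self.well_position <= 0:
                raise ParameterError("well position must be positive")
        else:
            if self.table is None:
                raise ParameterError("tabulated PMF needs a table")
            self.table = np.asarray(self.table, dtype=float)
            if self.table.ndim != 2 or self.table.shape[1] != 2:
                raise ParameterError("table must be (n, 2) of (s, F)")

    def F(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.form == "quartic_double_well":
            u = np.clip(np.abs(s) / self.well_position, None, 1.0)
            return self.barrier * (1.0 - u ** 2) ** 2
        return np.interp(s, self.table[:, 0], self.table[:, 1])

    def dF(self, s) -> np.ndarray:
        """Gradient dF/ds (kJ/mol/nm)."""
        s = np.asarray(s, dtype=float)
        if self.form == "quartic_double_well":
            z0 = self.well_position
            u = s / z0
            inside = np.abs(u) <= 1.0
            g = np.where(inside,
                         -4.0 * self.barrier * u * (1.0 - u ** 2) / z0, 0.0)
            return g
        xs, Fs = self.table[:, 0], self.table[:, 1]
        grads = np.gradient(Fs, xs)
        return np.interp(s, xs, grads)

    def max_gradient(self, domain=(-2.4, 2.4), n: int = 2001) -> float:
        grid = np.linspace(*domain, n)
        return float(np.max(np.abs(self.dF(grid))))


@dataclass
class LangevinParams:
    """Overdamped-dynamics parameters for :func:`simulate_flipflop`.

    D is the effective diffusion coefficient along the CV (nm^2/ps),
    dt the integration step (ps).  Construction validates the drift
    stability condition (D/kT)*max|F'|*dt <= 0.1 * well width so a
    single step can never ballistically cross a well.
    """

    D: float = 0.01
    dt: float = 5.0
    T: float = DEFAULT_TEMPERATURE
    n_steps: int = 200_000
    n_lipids: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.D <= 0 or self.dt <= 0:
            raise ParameterError("D and dt must be positive")
        if self.n_steps < 1 or self.n_lipids < 1:
            raise ParameterError("n_steps and n_lipids must be >= 1")

    @property
    def kT(self) -> float:
        return kt(self.T)

    def validate_stability(self, pmf: PMFSpec, domain=(-2.4, 2.4)):
        width = (pmf.well_position if pmf.form == "quartic_double_well"
                 else 0.25 * (domain[1] - domain[0]))
        drift = (self.D / self.kT) * pmf.max_gradient(domain) * self.dt
        if drift > 0.1 * width:
            raise ParameterError(
                f"unstable integration: max drift step {drift:.3g} nm "
                f"exceeds 10% of the well width {width:.3g} nm; reduce dt")


@dataclass
class FlipFlopTrajectory:
    """Langevin CV trajectories with the generator's crossing ledger.

    ``s`` has shape (n_recorded, n_lipids); ``events`` is the ground
    truth: every leaflet change observed at the recording stride, as
    (lipid_id, time_ps, direction).
    """

    times: np.ndarray
    s: np.ndarray
    events: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_us(self) -> float:
        return float(self.times[-1] - self.times[0]) / 1e6


def simulate_flipflop(pmf: PMFSpec, params: LangevinParams,
                      out_stride: int = 1, s0=None,
                      domain=(-2.4, 2.4)) -> FlipFlopTrajectory:
    """Euler-Maruyama overdamped dynamics over the PMF.

        s(t+dt) = s(t) - (D/kT) F'(s) dt + sqrt(2 D dt) xi

    Lipids start alternating in the two wells unless ``s0`` is given.
    Positions are recorded (and the crossing ledger updated) every
    ``out_stride`` steps; crossings are sign changes of s at that
    stride, with exact zeros inheriting the previous leaflet.
    """
    params.validate_stability(pmf, domain)
    rng = np.random.default_rng(params.seed)
    kT = params.kT
    n = params.n_lipids
    if s0 is None:
        z0 = (pmf.well_position if pmf.form == "quartic_double_well" else 0.0)
        s = np.where(np.arange(n) % 2 == 0, z0, -z0).astype(float)
    else:
        s = np.array(s0, dtype=float)
        if s.shape != (n,):
            raise ParameterError("s0 must have one value per lipid")
    noise_amp = np.sqrt(2.0 * params.D * params.dt)
    mob = params.D / kT

    n_rec = params.n_steps // out_stride + 1
    times = params.dt * out_stride * np.arange(n_rec)
    rec = np.empty((n_rec, n), dtype=float)
    rec[0] = s
    upper = s > 0  # ties at t0 default to upper, matching the analyzer
    upper |= (s == 0)
    events: list[tuple[int, float, str]] = []
    r = 1
    for step in range(1, params.n_steps + 1):
        s = s - mob * pmf.dF(s) * params.dt \
            + noise_amp * rng.standard_normal(n)
        np.clip(s, domain[0], domain[1], out=s)
        if step % out_stride == 0:
            rec[r] = s
            new_upper = upper.copy()
            new_upper[s > 0] = True
            new_upper[s < 0] = False
            for j in np.nonzero(new_upper != upper)[0]:
                events.append((int(j), float(times[r]),
                               UP_TO_DOWN if upper[j] else DOWN_TO_UP))
            upper = new_upper
            r += 1
    return FlipFlopTrajectory(times, rec[:r], events)


# ---------------------------------------------------------------------------
# umbrella ensembles
# ---------------------------------------------------------------------------

def umbrella_target_cdf(pmf: PMFSpec, center: float, k: float,
                        T: float = DEFAULT_TEMPERATURE,
                        domain=(-2.4, 2.4), n_grid: int = 4801):
    """Grid and CDF of the biased stationary density
    ~ exp(-[F(s) + k/2 (s-c)^2] / kT) on ``domain``."""
    grid = np.linspace(domain[0], domain[1], n_grid)
    energy = pmf.F(grid) + 0.5 * k * (grid - center) ** 2
    w = np.exp(-(energy - energy.min()) / kt(T))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(grid))])
    if cdf[-1] <= 0:
        raise ParameterError("unnormalizable biased density on the domain")
    cdf /= cdf[-1]
    return grid, cdf


def simulate_umbrella_set(pmf: PMFSpec, centers, k,
                          n_samples: int = 50_000,
                          T: float = DEFAULT_TEMPERATURE,
                          seed: int = 0, domain=(-2.4, 2.4),
                          n_grid: int = 4801) -> list[UmbrellaWindow]:
    """Boltzmann-exact i.i.d. samples for each umbrella window.

    Each window's samples are drawn by inverse-transform sampling from
    the exact biased stationary density on a fine grid — no dynamics, no
    autocorrelation.  ``k`` may be a scalar or one value per window.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    ks = np.broadcast_to(np.asarray(k, dtype=float), centers.shape)
    if np.any((centers < domain[0]) | (centers > domain[1])):
        raise ParameterError("window centers must lie within the domain")
    rng = np.random.default_rng(seed)
    windows = []
    for c, kk in zip(centers, ks):
        grid, cdf = umbrella_target_cdf(pmf, c, kk, T=T, domain=domain,
                                        n_grid=n_grid)
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(samples, center=float(c), k=float(kk),
                                      name=f"c={c:+.3f}"))
    return windows


def uniform_window_layout(n_windows: int = 67, lo: float = -2.3,
                          hi: float = 2.3) -> np.ndarray:
    """Evenly spaced window centers (the membrane-only CG layout uses 67)."""
    return np.linspace(lo, hi, n_windows)


def nonuniform_window_layout() -> tuple[np.ndarray, np.ndarray]:
    """The 59-window atomistic-style layout: spacing tapers from 0.1 nm
    near the membrane surface to 0.03 nm near the center; force constant
    2000 kJ/mol/nm^2 near the center, 1000 near the surface.

    Returns (centers, force_constants).
    """
    core = -0.25 + 0.03 * np.arange(16)            # -0.25 .. 0.20
    upper = np.concatenate([[0.25, 0.30], 0.40 + 0.1 * np.arange(20)])
    lower = -np.concatenate([[0.30], 0.40 + 0.1 * np.arange(20)])
    centers = np.sort(np.concatenate([lower, core, upper]))
    assert len(centers) == 59
    ks = np.where(np.abs(centers) <= 0.5, 2000.0, 1000.0)
    return centers, ks


# ---------------------------------------------------------------------------
# membrane fixtures
# ---------------------------------------------------------------------------

def build_membrane_fixture(n_lipids: int = 64, leaflet_z: float = 1.9,
                           box=(10.0, 10.0, 8.0), jitter: float = 0.0,
                           seed: int = 0, n_tail_beads: int = 0,
                           n_protein_beads: int = 0, n_water: int = 0,
                           times=None, crossings=None,
                           center_z: float | None = None
                           ) -> tuple[Structure, list[MembraneFrame], list]:
    """Deterministic two-leaflet bead membrane with optional extras.

    Lipids are single "PO4" beads (plus ``n_tail_beads`` tail beads
    toward the midplane) on an xy lattice, half at ``+leaflet_z`` and
    half at ``-leaflet_z`` around the box midheight, jittered by
    Gaussian noise of width ``jitter``.  ``crossings`` scripts flip-flop
    events as (lipid_residue_id, time_ps) pairs: at that frame time the
    lipid teleports to the mirrored z.  Returns
    (structure, frames, ledger) where the ledger lists the scripted
    events as (lipid_id, time, direction).
    """
    if n_lipids % 2 != 0:
        raise ParameterError("n_lipids must be even (two equal leaflets)")
    box = np.asarray(box, dtype=float)
    if center_z is None:
        center_z = box[2] / 2.0
    per_leaf = n_lipids // 2
    nx = int(np.ceil(np.sqrt(per_leaf)))
    if nx * box[0] / max(nx, 1) <= 0:
        raise ParameterError("box too small for the requested lipid count")
    rng = np.random.default_rng(seed)

    resids, resnames, names, base = [], [], [], []
    rid = 0
    lipid_z = []
    for leaf, zsign in ((0, +1.0), (1, -1.0)):
        for i in range(per_leaf):
            rid += 1
            gx = (i % nx + 0.5) * box[0] / nx
            gy = (i // nx + 0.5) * box[1] / nx
            z = center_z + zsign * leaflet_z
            if jitter > 0:
                gx, gy, z = (np.array([gx, gy, z])
                             + jitter * rng.standard_normal(3))
            resids.append(rid)
            resnames.append("POPC")
            names.append("PO4")
            base.append([gx, gy, z])
            lipid_z.append(z)
            for t in range(n_tail_beads):
                resids.append(rid)
                resnames.append("POPC")
                names.append(f"C{t + 1}A")
                frac = (t + 1) / (n_tail_beads + 1)
                base.append([gx, gy, z - zsign * leaflet_z * frac])
    if n_protein_beads:
        prot_center = np.array([box[0] / 2, box[1] / 2, center_z])
        for i in range(n_protein_beads):
            rid += 1
            resids.append(rid)
            resnames.append("GLY")
            names.append("BB")
            base.append(prot_center + 0.3 * rng.standard_normal(3))
    if n_water:
        for i in range(n_water):
            rid += 1
            resids.append(rid)
            resnames.append("W")
            names.append("W")
            base.append(rng.random(3) * box)

    structure = Structure.from_particles(resids, resnames, names)
    base = np.array(base, dtype=float)

    if times is None:
        times = [0.0]
    times = np.asarray(times, dtype=float)
    crossings = list(crossings or [])
    for lipid_id, t in crossings:
        if not (1 <= lipid_id <= n_lipids):
            raise ValidationError(f"crossing names unknown lipid {lipid_id}")
        if t <= times[0] or t > times[-1]:
            raise ValidationError(
                f"crossing time {t} outside frame times")

    frames = []
    flipped: dict[int, float] = {}
    ledger = []
    # mirror a lipid's z across the midplane at its scripted time
    lipid_particle_rows = {
        int(r): np.nonzero(structure.residue_ids == r)[0]
        for r in structure.lipid_residue_ids}
    for t in times:
        coords = base.copy()
        for lipid_id, tc in crossings:
            if tc <= t:
                rows = lipid_particle_rows[lipid_id]
                coords[rows, 2] = 2.0 * center_z - coords[rows, 2]
        frames.append(MembraneFrame(float(t), coords, box.copy()))
    for lipid_id, tc in sorted(crossings, key=lambda c: c[1]):
        head = structure.headgroup_of(lipid_id)
        was_upper = base[head, 2] > center_z
        # direction flips again on repeated crossings of the same lipid
        prior = sum(1 for lid, tt in crossings
                    if lid == lipid_id and tt < tc)
        if prior % 2 == 1:
            was_upper = not was_upper
        # snap the event to the first frame at/after the scripted time
        t_ev = float(times[np.searchsorted(times, tc)])
        ledger.append((int(lipid_id), t_ev,
                       UP_TO_DOWN if was_upper else DOWN_TO_UP))
    ledger.sort(key=lambda e: e[1])
    return structure, frames, ledger
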