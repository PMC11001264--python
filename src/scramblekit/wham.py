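"""Umbrella-sampling post-processing: WHAM and free-energy diagnostics.

The estimator combines biased histograms from many harmonically
restrained windows into one unbiased free-energy profile F(s) by
iterating the self-consistent WHAM equations

    p_j  =  ( sum_i N_ij ) / ( sum_i n_i exp[(f_i - c_ij)/kT] )
    f_i  =  -kT ln sum_j p_j exp(-c_ij / kT)

where ``N_ij`` are window i's counts in bin j, ``c_ij`` its bias energy
at the bin center, and ``f_i`` the per-window free-energy constants.
Iteration stops when max_i |delta f_i| drops below tolerance;
F_j = -kT ln p_j is anchored so min F = 0.

Usage follows the model/results idiom::

    model = WHAM(windows, bin_width=0.02, cv_range=(-2.4, 2.4))
    profile = model.fit()
    profile.barrier(bulk_region=(2.0, 2.3))
    print(profile.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import (ConnectivityError, ConvergenceError, DomainError,
                     ParameterError, ParseError, RangeError, ValidationError)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """CV samples from one harmonically biased simulation window.

    ``k`` may be 0 (unbiased window, useful as a closed-form check);
    ``discarded`` records how much equilibration time (ps) was dropped
    when the window was loaded.
    """

    samples: np.ndarray
    center: float
    k: float
    discarded: float = 0.0
    name: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if len(self.samples) == 0:
            raise ValidationError(
                f"window {self.name or self.center}: no samples")
        if self.k < 0:
            raise ParameterError("force constant must be non-negative")

    @property
    def n(self) -> int:
        return len(self.samples)

    def bias(self, x) -> np.ndarray:
        """Harmonic bias energy at CV value(s) x, kJ/mol."""
        return 0.5 * self.k * (np.asarray(x, dtype=float) - self.center) ** 2


def load_window(path, center: float, k: float,
                discard: float = 10_000.0) -> UmbrellaWindow:
    """Load a two-column (time_ps, cv_nm) window file.

    Lines starting with ``#`` or ``@`` (xmgrace headers) are ignored.
    Samples with ``time < discard`` are dropped as equilibration (the
    default mirrors discarding the first 10 ns).
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParseError("expected two columns (time, cv)",
                                 path=path, line=lineno)
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"non-numeric row {parts[:2]}",
                                 path=path, line=lineno) from None
            times.append(t)
            values.append(v)
    times = np.array(times)
    values = np.array(values)
    keep = times >= discard
    if not np.any(keep):
        raise ValidationError(
            f"{path}: no samples left after discarding the first "
            f"{discard} ps")
    return UmbrellaWindow(values[keep], center=center, k=k,
                          discarded=float(discard), name=str(path))


def read_metadata(path):
    """Read a window-metadata file: one ``path center_nm k`` line per window.

    ``#`` comments allowed; relative window paths are resolved against
    the metadata file's directory.  Returns a list of (path, center, k).
    """
    base = Path(path).parent
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ParseError("expected 'path center k'",
                                 path=path, line=lineno)
            try:
                center, k = float(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError("non-numeric center/k",
                                 path=path, line=lineno) from None
            wpath = Path(parts[0])
            if not wpath.is_absolute():
                wpath = base / wpath
            out.append((wpath, center, k))
    return out


def load_windows(metadata_path, discard: float = 10_000.0
                 ) -> list[UmbrellaWindow]:
    return [load_window(p, c, k, discard=discard)
            for p, c, k in read_metadata(metadata_path)]


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class HistogramSet:
    """Per-window histograms on a shared uniform grid."""

    bin_edges: np.ndarray
    counts: np.ndarray  # (n_windows, n_bins) integer
    n_i: np.ndarray     # samples per window

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def build_histograms(windows, bin_width: float,
                     cv_range: tuple[float, float]) -> HistogramSet:
    """Histogram every window on uniform bins over ``cv_range``.

    Bins are half-open ``[edge_j, edge_{j+1})`` with the final bin
    closed.  A sample outside the range raises :class:`RangeError`
    naming the window and value — samples are never silently dropped.
    """
    lo, hi = cv_range
    if hi <= lo:
        raise ParameterError("cv_range upper bound must exceed lower bound")
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    n_bins = int(round((hi - lo) / bin_width))
    if n_bins < 1 or abs(lo + n_bins * bin_width - hi) > 1e-9 * max(1.0, abs(hi)):
        raise ParameterError(
            f"bin width {bin_width} does not tile the range ({lo}, {hi})")
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = hi
    counts = np.zeros((len(windows), n_bins), dtype=np.int64)
    n_i = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        x = w.samples
        if np.any(x < lo) or np.any(x > hi):
            bad = x[(x < lo) | (x > hi)][0]
            raise RangeError(
                f"window {w.name or i} (center {w.center}): sample "
                f"{bad} outside histogram range ({lo}, {hi})")
        idx = np.searchsorted(edges, x, side="right") - 1
        idx[x == hi] = n_bins - 1  # final bin closed
        counts[i] = np.bincount(idx, minlength=n_bins)
        n_i[i] = len(x)
    return HistogramSet(edges, counts, n_i)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """Fitted free-energy profile F(s) with diagnostics.

    ``cv_grid`` holds the centers of bins with nonzero total counts;
    ``F`` is anchored so min F = 0.  ``f_i`` are the per-window
    constants in input-window order.  ``error`` is the asymmetry-based
    estimate when the profile covers a symmetric interval, else NaN.
    """

    cv_grid: np.ndarray
    F: np.ndarray
    f_i: np.ndarray
    kT: float
    error: float = float("nan")
    n_iter: int = 0
    residual: float = float("nan")
    residual_history: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    # -- measurements ---------------------------------------------------

    def barrier(self, bulk_region: tuple[float, float]) -> float:
        return barrier_height(self, bulk_region)

    def asymmetry_error(self, bulk_region: tuple[float, float] | None = None
                        ) -> float:
        return asymmetry_error(self, bulk_region)

    def interp(self, s) -> np.ndarray:
        """Linear interpolation of F onto arbitrary CV values."""
        return np.interp(s, self.cv_grid, self.F)

    # -- presentation ---------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Free-energy profile (WHAM)",
            "=" * 44,
            f"kT (kJ/mol)                {self.kT:>12.6f}",
            f"windows                    {len(self.f_i):>12d}",
            f"bins with samples          {len(self.cv_grid):>12d}",
            f"CV coverage (nm)           "
            f"[{self.cv_grid.min():.3f}, {self.cv_grid.max():.3f}]",
            f"iterations                 {self.n_iter:>12d}",
            f"final residual (kJ/mol)    {self.residual:>12.3e}",
            f"max F (kJ/mol)             {self.F.max():>12.3f}",
            f"asymmetry error (kJ/mol)   {self.error:>12.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path, header_lines=()):
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("# cv_nm\tF_kJ_per_mol\terror_kJ_per_mol\n")
            for s, f in zip(self.cv_grid, self.F):
                fh.write(f"{s:.6f}\t{f:.6f}\t{self.error:.6f}\n")

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.cv_grid, self.F, **kwargs)
        if np.isfinite(self.error):
            ax.fill_between(self.cv_grid, self.F - self.error,
                            self.F + self.error, alpha=0.25)
        ax.set_xlabel("CV s (nm)")
        ax.set_ylabel("F (kJ/mol)")
        return ax


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _merge_windows(hists: HistogramSet, windows) -> tuple:
    """Canonicalize: merge windows sharing (center, k), sort by bias.

    Makes the solve invariant — bit-identically — under window
    permutation and under splitting one window's samples across several
    windows with the same bias (counts are summed as integers).
    Returns (centers, ks, counts, n, group_of_window).
    """
    keys = [(float(w.center), float(w.k)) for w in windows]
    order = sorted(set(keys))
    group = {key: g for g, key in enumerate(order)}
    n_groups = len(order)
    counts = np.zeros((n_groups, hists.n_bins), dtype=np.int64)
    n = np.zeros(n_groups, dtype=np.int64)
    for i, key in enumerate(keys):
        g = group[key]
        counts[g] += hists.counts[i]
        n[g] += hists.n_i[i]
    centers = np.array([c for c, _ in order])
    ks = np.array([k for _, k in order])
    return centers, ks, counts, n, np.array([group[key] for key in keys])


def wham_solve(hists: HistogramSet, windows, kT: float | None = None,
               tol: float = 1e-6, max_iter: int = 100_000,
               damping: float = 0.0) -> FreeEnergyProfile:
    """Iterate the WHAM equations to self-consistency.

    ``damping`` in [0, 1) mixes a fraction of the previous ``f_i``
    into each update (0 = plain fixed-point iteration).
    """
    if kT is None:
        kT = kt(DEFAULT_TEMPERATURE)
    if len(windows) != hists.counts.shape[0]:
        raise ValidationError("histograms/windows length mismatch")
    if not 0.0 <= damping < 1.0:
        raise ParameterError("damping must be in [0, 1)")

    centers, ks, counts, n, group_of = _merge_windows(hists, windows)
    x = hists.bin_centers
    total = counts.sum(axis=0)
    defined = total > 0
    if not np.any(defined):
        raise ValidationError("no samples in any bin")
    nz = np.nonzero(defined)[0]
    interior_zero = np.nonzero(total[nz[0]:nz[-1] + 1] == 0)[0] + nz[0]
    for gap in interior_zero:
        # a zero-count bin only disconnects the range if no single
        # window has sampling on both sides of it
        spanned = np.any((counts[:, :gap].sum(axis=1) > 0)
                         & (counts[:, gap + 1:].sum(axis=1) > 0))
        if not spanned:
            raise ConnectivityError(
                f"zero-count gap at CV ~ {x[gap]:.3f} nm splits the "
                "sampled range; WHAM cannot connect the two sides")

    xd = x[defined]
    total_d = total[defined].astype(float)
    # Boltzmann factor of each (merged) window's bias at each defined bin
    # center.  Distant window/bin pairs underflow to exactly 0, which is
    # the correct negligible weight; double precision covers barriers up
    # to ~1500 kJ/mol at physiological kT before p_j itself underflows.
    c_ij = 0.5 * ks[:, None] * (xd[None, :] - centers[:, None]) ** 2
    with np.errstate(under="ignore"):
        b_ij = np.exp(-c_ij / kT)        # (G, B)
    nf = n.astype(float)

    f = np.zeros(len(centers))
    residuals = []
    converged = False
    with np.errstate(under="ignore"):
        for it in range(1, max_iter + 1):
            # denominator per bin: sum_i n_i exp[(f_i - c_ij)/kT]
            denom = np.exp(f / kT) * nf @ b_ij
            p = total_d / denom
            p /= p.sum()                 # normalize over defined bins
            f_new = -kT * np.log(b_ij @ p)
            if damping > 0.0:
                f_new = (1.0 - damping) * f_new + damping * f
            resid = float(np.max(np.abs(f_new - f)))
            residuals.append(resid)
            f = f_new
            if resid < tol:
                converged = True
                break
    if not converged:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residuals[-1]:.3e} kJ/mol)", residual=residuals[-1])

    with np.errstate(under="ignore"):
        denom = np.exp(f / kT) * nf @ b_ij
        p = total_d / denom
        p /= p.sum()
    F = -kT * np.log(p)
    F -= F.min()

    profile = FreeEnergyProfile(
        cv_grid=xd, F=F, f_i=f[group_of], kT=kT,
        n_iter=len(residuals), residual=residuals[-1],
        residual_history=np.array(residuals))
    try:
        profile.error = asymmetry_error(profile)
    except DomainError:
        profile.error = float("nan")
    return profile


class WHAM:
    """Model object for umbrella-sampling free-energy estimation.

    Parameters
    ----------
    windows : list of UmbrellaWindow
    bin_width : float
        Histogram bin width, nm (default 0.02 — below the smallest
        window spacing used in practice).
    cv_range : (float, float)
        Histogram range, nm.
    temperature : float
        Analysis temperature, K (default 310).
    """

    def __init__(self, windows, bin_width: float = 0.02,
                 cv_range: tuple[float, float] = (-2.4, 2.4),
                 temperature: float = DEFAULT_TEMPERATURE):
        self.windows = list(windows)
        if not self.windows:
            raise ValidationError("need at least one umbrella window")
        self.bin_width = float(bin_width)
        self.cv_range = (float(cv_range[0]), float(cv_range[1]))
        self.temperature = float(temperature)
        self.kT = kt(self.temperature)
        self.histograms = build_histograms(self.windows, self.bin_width,
                                           self.cv_range)

    def fit(self, tol: float = 1e-6, max_iter: int = 100_000,
            damping: float = 0.0) -> FreeEnergyProfile:
        return wham_solve(self.histograms, self.windows, kT=self.kT,
                          tol=tol, max_iter=max_iter, damping=damping)


# ---------------------------------------------------------------------------
# measurements on profiles
# ---------------------------------------------------------------------------

def barrier_height(profile: FreeEnergyProfile,
                   bulk_region: tuple[float, float]) -> float:
    """Barrier = max F between the bulk regions minus the bulk mean.

    ``bulk_region = (lo, hi)`` selects lo <= |s| <= hi on both sides of
    the membrane as the flat reference; the maximum is scanned over the
    interior |s| < lo.
    """
    lo, hi = bulk_region
    if not 0 <= lo < hi:
        raise ParameterError("bulk region must satisfy 0 <= lo < hi")
    s, F = profile.cv_grid, profile.F
    bulk_pos = (s >= lo) & (s <= hi)
    bulk_neg = (s <= -lo) & (s >= -hi)
    interior = np.abs(s) < lo
    if not (np.any(bulk_pos) and np.any(bulk_neg)):
        raise DomainError("profile does not cover both bulk regions")
    if not np.any(interior):
        raise DomainError("profile has no bins between the bulk regions")
    bulk_mean = float(np.mean(F[bulk_pos | bulk_neg]))
    return float(np.max(F[interior]) - bulk_mean)


def asymmetry_error(profile: FreeEnergyProfile,
                    bulk_region: tuple[float, float] | None = None) -> float:
    """Half the maximum mirror asymmetry |F(s) - F(-s)| / 2.

    Both branches are first anchored to equal means over the bulk
    region (default: the outermost 15% of the symmetric coverage);
    F(-s) is linearly interpolated onto the mirrored grid points.  For a
    physically symmetric system any asymmetry is statistical error, so
    this is the profile's internal error estimate.
    """
    s, F = profile.cv_grid, profile.F
    s_cov = min(-s.min(), s.max())
    if s_cov <= 0:
        raise DomainError(
            "profile does not cover an interval symmetric about s = 0")
    if bulk_region is None:
        bulk_region = (0.85 * s_cov, s_cov)
    lo, hi = bulk_region
    s_pos = s[(s >= 0) & (s <= s_cov)]
    if len(s_pos) == 0:
        raise DomainError("no grid points in the symmetric coverage")
    Fp = np.interp(s_pos, s, F)
    Fm = np.interp(-s_pos, s, F)
    bulk = (s_pos >= lo) & (s_pos <= hi)
    if not np.any(bulk):
        raise DomainError("no grid points in the bulk anchoring region")
    Fp = Fp - np.mean(Fp[bulk])
    Fm = Fm - np.mean(Fm[bulk])
    return float(np.max(np.abs(Fp - Fm)) / 2.0)


def block_bootstrap_error(windows, n_blocks: int = 50, n_boot: int = 20,
                          bin_width: float = 0.02,
                          cv_range: tuple[float, float] = (-2.4, 2.4),
                          temperature: float = DEFAULT_TEMPERATURE,
                          seed: int = 0, tol: float = 1e-6,
                          max_iter: int = 100_000):
    """Statistical alternative to the asymmetry error.

    Each window's (time-ordered) samples are cut into ``n_blocks``
    contiguous blocks; bootstrap replicates resample blocks with
    replacement, and WHAM is re-solved per replicate.  Returns
    ``(cv_grid, F_std)`` — the per-bin standard deviation over
    replicates on the grid common to all of them.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            blocks = np.array_split(w.samples, min(n_blocks, w.n))
            pick = rng.integers(0, len(blocks), size=len(blocks))
            resampled.append(UmbrellaWindow(
                np.concatenate([blocks[b] for b in pick]),
                center=w.center, k=w.k, name=w.name))
        profiles.append(WHAM(resampled, bin_width=bin_width,
                             cv_range=cv_range,
                             temperature=temperature).fit(
                                 tol=tol, max_iter=max_iter))
    grids = [p.cv_grid for p in profiles]
    lo = max(g.min() for g in grids)
    hi = min(g.max() for g in grids)
    base = grids[0][(grids[0] >= lo) & (grids[0] <= hi)]
    stack = np.stack([np.interp(base, p.cv_grid, p.F) for p in profiles])
    return base, stack.std(axis=0)
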