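# Methods

`scramblekit` analyzes lipid scrambling in membrane-protein MD data: it
counts flip-flop events from unbiased trajectories, reconstructs the
flip-flop free-energy profile from umbrella-sampling windows, and
produces the supporting geometric analyses (leaflet assignment,
collective-variable evaluation, 3D densities, RMSD).  This note records
the models, conventions and numerical choices, and what the synthetic
validation does and does not demonstrate.

Units throughout: nm, ps, kJ/mol, K.  The membrane normal is z.
kB = 0.008314462618 kJ/mol/K; the default analysis temperature is
310 K (kT = 2.5775 kJ/mol).

## Leaflet assignment and scrambling statistics

A lipid belongs to the upper leaflet at an analyzed snapshot iff the z
coordinate of its phosphate reference bead exceeds the membrane center.
The global center is the mean phosphate z after the bilayer is made
contiguous across the periodic z boundary (each phosphate is shifted by
box-z multiples to lie within half a box height of the running median of
those already placed — a split bilayer would otherwise corrupt the
mean).  Exact ties inherit the lipid's previous label, or "upper" at the
first snapshot; an optional hysteresis half-width around the center
(default 0) is available for robustness studies but is not part of the
default definition, which is the bare sign rule.

A lipid is *scrambled* at time t when its leaflet differs from its
leaflet at the first analyzed snapshot; an *event* is a label change
between consecutive analyzed snapshots, so a lipid that crosses and
returns contributes two events and no final scrambled count.  Snapshots
are analyzed on a fixed stride (default 10 ns); excursions shorter than
the stride are invisible by construction, and no sub-stride
interpolation is attempted.  The scrambled-count series is summarised
with a trailing running average (default window 200 ns, i.e. 20 samples
at the default stride; early samples average what is available) and a
rate in events per microsecond, reported jointly and per direction.
Both the instantaneous scrambled count and the cumulative count of
distinct scrambled lipids are emitted, since either can be the quantity
of interest; the instantaneous count is the default.

## The flip-flop collective variable

The reaction coordinate is the oriented z distance between a tracked
lipid's phosphate and the *local* membrane center of mass: the uniform
mean z of all lipid particles (headgroups and tails, the tracked lipid
excluded) whose minimum-image xy distance to the phosphate is at most
the cylinder radius — 2.0 nm for protein-free membranes, 3.0 nm when a
protein is present, matching the larger perturbed footprint.  Design
choices, where the convention is genuinely open:

* hard radial cutoff with uniform weighting (a cosine-taper switching
  option of configurable width exists for sensitivity checks; pull-code
  "cylinder" geometries in MD engines use a smooth radial weight whose
  exact form is implementation-specific);
* the tracked lipid is excluded from its own reference so it cannot
  bias the center it is measured against;
* all lipid beads contribute, not phosphates only, making the center a
  membrane-core property rather than a surface property.

An empty cylinder is an explicit error; callers may widen the radius.
Bias potentials: the harmonic umbrella restraint U = k/2 (s − c)^2 and
the flat-bottom xy restraint (zero inside the reference distance,
harmonic beyond; defaults 2.5 nm and 500 kJ/mol/nm^2) that keeps the
tracked lipid near the scrambling pathway.  A 3D particle-to-selection
distance is provided as a utility coordinate for steering-style setups.

## WHAM

Windows are two-column (time, CV) series; loading discards an
equilibration prefix (default 10 ns).  Histograms are uniform
(default bin width 0.02 nm over [−2.4, 2.4] — comfortably below the
smallest window spacing of 0.03 nm used in practice), half-open with the
final bin closed, and a sample outside the range is an error, never a
silent drop.

The solver iterates the standard self-consistent equations

    p_j = (sum_i N_ij) / (sum_i n_i exp[(f_i − c_ij)/kT])
    f_i = −kT ln sum_j p_j exp(−c_ij/kT)

to a tolerance of max_i |Δf_i| < 1e−6 kJ/mol (far below the 1 kJ/mol
reporting precision), with optional damping (default none).  The
profile F_j = −kT ln p_j is anchored to min F = 0 for plotting; barrier
and error measurements re-anchor to a bulk mean internally.  Numerical
notes:

* the iteration runs in linear space with per-window Boltzmann factors
  precomputed; factors for distant window/bin pairs underflow to exactly
  zero, which is the correct negligible weight.  Double precision covers
  barriers up to roughly 1500 kJ/mol at physiological kT — far beyond
  the tens of kJ/mol relevant here — and is ~30x faster than a log-space
  formulation, which matters for bootstrap and calibration loops;
* windows sharing (center, k) are merged (integer count sums) and
  sorted before solving, making the result exactly invariant — bit
  for bit — under window reordering and under splitting one window's
  samples across several files;
* the self-consistency residual decreases strictly once past a short
  cold-start transient (~20 iterations from f = 0 on steep barriers;
  no transient at all on mild fixtures);
* bins with zero total counts are excluded; a zero-count gap is an
  error only if no single window sampled on both sides of it;
* the CV is non-periodic: no histogram wraparound.

Barrier height is max F over the interior minus the mean F over the
bulk reference region, taken on both sides (|s| within the given bulk
interval; [2.0, 2.3] nm in the validation, outside the wells at
±1.9 nm).

## Error estimates

For a physically symmetric system any mirror asymmetry of the profile
is statistical error, so the default error estimate is
max_s |F(s) − F(−s)| / 2 after anchoring both branches to equal means
over a bulk region (default: the outermost 15% of the symmetric
coverage), with F(−s) linearly interpolated onto mirrored grid points.
Calibration against synthetic ground truth (50 independent noisy
recoveries of a symmetric 62 kJ/mol double well) shows this estimate
has the right order of magnitude but covers the true half-maximum
deviation from the analytic profile in only ~75% of replicates: WHAM's
error field accumulates like a random walk anchored in the bulk, so the
true deviation tends to peak near s = 0, exactly where the mirror
difference vanishes by continuity.  Treat it as a scale indicator, not
a confidence bound.  A block-bootstrap alternative (contiguous sample
blocks per window, default 50 blocks, seeded, WHAM re-solved per
replicate) provides per-bin standard deviations when a statistically
grounded error is needed.

## Density maps and alignment

Replicas are concatenated and every frame is rigid-body aligned
(Kabsch on a reference selection, typically the protein; the transform
is applied to the whole frame).  The reference is the first frame of
the first replica — deterministic and simple.  Densities are per-frame
voxel occupancy counts of a selection averaged over frames on an
isotropic grid (default 0.1 nm), with point (containing-voxel)
assignment so that conservation is exact: sum(values) x n_frames equals
the number of in-grid observations.  An optional Gaussian smear
(configurable sigma) exists for visual parity with viewer-style density
tools; it trades exact conservation near the grid edge for smoothness.
Auto-sized grids (0.5 nm margin) never raise; explicit bounds treat an
outside particle as an error.  Grids are exported as OpenDX scalar
fields in nm units, z-fastest, and round-trip through the package's own
reader at 6 significant digits.

## RMSD

Kabsch superposition via SVD with the determinant correction (proper
rotations only, never a reflection).  Degenerate inputs — fewer than
three points, or (near-)collinear sets where the optimal rotation is
not unique — are errors.  Pairing within a selection is positional: the
same topology is assumed across frames, and no sequence alignment is
attempted.  RMSD series are reported in nm against a reference frame
(first frame by default).

## Synthetic ground truth: what it shows and what it does not

The generators make every stage testable without MD:

* **Quartic double-well PMF** F(s) = B (1 − (s/z0)^2)^2 for |s| ≤ z0,
  flat beyond, with wells at ±z0 = 1.9 nm (approximately the phosphate
  levels of a POPC bilayer; the true well positions are not a published
  number) and barrier presets spanning the membrane-only (62, 83,
  92 kJ/mol) and protein-assisted (7, 15, 16 kJ/mol) regimes.
* **Overdamped Langevin dynamics** s(t+dt) = s − (D/kT) F′(s) dt +
  sqrt(2 D dt) ξ, with D = 0.01 nm^2/ps and dt = 5 ps by default.
  Construction enforces the drift-stability bound
  (D/kT) max|F′| dt ≤ 0.1 z0.  Diagnostic choices used in validation:
  the free-diffusion MSD slope is estimated from time- and
  ensemble-averaged MSD over lags 1–100 (10^4 steps x 100 lipids gives
  a standard error well under the 5% check); the harmonic-well variance
  uses dt = 0.5 ps and a 50 ps recording stride (~2 relaxation times at
  kappa = 10 kJ/mol/nm^2), since the Euler–Maruyama stationary variance
  is inflated by a factor 1/(1 − theta dt/2), theta = D kappa / kT —
  about 1% at these settings, inside the 2% check by design.
* **Umbrella ensembles** are i.i.d. draws from the exact biased
  stationary density via inverse-transform sampling on a 4801-point
  grid — no dynamics, no autocorrelation, no equilibration artifacts —
  so a recovery failure indicts the WHAM solver, not the data.  Window
  layouts: 67 uniform windows over [−2.3, 2.3] nm at k = 1000
  (membrane-only style), and a 59-window tapered layout (spacing 0.1 nm
  at the surface to 0.03 nm at the center, 16 windows at 0.03 nm
  spacing spanning [−0.25, 0.20], k = 2000 for |c| ≤ 0.5 else 1000,
  atomistic style).
* **Membrane fixtures** are lattice bead bilayers with optional tails,
  protein blob, water, jitter, and scripted flip-flop events whose
  ledger is the exact expected analyzer output.

All generators are bit-reproducible given (parameters, seed).

What passing these tests shows: the estimators are correct on data that
exactly satisfy their assumptions (Boltzmann-distributed windows,
discrete-snapshot leaflet logic, rigid-body motion).  What they do not
show: robustness to autocorrelated window samples (an optional
Langevin-sampled window mode exists for such studies), hysteresis
between pulling directions, force-field realism, or the behavior of the
local-center CV in a strongly deformed membrane — those are properties
of real trajectories, not of the estimators.

## Validation problem sizes

The standard validation run uses 67 (or 59) windows x 5x10^4 samples
for barrier recovery (recovered within 1 kJ/mol of truth uniformly;
2 kJ/mol for the tapered layout), 10^5 samples for the closed-form and
equipartition checks, 10^4 x 100 Langevin steps for the MSD check, 40–50
random fixtures for the geometric oracles, and 50 replicates x 1000
samples/window for the error calibration.  These sizes were chosen so
statistical error sits several times below each check's tolerance.

## Known limitations

* Orthorhombic boxes only; triclinic input is an explicit error.
* 1D WHAM only; no MBAR, no 2D coordinates, no replica-exchange
  demultiplexing (engine-side demuxed series are consumed as ordinary
  windows).
* The asymmetry error is a scale indicator (see above).
* Leaflet logic assumes a bilayer whose normal stays along z.
* No binary trajectory formats in the core contract; text GRO/TSV are
  the interchange dialects (an external converter can wrap them).
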