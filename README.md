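# scramblekit

Analysis toolkit for lipid scrambling in membrane-protein molecular
dynamics: scrambled-lipid detection and flip-flop rates from unbiased
trajectories, umbrella-sampling free-energy profiles of lipid flip-flop
(WHAM), 3D occupancy densities, and RMSD stability analysis — with
synthetic ground-truth generators that validate every stage.

## The problem

Scramblases let phospholipids cross a membrane bilayer passively, in
both directions, typically by offering a hydrophilic groove along which
the lipid headgroup slides while its tails stay in the hydrophobic core
(the "credit-card" mechanism).  Establishing scramblase activity from
MD simulation needs two complementary measurements:

1. **Kinetics** — count flip-flop events in unbiased trajectories: a
   lipid is *scrambled* when its phosphate sits in the leaflet opposite
   its starting one, judged against the membrane center; events per
   microsecond give the scrambling rate.
2. **Energetics** — reconstruct the free-energy profile F(s) of
   flip-flop along a collective variable s, the oriented z-distance
   between the tracked lipid's phosphate and the local membrane center
   of mass inside a cylinder (radius 2–3 nm).  Umbrella sampling
   restrains s window by window with harmonic biases k/2 (s − c_i)^2,
   and the weighted histogram analysis method (WHAM) solves

       p_j = (Σ_i N_ij) / (Σ_i n_i e^{(f_i − c_ij)/kT}),
       f_i = −kT ln Σ_j p_j e^{−c_ij/kT}

   self-consistently for the unbiased distribution, giving
   F_j = −kT ln p_j and the barrier ΔF‡ between leaflets.  A protein
   that lowers ΔF‡ from tens of kJ/mol (bare bilayer) to a few kJ/mol
   is an active scramblase.

`scramblekit` implements both measurements plus the supporting
geometry: leaflet assignment with periodic-boundary-safe membrane
centering, the cylinder CV and its bias potentials, Kabsch
superposition RMSD, replica alignment, and OpenDX density export.
Because the estimators must be trusted before they are pointed at real
trajectories, the package ships generators with exactly known ground
truth: overdamped Langevin flip-flop dynamics over analytic bilayer
PMFs, Boltzmann-exact umbrella ensembles, and scripted membrane
fixtures.  See `docs/methods.md` for conventions and numerics.

## Worked example

Recover a known 62 kJ/mol flip-flop barrier from a synthetic umbrella
set shaped like a typical membrane-only calculation (67 windows over
[−2.3, 2.3] nm, k = 1000 kJ/mol/nm², T = 310 K):

```python
import scramblekit as sk

pmf = sk.PMFSpec(barrier=62.0)                    # ground truth, kJ/mol
windows = sk.simulate_umbrella_set(
    pmf, sk.uniform_window_layout(), k=1000.0, n_samples=50_000, seed=1)
profile = sk.WHAM(windows, bin_width=0.02, cv_range=(-2.4, 2.4)).fit()
print(profile.summary())
print(f"barrier vs bulk (|s| in [2.0, 2.3] nm): "
      f"{profile.barrier((2.0, 2.3)):.2f} kJ/mol")
```

prints

```
Free-energy profile (WHAM)
============================================
kT (kJ/mol)                    2.577483
windows                              67
bins with samples                   240
CV coverage (nm)           [-2.390, 2.390]
iterations                         3450
final residual (kJ/mol)       9.994e-07
max F (kJ/mol)                   62.155
asymmetry error (kJ/mol)          0.052

barrier vs bulk (|s| in [2.0, 2.3] nm): 62.05 kJ/mol
```

The recovered barrier (62.05 kJ/mol) is within 0.1 kJ/mol of the
generating truth; the asymmetry-based error estimate (half the maximum
mirror asymmetry of the profile) correctly reports the statistical
noise scale of a well-sampled calculation.  `profile.plot()` draws the
profile with its error band; `profile.to_tsv(...)` writes it.

For kinetics, `ScramblingAnalysis(frames, structure).fit()` returns the
scrambled-lipid series with its event ledger, running average and rate —
or from the shell:

```sh
scramblekit simulate flipflop --barrier 10 --seed 1 --out run/
scramblekit scramble --structure mem.gro --traj traj.tsv --out series.tsv
scramblekit wham --meta meta.txt --temp 310 --bin 0.02 --out pmf.tsv
scramblekit density --structure mem.gro --traj t1.tsv --select "name PO4" --out phos.dx
```

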