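# hostguest

Analysis toolkit for host–guest complexation in truncated-cone macrocyclic
hosts (cyclodextrins and their methylated derivatives) and for the question
such systems raise: when a host accelerates a bimolecular reaction between
two bound guests, is the catalysis driven by specific hydrogen bonding or by
entropy-reducing pre-organization of the reactants?

The package is aimed at molecular-modelling practitioners who already have
trajectories and optimized stationary points in hand and need the analysis
layer: it does not run molecular dynamics or electronic-structure
calculations.

It provides three independent, composable stages:

1. **Trajectory statistics** (`hostguest.geometry`) — hydrogen-bond
   detection under the geometric criterion *d*(H···Y) < 2.2 Å and
   180° − ∠(X–H···Y) < 90°, with the occurrence percentage defined as
   frames-containing-the-bond / total frames; signed binding-depth metrics
   d1/d2/d3 (projections of guest/moiety centroids onto the cavity axis,
   positive toward the wide rim); guest RMSD after Kabsch superposition of
   the host; bound-state classification (RMSD < 5 Å) and residence
   statistics (occupancy percentage, dwell times).
2. **MM-PB/SA interaction enthalpy** (`hostguest.energy`, `hostguest.pb`,
   `hostguest.sasa`) —
   ΔH = ΔE<sub>Coulomb</sub> + ΔE<sub>PB</sub> + ΔE<sub>NP</sub> + ΔE<sub>VDW</sub>,
   with exact pairwise Coulomb (k<sub>e</sub> = 332.0637 kcal·Å/(mol·e²))
   and 12-6 Lennard-Jones sums, a finite-difference linearized
   Poisson–Boltzmann solver for the polar solvation term, and Shrake–Rupley
   SASA with ΔE<sub>NP</sub> = γ·ΔSASA (γ = 0.0072 kcal/(mol·Å²)), under the
   single-trajectory approximation.
3. **RRHO activation thermochemistry** (`hostguest.thermo`) — partition
   functions q<sub>trans</sub>·q<sub>rot</sub>·q<sub>vib</sub>·q<sub>elec</sub>
   from frequency datasets (S = Nk<sub>B</sub> + Nk<sub>B</sub> ln(q/N) +
   Nk<sub>B</sub>T(∂ln q/∂T)<sub>V</sub> per component), and activation
   decompositions ΔG‡ = ΔH‡ + (−TΔS‡) against a supermolecule or
   separated-species reactant reference.

Because raw MD/QM ensembles are too heavy to ship, `hostguest.synth`
generates synthetic inputs with known ground truth: a toy truncated-cone
host, guests with configurable H-bond probability, binding depth and
two-state residence kinetics, plus thermochemistry and Born-ion fixtures
with closed-form answers. These fixtures are first-class, tested code — the
statistical recovery of their imposed ground truth is what validates the
analysis stages.

## Worked example

```python
from hostguest.synth import SyntheticTrajectoryParams, simulate_binding_trajectory
from hostguest.geometry import (hbond_occupancy, guest_rmsd, classify_bound,
                                residence_summary, depth_metrics_trajectory)

bundle = simulate_binding_trajectory(params=SyntheticTrajectoryParams(seed=0))
traj, sel = bundle.trajectory, bundle.selections

occ = hbond_occupancy(traj, sel["donors"], sel["acceptors"])
print(f"H-bond occurrence: {occ.percent:.2f}% of {occ.n_frames} frames")

rmsd = guest_rmsd(traj, bundle.reference, sel["host"], sel["guest_b"])
summary = residence_summary(classify_bound(rmsd, threshold=5.0,
                                           frame_interval=traj.frame_interval))
print(f"ternary-complex occupancy: {summary.occupancy_percent:.1f}%")
print(f"longest dwell: {summary.max_dwell:.1f} ns")

depths = depth_metrics_trajectory(traj, sel["host"], sel["narrow_rim"],
                                  sel["wide_rim"],
                                  [sel["guest_a"], sel["guest_a_cyclohexyl"],
                                   sel["guest_a_imide"]])
print("d1 = {:.2f} +/- {:.2f} A".format(depths.d1.mean(), depths.d1.std(ddof=0)))
```

prints

```
H-bond occurrence: 0.80% of 3000 frames
ternary-complex occupancy: 31.9%
longest dwell: 20.9 ns
d1 = 2.07 +/- 0.73 A
```

One 300-ns synthetic run of the methylated-host system: the guest–host
hydrogen bond is present in under 1% of frames (so it cannot carry the
catalysis), the ternary complex is populated roughly a third of the time
with dwells of tens of nanoseconds (pre-organization is real and
persistent), and the maleimide-like guest sits 2.07 ± 0.73 Å above the
cavity center toward the wide rim. Single-seed kinetic quantities
fluctuate between seeds; the acceptance script below averages 20 runs.

## Command line

```sh
hostguest synth --outdir demo --seed 1          # write a synthetic bundle
hostguest full --config demo/config.yaml        # all three report stages
hostguest traj-report --config demo/config.yaml # one stage at a time
hostguest selfcheck                             # bundled-table identities
```

Reports are CSV (occupancy table, depth mean ± sd, residence summary,
MM-PB/SA decomposition, ΔG‡/ΔH‡/−TΔS‡ per reaction) plus a JSON run log.

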