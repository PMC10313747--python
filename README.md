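# siefel

Trajectory analysis for protein–ligand molecular-dynamics studies:
solvated interaction energy (SIE) binding free energies, per-residue
energy decomposition, geometric hydrogen-bond and contact criteria,
Shrake–Rupley solvent-accessible surface area, RMSD/RMSF stability
metrics, and two-dimensional free-energy landscapes with open/close
gate classification.

## The scientific problem

Wasp-venom phospholipase A₁ (Ves a 1, from *Vespa affinis*) carries a
catalytic pocket guarded by two mobile loops (T83–E93 and G251–C261) that
swing between a closed gate (loop centroid separation ≈ 19 Å) and an open
gate (≈ 22 Å). Ranking candidate inhibitors against such a target from MD
trajectories requires a reproducible chain of post-processing steps:
structural stability (RMSD, per-residue RMSF), pocket solvent exposure
(SASA of residues within 5 Å of the ligand), interaction persistence
(atom contacts within 3.5 Å; hydrogen bonds with donor–acceptor distance
≤ 3.5 Å and D–H···A angle ≥ 150°, reported as per-frame counts and
percent occupancy), an end-point binding free energy, and a free-energy
landscape over the gate coordinates. `siefel` implements that chain as a
tested, engine-agnostic library plus CLI; it consumes plain-text
structures (PDB), trajectories (multi-model PDB or XYZ) and a per-atom
parameter table (TSV), and emits CSV.

## Core quantities

**SIE binding free energy.** For a complex snapshot,

```
ΔG_bind = α·(ΔE_vdW + γΔSA + ΔE_Ele + ΔG_RF) + C
```

with calibrated coefficients α = 0.105, γ = 0.013 kcal·mol⁻¹·Å⁻² and
C = −2.89 kcal/mol. ΔE_vdW and ΔE_Ele are the intermolecular
Lennard-Jones and Coulomb energies of the bound state (no cutoff,
vacuum dielectric), γΔSA is the cavity term over the surface area buried
on binding, and ΔG_RF is the reaction-field (electrostatic solvation)
change, computed here with a Still-type generalized-Born surrogate
(ε_in = 2.25, ε_out = 78.5). Trajectory estimates average 100 evenly
spaced snapshots from the equilibrium window (by convention the last 10%
of the run). The combiner also accepts externally computed components,
so published component tables can be rescored directly.

**Per-residue decomposition.** The receptor–ligand interaction is split
residue-wise into van der Waals + nonpolar-solvation and Coulomb +
polar-solvation terms; residues with a total below −1.00 kcal/mol are
flagged as key binding residues.

**Free-energy landscape.** Over the gate reaction coordinates
(loop centroid distance, loop RMSD), the landscape is the
Boltzmann-inverted 2D histogram `ΔG(x,y) = −k_B·T·ln(g(x,y)/g_max)` at
310 K on a 0.10 Å grid, zeroed at the most populated bin; basins are
merged local minima, and frames are labelled open/close at the 20.5 Å
midpoint between the two basin positions.

A deterministic synthetic-data module generates parameterised toy
complexes and two-state gate trajectories (Markov switching between the
19/22 Å basins, Gaussian within-basin noise, scripted hydrogen-bond
occupancies), so every stage is testable without external data.

## Worked example

```python
from siefel import (SIEComponents, sie_combine, make_toy_complex,
                    simulate_gate_trajectory, GateModelParams,
                    SelectionSpec, fel_pipeline)
import numpy as np

# rescore a published set of SIE component means (kcal/mol)
dg = sie_combine(SIEComponents(e_vdw=-56.20, e_ele=-14.40,
                               g_rf=19.37, cavity=-11.77))
print(f"dG_bind(SIE) = {dg:.3f} kcal/mol")

# landscape of a synthetic two-state gate trajectory
toy = make_toy_complex(n_residues=60, seed=1)
traj = simulate_gate_trajectory(toy, GateModelParams(n_frames=30_000, seed=2))
res = fel_pipeline(traj, SelectionSpec("16-26"), SelectionSpec("41-51"))
print(res.basins.round(3))
print("open fraction:", round(float(np.mean(res.labels == "open")), 3))
```

prints

```
dG_bind(SIE) = -9.505 kcal/mol
   x_center  y_center  depth_kcal_mol
0     19.05      1.25           0.000
1     22.05      0.45           0.055
open fraction: 0.488
```

The rescored components reproduce the reported −9.49 kcal/mol for that
complex to within component rounding; the landscape recovers exactly two
basins at the closed (≈19 Å) and open (≈22 Å) gate separations, nearly
equally deep because the trajectory was generated at 50/50 occupancy.

## Command line

Every stage is a subcommand over a YAML run configuration:

```sh
siefel simulate --config run.yaml          # write a synthetic fixture
siefel all      --config run.yaml          # rmsd, rmsf, sasa, contacts,
                                           # hbonds, map, sie, decompose, fel
siefel fel      --config run.yaml --out-dir out
```

Outputs are stage-named CSV files plus a `manifest.json` recording the
configuration, package version and seed. Exit code 2 flags configuration
errors (the message names the offending key), 1 flags data errors.

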