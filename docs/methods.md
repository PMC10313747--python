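# Methods

This note records the models, numerical choices and limitations behind
`siefel`, in the order the pipeline runs.

## Data model and I/O

Structures and trajectories are plain text: PDB (ATOM/HETATM, with
MODEL/ENDMDL blocks for multi-frame files) and multi-frame XYZ. Atom
parameters — partial charge (e), Lennard-Jones r_min/2 (Å) and ε
(kcal/mol), a van der Waals radius for surface area and a Born radius for
the solvation surrogate — live in a sidecar TSV keyed by atom serial, one
row per atom, validated strictly (a missing or surplus row is an error).
Keeping parameters out of force-field files makes the pipeline
engine-agnostic: any MD package's topology can be exported to this table.
Residue numbering is taken verbatim from the input and never renumbered;
selections are comma-separated residue ranges with optional chain and
atom-name filters, and ranges spanning gaps in the numbering simply match
fewer residues. When a trajectory carries no times, frames are assumed
10 ps apart (a 300 ns run sampled as 30,000 frames). Binary formats
(DCD/NetCDF) are an explicit non-goal; converting to multi-model PDB or
XYZ is the supported path.

## Superposition and fluctuation metrics

Rigid-body fits use the Kabsch SVD algorithm with the determinant
correction, so reflections are never returned; inputs with fewer than
three points, or collinear points (second singular value ≤ 1e−8 of the
first), raise an error rather than returning an arbitrary rotation.
RMSD series fit each frame on a configurable selection (receptor CA by
default) before measuring on a possibly different selection. RMSF is
computed about the time-averaged structure after fitting — not about the
first frame — which is the standard convention and makes the statistic
invariant to global rigid motion; per-residue values are the root of the
residue-mean squared per-atom fluctuation. For isotropic per-coordinate
noise of width σ the expected RMSF is √3·σ, which the tests use as a
closed-form anchor.

The gate coordinate is the CA-centroid separation of the two loop
selections. Frames at or beyond 20.5 Å are labelled open, below it
closed; 20.5 Å is the midpoint of the two basin positions (19 and 22 Å)
and ties deliberately go to open, since the open state is the
reference conformation for docking.

## Solvent-accessible surface area

SASA uses the Shrake–Rupley construction: each atom is inflated by the
probe radius (1.4 Å) and covered with a deterministic golden-section
spiral of quadrature points (960 by default, minimum 92); a point is
accessible if it lies outside every neighbouring inflated sphere. The
spiral is fixed in the laboratory frame, so SASA is invariant under
rigid motion only to within quadrature error (≲0.5% at 960 points).
The binding-site series recomputes shell membership every frame at
whole-residue granularity — a residue is in the shell if any of its
atoms is within 5.0 Å of any ligand atom — and sums those residues'
per-atom SASA evaluated in the full complex, so ligand burial lowers
the reported exposure. LCPO and analytic (power-diagram) SASA are
non-goals; the Shrake–Rupley choice is validated against the
isolated-sphere closed form, a dense random-point oracle, and an
independent established implementation.

## Contacts and hydrogen bonds

A contact is a receptor atom whose minimum distance to any ligand atom
is ≤ 3.5 Å; hydrogens are excluded by default (reported contact counts
in the benchmark study, ~17–19, are consistent with heavy-atom
counting — this is an assumption, switchable via
`ContactCriteria(heavy_atoms_only=False)`). A hydrogen bond requires a
donor–acceptor distance ≤ 3.5 Å and a D–H···A angle, measured at the
hydrogen, ≥ 150°; both bounds are inclusive. Donors and acceptors are
restricted to N and O (sulfur excluded); donor hydrogens are identified
from the covalent bond list, so bond information is mandatory for
hydrogen-bond analyses. Occupancy is the percentage of window frames in
which a specific donor/acceptor pair satisfies both criteria with any of
the donor's hydrogens. The interaction map reports, per receptor residue
ever within contact range during the window, the hydrogen-bond
occurrence (either donor direction) and the occurrence of carbon–carbon
contacts as a hydrophobic proxy; pharmacophore feature typing is a
non-goal. The analysis window defaults to the final 10% of the
trajectory, the equilibrium-phase convention for these systems
(the last 10 ns of a 100 ns segment).

## Energetics

Pair energies use the 12-6 Lennard-Jones form with Lorentz–Berthelot
combination (r_min additive in the half-parameters, ε geometric) and
Coulomb's law with constant 332.0636 kcal·Å·mol⁻¹·e⁻². Intermolecular
terms sum over all receptor–ligand pairs with no cutoff and vacuum
dielectric — distance cutoffs belong to the MD engine, not to end-point
rescoring.

The reaction-field term is a Still-type pairwise generalized-Born model
over fixed per-atom Born radii, with ε_in = 2.25 and ε_out = 78.5 (the
interior dielectric conventionally paired with the SIE coefficient set).
Because the radii are fixed, the binding value ΔG_RF = GB(complex) −
GB(receptor) − GB(ligand) reduces to the cross receptor–ligand screening
term, which is what is evaluated; the full-sum route is kept as an
independent cross-check in the tests. The single-charge limit reproduces
the Born ion formula exactly. Self-consistent (Poisson–Boltzmann) and
effective-radius GB solvers are non-goals; the combiner therefore accepts
externally computed components so that published component tables can be
rescored independently of this surrogate.

The cavity term is γ·ΔSASA with ΔSASA = SASA(complex) − SASA(receptor) −
SASA(ligand), negative on burial. The SIE combination
ΔG = α(ΔE_vdW + γΔSA + ΔE_Ele + ΔG_RF) + C uses α = 0.105,
γ = 0.013 kcal·mol⁻¹·Å⁻², C = −2.89 kcal/mol. Trajectory estimates take
`n_snapshots` (default 100) evenly spaced frames from the window, first
and last included — the plainest reading of "snapshots extracted from
the window" absent a stated spacing rule — and report mean ± sample SD.

Per-residue decomposition attributes to each receptor residue its
pairwise Lennard-Jones and Coulomb sums with the ligand (these conserve:
summed over residues they equal the intermolecular totals to 1e−6), its
share of the GB cross term, and a nonpolar share proportional to the
residue's buried SASA using the same γ as the cavity term (one
coefficient keeps the model self-consistent; a PB-grid decomposition is
out of scope). Residues with a total strictly below −1.00 kcal/mol are
key residues — the boundary value itself is excluded ("lower than" is
strict).

## Free-energy landscape

The landscape is ΔG(x, y) = −k_B·T·ln(g(x, y)/g_max) over the joint
histogram of gate distance and loop RMSD, with k_B = 0.0019872041
kcal·mol⁻¹·K⁻¹, T = 310 K and 0.10 Å bins on both axes. Normalising by
g_max zeroes the most-populated bin and makes every occupied bin
non-negative — the only reading of a Boltzmann-inverted landscape
"with the minimum set to zero" that is self-consistent (a bare
+k_B·T·ln g would be negative everywhere and minimised at the *most*
probable bin). Bin edges are anchored at 0.0 Å rather than at the data
minimum so grids from different runs align bin-for-bin. Empty bins are
masked, not infinite, so CSV export stays finite. The RMSD coordinate is
measured over both loops' CA atoms jointly against the first frame after
superposition on the receptor CA set (no reference structure being
canonical, the initial frame is used).

Basins are local minima over the 8-neighbourhood; equal-valued plateaus
collapse to their lowest-index cell; minima within `min_separation_bins`
(Chebyshev) of a deeper basin merge into it; and minima more than
`max_depth` (default 2.0 kcal/mol) above the global minimum are
discarded. The depth cutoff exists because a sampled histogram's sparse
tails always contain count-level local minima that are sampling noise,
not metastable states; 2.0 kcal/mol ≈ 3 k_BT at 310 K separates them
cleanly from basins with meaningful occupancy. The pipeline default
merge radius is 10 bins (1.0 Å, about 2.5× the within-basin width of the
gate coordinate); `find_basins` itself defaults to 3 bins for generic
grids.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not physical dynamics. The toy receptor is a CA/CB/OG/HG trace: two
11-residue gate loops face each other at a 19 Å CA-centroid separation;
18 pocket residues point their CB atoms at distinct ligand atoms 3.2 Å
away, pinning the heavy-atom contact count at the build target
(echoing the ~17–19 contacts typical of a well-seated ligand); the rest
form a distant ring. Gate dynamics are a two-state Markov chain between
basins at 19.0 and 22.0 Å with Gaussian within-basin noise (σ = 0.4 Å)
and stationary open-state occupancy set directly by a parameter —
a Markov chain rather than Langevin dynamics because the analyses only
consume the stationary distribution and switching structure, not
kinetics. Per-atom positional jitter is Gaussian (0.15 Å per coordinate
for the core; loop jitter of 0.52 Å reproduces the ~0.9 Å loop RMSF
scale typical of flexible gate loops). Hydrogen bonds are scripted
geometrically: a per-frame Bernoulli draw places the ligand acceptor on
the donor's O–H axis at 2.75 Å (compliant, exactly linear) or 4.30 Å
(violating the distance criterion), making truth occupancies exact by
construction. The default trajectory length is 30,000 frames at 10 ps
spacing, matching the 300 ns analysis convention.

What the generator does **not** emulate: realistic force-field energy
surfaces (jittered hard contacts produce occasional steep Lennard-Jones
values, so absolute toy SIE numbers are not meaningful — only their
internal consistency is tested), solvent degrees of freedom, correlated
loop motions beyond the single gate mode, and rotameric sidechain
states. Passing tests therefore demonstrate that the analysis operators
recover known generating parameters (basin positions and occupancies,
H-bond occupancies, contact counts, RMSF amplitudes) and match closed
forms and exhaustive oracles — not that any particular real complex
would reproduce published trajectory averages, which depend on the
original simulations.

## Problem sizes and defaults

Landscape analyses use 30,000-frame trajectories (the full-run
convention); interaction statistics use 2,000-frame scripted
trajectories with the final 10% as the analysis window; SIE trajectory
estimates use 100 snapshots; decomposition defaults to 25 snapshots
(it is ~5× the per-snapshot cost of the SIE terms); test fixtures use
shorter trajectories and coarser SASA quadrature (96 points) where only
behavioural properties are asserted. All generators and analyses are
pure functions of their parameters and seeds; CSV output is written at
fixed precision, so reruns are byte-identical.

## Known limitations

- The GB surrogate uses fixed Born radii (no self-consistent effective
  radii), so absolute ΔG_RF values differ from boundary-element or
  finite-difference Poisson results; rescoring published component
  tables bypasses the surrogate entirely.
- SASA quadrature error (~1% at 960 points) propagates into the cavity
  term at the γ-scaled level (~0.1 kcal/mol on typical buried areas).
- Basin detection is histogram-based; basins narrower than the bin
  width or shallower than the depth cutoff are not resolved.
- The H-bond model is purely geometric; no energetic or wavefunction
  criteria, and S/π acceptors are excluded.
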