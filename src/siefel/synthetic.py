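"""Seeded generators for toy receptor-ligand complexes and gate trajectories.

Every analysis stage in the pipeline is exercised against data produced
here, so the generators emulate the statistical structure the analyses
assume rather than physical dynamics:

* a CA-trace receptor with dummy sidechain atoms (CB, a hydroxyl OG-HG pair
  per residue) whose two designated "gate" loops sit opposite each other so
  their CA-centroid separation is a clean reaction coordinate;
* a small ligand docked in a pocket lined by enough residues to pin the
  heavy-atom contact count at a prescribed target;
* a two-state Markov chain on the gate separation (basins at 19 and 22 A by
  default, matching the closed/open gate picture) with Gaussian within-basin
  noise and per-residue positional jitter;
* Bernoulli-scripted hydrogen-bond geometries with exact per-pair occupancy
  targets, built by placing the acceptor on the donor-hydrogen axis
  (compliant) or beyond the distance cutoff (violated).

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, Topology, Trajectory
from .surface import sphere_points

__all__ = ["GateModelParams", "LigandScriptParams", "ToyComplex",
           "make_toy_complex", "simulate_gate_trajectory",
           "script_ligand_interactions"]

# per-atom-type nonbonded parameters: charge, rmin/2, epsilon, vdw, born
_ATOM_PARAMS = {
    "CA": (0.10, 1.9080, 0.1094, 1.70, 1.70),
    "CB": (-0.10, 1.9080, 0.1094, 1.70, 1.70),
    "OG": (-0.40, 1.6612, 0.2100, 1.52, 1.52),
    "HG": (0.40, 0.6000, 0.0157, 1.20, 1.15),
    "C": (0.00, 1.9080, 0.1094, 1.70, 1.70),     # ligand carbon
    "O": (-0.35, 1.6612, 0.2100, 1.52, 1.52),    # ligand oxygen
    "H": (0.35, 0.6000, 0.0157, 1.20, 1.15),     # ligand hydroxyl H
}


@dataclass(frozen=True)
class GateModelParams:
    """Two-state gate dynamics: which loops move, where the basins sit.

    ``occupancy_target`` is the stationary fraction of open-state (second
    basin) frames; ``switch_prob`` scales the per-frame switching rate while
    leaving the stationary occupancy unchanged. ``jitter_sigma`` is the
    per-coordinate Gaussian positional noise (A) on non-loop atoms,
    ``loop_jitter_sigma`` on gate-loop atoms (defaults to ``jitter_sigma``).
    """

    loopA_range: tuple[int, int] = (16, 26)
    loopB_range: tuple[int, int] = (41, 51)
    basin_means: tuple[float, float] = (19.0, 22.0)
    basin_sigmas: tuple[float, float] = (0.4, 0.4)
    switch_prob: float = 0.02
    occupancy_target: float = 0.5
    n_frames: int = 30_000
    jitter_sigma: float = 0.15
    loop_jitter_sigma: float | None = None
    frame_spacing_ps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basin_means[0] == self.basin_means[1]:
            raise ValueError("basin means must be distinct")
        if not 0 <= self.switch_prob < 1:
            raise ValueError("switch_prob must be in [0, 1)")
        if not 0 <= self.occupancy_target <= 1:
            raise ValueError("occupancy_target must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


@dataclass(frozen=True)
class LigandScriptParams:
    """Scripted H-bond occupancies and contact-shell maintenance.

    ``hbond_pairs`` maps scripted bonds as (donor residue number, ligand
    atom name, occupancy fraction): the donor is that residue's OG-HG
    hydroxyl, the acceptor the named ligand oxygen.
    """

    hbond_pairs: tuple[tuple[int, str, float], ...] = ()
    contact_count_target: int | None = None
    jitter_sigma: float = 0.05
    on_distance: float = 2.75
    off_distance: float = 4.30
    seed: int = 0

    def __post_init__(self) -> None:
        for res, name, occ in self.hbond_pairs:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(
                    f"occupancy for pair ({res}, {name}) outside [0, 1]")


@dataclass
class ToyComplex:
    topology: Topology
    parameters: pd.DataFrame
    loopA_range: tuple[int, int] = (16, 26)
    loopB_range: tuple[int, int] = (41, 51)
    pocket_residues: tuple[int, ...] = ()


def _tangent(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u (deterministic choice)."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t = np.cross(u, ref)
    return t / np.linalg.norm(t)


def make_toy_complex(n_residues: int = 60, seed: int = 0,
                     loopA_range: tuple[int, int] = (16, 26),
                     loopB_range: tuple[int, int] = (41, 51),
                     n_pocket_contacts: int = 18,
                     ligand_n_heavy: int = 20,
                     receptor_net_charge: float = 0.0,
                     ligand_net_charge: float = 0.0) -> ToyComplex:
    """Build a parameterised toy receptor-ligand complex.

    The receptor is a CA/CB/OG/HG trace: two 11-residue gate loops face each
    other across the pocket at a 19 A CA-centroid separation, pocket
    residues point their CB atoms at distinct ligand atoms 3.2 A away (so
    the heavy-atom contact count equals ``n_pocket_contacts``), and the
    remaining residues form a distant ring. The ligand is a small cluster of
    carbons and oxygens (two hydroxyls) with internal bonds. Every atom
    carries charges, Lennard-Jones parameters and radii; the same values are
    returned as a parameter table for round-tripping through the TSV format.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    loopA = list(range(loopA_range[0], loopA_range[1] + 1))
    loopB = list(range(loopB_range[0], loopB_range[1] + 1))
    loop_set = set(loopA) | set(loopB)
    if len(loopA) < 1 or len(loopB) < 1 or (set(loopA) & set(loopB)):
        raise ValueError("loops must be non-empty and disjoint")
    if max(loop_set) > n_residues:
        raise ValueError("loop ranges exceed n_residues")
    others = [r for r in range(1, n_residues + 1) if r not in loop_set]
    if len(others) < n_pocket_contacts:
        raise ValueError("not enough non-loop residues to line the pocket")
    if n_pocket_contacts > ligand_n_heavy:
        raise ValueError("pocket contacts cannot exceed ligand heavy atoms")
    pocket = others[:n_pocket_contacts]
    ring = others[n_pocket_contacts:]

    lig_center = np.zeros(3)
    lig_dirs = sphere_points(ligand_n_heavy)
    lig_heavy = lig_center + 2.2 * lig_dirs

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    serial = 0
    index_of: dict[tuple[int, str], int] = {}

    def add_atom(name: str, element: str, res_name: str, res_seq: int,
                 pos: np.ndarray, ptype: str) -> int:
        nonlocal serial
        serial += 1
        q, rm, ep, vdw, born = _ATOM_PARAMS[ptype]
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, residue_name=res_name,
            residue_seq=res_seq, chain_id="A", position=tuple(pos),
            partial_charge=q, lj_rmin_half=rm, lj_epsilon=ep,
            vdw_radius=vdw, born_radius=born))
        index_of[(res_seq, name)] = len(atoms) - 1
        return len(atoms) - 1

    def add_residue(res_seq: int, ca: np.ndarray, axis: np.ndarray,
                    res_name: str) -> None:
        ia = add_atom("CA", "C", res_name, res_seq, ca, "CA")
        cb = ca + 2.0 * axis
        ib = add_atom("CB", "C", res_name, res_seq, cb, "CB")
        t = _tangent(axis)
        og = cb + 1.4 * t
        io = add_atom("OG", "O", res_name, res_seq, og, "OG")
        ih = add_atom("HG", "H", res_name, res_seq, og + 0.96 * t, "HG")
        bonds.extend([(ia, ib), (ib, io), (io, ih)])

    # gate loops: CA rows along y at x = -9.5 / +9.5, above the pocket
    for k, res in enumerate(loopA):
        ca = np.array([-9.5, -5.0 + 10.0 * k / max(1, len(loopA) - 1), 5.0])
        add_residue(res, ca, np.array([0.0, 0.0, 1.0]), "GLY")
    for k, res in enumerate(loopB):
        ca = np.array([9.5, -5.0 + 10.0 * k / max(1, len(loopB) - 1), 5.0])
        add_residue(res, ca, np.array([0.0, 0.0, 1.0]), "GLY")
    # pocket residues: CB aimed at a distinct ligand atom, 3.2 A away; the
    # CA sits off-axis and the hydroxyl points radially outward so only the
    # CB is within contact range and the outward O-H axis stays clear of
    # other atoms (scripted acceptors are placed along it)
    for k, res in enumerate(pocket):
        u = lig_dirs[k]
        cb = lig_center + (2.2 + 3.0) * u
        t = _tangent(u)
        ia = add_atom("CA", "C", "SER", res, cb + 2.6 * t, "CA")
        ib = add_atom("CB", "C", "SER", res, cb, "CB")
        og = cb + 1.4 * u
        io = add_atom("OG", "O", "SER", res, og, "OG")
        ih = add_atom("HG", "H", "SER", res, og + 0.96 * u, "HG")
        bonds.extend([(ia, ib), (ib, io), (io, ih)])
    # remaining residues: a distant ring below the pocket
    for k, res in enumerate(ring):
        theta = 2.0 * np.pi * k / max(1, len(ring))
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = 16.0 * radial + np.array([0.0, 0.0, -8.0])
        ca = ca + rng.normal(0.0, 0.05, size=3)
        add_residue(res, ca, radial, "ALA")

    # backbone CA-CA bonds in residue order
    order = sorted({a.residue_seq for a in atoms})
    for r1, r2 in zip(order[:-1], order[1:]):
        bonds.append((index_of[(r1, "CA")], index_of[(r2, "CA")]))

    # ligand: heavy atoms on a small sphere, oxygens every third atom,
    # hydroxyl hydrogens on the first two oxygens
    lig_seq = n_residues + 1
    lig_indices: list[int] = []
    oxygens: list[int] = []
    for k in range(ligand_n_heavy):
        if k % 3 == 0:
            name = f"O{len(oxygens) + 1}"
            i = add_atom(name, "O", "LIG", lig_seq, lig_heavy[k], "O")
            oxygens.append(i)
        else:
            i = add_atom(f"C{k + 1}", "C", "LIG", lig_seq, lig_heavy[k], "C")
        lig_indices.append(i)
    for a, b in zip(lig_indices[:-1], lig_indices[1:]):
        bonds.append((a, b))
    for io in oxygens[:2]:
        pos = np.array(atoms[io].position)
        u = pos - lig_center
        u = u / np.linalg.norm(u)
        ih = add_atom(f"H{io}", "H", "LIG", lig_seq, pos + 0.96 * u, "H")
        bonds.append((io, ih))
        lig_indices.append(ih)

    # distribute requested net charges over receptor CAs / ligand carbons
    rec_idx = tuple(i for i, a in enumerate(atoms) if a.residue_seq != lig_seq)
    lig_idx = tuple(i for i, a in enumerate(atoms) if a.residue_seq == lig_seq)
    base_rec = sum(atoms[i].partial_charge for i in rec_idx)
    base_lig = sum(atoms[i].partial_charge for i in lig_idx)
    ca_idx = [i for i in rec_idx if atoms[i].name == "CA"]
    lc_idx = [i for i in lig_idx if atoms[i].element == "C"]
    from dataclasses import replace as _replace
    if abs(receptor_net_charge - base_rec) > 1e-12:
        dq = (receptor_net_charge - base_rec) / len(ca_idx)
        for i in ca_idx:
            atoms[i] = _replace(atoms[i], partial_charge=atoms[i].partial_charge + dq)
    if abs(ligand_net_charge - base_lig) > 1e-12:
        dq = (ligand_net_charge - base_lig) / len(lc_idx)
        for i in lc_idx:
            atoms[i] = _replace(atoms[i], partial_charge=atoms[i].partial_charge + dq)

    topology = Topology(atoms=atoms, bonds=sorted(set(bonds)),
                        groups={"receptor": rec_idx, "ligand": lig_idx})
    table = pd.DataFrame({
        "serial": [a.serial for a in atoms],
        "charge": [a.partial_charge for a in atoms],
        "rmin_half": [a.lj_rmin_half for a in atoms],
        "epsilon": [a.lj_epsilon for a in atoms],
        "vdw_radius": [a.vdw_radius for a in atoms],
        "born_radius": [a.born_radius for a in atoms],
    })
    return ToyComplex(topology=topology, parameters=table,
                      loopA_range=loopA_range, loopB_range=loopB_range,
                      pocket_residues=tuple(pocket))


def _stationary_markov_states(rng: np.random.Generator, n: int,
                              p_open: float, switch_prob: float) -> np.ndarray:
    """0/1 state chain with stationary open fraction ``p_open``."""
    if switch_prob == 0.0 or p_open in (0.0, 1.0):
        s0 = 1 if (p_open > 0.5 or p_open == 1.0) else 0
        if 0.0 < p_open < 1.0:
            s0 = int(rng.random() < p_open)
        states = np.full(n, s0, dtype=int)
        if switch_prob == 0.0:
            return states
    p_co = min(1.0, 2.0 * switch_prob * p_open)          # close -> open
    p_oc = min(1.0, 2.0 * switch_prob * (1.0 - p_open))  # open -> close
    states = np.empty(n, dtype=int)
    states[0] = int(rng.random() < p_open)
    u = rng.random(n)
    for t in range(1, n):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p_co else 0
        else:
            states[t] = 0 if u[t] < p_oc else 1
    return states


def simulate_gate_trajectory(toy: ToyComplex,
                             params: GateModelParams = GateModelParams()
                             ) -> Trajectory:
    """Two-state gate trajectory over a toy complex.

    The gate separation follows a two-state Markov chain between the basin
    means with Gaussian within-basin noise; each loop is displaced rigidly
    by half the separation change along the gate axis, and every atom gets
    independent Gaussian jitter.
    """
    top = toy.topology
    rng = np.random.default_rng(params.seed)
    seqs = top.residue_seqs
    loopA_mask = (seqs >= params.loopA_range[0]) & (seqs <= params.loopA_range[1])
    loopB_mask = (seqs >= params.loopB_range[0]) & (seqs <= params.loopB_range[1])
    lig = top.group_indices("ligand")
    loopA_mask[lig] = False
    loopB_mask[lig] = False
    if not loopA_mask.any() or not loopB_mask.any():
        raise ValueError("gate loops not resolvable on this topology")
    base = top.coords()
    names = np.array([a.name for a in top.atoms])
    caA = base[loopA_mask & (names == "CA")].mean(axis=0)
    caB = base[loopB_mask & (names == "CA")].mean(axis=0)
    axis = (caB - caA) / np.linalg.norm(caB - caA)
    s0 = float(np.linalg.norm(caB - caA))

    n = params.n_frames
    states = _stationary_markov_states(rng, n, params.occupancy_target,
                                       params.switch_prob)
    means = np.asarray(params.basin_means)[states]
    sigmas = np.asarray(params.basin_sigmas)[states]
    sep = means + rng.normal(0.0, 1.0, size=n) * sigmas

    sig = np.full(top.n_atoms, params.jitter_sigma)
    loop_sigma = (params.loop_jitter_sigma if params.loop_jitter_sigma is not None
                  else params.jitter_sigma)
    sig[loopA_mask | loopB_mask] = loop_sigma

    frames = np.empty((n, top.n_atoms, 3))
    jitter = rng.normal(0.0, 1.0, size=(n, top.n_atoms, 3)) * sig[None, :, None]
    half = 0.5 * (sep - s0)
    frames[:] = base[None, :, :] + jitter
    frames[:, loopA_mask, :] -= half[:, None, None] * axis[None, None, :]
    frames[:, loopB_mask, :] += half[:, None, None] * axis[None, None, :]
    times = np.arange(n, dtype=float) * params.frame_spacing_ps
    return Trajectory(topology=top, frames=frames, times=times)


def script_ligand_interactions(traj: Trajectory, toy: ToyComplex,
                               params: LigandScriptParams = LigandScriptParams()
                               ) -> Trajectory:
    """Overwrite ligand positions so scripted H-bonds hit target occupancies.

    For each scripted (residue, ligand oxygen, occupancy) triple, an
    independent per-frame Bernoulli draw decides whether the acceptor is
    placed on the donor's O-H axis at a compliant distance (linear geometry,
    D-A = 2.75 A) or pushed past the distance cutoff (4.30 A). Unscripted
    ligand atoms keep their trajectory positions plus small jitter, which
    leaves the pocket contact count within about +/-2 of the built target.
    """
    top = traj.topology
    rng = np.random.default_rng(params.seed)
    frames = traj.frames.copy()
    lig = top.group_indices("ligand")
    frames[:, lig, :] += rng.normal(0.0, params.jitter_sigma,
                                    size=(traj.n_frames, lig.size, 3))
    name_of = {(a.residue_seq, a.name): i for i, a in enumerate(top.atoms)}
    lig_seq = top.atoms[lig[0]].residue_seq
    for res, lig_atom, occ in params.hbond_pairs:
        try:
            d_idx = name_of[(res, "OG")]
            h_idx = name_of[(res, "HG")]
            a_idx = name_of[(lig_seq, lig_atom)]
        except KeyError as exc:
            raise ValueError(
                f"scripted pair ({res}, {lig_atom}) not present in topology"
            ) from exc
        on = rng.random(traj.n_frames) < occ
        og = frames[:, d_idx, :]
        hg = frames[:, h_idx, :]
        u = hg - og
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dist = np.where(on, params.on_distance, params.off_distance)
        frames[:, a_idx, :] = og + dist[:, None] * u
    out = Trajectory(topology=top, frames=frames, times=traj.times.copy())
    if params.contact_count_target is not None:
        from .interactions import atom_contacts
        c0 = atom_contacts(out.frames[0], top)
        if abs(c0 - params.contact_count_target) > 2:
            raise ValueError(
                f"frame-0 contact count {c0} misses target "
                f"{params.contact_count_target} by more than 2")
    return out
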