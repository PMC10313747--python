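"""Hand-built miniature topologies/trajectories used across test modules."""

from __future__ import annotations

import numpy as np

from siefel.structure_io import AtomRecord, Topology, Trajectory


def make_atom(serial, pos, *, name="CA", element="C", res_name="ALA",
              res_seq=None, chain="A", charge=0.0, rmin_half=1.908,
              epsilon=0.1094, vdw=1.70, born=1.70):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=res_name,
        residue_seq=res_seq if res_seq is not None else serial, chain_id=chain,
        position=tuple(pos), partial_charge=charge, lj_rmin_half=rmin_half,
        lj_epsilon=epsilon, vdw_radius=vdw, born_radius=born)


def ca_chain(residues, spacing=3.8, name="CA"):
    """One CA atom per residue number, on a line along x."""
    return [make_atom(i + 1, (spacing * i, 0.0, 0.0), name=name, res_seq=r)
            for i, r in enumerate(residues)]


def topology_from_atoms(atoms, bonds=(), receptor=None, ligand=()):
    n = len(atoms)
    lig = tuple(ligand)
    rec = tuple(receptor) if receptor is not None else tuple(
        i for i in range(n) if i not in set(lig))
    return Topology(atoms=list(atoms), bonds=list(bonds),
                    groups={"receptor": rec, "ligand": lig})


def constant_trajectory(topology, n_frames, dt=10.0):
    base = topology.coords()
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    return Trajectory(topology=topology, frames=frames,
                      times=np.arange(n_frames, dtype=float) * dt)


def random_rotation(rng):
    """Uniform random proper rotation from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
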