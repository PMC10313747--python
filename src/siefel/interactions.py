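"""Geometric contacts, hydrogen bonds, occupancies and interaction maps.

A contact is a receptor atom whose minimum distance to any ligand atom is
within the cutoff (3.5 Å default, heavy atoms only by default). A hydrogen
bond is a donor-hydrogen-acceptor triple with donor-acceptor distance
<= 3.5 Å and a D-H...A angle (measured at the hydrogen, the standard
convention) >= 150 degrees; both bounds are inclusive. Donors and acceptors
are restricted to N and O; donor hydrogens are identified from the covalent
bond list, so a topology without bonds cannot be searched for H-bonds.

Occupancy is the percentage of frames in an analysis window in which a
given donor/acceptor pair satisfies the criteria; interaction maps report,
per receptor residue, the H-bond occupancy and the occurrence of
carbon-carbon (hydrophobic) contacts with the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AnalysisError, Topology, Trajectory

__all__ = [
    "ContactCriteria",
    "HBondCriteria",
    "HBondEvent",
    "atom_contacts",
    "contact_series",
    "detect_hbonds",
    "hbond_count_series",
    "hbond_occupancy",
    "interaction_map",
]

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}  # S deliberately excluded


@dataclass(frozen=True)
class ContactCriteria:
    cutoff: float = 3.5
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5
    min_dha_angle: float = 150.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    distance: float
    angle: float
    frame: int = 0


def atom_contacts(frame: np.ndarray, topology: Topology,
                  receptor_group: str = "receptor", ligand_group: str = "ligand",
                  criteria: ContactCriteria = ContactCriteria()) -> int:
    """Number of receptor atoms within the cutoff of any ligand atom."""
    rec = topology.group_indices(receptor_group)
    lig = topology.group_indices(ligand_group)
    if rec.size == 0 or lig.size == 0:
        raise AnalysisError("contact groups must be non-empty")
    if np.intersect1d(rec, lig).size:
        raise AnalysisError("contact groups overlap")
    coords = np.asarray(frame, dtype=float)
    elements = topology.elements
    if criteria.heavy_atoms_only:
        rec = rec[elements[rec] != "H"]
        lig = lig[elements[lig] != "H"]
        if rec.size == 0 or lig.size == 0:
            return 0
    tree = cKDTree(coords[lig])
    dmin, _ = tree.query(coords[rec], k=1)
    return int(np.count_nonzero(dmin <= criteria.cutoff))


def contact_series(traj: Trajectory, criteria: ContactCriteria = ContactCriteria(),
                   receptor_group: str = "receptor", ligand_group: str = "ligand",
                   frames: range | None = None) -> pd.DataFrame:
    frame_range = frames if frames is not None else range(traj.n_frames)
    rows = [(f, traj.times[f],
             atom_contacts(traj.frames[f], traj.topology, receptor_group,
                           ligand_group, criteria))
            for f in frame_range]
    return pd.DataFrame(rows, columns=["frame_index", "time_ps", "n_contacts"])


def _donor_hydrogen_pairs(topology: Topology, donors_from: np.ndarray
                          ) -> list[tuple[int, int]]:
    if not topology.bonds:
        raise AnalysisError(
            "topology has no bonds; donor hydrogens cannot be identified")
    elements = topology.elements
    donors = set(int(i) for i in donors_from)
    pairs = []
    for i, j in topology.bonds:
        ei, ej = elements[i], elements[j]
        if ei in _DONOR_ACCEPTOR_ELEMENTS and ej == "H" and i in donors:
            pairs.append((i, j))
        elif ej in _DONOR_ACCEPTOR_ELEMENTS and ei == "H" and j in donors:
            pairs.append((j, i))
    return pairs


def _dha_angle(coords: np.ndarray, d: int, h: int, a: int) -> float:
    """D-H...A angle at the hydrogen, degrees (180 = linear)."""
    v1 = coords[d] - coords[h]
    v2 = coords[a] - coords[h]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  donors_from: np.ndarray, acceptors_from: np.ndarray,
                  criteria: HBondCriteria = HBondCriteria(),
                  frame_index: int = 0) -> list[HBondEvent]:
    """All donor-H...acceptor triples satisfying the geometric criteria.

    ``donors_from`` / ``acceptors_from`` are atom index pools (typically the
    two groups of a complex, in either direction). Acceptors are N/O atoms
    of the acceptor pool; donors are N/O atoms of the donor pool that carry
    a covalently bonded hydrogen.
    """
    coords = np.asarray(frame, dtype=float)
    elements = topology.elements
    acc = np.asarray([i for i in acceptors_from
                      if elements[i] in _DONOR_ACCEPTOR_ELEMENTS], dtype=int)
    dh = _donor_hydrogen_pairs(topology, np.asarray(donors_from, dtype=int))
    if acc.size == 0 or not dh:
        return []
    tree = cKDTree(coords[acc])
    events = []
    for d, h in dh:
        for k in tree.query_ball_point(coords[d], r=criteria.max_da_distance):
            a = int(acc[k])
            if a == d or a == h:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > criteria.max_da_distance:
                continue
            ang = _dha_angle(coords, d, h, a)
            if ang >= criteria.min_dha_angle:
                events.append(HBondEvent(d, h, a, dist, ang, frame_index))
    return events


def hbond_count_series(traj: Trajectory, criteria: HBondCriteria = HBondCriteria(),
                       receptor_group: str = "receptor",
                       ligand_group: str = "ligand",
                       frames: range | None = None) -> pd.DataFrame:
    """Per-frame count of receptor-ligand H-bonds (both donor directions)."""
    rec = traj.topology.group_indices(receptor_group)
    lig = traj.topology.group_indices(ligand_group)
    frame_range = frames if frames is not None else range(traj.n_frames)
    rows = []
    for f in frame_range:
        ev = detect_hbonds(traj.frames[f], traj.topology, rec, lig, criteria, f)
        ev += detect_hbonds(traj.frames[f], traj.topology, lig, rec, criteria, f)
        rows.append((f, traj.times[f], len(ev)))
    return pd.DataFrame(rows, columns=["frame_index", "time_ps", "n_hbonds"])


def hbond_occupancy(traj: Trajectory, donor_atom: int, acceptor_atom: int,
                    criteria: HBondCriteria = HBondCriteria(),
                    window: range | None = None) -> float:
    """Occupancy (%) of one donor/acceptor pair over an analysis window.

    The pair is present in a frame if any hydrogen bonded to the donor
    satisfies both geometric criteria with the acceptor.
    """
    top = traj.topology
    window = window if window is not None else range(traj.n_frames)
    if len(window) == 0:
        raise AnalysisError("empty analysis window")
    hydrogens = top.hydrogens_bonded_to(donor_atom)
    if not top.bonds:
        raise AnalysisError(
            "topology has no bonds; donor hydrogens cannot be identified")
    if not hydrogens:
        return 0.0
    fr = np.asarray(list(window), dtype=int)
    X = traj.frames[fr]
    dist = np.linalg.norm(X[:, acceptor_atom] - X[:, donor_atom], axis=1)
    present = np.zeros(len(fr), dtype=bool)
    for h in hydrogens:
        v1 = X[:, donor_atom] - X[:, h]
        v2 = X[:, acceptor_atom] - X[:, h]
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        present |= ang >= criteria.min_dha_angle
    present &= dist <= criteria.max_da_distance
    return float(100.0 * present.mean())


def interaction_map(traj: Trajectory,
                    contact_criteria: ContactCriteria = ContactCriteria(),
                    hbond_criteria: HBondCriteria = HBondCriteria(),
                    receptor_group: str = "receptor",
                    ligand_group: str = "ligand",
                    window: range | None = None) -> pd.DataFrame:
    """Per-residue H-bond and hydrophobic-contact occurrence (%) table.

    One row per receptor residue that comes within the contact cutoff of
    the ligand at least once during the window. ``hbond_pct`` counts frames
    with any H-bond between that residue and the ligand (either donor
    direction); ``hydrophobic_pct`` counts frames with any carbon-carbon
    pair within the contact cutoff.
    """
    top = traj.topology
    rec = top.group_indices(receptor_group)
    lig = top.group_indices(ligand_group)
    window = window if window is not None else range(traj.n_frames)
    n_frames = len(window)
    if n_frames == 0:
        raise AnalysisError("empty analysis window")
    elements = top.elements
    res_of = top.residue_seqs
    rec_c = rec[elements[rec] == "C"]
    lig_c = lig[elements[lig] == "C"]
    contact_frames: dict[int, int] = {}
    hydrophobic_frames: dict[int, int] = {}
    hbond_frames: dict[int, int] = {}
    for f in window:
        coords = traj.frames[f]
        lig_tree = cKDTree(coords[lig])
        dmin, _ = lig_tree.query(coords[rec], k=1)
        for r in np.unique(res_of[rec][dmin <= contact_criteria.cutoff]):
            contact_frames[int(r)] = contact_frames.get(int(r), 0) + 1
        if rec_c.size and lig_c.size:
            ctree = cKDTree(coords[lig_c])
            cmin, _ = ctree.query(coords[rec_c], k=1)
            for r in np.unique(res_of[rec_c][cmin <= contact_criteria.cutoff]):
                hydrophobic_frames[int(r)] = hydrophobic_frames.get(int(r), 0) + 1
        events = detect_hbonds(coords, top, rec, lig, hbond_criteria, f)
        events += detect_hbonds(coords, top, lig, rec, hbond_criteria, f)
        seen: set[int] = set()
        for ev in events:
            r = int(res_of[ev.donor_atom]) if ev.donor_atom in set(rec.tolist()) \
                else int(res_of[ev.acceptor_atom])
            seen.add(r)
        for r in seen:
            hbond_frames[r] = hbond_frames.get(r, 0) + 1
    residues = sorted(contact_frames)
    rows = []
    for r in residues:
        rows.append((
            r, top.residue_name_of(r),
            100.0 * hbond_frames.get(r, 0) / n_frames,
            100.0 * hydrophobic_frames.get(r, 0) / n_frames,
        ))
    return pd.DataFrame(rows, columns=["residue_seq", "residue_name",
                                       "hbond_pct", "hydrophobic_pct"])
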