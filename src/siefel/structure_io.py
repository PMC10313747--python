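"""Structures, trajectories, parameter tables and atom selections.

The shared data model for the whole pipeline lives here: an ordered list of
:class:`AtomRecord` objects makes a :class:`Topology`, a stack of coordinate
frames over a topology makes a :class:`Trajectory`, and residue-range
:class:`SelectionSpec` strings resolve to atom index sets.

Coordinates are Ångström throughout; times are picoseconds; charges are
elementary charges; energies downstream are kcal/mol.

Supported on-disk formats are plain-text only: PDB (ATOM/HETATM with
MODEL/ENDMDL for multi-frame files), multi-frame XYZ, and a tab-separated
per-atom parameter table (partial charge, Lennard-Jones r_min/2 and epsilon,
van der Waals radius for surface area, Born radius for the reaction-field
surrogate). Parameters deliberately live in a sidecar table rather than in a
force-field file so the pipeline stays engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisError",
    "PDBParseError",
    "EmptyInputError",
    "ParameterError",
    "SelectionError",
    "AtomRecord",
    "Topology",
    "Trajectory",
    "SelectionSpec",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "read_parameter_table",
    "write_parameter_table",
    "resolve_selection",
]

#: Default frame spacing (ps) assumed when a trajectory file carries no times
#: (300 ns over 30,000 frames).
DEFAULT_FRAME_SPACING_PS = 10.0


class AnalysisError(Exception):
    """Base class for all errors raised by this package."""


class PDBParseError(AnalysisError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyInputError(AnalysisError):
    """An input contained no usable records."""


class ParameterError(AnalysisError):
    """The per-atom parameter table does not match the topology."""


class SelectionError(AnalysisError):
    """A selection expression is malformed or resolves to nothing."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, reference position, and nonbonded parameters.

    Parameters default to NaN until populated from a parameter table; the
    energetics and surface modules refuse to run on unparameterised atoms.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: tuple[float, float, float]
    partial_charge: float = float("nan")
    lj_rmin_half: float = float("nan")
    lj_epsilon: float = float("nan")
    vdw_radius: float = float("nan")
    born_radius: float = float("nan")

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.residue_seq < 1:
            raise ValueError(
                f"residue_seq must be >= 1, got {self.residue_seq} "
                f"(atom serial {self.serial})"
            )
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom serial {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Topology:
    """Ordered atoms plus bonds and named atom groups.

    Groups are name -> sorted tuple of atom indices (0-based). The two
    groups the pipeline cares about are ``"receptor"`` and ``"ligand"``;
    they must be disjoint.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) outside 0..{n - 1}")
        # canonical order so bond lists round-trip through CONECT records
        self.bonds = sorted({(min(i, j), max(i, j)) for i, j in self.bonds})
        self.groups = {k: tuple(sorted(set(v))) for k, v in self.groups.items()}
        for name, idx in self.groups.items():
            for i in idx:
                if not 0 <= i < n:
                    raise ValueError(f"group {name!r} index {i} outside 0..{n - 1}")
        rec = set(self.groups.get("receptor", ()))
        lig = set(self.groups.get("ligand", ()))
        if rec & lig:
            raise ValueError("'receptor' and 'ligand' groups overlap")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """Reference-frame coordinates, (N, 3) float64 Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def group_indices(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"no atom group named {name!r}")
        return np.asarray(self.groups[name], dtype=int)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element.upper() for a in self.atoms])

    @property
    def residue_seqs(self) -> np.ndarray:
        return np.array([a.residue_seq for a in self.atoms], dtype=int)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def born_radii(self) -> np.ndarray:
        return np.array([a.born_radius for a in self.atoms], dtype=float)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms], dtype=float)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    def residue_name_of(self, residue_seq: int) -> str:
        for a in self.atoms:
            if a.residue_seq == residue_seq:
                return a.residue_name
        raise KeyError(f"no residue with sequence number {residue_seq}")

    def hydrogens_bonded_to(self, atom_index: int) -> list[int]:
        """Indices of H atoms covalently bonded to ``atom_index``."""
        out = []
        for i, j in self.bonds:
            if i == atom_index and self.atoms[j].is_hydrogen:
                out.append(j)
            elif j == atom_index and self.atoms[i].is_hydrogen:
                out.append(i)
        return out


@dataclass
class Trajectory:
    """Frames over a fixed topology: (F, N, 3) Å coordinates, (F,) ps times."""

    topology: Topology
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def window(self, start: int | None = None, stop: int | None = None,
               last_fraction: float | None = None) -> range:
        """Frame-index range for an analysis window.

        ``last_fraction`` selects the trailing fraction of the run (the
        equilibrium-phase convention: the last 10 ns of a 100 ns segment is
        ``last_fraction=0.1``); otherwise an explicit ``[start, stop)`` pair
        is used, with Python slice defaults.
        """
        if last_fraction is not None:
            if not 0 < last_fraction <= 1:
                raise ValueError("last_fraction must be in (0, 1]")
            start = self.n_frames - max(1, int(round(self.n_frames * last_fraction)))
            stop = self.n_frames
        start = 0 if start is None else int(start)
        stop = self.n_frames if stop is None else int(stop)
        if start < 0 or stop > self.n_frames or start >= stop:
            raise ValueError(f"empty or out-of-range window [{start}, {stop})")
        return range(start, stop)


@dataclass(frozen=True)
class SelectionSpec:
    """Residue-range selection, e.g. ``"83-93"`` with an optional CA filter.

    The expression is a comma-separated list of 1-based residue numbers or
    inclusive ranges (``"83-93,100"``). Numbering is taken verbatim from the
    structure; gaps in the numbering are tolerated (a range spanning a
    missing residue simply selects fewer residues).
    """

    expression: str
    chain: str | None = None
    atom_names: tuple[str, ...] | None = None

    def residue_numbers(self) -> set[int]:
        out: set[int] = set()
        expr = self.expression.strip()
        if not expr:
            raise SelectionError("empty selection expression")
        for part in expr.split(","):
            part = part.strip()
            try:
                if "-" in part:
                    lo_s, hi_s = part.split("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                    if hi < lo:
                        raise ValueError
                    out.update(range(lo, hi + 1))
                else:
                    out.add(int(part))
            except ValueError:
                raise SelectionError(
                    f"malformed selection term {part!r} in {self.expression!r}"
                ) from None
        return out


def resolve_selection(spec: SelectionSpec, topology: Topology) -> np.ndarray:
    """Resolve a selection to a sorted, duplicate-free atom index array."""
    wanted = spec.residue_numbers()
    names = {n.strip().upper() for n in spec.atom_names} if spec.atom_names else None
    idx = [
        i for i, a in enumerate(topology.atoms)
        if a.residue_seq in wanted
        and (spec.chain is None or a.chain_id == spec.chain)
        and (names is None or a.name.strip().upper() in names)
    ]
    if not idx:
        raise SelectionError(
            f"selection {spec.expression!r} (chain={spec.chain!r}, "
            f"atoms={spec.atom_names!r}) matches no atoms"
        )
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_PDB_COORD_FMT = (
    "{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}"
    "{b:>6.2f}          {elem:>2s}"
)


def _format_atom_name(name: str) -> str:
    # PDB convention: names of <4 chars start in column 14 (one leading space)
    name = name.strip()
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed PDB record at line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        # fall back to the first alphabetic character of the atom name
        stripped = name.lstrip("0123456789")
        element = stripped[:1] or "X"
    return AtomRecord(
        serial=serial,
        name=name,
        element=element.capitalize(),
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain_id=chain_id,
        position=(x, y, z),
    )


def read_pdb(path: str | Path,
             ligand_resnames: Iterable[str] = ()) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-model) PDB file.

    Returns ``(topology, trajectory)``. A single-model file yields a
    one-frame trajectory; MODEL/ENDMDL blocks yield one frame each and must
    all contain the same atoms. Atoms whose residue name is listed in
    ``ligand_resnames`` form the ``"ligand"`` group; all others form
    ``"receptor"``. CONECT records populate the bond list.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()
    serial_to_index: dict[int, int] = {}
    in_model = False
    conect_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec == "MODEL":
                in_model = True
                if current:
                    models.append(current)
                    current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec == "CONECT":
                conect_lines.append((lineno, line))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")

    first = models[0]
    serial_to_index = {a.serial: i for i, a in enumerate(first)}
    for lineno, line in conect_lines:
        try:
            serials = [int(line[k:k + 5]) for k in range(6, len(line.rstrip()), 5)]
        except ValueError as exc:
            raise PDBParseError(f"malformed CONECT at line {lineno}") from exc
        if not serials:
            continue
        base = serials[0]
        for other in serials[1:]:
            if base in serial_to_index and other in serial_to_index:
                i, j = serial_to_index[base], serial_to_index[other]
                bonds.add((min(i, j), max(i, j)))

    lig_names = {n.strip().upper() for n in ligand_resnames}
    lig_idx = tuple(i for i, a in enumerate(first)
                    if a.residue_name.upper() in lig_names)
    rec_idx = tuple(i for i in range(len(first)) if i not in set(lig_idx))
    topology = Topology(atoms=list(first), bonds=sorted(bonds),
                        groups={"receptor": rec_idx, "ligand": lig_idx})

    n = len(first)
    frames = np.empty((len(models), n, 3), dtype=float)
    for f, model in enumerate(models):
        if len(model) != n:
            raise PDBParseError(
                f"{path}: model {f + 1} has {len(model)} atoms, expected {n}"
            )
        frames[f] = [a.position for a in model]
    times = np.arange(len(models), dtype=float) * DEFAULT_FRAME_SPACING_PS
    _ = in_model  # single- vs multi-model handled uniformly
    return topology, Trajectory(topology=topology, frames=frames, times=times)


def write_pdb(path: str | Path, topology: Topology,
              frames: np.ndarray | None = None) -> None:
    """Write a PDB file; multiple frames become MODEL/ENDMDL blocks.

    Ligand-group atoms are written as HETATM, everything else as ATOM.
    Coordinates are written at standard PDB precision (3 decimals), which
    bounds the round-trip accuracy of the format.
    """
    coords = topology.coords()[None, :, :] if frames is None else np.asarray(frames, float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    lig = set(topology.groups.get("ligand", ()))
    multi = coords.shape[0] > 1
    lines: list[str] = []
    for f in range(coords.shape[0]):
        if multi:
            lines.append(f"MODEL     {f + 1:>4d}")
        for i, a in enumerate(topology.atoms):
            lines.append(_PDB_COORD_FMT.format(
                rec="HETATM" if i in lig else "ATOM",
                serial=a.serial, name=_format_atom_name(a.name), alt=" ",
                res=a.residue_name, chain=a.chain_id, resseq=a.residue_seq,
                icode=" ", x=coords[f, i, 0], y=coords[f, i, 1],
                z=coords[f, i, 2], occ=1.00, b=0.00, elem=a.element.upper(),
            ))
        if multi:
            lines.append("ENDMDL")
    for i, j in topology.bonds:
        lines.append(f"CONECT{topology.atoms[i].serial:>5d}{topology.atoms[j].serial:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(path: str | Path, trajectory: Trajectory) -> None:
    """Write a multi-frame XYZ file; times go in the comment line (``t= <ps>``)."""
    top = trajectory.topology
    elems = [a.element for a in top.atoms]
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"t= {trajectory.times[f]:.4f}\n")
            for e, (x, y, z) in zip(elems, trajectory.frames[f]):
                fh.write(f"{e:<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def read_xyz(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-frame XYZ file against an existing topology.

    Frame times are taken from ``t= <ps>`` comment lines when present,
    otherwise assigned on a uniform 10 ps grid.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise PDBParseError(f"{path}: expected atom count at line {pos + 1}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t = None
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                t = None
        block = lines[pos + 2:pos + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"{path}: truncated frame starting at line {pos + 1}")
        coords = np.empty((n, 3))
        for k, row in enumerate(block):
            parts = row.split()
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"{path}: malformed XYZ row at line {pos + 3 + k}"
                ) from exc
        frames.append(coords)
        times.append(t if t is not None else len(frames) * DEFAULT_FRAME_SPACING_PS)
        pos += 2 + n
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    if any(f.shape[0] != topology.n_atoms for f in frames):
        raise PDBParseError(f"{path}: frame atom count differs from topology")
    times_arr = np.asarray(times, dtype=float)
    if np.any(np.diff(times_arr) <= 0):
        times_arr = np.arange(len(frames), dtype=float) * DEFAULT_FRAME_SPACING_PS
    return Trajectory(topology=topology, frames=np.stack(frames), times=times_arr)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

PARAMETER_COLUMNS = ("serial", "charge", "rmin_half", "epsilon",
                     "vdw_radius", "born_radius")


def read_parameter_table(path: str | Path, topology: Topology) -> Topology:
    """Attach per-atom nonbonded parameters from a TSV to a topology.

    The table must have exactly one row per atom, keyed by atom serial.
    Returns a new :class:`Topology`; the input is not modified.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParameterError(f"{path}: missing columns {missing_cols}")
    by_serial = {int(r.serial): r for r in df.itertuples(index=False)}
    if len(by_serial) != len(df):
        raise ParameterError(f"{path}: duplicate serials in parameter table")
    wanted = [a.serial for a in topology.atoms]
    absent = [s for s in wanted if s not in by_serial]
    if absent:
        raise ParameterError(
            f"{path}: incomplete parameters; missing serials {absent[:20]}"
            + ("..." if len(absent) > 20 else "")
        )
    extra = set(by_serial) - set(wanted)
    if extra:
        raise ParameterError(
            f"{path}: {len(extra)} rows do not match any atom "
            f"(e.g. serials {sorted(extra)[:10]})"
        )
    new_atoms = []
    for a in topology.atoms:
        r = by_serial[a.serial]
        if r.epsilon < 0 or r.vdw_radius <= 0 or r.born_radius <= 0:
            raise ParameterError(
                f"{path}: invalid parameters for serial {a.serial} "
                f"(epsilon >= 0, radii > 0 required)"
            )
        new_atoms.append(replace(
            a, partial_charge=float(r.charge), lj_rmin_half=float(r.rmin_half),
            lj_epsilon=float(r.epsilon), vdw_radius=float(r.vdw_radius),
            born_radius=float(r.born_radius),
        ))
    return Topology(atoms=new_atoms, bonds=list(topology.bonds),
                    groups=dict(topology.groups))


def write_parameter_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = list(PARAMETER_COLUMNS)
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def group_net_charge(topology: Topology, group: str) -> float:
    """Sum of partial charges over a named group (e)."""
    idx = topology.group_indices(group)
    q = topology.charges[idx]
    if np.any(~np.isfinite(q)):
        raise ParameterError(f"group {group!r} has unparameterised atoms")
    return float(q.sum())
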