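"""Superposition and deviation/fluctuation/distance metrics.

Rigid-body fitting uses the Kabsch SVD algorithm with the reflection
correction, so the returned rotation is always proper (det = +1). RMSD
series are computed after per-frame superposition on a configurable fit
selection (by convention the receptor CA atoms); RMSF is computed about the
time-averaged structure after fitting, which makes it invariant to global
rigid motion of the trajectory.

The open/close gate classification encodes the two-basin picture of the
T83-E93 / G251-C261 loop pair: centroid separations near 19 Å (closed gate)
and 22 Å (open gate), split at the 20.5 Å midpoint with ties counted open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import (
    AnalysisError,
    SelectionSpec,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "GeometryError",
    "SuperpositionResult",
    "ConformationThresholds",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "centroid_distance_series",
    "classify_conformation",
]


class GeometryError(AnalysisError):
    """Degenerate or mismatched geometric input."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    The transform is ``x' = R @ (x - mobile_centroid) + reference_centroid``;
    ``translation`` stores ``reference_centroid - R @ mobile_centroid`` so
    that ``x' = R @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ConformationThresholds:
    """Gate-distance basins and the decision boundary between them (Å)."""

    d_open: float = 22.0
    d_close: float = 19.0
    boundary: float = 20.5

    def __post_init__(self) -> None:
        if not self.d_close < self.boundary < self.d_open:
            raise ValueError(
                f"require d_close < boundary < d_open, got "
                f"{self.d_close}, {self.boundary}, {self.d_open}"
            )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Minimises the (optionally weighted) RMSD over proper rotations and
    translations. Reflections are disallowed. Raises :class:`GeometryError`
    for fewer than 3 points or (near-)collinear input, where the rotation is
    not uniquely determined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"shape mismatch: mobile {P.shape} vs reference {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points for superposition, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ P
    cr = w @ Q
    P0 = P - cm
    Q0 = Q - cr
    H = P0.T @ (Q0 * w[:, None])
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-8 * max(S[0], 1e-12):
        raise GeometryError("ill-conditioned superposition (collinear points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=cr - R @ cm, rmsd=rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                fit_sel: SelectionSpec, measure_sel: SelectionSpec) -> pd.DataFrame:
    """Per-frame RMSD (Å) against a reference structure.

    Each frame is first superposed on the reference over ``fit_sel``; the
    RMSD is then measured over ``measure_sel`` (which may differ from the
    fit set). ``reference`` must be an (N, 3) coordinate array over the same
    topology.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.topology.n_atoms, 3):
        raise GeometryError(
            f"reference shape {reference.shape} does not match topology "
            f"({traj.topology.n_atoms} atoms)"
        )
    fit_idx = resolve_selection(fit_sel, traj.topology)
    meas_idx = resolve_selection(measure_sel, traj.topology)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.frames[f][fit_idx], reference[fit_idx])
        values[f] = _rmsd(sup.apply(traj.frames[f][meas_idx]), reference[meas_idx])
    return pd.DataFrame({
        "frame_index": np.arange(traj.n_frames),
        "time_ps": traj.times,
        "rmsd_A": values,
    })


def _aligned_frames(traj: Trajectory, fit_idx: np.ndarray) -> np.ndarray:
    """All frames rigidly fitted to frame 0 on ``fit_idx``."""
    ref = traj.frames[0]
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.frames[f][fit_idx], ref[fit_idx])
        out[f] = sup.apply(traj.frames[f])
    return out


def rmsf_per_residue(traj: Trajectory, sel: SelectionSpec,
                     fit_sel: SelectionSpec) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the time-averaged structure.

    Frames are superposed on ``fit_sel`` first, so global rigid motion does
    not register as fluctuation. Per-atom fluctuations within a residue are
    combined as the root of the mean squared fluctuation.
    """
    if traj.n_frames < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    fit_idx = resolve_selection(fit_sel, traj.topology)
    sel_idx = resolve_selection(sel, traj.topology)
    aligned = _aligned_frames(traj, fit_idx)[:, sel_idx, :]
    mean = aligned.mean(axis=0)
    msf_atom = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # (M,)
    res = traj.topology.residue_seqs[sel_idx]
    names = np.array([traj.topology.atoms[i].residue_name for i in sel_idx])
    df = pd.DataFrame({"residue_seq": res, "residue_name": names, "msf": msf_atom})
    agg = (df.groupby(["residue_seq", "residue_name"], as_index=False)["msf"].mean())
    agg["rmsf_A"] = np.sqrt(agg.pop("msf"))
    return agg.sort_values("residue_seq", ignore_index=True)


def centroid_distance_series(traj: Trajectory, selA: SelectionSpec,
                             selB: SelectionSpec) -> pd.DataFrame:
    """Per-frame Euclidean distance (Å) between two selections' centroids."""
    ia = resolve_selection(selA, traj.topology)
    ib = resolve_selection(selB, traj.topology)
    ca = traj.frames[:, ia, :].mean(axis=1)
    cb = traj.frames[:, ib, :].mean(axis=1)
    d = np.linalg.norm(ca - cb, axis=1)
    return pd.DataFrame({
        "frame_index": np.arange(traj.n_frames),
        "time_ps": traj.times,
        "distance_A": d,
    })


def classify_conformation(distance: float | np.ndarray,
                          thresholds: ConformationThresholds = ConformationThresholds(),
                          ) -> str | np.ndarray:
    """Label a gate distance as ``"open"`` or ``"close"``.

    Distances at or beyond the boundary count as open (ties go to open).
    Accepts a scalar or an array; arrays return an object array of labels.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise GeometryError("gate distance must be positive")
    labels = np.where(d >= thresholds.boundary, "open", "close")
    if np.isscalar(distance) or d.ndim == 0:
        return str(labels)
    return labels
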