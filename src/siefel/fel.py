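"""Two-dimensional free-energy landscape by Boltzmann inversion.

The landscape over two reaction coordinates (gate-loop centroid distance on
x, loop RMSD on y) is the inverted normalised 2D histogram,

    dG(x, y) = -kB T ln( g(x, y) / g_max ),

so the most populated bin sits at zero and every occupied bin is
non-negative; empty bins are masked rather than set to infinity. Bin edges
are anchored at 0 A with a 0.10 A width on both axes, and the default
temperature is 310 K.

Basins are local minima of the landscape over the 8-neighbourhood, with
equal-value plateaus collapsed to one representative, nearby minima merged,
and shallow sampling-noise minima discarded by a depth cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    ConformationThresholds,
    classify_conformation,
    rmsd_series,
)
from .structure_io import (
    AnalysisError,
    SelectionSpec,
    Trajectory,
    resolve_selection,
)

__all__ = ["FELParams", "FELGrid", "FELResult", "build_fel", "find_basins",
           "fel_pipeline", "BOLTZMANN_KCAL"]

#: Boltzmann constant, kcal mol^-1 K^-1.
BOLTZMANN_KCAL = 0.0019872041


@dataclass(frozen=True)
class FELParams:
    bin_width_x: float = 0.10
    bin_width_y: float = 0.10
    temperature: float = 310.0
    kB: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if self.bin_width_x <= 0 or self.bin_width_y <= 0:
            raise ValueError("bin widths must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature


@dataclass
class FELGrid:
    """Binned joint distribution and free-energy surface.

    ``probability`` sums to 1 over all bins; ``free_energy`` is a masked
    array (masked where the count is zero) whose minimum over occupied bins
    is exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    probability: np.ndarray
    free_energy: np.ma.MaskedArray
    params: FELParams = field(default_factory=FELParams)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        """Occupied bins as rows (masked bins omitted, so output is finite)."""
        xi, yi = np.nonzero(self.counts > 0)
        return pd.DataFrame({
            "x_center": self.x_centers[xi],
            "y_center": self.y_centers[yi],
            "count": self.counts[xi, yi].astype(int),
            "probability": self.probability[xi, yi],
            "free_energy_kcal_mol": np.asarray(self.free_energy[xi, yi]),
        })


def _anchored_edges(values: np.ndarray, width: float) -> np.ndarray:
    # bin edges on a 0-anchored grid of the given width, covering the data
    lo = int(np.floor(values.min() / width))
    hi = int(np.floor(values.max() / width)) + 1
    return np.arange(lo, hi + 1, dtype=float) * width


def build_fel(x_series: np.ndarray, y_series: np.ndarray,
              params: FELParams = FELParams()) -> FELGrid:
    """Histogram two coordinate series and Boltzmann-invert to a landscape."""
    x = np.asarray(x_series, dtype=float).ravel()
    y = np.asarray(y_series, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise AnalysisError("cannot build a landscape from empty series")
    if x.size != y.size:
        raise AnalysisError(f"series lengths differ: {x.size} vs {y.size}")
    x_edges = _anchored_edges(x, params.bin_width_x)
    y_edges = _anchored_edges(y, params.bin_width_y)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    g = counts / counts.sum()
    gmax = g.max()
    occupied = counts > 0
    fe = np.zeros_like(g)
    # maximum() also normalises the peak bin's -0.0 to exactly 0.0
    fe[occupied] = np.maximum(0.0, -params.kT * np.log(g[occupied] / gmax))
    free_energy = np.ma.MaskedArray(fe, mask=~occupied)
    return FELGrid(x_edges=x_edges, y_edges=y_edges, counts=counts,
                   probability=g, free_energy=free_energy, params=params)


def find_basins(grid: FELGrid, min_separation_bins: int = 3,
                max_depth: float | None = 2.0) -> pd.DataFrame:
    """Local minima of the landscape, as (x_center, y_center, depth) rows.

    Minima are taken over the 8-neighbourhood (masked bins never
    participate); connected equal-value plateaus yield their
    lowest-(x, y)-index cell; candidates within ``min_separation_bins``
    (Chebyshev distance) of a deeper basin are merged into it; candidates
    more than ``max_depth`` kcal/mol above the global minimum are dropped
    (sampling-noise minima live in sparse histogram tails). Sorted by depth
    ascending.
    """
    if not np.any(grid.counts > 0):
        raise AnalysisError("landscape has no occupied bins")
    F = grid.free_energy.filled(np.inf)
    neigh_min = ndimage.minimum_filter(F, size=3, mode="constant", cval=np.inf)
    candidate = (F <= neigh_min) & np.isfinite(F)
    # collapse equal-value plateaus: label connected candidate regions and
    # keep the lexicographically smallest cell of each region
    labels, n_lab = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    reps: list[tuple[float, int, int]] = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        vals = F[cells[:, 0], cells[:, 1]]
        best = np.lexsort((cells[:, 1], cells[:, 0], vals))[0]
        i, j = cells[best]
        reps.append((float(F[i, j]), int(i), int(j)))
    reps.sort()
    kept: list[tuple[float, int, int]] = []
    fmin = min(r[0] for r in reps)
    for depth, i, j in reps:
        if max_depth is not None and depth - fmin > max_depth:
            continue
        if any(max(abs(i - ki), abs(j - kj)) <= min_separation_bins
               for _, ki, kj in kept):
            continue
        kept.append((depth, i, j))
    rows = [(grid.x_centers[i], grid.y_centers[j], depth)
            for depth, i, j in kept]
    return pd.DataFrame(rows, columns=["x_center", "y_center", "depth_kcal_mol"])


@dataclass
class FELResult:
    grid: FELGrid
    basins: pd.DataFrame
    labels: np.ndarray
    distance_series: np.ndarray
    rmsd_series: np.ndarray


def fel_pipeline(traj: Trajectory, loopA: SelectionSpec, loopB: SelectionSpec,
                 params: FELParams = FELParams(),
                 thresholds: ConformationThresholds = ConformationThresholds(),
                 fit_sel: SelectionSpec | None = None,
                 min_separation_bins: int = 10,
                 max_depth: float | None = 2.0) -> FELResult:
    """Landscape over (loop centroid distance, joint loop-CA RMSD).

    The x coordinate is the CA-centroid separation of the two gate loops;
    the y coordinate is the RMSD of both loops' CA atoms against the first
    frame after superposition on ``fit_sel`` (receptor CA by default).
    Frames are additionally labelled open/close from the distance.
    """
    top = traj.topology
    ca_a = SelectionSpec(loopA.expression, loopA.chain, ("CA",))
    ca_b = SelectionSpec(loopB.expression, loopB.chain, ("CA",))
    ia = resolve_selection(ca_a, top)
    ib = resolve_selection(ca_b, top)
    dist = np.linalg.norm(traj.frames[:, ia, :].mean(axis=1)
                          - traj.frames[:, ib, :].mean(axis=1), axis=1)
    if fit_sel is None:
        rec = top.group_indices("receptor")
        res = np.unique(top.residue_seqs[rec])
        fit_sel = SelectionSpec(f"{res.min()}-{res.max()}", None, ("CA",))
    both = SelectionSpec(f"{ca_a.expression},{ca_b.expression}", loopA.chain, ("CA",))
    rms = rmsd_series(traj, traj.frames[0], fit_sel, both)["rmsd_A"].to_numpy()
    grid = build_fel(dist, rms, params)
    basins = find_basins(grid, min_separation_bins=min_separation_bins,
                         max_depth=max_depth)
    labels = classify_conformation(dist, thresholds)
    return FELResult(grid=grid, basins=basins, labels=np.asarray(labels),
                     distance_series=dist, rmsd_series=rms)
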