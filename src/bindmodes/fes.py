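"""Metadynamics post-processing: FES grids, replica averaging, minima,
hill-height convergence.

A well-tempered metadynamics run deposits Gaussian bias hills along one or
two collective variables (CVs); at long times the accumulated bias V(s)
converges to -dT/(T+dT) * F(s), so the free energy is recovered as

    F(s) = -(T+dT)/dT * V(s) = -gamma/(gamma-1) * V(s)

with bias factor gamma = (T+dT)/T.  Without a bias factor (ordinary
metadynamics) F(s) = -V(s).  Surfaces are normalized so the global minimum
sits at zero; replicas on identical grids are combined by a cell-wise
arithmetic mean.  Energies are kcal/mol, CVs Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class FESError(ValueError):
    """Raised for inconsistent grids or hill logs."""


@dataclass
class CVAxis:
    """One collective-variable axis of a FES grid."""

    name: str
    minimum: float
    maximum: float
    bins: int

    def __post_init__(self) -> None:
        if self.maximum <= self.minimum or self.bins < 2:
            raise FESError(f"bad axis {self.name}: range/bins invalid")

    @property
    def centers(self) -> np.ndarray:
        edges = np.linspace(self.minimum, self.maximum, self.bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def spacing(self) -> float:
        return (self.maximum - self.minimum) / self.bins


@dataclass
class FESGrid:
    """Free energy (kcal/mol) on a 1-D or 2-D CV grid, min-normalized."""

    axes: list  # list[CVAxis], length 1 or 2
    values: np.ndarray
    replica: str = "replica-0"

    def __post_init__(self) -> None:
        if len(self.axes) not in (1, 2):
            raise FESError("FES grids are 1-D or 2-D")
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(ax.bins for ax in self.axes)
        if self.values.shape != expected:
            raise FESError(
                f"value shape {self.values.shape} != grid shape {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FESError("non-finite free-energy values on the grid")

    def normalized(self) -> "FESGrid":
        return FESGrid(axes=self.axes, values=self.values - self.values.min(),
                       replica=self.replica)

    def same_grid(self, other: "FESGrid") -> bool:
        return len(self.axes) == len(other.axes) and all(
            a.name == b.name and a.bins == b.bins
            and np.isclose(a.minimum, b.minimum) and np.isclose(a.maximum, b.maximum)
            for a, b in zip(self.axes, other.axes)
        )

    def to_frame(self) -> pd.DataFrame:
        if len(self.axes) == 1:
            return pd.DataFrame({self.axes[0].name: self.axes[0].centers,
                                 "free_energy_kcal_mol": self.values})
        xa, ya = self.axes
        xx, yy = np.meshgrid(xa.centers, ya.centers, indexing="ij")
        return pd.DataFrame({xa.name: xx.ravel(), ya.name: yy.ravel(),
                             "free_energy_kcal_mol": self.values.ravel()})


@dataclass
class HillLog:
    """Deposited Gaussian bias increments of one metadynamics run."""

    times_ps: np.ndarray
    centers: np.ndarray  # (n_hills,) or (n_hills, 2)
    heights: np.ndarray  # kcal/mol, > 0
    widths: np.ndarray  # Angstrom, per-hill (scalar broadcast allowed)

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim == 1:
            self.centers = self.centers[:, None]
        self.heights = np.asarray(self.heights, dtype=float)
        self.widths = np.broadcast_to(
            np.asarray(self.widths, dtype=float), self.heights.shape
        ).copy()
        n = len(self.times_ps)
        if len(self.centers) != n or len(self.heights) != n:
            raise FESError("hill log arrays must have equal length")
        if n and np.any(np.diff(self.times_ps) <= 0):
            raise FESError("hill deposition times must be strictly increasing")
        if np.any(self.heights <= 0) or np.any(self.widths <= 0):
            raise FESError("hill heights and widths must be positive")

    @property
    def n_hills(self) -> int:
        return len(self.times_ps)

    @property
    def dimensionality(self) -> int:
        return self.centers.shape[1]


@dataclass
class Minimum:
    """A local FES minimum, labeled A, B, C, ... in depth order."""

    label: str
    coordinates: tuple
    depth: float  # free energy relative to the global minimum (>= 0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fes_from_hills(
    hills: HillLog,
    axes: list,
    bias_factor: float | None = None,
) -> FESGrid:
    """Reconstruct the FES as the (scaled) negative of the deposited bias.

    ``bias_factor`` is the well-tempered gamma = (T+dT)/T; when supplied the
    bias is rescaled by gamma/(gamma-1) = (T+dT)/dT.  Hills outside the grid
    bounds are an error (the run escaped the region of interest).
    """
    if hills.dimensionality != len(axes):
        raise FESError(
            f"{hills.dimensionality}-D hills on a {len(axes)}-D grid"
        )
    for d, ax in enumerate(axes):
        lo, hi = hills.centers[:, d].min(), hills.centers[:, d].max()
        if lo < ax.minimum or hi > ax.maximum:
            raise FESError(
                f"hill centers on axis {ax.name!r} span [{lo:.3f}, {hi:.3f}] "
                f"outside grid [{ax.minimum}, {ax.maximum}]"
            )
    if len(axes) == 1:
        s = axes[0].centers[:, None]  # (bins, 1)
        diff = s - hills.centers[:, 0][None, :]  # (bins, n_hills)
        bias = np.sum(
            hills.heights[None, :]
            * np.exp(-(diff ** 2) / (2.0 * hills.widths[None, :] ** 2)),
            axis=1,
        )
    else:
        xa, ya = axes
        xx, yy = np.meshgrid(xa.centers, ya.centers, indexing="ij")
        bias = np.zeros_like(xx)
        for c, h, w in zip(hills.centers, hills.heights, hills.widths):
            bias += h * np.exp(
                -((xx - c[0]) ** 2 + (yy - c[1]) ** 2) / (2.0 * w ** 2)
            )
    scale = 1.0
    if bias_factor is not None:
        if bias_factor <= 1.0:
            raise FESError("well-tempered bias factor must exceed 1")
        scale = bias_factor / (bias_factor - 1.0)
    free = -scale * bias
    return FESGrid(axes=list(axes), values=free - free.min(), replica="from-hills")


def average_fes(replicas: list) -> FESGrid:
    """Cell-wise mean over replicas on identical grids, re-normalized."""
    if not replicas:
        raise FESError("no replicas to average")
    first = replicas[0]
    for rep in replicas[1:]:
        if not first.same_grid(rep):
            raise FESError(
                f"replica {rep.replica!r} grid differs from {first.replica!r}"
            )
    mean = np.mean([r.values for r in replicas], axis=0)
    return FESGrid(axes=first.axes, values=mean - mean.min(),
                   replica=f"mean-of-{len(replicas)}")


def _prominences(values: np.ndarray) -> dict:
    """Topographic prominence of every basin minimum (watershed flooding).

    Cells are flooded in order of increasing free energy; a cell with no
    flooded neighbour starts a basin, and when two basins meet, the
    shallower one's prominence is the merge level minus its minimum.
    Ties (plateau minima) resolve canonically by scan order, so a two-cell
    plateau contributes one basin.  The global-minimum basin never merges
    and gets infinite prominence.
    """
    shape = values.shape
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    parent = np.full(flat.size, -1, dtype=int)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    if values.ndim == 1:
        neighbour_offsets = [(-1,), (1,)]
    else:
        neighbour_offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                             if (di, dj) != (0, 0)]
    basin_min: dict[int, float] = {}
    prominence: dict[int, float] = {}
    for idx in order:
        level = flat[idx]
        coord = np.unravel_index(idx, shape)
        parent[idx] = idx
        basin_min[idx] = level
        for off in neighbour_offsets:
            ncoord = tuple(c + o for c, o in zip(coord, off))
            if any(c < 0 or c >= s for c, s in zip(ncoord, shape)):
                continue
            nidx = int(np.ravel_multi_index(ncoord, shape))
            if parent[nidx] == -1:
                continue  # neighbour not yet flooded
            ra, rb = find(idx), find(nidx)
            if ra == rb:
                continue
            # merge: shallower basin dies at this level
            if basin_min[ra] <= basin_min[rb]:
                keep, die = ra, rb
            else:
                keep, die = rb, ra
            prominence[die] = level - basin_min[die]
            parent[die] = keep
            basin_min[keep] = min(basin_min[keep], basin_min[die])
    survivor = find(int(order[0]))
    prominence[survivor] = np.inf
    return prominence


def find_minima(grid: FESGrid, depth_cut: float = 0.5) -> list:
    """Locate significant local minima, deepest (global) first.

    A basin minimum qualifies when its prominence — the barrier it takes
    to reach any deeper cell — is at least ``depth_cut`` kcal/mol.  Labels
    run A, B, C, ... in order of increasing free energy.
    """
    values = grid.values - grid.values.min()
    if values.max() <= 1e-12:
        return []  # flat surface: nothing to report
    prom = _prominences(values)
    shape = values.shape
    entries = []
    for idx, p in prom.items():
        if p >= depth_cut:
            coord = np.unravel_index(int(idx), shape)
            cvs = tuple(ax.centers[c] for ax, c in zip(grid.axes, coord))
            entries.append((float(values[coord]), cvs))
    entries.sort()
    labels = [chr(ord("A") + i) for i in range(len(entries))]
    return [Minimum(label=lab, coordinates=cv, depth=depth)
            for lab, (depth, cv) in zip(labels, entries)]


def hill_convergence(
    hills: HillLog,
    window: int = 50,
    converged_fraction: float = 0.5,
) -> dict:
    """Windowed hill-height decay diagnostic.

    Returns the windowed mean heights, a Kendall-type sign trend in
    [-1, 1] over all window pairs (strictly decreasing -> -1, constant ->
    0), and a ``converging`` flag set when the last window's mean height
    has dropped below ``converged_fraction`` of the first window's.
    """
    n_windows = hills.n_hills // window
    if n_windows < 2:
        raise FESError(
            f"need at least 2 windows of {window} hills, have {hills.n_hills} hills"
        )
    means = np.array([
        hills.heights[i * window:(i + 1) * window].mean()
        for i in range(n_windows)
    ])
    times = np.array([
        hills.times_ps[i * window:(i + 1) * window].mean()
        for i in range(n_windows)
    ])
    signs = []
    for i in range(n_windows):
        for j in range(i + 1, n_windows):
            signs.append(np.sign(means[j] - means[i]))
    trend = float(np.mean(signs))
    converging = bool(means[-1] < converged_fraction * means[0])
    return {
        "window_times_ps": times,
        "window_mean_heights": means,
        "trend": trend,
        "converging": converging,
    }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_fes_csv(path, replica: str | None = None) -> FESGrid:
    """Read a FES grid CSV: CV column(s) then a free-energy column.

    The engine's own grid export is accepted directly; the grid geometry is
    inferred from the sorted unique CV values (uniform spacing required).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FESError("FES CSV needs CV column(s) plus a free-energy column")
    cv_cols = list(df.columns[:-1])
    axes = []
    for col in cv_cols:
        centers = np.sort(df[col].unique())
        spacing = np.diff(centers)
        if len(centers) < 2 or not np.allclose(spacing, spacing[0]):
            raise FESError(f"axis {col!r} is not a uniform grid")
        half = spacing[0] / 2.0
        axes.append(CVAxis(name=col, minimum=float(centers[0] - half),
                           maximum=float(centers[-1] + half), bins=len(centers)))
    if len(axes) == 1:
        values = df.sort_values(cv_cols[0]).iloc[:, -1].to_numpy(dtype=float)
    else:
        pivot = df.pivot_table(index=cv_cols[0], columns=cv_cols[1],
                               values=df.columns[-1])
        values = pivot.to_numpy(dtype=float)
    grid = FESGrid(axes=axes, values=values - values.min(),
                   replica=replica or str(path))
    return grid


def read_hills_csv(path) -> HillLog:
    """Read a hill log CSV: time_ps, center columns, height, width."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "height" not in cols or "width" not in cols:
        raise FESError("hill CSV needs 'height' and 'width' columns")
    df.columns = cols
    center_cols = [c for c in cols if c not in ("time_ps", "height", "width")]
    return HillLog(
        times_ps=df["time_ps"].to_numpy(dtype=float),
        centers=df[center_cols].to_numpy(dtype=float),
        heights=df["height"].to_numpy(dtype=float),
        widths=df["width"].to_numpy(dtype=float),
    )
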