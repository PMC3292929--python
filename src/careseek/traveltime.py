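"""Least-cost travel-time accumulation and facility allocation.

The friction surface defines an 8-connected graph over non-barrier cells.
The time to traverse an edge between adjacent cells is

    minutes = 60 * d / v_edge

with d the centre-to-centre distance in km (cell_size, or cell_size*sqrt(2)
diagonally) and v_edge the harmonic mean of the two cells' effective speeds
(each cell contributes half the edge, so the harmonic mean is the
time-correct average).  A cell's effective speed for an edge is its base
speed multiplied by the Tobler slope factor when its mode is WALKING or
CYCLING; MOTORIZED cells ignore slope.  The edge slope is
arctan(|delta elevation| / d), symmetric in direction.

Multi-source Dijkstra from all facility cells yields, per cell, the minutes
to — and the identity of — the least-cost nearest facility.  Unreached
cells carry +inf (never a nodata zero, which would silently join a
catchment).  Ties are broken toward the lowest facility id, making the
allocation raster deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .friction import FrictionSurface, Mode, walking_speed_multiplier
from .grids import GridSpec, Raster, check_same_grid

__all__ = [
    "TravelTimeSurface",
    "AllocationSurface",
    "Facility",
    "accumulate_cost",
    "sample_travel_time",
    "euclidean_nearest",
    "pearson_r",
]

UNALLOCATED = -1

# 8-connectivity offsets and their length factors (1 orthogonal, sqrt(2) diagonal)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_LENGTH = [np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)]


@dataclass(frozen=True)
class Facility:
    """A health facility point in the planar frame (metres)."""

    facility_id: int
    x: float
    y: float


@dataclass
class TravelTimeSurface:
    """Minutes to the least-cost nearest facility; +inf where unreached."""

    minutes: Raster

    @property
    def grid(self) -> GridSpec:
        return self.minutes.grid


@dataclass
class AllocationSurface:
    """Facility id of the least-cost nearest facility; -1 where unreached."""

    facility_id: Raster

    @property
    def grid(self) -> GridSpec:
        return self.facility_id.grid


def _facility_cells(facilities, grid: GridSpec) -> list[tuple[int, int, int]]:
    cells = []
    for f in facilities:
        if hasattr(f, "facility_id"):
            fid, x, y = int(f.facility_id), f.x, f.y
        else:
            fid, x, y = int(f[0]), f[1], f[2]
        row, col = grid.point_to_cell(x, y)
        cells.append((fid, int(row), int(col)))
    return cells


def _effective_speeds(
    friction: FrictionSurface, dem: Raster | None, d_km: float, dr: int, dc: int
) -> tuple[np.ndarray, np.ndarray]:
    """Effective speed (km/h) of each endpoint cell for edges in one direction.

    Returns (speed_from, speed_to) arrays over the overlap region where a
    step (dr, dc) stays on the grid.
    """
    sp = friction.base_speed.values
    mode = friction.mode.values
    n_rows, n_cols = sp.shape
    r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
    c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    v_src = sp[src].astype(float).copy()
    v_dst = sp[dst].astype(float).copy()
    if dem is not None:
        dz = np.abs(dem.values[dst] - dem.values[src])
        slope_deg = np.degrees(np.arctan(dz / (d_km * 1000.0)))
        mult = np.asarray(walking_speed_multiplier(slope_deg))
        slope_applies_src = np.isin(mode[src], (int(Mode.WALKING), int(Mode.CYCLING)))
        slope_applies_dst = np.isin(mode[dst], (int(Mode.WALKING), int(Mode.CYCLING)))
        v_src = np.where(slope_applies_src, v_src * mult, v_src)
        v_dst = np.where(slope_applies_dst, v_dst * mult, v_dst)
    return v_src, v_dst


def _build_edges(friction: FrictionSurface, dem: Raster | None):
    """Adjacency as flat arrays: for each node, neighbour ids and edge minutes."""
    g = friction.grid
    n_rows, n_cols = g.shape
    barrier = friction.barrier.values.astype(bool)
    cell_km = g.cell_size / 1000.0

    # neighbour index and weight per (direction, cell); inf where invalid
    nbr = np.full((8, n_rows, n_cols), -1, dtype=np.int64)
    wt = np.full((8, n_rows, n_cols), np.inf, dtype=float)
    node_id = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    for k, ((dr, dc), lf) in enumerate(zip(_OFFSETS, _LENGTH)):
        d_km = cell_km * lf
        v_src, v_dst = _effective_speeds(friction, dem, d_km, dr, dc)
        r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
        c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        with np.errstate(divide="ignore", invalid="ignore"):
            v_edge = 2.0 * v_src * v_dst / (v_src + v_dst)  # harmonic mean
            minutes = 60.0 * d_km / v_edge
        ok = (~barrier[src]) & (~barrier[dst]) & np.isfinite(minutes) & (minutes > 0)
        w = np.where(ok, minutes, np.inf)
        nbr[k][src] = node_id[dst]
        wt[k][src] = w
    return nbr.reshape(8, -1), wt.reshape(8, -1)


def accumulate_cost(
    friction: FrictionSurface,
    dem: Raster | None,
    facilities,
) -> tuple[TravelTimeSurface, AllocationSurface]:
    """Multi-source least-cost accumulation over the friction surface.

    Parameters
    ----------
    friction : FrictionSurface
    dem : Raster or None
        Elevation in metres on the same grid; None means flat terrain.
    facilities : iterable of Facility or (id, x, y)
        At least one must fall on a non-barrier cell.

    Returns
    -------
    (TravelTimeSurface, AllocationSurface)
        Globally optimal minutes per cell and the facility achieving them.

    Raises
    ------
    ValueError
        If a facility lies outside the grid or every facility sits on a
        barrier cell.
    """
    g = friction.grid
    if dem is not None:
        check_same_grid(friction.base_speed, dem, names=["friction", "dem"])
    barrier = friction.barrier.values.astype(bool)
    cells = _facility_cells(facilities, g)
    sources = [(fid, r, c) for fid, r, c in cells if not barrier[r, c]]
    if not sources:
        raise ValueError("every facility falls on a barrier cell; nothing is reachable")

    nbr, wt = _build_edges(friction, dem)
    n = g.n_rows * g.n_cols
    dist = np.full(n, np.inf)
    alloc = np.full(n, UNALLOCATED, dtype=np.int64)
    # heap entries (minutes, facility_id, node): lexicographic order breaks
    # exact ties toward the lowest facility id
    heap: list[tuple[float, int, int]] = []
    for fid, r, c in sorted(sources, key=lambda t: t[0]):
        node = r * g.n_cols + c
        if alloc[node] == UNALLOCATED:  # first (lowest) id wins co-located ties
            dist[node] = 0.0
            alloc[node] = fid
            heapq.heappush(heap, (0.0, fid, node))

    nbr_T = nbr.T.copy()  # (n, 8) for cache-friendly row access
    wt_T = wt.T.copy()
    pop = heapq.heappop
    push = heapq.heappush
    while heap:
        t, fid, node = pop(heap)
        if t > dist[node] or (t == dist[node] and fid != alloc[node]):
            continue
        row_n = nbr_T[node]
        row_w = wt_T[node]
        for k in range(8):
            m = row_n[k]
            if m < 0:
                continue
            w = row_w[k]
            if w == np.inf:
                continue
            nt = t + w
            if nt < dist[m] or (nt == dist[m] and fid < alloc[m]):
                dist[m] = nt
                alloc[m] = fid
                push(heap, (nt, fid, m))

    minutes = dist.reshape(g.shape)
    fids = alloc.reshape(g.shape)
    return (
        TravelTimeSurface(Raster(minutes, g)),
        AllocationSurface(Raster(fids, g)),
    )


def sample_travel_time(surface: TravelTimeSurface, points) -> np.ndarray:
    """Travel time (minutes) of the cell containing each (x, y) point.

    Points in unreached cells return +inf; points outside the grid raise.
    """
    pts = np.asarray(points, dtype=float)
    return np.atleast_1d(surface.minutes.sample(pts[..., 0], pts[..., 1]))


def euclidean_nearest(points, facilities) -> np.ndarray:
    """Straight-line distance (km) from each point to its nearest facility."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fac = np.array(
        [
            (f.x, f.y) if hasattr(f, "x") else (f[1], f[2])
            for f in facilities
        ],
        dtype=float,
    )
    if fac.size == 0:
        raise ValueError("no facilities given")
    d = np.hypot(
        pts[:, None, 0] - fac[None, :, 0], pts[:, None, 1] - fac[None, :, 1]
    )
    return d.min(axis=1) / 1000.0


def pearson_r(x, y) -> float:
    """Pearson's correlation coefficient between two samples."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson_r needs two equal-length samples of size >= 2")
    return float(stats.pearsonr(x, y).statistic)
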