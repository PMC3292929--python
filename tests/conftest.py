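"""Shared fixtures: small grids, friction surfaces and an independent
shortest-path oracle for travel-time verification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from careseek.friction import FrictionSurface, Mode, walking_speed_multiplier
from careseek.grids import GridSpec, Raster


@pytest.fixture
def grid5() -> GridSpec:
    return GridSpec(n_rows=5, n_cols=5, cell_size=1000.0)


@pytest.fixture
def grid20() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=20, cell_size=1000.0)


def make_uniform_friction(grid: GridSpec, speed_kmh: float = 5.0,
                          mode: Mode = Mode.WALKING) -> FrictionSurface:
    """A constant-speed walking surface with no barriers."""
    return FrictionSurface(
        base_speed=Raster(np.full(grid.shape, speed_kmh), grid),
        mode=Raster(np.full(grid.shape, int(mode)), grid),
        barrier=Raster(np.zeros(grid.shape, dtype=bool), grid),
    )


def make_random_friction(grid: GridSpec, seed: int,
                         barrier_fraction: float = 0.1) -> FrictionSurface:
    """Random walking speeds in [1, 10] km/h with scattered barriers."""
    rng = np.random.default_rng(seed)
    speed = rng.uniform(1.0, 10.0, grid.shape)
    barrier = rng.uniform(size=grid.shape) < barrier_fraction
    speed[barrier] = 0.0
    mode = np.where(barrier, int(Mode.NONE), int(Mode.WALKING))
    return FrictionSurface(
        base_speed=Raster(speed, grid),
        mode=Raster(mode, grid),
        barrier=Raster(barrier, grid),
    )


@pytest.fixture
def uniform_friction(grid5):
    return make_uniform_friction(grid5)


def oracle_edge_minutes(friction: FrictionSurface, dem: Raster | None):
    """Edge list (u, v, minutes) built cell by cell, independently of the
    vectorised adjacency construction in careseek.traveltime."""
    g = friction.grid
    sp = friction.base_speed.values
    mode = friction.mode.values
    bar = friction.barrier.values.astype(bool)
    cell_km = g.cell_size / 1000.0
    edges = []
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            if bar[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < g.n_rows and 0 <= c2 < g.n_cols):
                        continue
                    if bar[r2, c2]:
                        continue
                    d_km = cell_km * (math.sqrt(2.0) if dr and dc else 1.0)
                    v1, v2 = float(sp[r, c]), float(sp[r2, c2])
                    if dem is not None:
                        dz = abs(float(dem.values[r2, c2]) - float(dem.values[r, c]))
                        slope = math.degrees(math.atan(dz / (d_km * 1000.0)))
                        mult = float(walking_speed_multiplier(slope))
                        if mode[r, c] in (int(Mode.WALKING), int(Mode.CYCLING)):
                            v1 *= mult
                        if mode[r2, c2] in (int(Mode.WALKING), int(Mode.CYCLING)):
                            v2 *= mult
                    v_edge = 2.0 * v1 * v2 / (v1 + v2)
                    edges.append((r * g.n_cols + c, r2 * g.n_cols + c2,
                                  60.0 * d_km / v_edge))
    return edges


def bellman_ford_minutes(friction: FrictionSurface, dem: Raster | None,
                         source_nodes) -> np.ndarray:
    """Brute-force multi-source Bellman-Ford distances (minutes) per cell.

    Iterative relaxation to a fixed point; O(V*E) worst case, fine for the
    small instances used as oracles.
    """
    g = friction.grid
    n = g.n_rows * g.n_cols
    edges = oracle_edge_minutes(friction, dem)
    dist = np.full(n, np.inf)
    for s in source_nodes:
        dist[s] = 0.0
    for _ in range(n):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    return dist.reshape(g.shape)
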