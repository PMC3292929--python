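"""Friction ("cost") surfaces: per-cell permissible travel speed and mode.

Land cover, roads and rivers are combined into a single raster of travel
speeds (km/h) with a transport mode per cell, the input to least-cost
travel-time accumulation.  Slope is *not* baked into the surface: the
slope-dependent walking-speed correction (Tobler's hiking function) is
applied per edge at traversal time, to WALKING and CYCLING cells only, so
that the tabulated land-cover and road speeds remain exact on flat terrain.

Default speeds follow a standard multi-modal assignment for rural
sub-Saharan accessibility modelling: walking at 2-5 km/h by land-cover
class, cycling at 10 km/h on tertiary roads, motorised transport at
60-80 km/h on secondary/primary roads, and water and major rivers as
absolute barriers (roads crossing rivers are assumed bridged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as _geojson_shape

from .grids import GridSpec, Raster, check_same_grid

__all__ = [
    "Mode",
    "SpeedTable",
    "FrictionSurface",
    "tobler_speed",
    "walking_speed_multiplier",
    "build_friction_surface",
    "rasterize_lines",
]

# Tobler's hiking function: V = 6 exp(-3.5 |tan(slope) + 0.05|) km/h.
# Maximum 6 km/h at a gentle downhill (tan = -0.05); about 5.0 km/h on flat
# ground.  Symmetric in |.|, so traversal is direction-independent.
_TOBLER_MAX = 6.0
_TOBLER_RATE = 3.5
_TOBLER_OFFSET = 0.05


class Mode(IntEnum):
    """Transport mode of a friction cell."""

    NONE = 0  # barrier (water, rivers)
    WALKING = 1
    CYCLING = 2
    MOTORIZED = 3


def tobler_speed(slope_degrees) -> np.ndarray | float:
    """Walking speed (km/h) on a given slope, by Tobler's hiking function.

    Parameters
    ----------
    slope_degrees : array_like
        Signed slope in degrees; must satisfy ``|slope| < 90``.

    Returns
    -------
    Speed in km/h, in (0, 6].  About 5.0 km/h on flat terrain, 3.71 at 5
    degrees, 1.41 at 20 degrees.
    """
    s = np.asarray(slope_degrees, dtype=float)
    if np.any(np.abs(s) >= 90.0):
        raise ValueError("slope must satisfy |slope| < 90 degrees (tangent undefined)")
    v = _TOBLER_MAX * np.exp(
        -_TOBLER_RATE * np.abs(np.tan(np.radians(s)) + _TOBLER_OFFSET)
    )
    return v if v.ndim else float(v)


def walking_speed_multiplier(slope_degrees) -> np.ndarray | float:
    """Slope correction factor relative to flat ground.

    ``tobler_speed(slope) / tobler_speed(0)``: 1.0 on flat terrain, < 1 on
    any rise, slightly > 1 on a gentle downhill (the Tobler optimum).
    Applied multiplicatively to WALKING and CYCLING cells; MOTORIZED cells
    are unaffected by slope.
    """
    return tobler_speed(slope_degrees) / tobler_speed(0.0)


@dataclass(frozen=True)
class SpeedTable:
    """Travel speed and mode per land-cover class and road class.

    ``landcover`` maps integer class codes to ``(speed_kmh, Mode)``;
    ``roads`` maps road class names ('primary', 'secondary', 'tertiary')
    likewise.  Speed 0 is synonymous with a barrier (mode NONE).
    """

    landcover: dict[int, tuple[float, Mode]]
    roads: dict[str, tuple[float, Mode]]
    class_names: dict[int, str]

    def __post_init__(self) -> None:
        for code, (speed, mode) in self.landcover.items():
            if speed < 0:
                raise ValueError(f"negative speed for land-cover class {code}")
            if (speed == 0) != (mode == Mode.NONE):
                raise ValueError(
                    f"class {code}: speed 0 must pair with mode NONE and vice versa"
                )
        for name, (speed, mode) in self.roads.items():
            if speed <= 0:
                raise ValueError(f"road class {name!r} must have positive speed")

    @classmethod
    def default(cls) -> "SpeedTable":
        """The packaged default speed table."""
        with resources.files("careseek.data").joinpath("default_speeds.json").open() as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedTable":
        lc = {}
        names = {}
        for name, entry in d["landcover"].items():
            code = int(entry["code"])
            lc[code] = (float(entry["speed_kmh"]), Mode[entry["mode"]])
            names[code] = name
        roads = {
            name: (float(entry["speed_kmh"]), Mode[entry["mode"]])
            for name, entry in d["roads"].items()
        }
        return cls(landcover=lc, roads=roads, class_names=names)

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeedTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "landcover": {
                self.class_names.get(code, str(code)): {
                    "code": code,
                    "speed_kmh": speed,
                    "mode": mode.name,
                }
                for code, (speed, mode) in self.landcover.items()
            },
            "roads": {
                name: {"speed_kmh": speed, "mode": mode.name}
                for name, (speed, mode) in self.roads.items()
            },
            "rivers": {"speed_kmh": 0, "mode": "NONE"},
        }

    def code_for(self, name: str) -> int:
        """Integer raster code of a named land-cover class."""
        for code, n in self.class_names.items():
            if n == name:
                return code
        raise KeyError(name)


@dataclass
class FrictionSurface:
    """Per-cell permissible speed, transport mode and barrier mask."""

    base_speed: Raster  # km/h; 0 on barrier cells
    mode: Raster  # Mode codes, int
    barrier: Raster  # bool

    @property
    def grid(self) -> GridSpec:
        return self.base_speed.grid

    def __post_init__(self) -> None:
        check_same_grid(
            self.base_speed, self.mode, self.barrier,
            names=["base_speed", "mode", "barrier"],
        )
        sp = self.base_speed.values
        bar = self.barrier.values.astype(bool)
        if np.any(sp[~bar] <= 0):
            raise ValueError("non-barrier cells must have positive speed")
        if np.any(sp[bar] != 0):
            raise ValueError("barrier cells must have speed 0")


def rasterize_lines(lines, grid: GridSpec) -> np.ndarray:
    """All-touched line rasterization: a cell is marked if any line intersects it.

    Returns a boolean (n_rows, n_cols) mask.  Deterministic: uses exact
    shapely box/line intersection over the lines' bounding-box cells.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    cs = grid.cell_size
    x0, y0, x1, y1 = grid.extent
    for line in lines:
        geom = _geojson_shape(line) if isinstance(line, dict) else line
        bx0, by0, bx1, by1 = geom.bounds
        c0 = max(0, int(np.floor((bx0 - x0) / cs)))
        c1 = min(grid.n_cols - 1, int(np.floor((bx1 - x0) / cs)))
        rb0 = max(0, int(np.floor((by0 - y0) / cs)))
        rb1 = min(grid.n_rows - 1, int(np.floor((by1 - y0) / cs)))
        if c1 < c0 or rb1 < rb0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows_b = np.arange(rb0, rb1 + 1)
        cc, rr = np.meshgrid(cols, rows_b)
        boxes = shapely.box(
            x0 + cc.ravel() * cs,
            y0 + rr.ravel() * cs,
            x0 + (cc.ravel() + 1) * cs,
            y0 + (rr.ravel() + 1) * cs,
        )
        hit = shapely.intersects(boxes, geom).reshape(cc.shape)
        rows = grid.n_rows - 1 - rr[hit]
        mask[rows, cc[hit]] = True
    return mask


def build_friction_surface(
    landcover: Raster,
    roads=None,
    rivers=None,
    dem: Raster | None = None,
    table: SpeedTable | None = None,
    grid: GridSpec | None = None,
) -> FrictionSurface:
    """Combine land cover, roads and rivers into a friction surface.

    Speed precedence within a cell: primary > secondary > tertiary road >
    land-cover class.  River cells are absolute barriers unless a road
    passes through the same cell (bridge assumption).  The DEM, if given,
    only validates grid agreement here — slope is applied per edge during
    accumulation, not per pixel.

    Parameters
    ----------
    roads : iterable of (geometry, class) pairs or objects with
        ``.geometry``/``.road_class``, optional
    rivers : iterable of line geometries, optional
    table : SpeedTable, defaults to the packaged table

    Raises
    ------
    KeyError
        If the land-cover raster contains a class code missing from the table.
    """
    if table is None:
        table = SpeedTable.default()
    layers = [landcover] + ([dem] if dem is not None else [])
    names = ["landcover"] + (["dem"] if dem is not None else [])
    g = check_same_grid(*layers, names=names)
    if grid is not None and grid != g:
        raise ValueError("explicit grid does not match the land-cover grid")

    codes = np.unique(landcover.values.astype(int))
    missing = [int(c) for c in codes if int(c) not in table.landcover]
    if missing:
        raise KeyError(
            f"land-cover class codes {missing} are absent from the speed table"
        )

    speed = np.zeros(g.shape, dtype=float)
    mode = np.full(g.shape, int(Mode.NONE), dtype=int)
    lc = landcover.values.astype(int)
    for code, (s, m) in table.landcover.items():
        sel = lc == code
        speed[sel] = s
        mode[sel] = int(m)

    river_mask = np.zeros(g.shape, dtype=bool)
    if rivers is not None:
        river_geoms = [getattr(r, "geometry", r) for r in rivers]
        river_mask = rasterize_lines(river_geoms, g)
        speed[river_mask] = 0.0
        mode[river_mask] = int(Mode.NONE)

    # roads override land cover and rivers; lowest class first so that
    # higher classes win where roads overlap
    if roads is not None:
        pairs = []
        for r in roads:
            if hasattr(r, "geometry"):
                pairs.append((r.geometry, r.road_class))
            else:
                pairs.append((r[0], r[1]))
        for cls in ("tertiary", "secondary", "primary"):
            geoms = [geom for geom, c in pairs if c == cls]
            if not geoms:
                continue
            if cls not in table.roads:
                raise KeyError(f"road class {cls!r} is absent from the speed table")
            s, m = table.roads[cls]
            road_mask = rasterize_lines(geoms, g)
            speed[road_mask] = s
            mode[road_mask] = int(m)

    barrier = speed == 0.0
    return FrictionSurface(
        base_speed=Raster(speed, g),
        mode=Raster(mode, g),
        barrier=Raster(barrier, g),
    )
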