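"""Synthetic landscapes, populations and household fever surveys.

Generates internally consistent test data with the statistical structure
the accessibility analysis assumes: a smooth elevation field, a
spatially coherent land-cover map on the standard legend, random road and
river polylines, a clustered gridded population, a regional partition,
population-weighted facility locations, and a two-stage cluster household
survey in which each under-five child's fever status is Bernoulli with the
regional prevalence and, given fever, public-facility attendance is
Bernoulli with probability given by a known ("true") distance-decay model
evaluated at the cluster's travel time.  Because the true model and the
true travel times are carried in the output, parameter-recovery tests need
no re-extraction.

Default scenario dimensions mirror a national malaria indicator survey:
120 clusters of about 25 households, regional fever prevalence between 7%
and 28%, 1 km grid cells, and a true decay model with C = 0.766,
A = 3.736, B = -0.609 on log10 minutes.

All generators are deterministic functions of (inputs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .decay import DecayResults, predict_probability
from .grids import GridSpec, Raster
from .traveltime import Facility, TravelTimeSurface

__all__ = [
    "SyntheticScenario",
    "Road",
    "generate_dem",
    "generate_landcover",
    "generate_roads",
    "generate_rivers",
    "generate_population",
    "generate_regions",
    "generate_facilities",
    "simulate_survey",
]

logger = logging.getLogger(__name__)

# Regional fever prevalence defaults span the range observed in northern
# Namibia's 2009 survey (7%-28% across nine regions).
DEFAULT_PREVALENCE = (0.276, 0.239, 0.174, 0.118, 0.171, 0.127, 0.148, 0.070, 0.175)
#: children under five as a fraction of regional population (sub-Saharan
#: national censuses put this near 15-17%)
DEFAULT_UNDER5_FRACTION = 0.165
#: mean of the (pre-truncation) Poisson for under-five children per
#: household; 0.81 children per household matches a 2,283 / 2,823
#: children-to-households ratio
CHILDREN_PER_HOUSEHOLD_MEAN = 0.81
CHILDREN_PER_HOUSEHOLD_MAX = 3


@dataclass(frozen=True)
class Road:
    geometry: LineString
    road_class: str  # primary | secondary | tertiary


@dataclass
class SyntheticScenario:
    """Complete parameterisation of a synthetic study."""

    grid: GridSpec
    seed: int
    n_regions: int = 9
    n_facilities: int = 25
    n_clusters: int = 120
    households_per_cluster: int = 25
    true_decay: DecayResults = field(
        default_factory=lambda: DecayResults.from_params(
            0.766, 3.736, -0.609, transform="log10"
        )
    )
    fever_prevalence_by_region: tuple[float, ...] = DEFAULT_PREVALENCE
    under5_fraction_by_region: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        prev = self.fever_prevalence_by_region[: self.n_regions]
        if len(prev) < self.n_regions:
            # cycle the defaults if more regions than defaults
            reps = -(-self.n_regions // len(self.fever_prevalence_by_region))
            prev = (self.fever_prevalence_by_region * reps)[: self.n_regions]
        self.fever_prevalence_by_region = tuple(prev)
        if self.under5_fraction_by_region is None:
            self.under5_fraction_by_region = (DEFAULT_UNDER5_FRACTION,) * self.n_regions
        for p in self.fever_prevalence_by_region:
            if not 0 < p <= 1:
                raise ValueError(f"prevalence {p} must lie in (0, 1]")
        for f in self.under5_fraction_by_region:
            if not 0 < f < 1:
                raise ValueError(f"under-five fraction {f} must lie in (0, 1)")

    def to_dict(self) -> dict:
        g = self.grid
        return {
            "grid": {
                "n_rows": g.n_rows, "n_cols": g.n_cols, "cell_size": g.cell_size,
                "origin_x": g.origin_x, "origin_y": g.origin_y, "nodata": g.nodata,
            },
            "seed": self.seed,
            "n_regions": self.n_regions,
            "n_facilities": self.n_facilities,
            "n_clusters": self.n_clusters,
            "households_per_cluster": self.households_per_cluster,
            "true_decay": {
                "C": self.true_decay.C, "A": self.true_decay.A,
                "B": self.true_decay.B, "transform": self.true_decay.transform,
            },
            "fever_prevalence_by_region": list(self.fever_prevalence_by_region),
            "under5_fraction_by_region": list(self.under5_fraction_by_region),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        td = d.get("true_decay", {})
        return cls(
            grid=GridSpec(**d["grid"]),
            seed=int(d["seed"]),
            n_regions=int(d.get("n_regions", 9)),
            n_facilities=int(d.get("n_facilities", 25)),
            n_clusters=int(d.get("n_clusters", 120)),
            households_per_cluster=int(d.get("households_per_cluster", 25)),
            true_decay=DecayResults.from_params(
                td.get("C", 0.766), td.get("A", 3.736), td.get("B", -0.609),
                transform=td.get("transform", "log10"),
            ),
            fever_prevalence_by_region=tuple(
                d.get("fever_prevalence_by_region", DEFAULT_PREVALENCE)
            ),
            under5_fraction_by_region=(
                tuple(d["under5_fraction_by_region"])
                if d.get("under5_fraction_by_region") else None
            ),
        )


def _smooth_field(grid: GridSpec, rng: np.random.Generator, sigma_cells: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian-smoothed noise field."""
    noise = rng.standard_normal(grid.shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(grid.shape)


def generate_dem(grid: GridSpec, seed: int, relief_amplitude: float = 300.0) -> Raster:
    """Smooth random elevation field (metres).

    ``relief_amplitude`` scales the standard deviation of the field;
    0 yields perfectly flat terrain.  Deterministic per (grid, seed).
    """
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    f = _smooth_field(grid, rng, sigma_cells=3.0)
    return Raster(relief_amplitude * f, grid)


def generate_landcover(grid: GridSpec, seed: int, class_proportions: dict[int, float]) -> Raster:
    """Spatially coherent categorical land-cover raster.

    Classes are assigned by thresholding a smoothed random field at the
    quantiles implied by ``class_proportions`` (codes from the packaged
    legend), so patch structure is realistic and achieved proportions match
    the requested ones to within one cell.

    Raises
    ------
    ValueError
        If proportions do not sum to 1 (tolerance 1e-9) or a class code is
        unknown to the default legend.
    """
    from .friction import SpeedTable

    total = sum(class_proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {total}")
    legend = SpeedTable.default().landcover
    unknown = [c for c in class_proportions if int(c) not in legend]
    if unknown:
        raise ValueError(f"unknown land-cover class ids {unknown}")

    rng = np.random.default_rng(seed)
    f = _smooth_field(grid, rng, sigma_cells=2.0)
    # tiny deterministic jitter breaks ties so quantile counts are exact
    f = f + rng.uniform(-1e-9, 1e-9, grid.shape)
    order = np.argsort(f, axis=None, kind="stable")
    out = np.empty(grid.n_rows * grid.n_cols, dtype=int)
    n = out.size
    start = 0
    items = sorted(class_proportions.items())
    for i, (code, prop) in enumerate(items):
        stop = n if i == len(items) - 1 else start + int(round(prop * n))
        out[order[start:stop]] = int(code)
        start = stop
    return Raster(out.reshape(grid.shape), grid)


def _random_polyline(grid: GridSpec, rng: np.random.Generator, n_bends: int = 2) -> LineString:
    """A polyline crossing the grid between two random boundary points."""
    x0, y0, x1, y1 = grid.extent
    w, h = x1 - x0, y1 - y0

    def boundary_point(side: int) -> tuple[float, float]:
        u = rng.uniform()
        return [
            (x0 + u * w, y0), (x0 + u * w, y1), (x0, y0 + u * h), (x1, y0 + u * h)
        ][side]

    s0 = int(rng.integers(4))
    s1 = int((s0 + 1 + rng.integers(3)) % 4)
    p0 = boundary_point(s0)
    p1 = boundary_point(s1)
    pts = [p0]
    for i in range(1, n_bends + 1):
        f = i / (n_bends + 1)
        mx = p0[0] + f * (p1[0] - p0[0]) + rng.uniform(-0.1, 0.1) * w
        my = p0[1] + f * (p1[1] - p0[1]) + rng.uniform(-0.1, 0.1) * h
        pts.append((float(np.clip(mx, x0, x1)), float(np.clip(my, y0, y1))))
    pts.append(p1)
    return LineString(pts)


def generate_roads(
    grid: GridSpec,
    seed: int,
    n_roads: int = 5,
    class_mix: dict[str, float] | None = None,
) -> list[Road]:
    """Random road polylines within the grid extent, one class each."""
    if class_mix is None:
        class_mix = {"primary": 0.2, "secondary": 0.3, "tertiary": 0.5}
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    roads = []
    for _ in range(n_roads):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        roads.append(Road(geometry=_random_polyline(grid, rng), road_class=cls))
    return roads


def generate_rivers(grid: GridSpec, seed: int, n_rivers: int = 2) -> list[LineString]:
    """Random river polylines; treated as absolute barriers downstream."""
    rng = np.random.default_rng(seed)
    return [_random_polyline(grid, rng, n_bends=3) for _ in range(n_rivers)]


def generate_population(
    grid: GridSpec,
    seed: int,
    n_centres: int = 5,
    total_population: int = 100_000,
    uniform: bool = False,
) -> Raster:
    """Clustered integer population counts summing exactly to the total.

    Population density is a mixture of Gaussian foci over the grid (plus a
    small uniform floor); counts are integerised by largest remainder so
    the raster sum equals ``total_population`` exactly.  ``uniform`` spreads
    the total evenly instead.
    """
    if total_population < 0:
        raise ValueError("total_population must be non-negative")
    rng = np.random.default_rng(seed)
    xs, ys = grid.cell_centers()
    if uniform:
        dens = np.ones(grid.shape)
    else:
        x0, y0, x1, y1 = grid.extent
        dens = np.full(grid.shape, 0.02)
        sigma = 0.08 * min(x1 - x0, y1 - y0)
        for _ in range(n_centres):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            dens += np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    w = dens / dens.sum()
    real = w * total_population
    base = np.floor(real).astype(np.int64)
    deficit = int(total_population - base.sum())
    if deficit > 0:
        frac = (real - base).ravel()
        top = np.argsort(-frac, kind="stable")[:deficit]
        flat = base.ravel()
        flat[top] += 1
        base = flat.reshape(grid.shape)
    return Raster(base.astype(float), grid)


def generate_regions(grid: GridSpec, n_regions: int) -> Raster:
    """Deterministic partition of the grid into contiguous regions.

    Voronoi partition of cell centres around region seed points laid out on
    a regular sub-grid; every cell belongs to exactly one region (codes
    0..n_regions-1).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be at least 1")
    # seed layout: the most-square factorisation of n_regions
    best = (1, n_regions)
    for a in range(1, int(np.sqrt(n_regions)) + 1):
        if n_regions % a == 0:
            best = (a, n_regions // a)
    ra, rb = best if grid.n_rows <= grid.n_cols else best[::-1]
    x0, y0, x1, y1 = grid.extent
    seeds_y = y0 + (np.arange(ra) + 0.5) / ra * (y1 - y0)
    seeds_x = x0 + (np.arange(rb) + 0.5) / rb * (x1 - x0)
    sx, sy = np.meshgrid(seeds_x, seeds_y)
    sx, sy = sx.ravel(), sy.ravel()
    xs, ys = grid.cell_centers()
    d2 = (xs[..., None] - sx) ** 2 + (ys[..., None] - sy) ** 2
    return Raster(np.argmin(d2, axis=-1).astype(int), grid)


def generate_facilities(
    population: Raster,
    n_facilities: int,
    seed: int,
    barrier: Raster | None = None,
) -> list[Facility]:
    """Facility points sampled on non-barrier cells, weight ∝ population.

    Cells with zero population share a small floor weight so facilities can
    appear in sparsely populated areas, as real facility networks do.
    """
    rng = np.random.default_rng(seed)
    g = population.grid
    pop = population.values.astype(float).copy()
    ok = np.ones(g.shape, dtype=bool)
    if barrier is not None:
        ok &= ~barrier.values.astype(bool)
    if not ok.any():
        raise ValueError("no non-barrier cells available for facilities")
    w = np.where(ok, pop + 1e-3, 0.0).ravel()
    w = w / w.sum()
    n_avail = int(ok.sum())
    if n_facilities > n_avail:
        raise ValueError(f"cannot place {n_facilities} facilities on {n_avail} cells")
    flat = rng.choice(g.n_rows * g.n_cols, size=n_facilities, replace=False, p=w)
    facs = []
    for fid, node in enumerate(sorted(int(i) for i in flat)):
        r, c = divmod(node, g.n_cols)
        x, y = g.cell_center(r, c)
        facs.append(Facility(facility_id=fid, x=float(x), y=float(y)))
    return facs


def _truncated_poisson(rng: np.random.Generator, lam: float, cap: int, size: int) -> np.ndarray:
    return np.minimum(rng.poisson(lam, size=size), cap)


def simulate_survey(
    scenario: SyntheticScenario,
    travel_time_surface: TravelTimeSurface,
    regions: Raster | None = None,
    barrier: Raster | None = None,
) -> pd.DataFrame:
    """Two-stage cluster household survey of under-five fever and attendance.

    Clusters are allocated to regions proportionally to region size and
    placed at cell centres of cells with finite travel time (clusters
    landing on barrier or unreached cells are resampled and logged).
    Households within a cluster carry 0-3 under-five children (truncated
    Poisson); each child independently has fever with the regional
    prevalence, and each fever case attends a public facility with
    probability given by the scenario's true decay model at the cluster's
    travel time.

    Returns
    -------
    DataFrame with one row per child: cluster_id, region_id, x, y,
    child_id, fever (0/1), attended_public (0/1, NaN when fever = 0) and
    travel_time_min (the true value used, for recovery tests).
    """
    g = scenario.grid
    if travel_time_surface.grid != g:
        raise ValueError("travel-time surface grid differs from the scenario grid")
    if regions is None:
        regions = generate_regions(g, scenario.n_regions)
    rng = np.random.default_rng(scenario.seed)
    minutes = travel_time_surface.minutes.values
    reg = regions.values.astype(int)
    bar = barrier.values.astype(bool) if barrier is not None else np.zeros(g.shape, bool)

    usable = np.isfinite(minutes) & ~bar
    if not usable.any():
        raise ValueError("no cell has a finite travel time; cannot place clusters")

    # proportional allocation of clusters to regions (largest remainder)
    region_ids = np.arange(scenario.n_regions)
    sizes = np.array([(reg == r).sum() for r in region_ids], dtype=float)
    share = sizes / sizes.sum() * scenario.n_clusters
    alloc = np.floor(share).astype(int)
    rem = scenario.n_clusters - alloc.sum()
    for r in np.argsort(-(share - np.floor(share)), kind="stable")[:rem]:
        alloc[r] += 1

    rows = []
    cluster_id = 0
    n_resampled = 0
    for r, k in zip(region_ids, alloc):
        cells = np.flatnonzero(reg.ravel() == r)
        for _ in range(int(k)):
            # rejection-sample a usable cell within the region
            for attempt in range(1000):
                node = int(rng.choice(cells))
                rr, cc = divmod(node, g.n_cols)
                if usable[rr, cc]:
                    break
                n_resampled += 1
            else:
                raise RuntimeError(f"could not place a cluster in region {r}")
            x, y = g.cell_center(rr, cc)
            t = float(minutes[rr, cc])
            p_attend = float(predict_probability(scenario.true_decay, t))
            prev = scenario.fever_prevalence_by_region[r]
            n_children = _truncated_poisson(
                rng, CHILDREN_PER_HOUSEHOLD_MEAN, CHILDREN_PER_HOUSEHOLD_MAX,
                scenario.households_per_cluster,
            )
            child_id = 0
            for hh, nc in enumerate(n_children):
                for _ in range(int(nc)):
                    fever = int(rng.uniform() < prev)
                    attended = (
                        float(rng.uniform() < p_attend) if fever else np.nan
                    )
                    rows.append(
                        (cluster_id, r, float(x), float(y), child_id,
                         fever, attended, t)
                    )
                    child_id += 1
            cluster_id += 1
    if n_resampled:
        logger.info("resampled %d cluster placements off barrier/unreached cells",
                    n_resampled)
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "region_id", "x", "y", "child_id",
                 "fever", "attended_public", "travel_time_min"],
    )
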