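"""Catchments, under-five population, fever burden and attendance summaries.

Given the travel-time and allocation surfaces, a gridded population layer
and a regional table of fever prevalence and under-five fractions, this
module delineates facility catchments under a travel-time threshold
(default 180 minutes), converts population to expected under-five fever
cases, splits those cases into expected attendees and non-attendees using
the fitted decay model's probability surface, and aggregates the result by
region, travel-time band, probability band or facility.

Counts are kept as real numbers throughout; rounding (half away from
zero) happens only when a report table is rendered, so the identity
attendees + non-attendees = fever cases holds exactly in every stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Raster, check_same_grid
from .traveltime import UNALLOCATED, AllocationSurface, TravelTimeSurface

__all__ = [
    "RegionTable",
    "CatchmentSet",
    "delineate_catchments",
    "children_surface",
    "fever_surface",
    "expected_attendance",
    "summarize",
    "proportion_ci",
    "round_half_away",
    "percentage",
]

DEFAULT_THRESHOLD_MINUTES = 180.0
OUTSIDE = -1  # catchment code for cells beyond the threshold or unreached


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of printed survey tables).

    numpy's default rounds half to even; health-survey reports round 0.05
    up, so 17.55 -> 17.6.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    r = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return r if r.ndim else float(r)


def percentage(part, whole, decimals: int = 1):
    """100 * part / whole, rounded half away from zero."""
    part = np.asarray(part, dtype=float)
    whole = np.asarray(whole, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(whole > 0, 100.0 * part / whole, 0.0)
    return round_half_away(p, decimals)


def proportion_ci(successes: int, n: int, level: float = 0.95):
    """Binomial proportion with a Wald confidence interval.

    Returns (p_hat, lower, upper) as proportions in [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p = successes / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)


@dataclass
class RegionTable:
    """Per-region fever prevalence (with CI) and under-five fraction."""

    data: pd.DataFrame  # region_id, name, prevalence, ci_low, ci_high, under5_fraction

    REQUIRED = ("region_id", "name", "prevalence", "under5_fraction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"region table is missing columns {missing}")
        d = self.data
        for col in ("prevalence", "under5_fraction"):
            if ((d[col] < 0) | (d[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if {"ci_low", "ci_high"}.issubset(d.columns):
            bad = (d["ci_low"] > d["prevalence"]) | (d["prevalence"] > d["ci_high"])
            if bad.any():
                raise ValueError("prevalence CI must contain the point estimate")
        if d["region_id"].duplicated().any():
            raise ValueError("duplicate region_id in region table")

    @classmethod
    def from_mapping(
        cls,
        prevalence: dict[int, float],
        under5_fraction: dict[int, float],
        names: dict[int, str] | None = None,
    ) -> "RegionTable":
        rows = []
        for rid in sorted(prevalence):
            rows.append(
                {
                    "region_id": rid,
                    "name": (names or {}).get(rid, f"region_{rid}"),
                    "prevalence": prevalence[rid],
                    "under5_fraction": under5_fraction[rid],
                }
            )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def lookup(self, column: str) -> dict[int, float]:
        return dict(zip(self.data["region_id"].astype(int), self.data[column]))


@dataclass
class CatchmentSet:
    """Facility catchments under a travel-time threshold.

    ``catchment.values`` holds the facility id where minutes <= threshold,
    else the OUTSIDE code (-1).
    """

    catchment: Raster
    threshold_minutes: float

    @property
    def grid(self):
        return self.catchment.grid

    def mask(self) -> np.ndarray:
        """Boolean mask of cells inside any catchment."""
        return self.catchment.values != OUTSIDE


def delineate_catchments(
    tt: TravelTimeSurface,
    alloc: AllocationSurface,
    threshold_minutes: float = DEFAULT_THRESHOLD_MINUTES,
) -> CatchmentSet:
    """Cells within the threshold keep their allocated facility; rest are outside."""
    check_same_grid(tt.minutes, alloc.facility_id, names=["travel_time", "allocation"])
    inside = (tt.minutes.values <= threshold_minutes) & np.isfinite(tt.minutes.values)
    fid = np.where(inside, alloc.facility_id.values, OUTSIDE).astype(int)
    if np.any(fid[inside] == UNALLOCATED):
        raise ValueError("cells with finite travel time must carry an allocation")
    return CatchmentSet(
        catchment=Raster(fid, tt.grid), threshold_minutes=threshold_minutes
    )


def children_surface(
    population: Raster, regions: Raster, table: RegionTable
) -> Raster:
    """Expected under-five count per cell: population x regional under-five fraction."""
    check_same_grid(population, regions, names=["population", "regions"])
    frac = table.lookup("under5_fraction")
    out = np.zeros(population.grid.shape, dtype=float)
    reg = regions.values.astype(int)
    for rid, f in frac.items():
        out[reg == rid] = f
    return Raster(out * population.values, population.grid)


def fever_surface(children: Raster, regions: Raster, table: RegionTable) -> Raster:
    """Expected fever cases per cell: children x regional prevalence.

    One episode of fever per child per reporting period.
    """
    check_same_grid(children, regions, names=["children", "regions"])
    prev = table.lookup("prevalence")
    out = np.zeros(children.grid.shape, dtype=float)
    reg = regions.values.astype(int)
    for rid, p in prev.items():
        out[reg == rid] = p
    return Raster(out * children.values, children.grid)


def expected_attendance(fever: Raster, probability: Raster) -> tuple[Raster, Raster]:
    """Split fever cases into expected attendees and non-attendees, cell-wise."""
    check_same_grid(fever, probability, names=["fever", "probability"])
    att = fever.values * probability.values
    non = fever.values - att  # exact complement: att + non == fever cell-wise
    return Raster(att, fever.grid), Raster(non, fever.grid)


def _strata_masks(
    strata: str,
    band_edges,
    cumulative: bool,
    regions: Raster | None,
    table: RegionTable | None,
    tt: TravelTimeSurface | None,
    probability: Raster | None,
    catchments: CatchmentSet | None,
):
    """Yield (label, mask) pairs for the requested stratification."""
    if strata == "regions":
        if regions is None or table is None:
            raise ValueError("region stratification needs regions raster and table")
        reg = regions.values.astype(int)
        names = table.lookup("name")
        for rid in sorted(names):
            yield str(names[rid]), reg == rid
    elif strata == "time-bands":
        if tt is None:
            raise ValueError("time-band stratification needs the travel-time surface")
        m = tt.minutes.values
        edges = list(band_edges)
        if cumulative:
            for e in edges:
                yield f"<= {e:g} min", np.isfinite(m) & (m <= e)
            yield f"> {edges[-1]:g} min", ~np.isfinite(m) | (m > edges[-1])
        else:
            lo = 0.0
            for e in edges:
                yield f"{lo:g}-{e:g} min", np.isfinite(m) & (m > lo if lo else m >= 0) & (m <= e)
                lo = e
            yield f"> {edges[-1]:g} min", ~np.isfinite(m) | (m > edges[-1])
    elif strata == "probability-bands":
        if probability is None:
            raise ValueError("probability stratification needs the probability raster")
        p = probability.values
        edges = list(band_edges)
        lo = 0.0
        for e in edges:
            yield f"{lo:g}-{e:g}", (p >= lo) & (p < e)
            lo = e
        yield f">= {edges[-1]:g}", p >= edges[-1]
    elif strata == "catchments":
        if catchments is None:
            raise ValueError("catchment stratification needs a CatchmentSet")
        fid = catchments.catchment.values
        for f in sorted(np.unique(fid[fid != OUTSIDE])):
            yield f"facility_{int(f)}", fid == f
        yield "outside", fid == OUTSIDE
    else:
        raise ValueError(f"unknown strata {strata!r}")


def summarize(
    children: Raster,
    fever: Raster,
    attendees: Raster,
    strata: str = "regions",
    band_edges=None,
    cumulative: bool = False,
    regions: Raster | None = None,
    table: RegionTable | None = None,
    tt: TravelTimeSurface | None = None,
    probability: Raster | None = None,
    catchments: CatchmentSet | None = None,
) -> pd.DataFrame:
    """Aggregate counts by stratum into a report table.

    Parameters
    ----------
    strata : 'regions' | 'time-bands' | 'probability-bands' | 'catchments'
    band_edges : sequence of band upper edges (minutes or probabilities)
    cumulative : for time bands, report nested "within e minutes" rows
        instead of exclusive bands (headline within-30-min / within-1-h
        counts are cumulative).
    catchments : restricts the children_in_catchment column; cells outside
        any catchment still contribute fever cases and attendance to their
        stratum.

    Returns
    -------
    DataFrame with columns stratum, children_u5, children_in_catchment,
    fever_cases, expected_attendees, expected_non_attendees,
    pct_attendees, pct_non_attendees (percentages to one decimal).
    """
    check_same_grid(children, fever, attendees, names=["children", "fever", "attendees"])
    non_att = fever.values - attendees.values
    in_catch = catchments.mask() if catchments is not None else np.ones(
        children.grid.shape, dtype=bool
    )
    rows = []
    for label, mask in _strata_masks(
        strata, band_edges, cumulative, regions, table, tt, probability, catchments
    ):
        fe = float(fever.values[mask].sum())
        at = float(attendees.values[mask].sum())
        na = float(non_att[mask].sum())
        rows.append(
            {
                "stratum": label,
                "children_u5": float(children.values[mask].sum()),
                "children_in_catchment": float(children.values[mask & in_catch].sum()),
                "fever_cases": fe,
                "expected_attendees": at,
                "expected_non_attendees": na,
                "pct_attendees": percentage(at, fe),
                "pct_non_attendees": percentage(na, fe),
            }
        )
    total_mask = np.ones(children.grid.shape, dtype=bool)
    fe = float(fever.values.sum())
    at = float(attendees.values.sum())
    rows.append(
        {
            "stratum": "Total",
            "children_u5": float(children.values.sum()),
            "children_in_catchment": float(children.values[in_catch].sum()),
            "fever_cases": fe,
            "expected_attendees": at,
            "expected_non_attendees": fe - at,
            "pct_attendees": percentage(at, fe),
            "pct_non_attendees": percentage(fe - at, fe),
        }
    )
    return pd.DataFrame(rows)
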