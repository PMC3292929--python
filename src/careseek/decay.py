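"""Three-parameter logistic distance-decay model of facility attendance.

The probability that a febrile child is taken to a public health facility
is modelled as a function of travel time t (minutes) through

    Y(x) = C / (1 + exp((A - x) / B)),      x = log10(max(t, 1))

where C in (0, 1] is the limiting probability of attendance at zero travel
time (the upper asymptote — attendance never reaches 100% even next door
to a facility), A locates the inflection point on the transformed scale,
and B < 0 is the decay parameter (more negative = slower decay).  With C
fixed at 1 the model reduces to the ordinary two-parameter logistic.

Fitting follows the grouped nonlinear-least-squares route: individual
attended/not-attended outcomes are binned on transformed travel time
(default 15 quantile bins), and the curve is fitted to the per-bin
attendance proportions by unweighted least squares with multi-start
initialisation.  Coefficient t-statistics and p-values come from the
asymptotic covariance (J'J)^-1 * s^2 at the solution.

The API follows the statsmodels convention: build a
:class:`DistanceDecayModel` from data, call ``fit()``, and read estimates,
standard errors and diagnostics off the returned :class:`DecayResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grids import Raster

__all__ = [
    "transform_time",
    "bin_attendance",
    "BinnedAttendance",
    "DistanceDecayModel",
    "DecayResults",
    "fit_logistic3",
    "predict_probability",
    "probability_surface",
    "logistic3",
]

#: floor (minutes) applied before the log transform; guards log(0) for
#: households in a facility cell, whose access time is near zero but positive
T_FLOOR_MINUTES = 1.0

_TRANSFORMS = ("log10", "ln", "identity")


def transform_time(t, transform: str = "log10", t_floor: float = T_FLOOR_MINUTES):
    """Transform travel time (minutes >= 0) to the model's x scale."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}, got {transform!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("travel times must be non-negative")
    if transform == "identity":
        return t if t.ndim else float(t)
    tf = np.maximum(t, t_floor)
    x = np.log10(tf) if transform == "log10" else np.log(tf)
    return x if x.ndim else float(x)


def logistic3(x, C, A, B):
    """The three-parameter logistic C / (1 + exp((A - x) / B))."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        v = C / (1.0 + np.exp((A - x) / B))
    return v if v.ndim else float(v)


@dataclass
class BinnedAttendance:
    """Attendance proportions grouped on the transformed time scale.

    Attributes
    ----------
    edges : ndarray, len n_bins + 1
        Bin boundaries on the transformed scale, covering the data.
    x_mean : ndarray
        Within-bin mean of transformed travel times.
    p_hat : ndarray
        Within-bin attendance proportion.
    n : ndarray of int
        Fever cases per bin; sums to the number of records.
    transform : str
    """

    edges: np.ndarray
    x_mean: np.ndarray
    p_hat: np.ndarray
    n: np.ndarray
    transform: str = "log10"

    def __post_init__(self) -> None:
        if np.any((self.p_hat < 0) | (self.p_hat > 1)):
            raise ValueError("bin proportions must lie in [0, 1]")
        if len(self.x_mean) != len(self.p_hat) or len(self.p_hat) != len(self.n):
            raise ValueError("binned arrays must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.x_mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_mean": self.x_mean, "p_hat": self.p_hat, "n": self.n}
        )


def bin_attendance(
    records,
    n_bins: int = 15,
    scheme: str = "quantile",
    transform: str = "log10",
    t_floor: float = T_FLOOR_MINUTES,
) -> BinnedAttendance:
    """Group attendance outcomes into bins of transformed travel time.

    Parameters
    ----------
    records : DataFrame with columns travel_time, attended — or a pair of
        arrays (travel_time, attended)
    scheme : 'quantile' (equal counts, sizes differing by at most 1) or
        'equal-width' on the transformed scale.  Empty bins are dropped.
    """
    if isinstance(records, pd.DataFrame):
        t = records["travel_time"].to_numpy(dtype=float)
        a = records["attended"].to_numpy(dtype=float)
    else:
        t, a = (np.asarray(v, dtype=float) for v in records)
    if t.size == 0:
        raise ValueError("no records to bin")
    if np.any((a != 0) & (a != 1)):
        raise ValueError("attended must be binary")
    x = np.asarray(transform_time(t, transform, t_floor))

    if scheme == "quantile":
        order = np.argsort(x, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(x.size)
        idx = (ranks * n_bins) // x.size  # sizes differ by <= 1
    elif scheme == "equal-width":
        lo, hi = x.min(), x.max()
        width = (hi - lo) / n_bins if hi > lo else 1.0
        idx = np.minimum(((x - lo) / width).astype(int), n_bins - 1)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")

    x_mean, p_hat, counts, uppers = [], [], [], []
    lo_edge = x.min()
    for b in range(n_bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        x_mean.append(x[sel].mean())
        p_hat.append(a[sel].mean())
        counts.append(nb)
        uppers.append(x[sel].max())
    edges = np.concatenate([[lo_edge], uppers])
    return BinnedAttendance(
        edges=np.asarray(edges),
        x_mean=np.asarray(x_mean),
        p_hat=np.asarray(p_hat),
        n=np.asarray(counts, dtype=int),
        transform=transform,
    )


def _fit_binned(
    binned: BinnedAttendance, fix_C: float | None = None
) -> tuple[np.ndarray, dict]:
    """Multi-start NLS of the 3-parameter logistic on binned proportions."""
    x = binned.x_mean
    p = binned.p_hat
    k_free = 3 if fix_C is None else 2
    if binned.n_bins < k_free + 1:
        raise ValueError(
            f"need at least {k_free + 1} non-degenerate bins to fit "
            f"{k_free} parameters, got {binned.n_bins}"
        )

    def residuals(theta):
        if fix_C is None:
            C, A, B = theta
        else:
            C = fix_C
            A, B = theta
        return logistic3(x, C, A, B) - p

    C0 = float(np.clip(p.max(), 1e-3, 1.0))
    A0 = float(np.median(x))
    best = None
    for B0 in (-0.5, 0.5, -1.0, 1.0):
        theta0 = [C0, A0, B0] if fix_C is None else [A0, B0]
        lb = [1e-6, -np.inf, -np.inf] if fix_C is None else [-np.inf, -np.inf]
        ub = [1.0, np.inf, np.inf] if fix_C is None else [np.inf, np.inf]
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lb, ub), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        ssr = 2.0 * sol.cost
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise RuntimeError(
            "nonlinear least squares failed to converge from any start; "
            f"binned data: x in [{x.min():.3g}, {x.max():.3g}], "
            f"p in [{p.min():.3g}, {p.max():.3g}]"
        )
    ssr, sol = best
    if fix_C is None:
        params = sol.x
    else:
        params = np.array([fix_C, sol.x[0], sol.x[1]])

    n_bins = binned.n_bins
    df_resid = n_bins - k_free
    s2 = ssr / df_resid if df_resid > 0 else np.nan
    J = sol.jac
    try:
        cov_free = np.linalg.inv(J.T @ J) * s2
        bse_free = np.sqrt(np.diag(cov_free))
    except np.linalg.LinAlgError:
        bse_free = np.full(k_free, np.nan)
    if fix_C is None:
        bse = bse_free
    else:
        bse = np.concatenate([[np.nan], bse_free])

    monotone_increasing = bool(np.all(np.diff(p) >= 0)) and p[-1] > p[0]
    if monotone_increasing:
        warnings.warn(
            "attendance proportions increase with travel time; the decay fit "
            "is returned but is unlikely to be meaningful",
            stacklevel=3,
        )
    diag = {
        "ssr": float(ssr),
        "df_resid": int(df_resid),
        "rse": float(np.sqrt(s2)) if df_resid > 0 else np.nan,
        "bse": bse,
        "monotone_increasing": monotone_increasing,
        "n_bins": n_bins,
    }
    return params, diag


class DistanceDecayModel:
    """Distance-decay model of public-facility attendance vs travel time.

    Parameters
    ----------
    travel_time : array_like, minutes
        One entry per fever case.
    attended : array_like of {0, 1}
        Whether the child was taken to a public health facility.
    transform : {'log10', 'ln', 'identity'}
        Time transform for the x axis; log10 minutes by default.
    n_bins, scheme : grouping used before the least-squares fit.

    Examples
    --------
    >>> model = DistanceDecayModel(travel_time=t, attended=a)
    >>> res = model.fit()
    >>> res.params  # (C, A, B)
    >>> print(res.summary())
    """

    param_names = ("C", "A", "B")

    def __init__(
        self,
        travel_time,
        attended,
        transform: str = "log10",
        n_bins: int = 15,
        scheme: str = "quantile",
        t_floor: float = T_FLOOR_MINUTES,
    ):
        self.travel_time = np.asarray(travel_time, dtype=float)
        self.attended = np.asarray(attended, dtype=float)
        if self.travel_time.shape != self.attended.shape:
            raise ValueError("travel_time and attended must be the same length")
        if np.any(self.travel_time < 0):
            raise ValueError("travel times must be non-negative")
        self.transform = transform
        self.n_bins = n_bins
        self.scheme = scheme
        self.t_floor = t_floor
        self.nobs = self.travel_time.size

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        time_col: str = "travel_time_min",
        attended_col: str = "attended_public",
        fever_col: str | None = "fever",
        **kwargs,
    ) -> "DistanceDecayModel":
        """Build the model from a survey table, keeping fever cases only."""
        df = data
        if fever_col is not None and fever_col in df.columns:
            df = df[df[fever_col] == 1]
        df = df.dropna(subset=[attended_col])
        return cls(
            travel_time=df[time_col].to_numpy(dtype=float),
            attended=df[attended_col].to_numpy(dtype=float),
            **kwargs,
        )

    def bin(self) -> BinnedAttendance:
        return bin_attendance(
            (self.travel_time, self.attended),
            n_bins=self.n_bins,
            scheme=self.scheme,
            transform=self.transform,
            t_floor=self.t_floor,
        )

    def fit(self, fix_C: float | None = None) -> "DecayResults":
        """Fit by grouped nonlinear least squares; returns :class:`DecayResults`."""
        binned = self.bin()
        params, diag = _fit_binned(binned, fix_C=fix_C)
        return DecayResults(model=self, binned=binned, params=params, diag=diag)


@dataclass
class DecayResults:
    """Fitted three-parameter logistic decay: estimates and diagnostics."""

    model: DistanceDecayModel | None
    binned: BinnedAttendance
    params: np.ndarray  # (C, A, B)
    diag: dict

    @property
    def C(self) -> float:
        return float(self.params[0])

    @property
    def A(self) -> float:
        return float(self.params[1])

    @property
    def B(self) -> float:
        return float(self.params[2])

    @property
    def transform(self) -> str:
        return self.binned.transform

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.diag["bse"], dtype=float)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        df = self.diag["df_resid"]
        return 2.0 * stats.t.sf(np.abs(self.tvalues), df)

    @property
    def ssr(self) -> float:
        return self.diag["ssr"]

    @property
    def rse(self) -> float:
        """Residual standard error sqrt(SSR / (n_bins - 3))."""
        return self.diag["rse"]

    def predict(self, t) -> np.ndarray | float:
        """Probability of attendance at travel time t (minutes)."""
        return predict_probability(self, t)

    def probability_surface(self, tt) -> Raster:
        return probability_surface(self, tt)

    def summary(self) -> str:
        names = DistanceDecayModel.param_names
        lines = [
            "Three-parameter logistic distance-decay model",
            "=" * 62,
            f"Transform: {self.transform}(minutes), floor "
            f"{self.binned_t_floor():g} min; bins: {self.binned.n_bins} "
            f"({getattr(self.model, 'scheme', 'quantile')})",
            f"Fever cases: {getattr(self.model, 'nobs', int(self.binned.n.sum()))}"
            f"   SSR: {self.ssr:.4g}   RSE: {self.rse:.4g}"
            f"   df_resid: {self.diag['df_resid']}",
            "-" * 62,
            f"{'':>6}{'coef':>12}{'std err':>12}{'t':>10}{'P>|t|':>12}",
        ]
        for i, name in enumerate(names):
            lines.append(
                f"{name:>6}{self.params[i]:>12.4f}{self.bse[i]:>12.4f}"
                f"{self.tvalues[i]:>10.2f}{self.pvalues[i]:>12.3g}"
            )
        lines.append("=" * 62)
        if self.diag.get("monotone_increasing"):
            lines.append("Warning: attendance increases with travel time.")
        return "\n".join(lines)

    def binned_t_floor(self) -> float:
        return getattr(self.model, "t_floor", T_FLOOR_MINUTES)

    def plot(self, ax=None):
        """Binned attendance proportions with the fitted decay curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.binned.x_mean, self.binned.p_hat, s=20, label="binned data")
        xs = np.linspace(self.binned.edges[0], self.binned.edges[-1], 200)
        ax.plot(xs, logistic3(xs, *self.params), "r-", label="fitted decay")
        ax.set_xlabel(f"{self.transform}(travel time, min)")
        ax.set_ylabel("probability of attendance")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "A": self.A,
            "B": self.B,
            "transform": self.transform,
            "t_floor": self.binned_t_floor(),
            "diagnostics": {
                "ssr": self.ssr,
                "rse": self.rse,
                "df_resid": self.diag["df_resid"],
                "n_bins": self.diag["n_bins"],
                "bse": [None if not np.isfinite(v) else float(v) for v in self.bse],
                "tvalues": [
                    None if not np.isfinite(v) else float(v) for v in self.tvalues
                ],
                "pvalues": [
                    None if not np.isfinite(v) else float(v) for v in self.pvalues
                ],
                "monotone_increasing": bool(self.diag.get("monotone_increasing", False)),
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DecayResults":
        d = json.loads(Path(path).read_text())
        return cls.from_params(
            d["C"], d["A"], d["B"], transform=d.get("transform", "log10"),
            diagnostics=d.get("diagnostics"),
        )

    @classmethod
    def from_params(
        cls, C: float, A: float, B: float, transform: str = "log10",
        diagnostics: dict | None = None,
    ) -> "DecayResults":
        """A results object from known coefficients (no data attached).

        C = 0 is admitted here as a degenerate truth (zero attendance
        everywhere) for simulation; fitted models always have C > 0.
        """
        if not (0 <= C <= 1):
            raise ValueError("C must lie in [0, 1]")
        if B == 0:
            raise ValueError("B must be nonzero")
        diag = {
            "ssr": np.nan, "rse": np.nan, "df_resid": 0,
            "bse": np.full(3, np.nan), "n_bins": 0, "monotone_increasing": False,
        }
        if diagnostics:
            diag.update(
                {k: diagnostics[k] for k in ("ssr", "rse", "df_resid", "n_bins")
                 if k in diagnostics}
            )
        binned = BinnedAttendance(
            edges=np.array([0.0, 0.0]), x_mean=np.array([]), p_hat=np.array([]),
            n=np.array([], dtype=int), transform=transform,
        )
        return cls(model=None, binned=binned, params=np.array([C, A, B]), diag=diag)


def fit_logistic3(
    binned: BinnedAttendance,
    transform: str | None = None,
    fix_C: float | None = None,
) -> DecayResults:
    """Fit the three-parameter logistic directly to pre-binned proportions.

    ``fix_C=1`` pins the asymptote, reducing the model to the ordinary
    two-parameter logistic.
    """
    if transform is not None and transform != binned.transform:
        raise ValueError(
            f"binned data carry transform {binned.transform!r}, got {transform!r}"
        )
    params, diag = _fit_binned(binned, fix_C=fix_C)
    return DecayResults(model=None, binned=binned, params=params, diag=diag)


def predict_probability(model, t) -> np.ndarray | float:
    """Probability of attendance at travel time t (minutes).

    ``model`` may be a DecayResults or any object with C, A, B and
    transform attributes.  t = +inf evaluates the tail limit (0 for B < 0).
    """
    C, A, B = float(model.C), float(model.A), float(model.B)
    transform = getattr(model, "transform", "log10")
    t_floor = getattr(model, "t_floor", None) or T_FLOOR_MINUTES
    t = np.asarray(t, dtype=float)
    x = np.where(np.isfinite(t), transform_time(np.where(np.isfinite(t), t, 0.0),
                                                transform, t_floor), np.inf)
    with np.errstate(over="ignore"):
        expo = (A - x) / B
        p = np.where(np.isposinf(x), C if B > 0 else 0.0, C / (1.0 + np.exp(expo)))
    return p if p.ndim else float(p)


def probability_surface(model, tt) -> Raster:
    """Per-cell attendance probability from a travel-time surface.

    Unreached cells (travel time +inf) take the model's infinite-time
    limit, which is 0 for a decaying model (B < 0).
    """
    minutes = tt.minutes if hasattr(tt, "minutes") else tt
    p = predict_probability(model, minutes.values)
    return Raster(np.asarray(p, dtype=float), minutes.grid)
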