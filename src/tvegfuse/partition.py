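"""Evapotranspiration partitioning via underlying water-use efficiency (uWUE).

uWUE = GPP * sqrt(VPD) / ET couples carbon uptake and water loss through
stomatal regulation.  Its *potential* value (uWUE_p, estimated annually as
the 95th-percentile through-origin regression slope of GPP*sqrt(VPD) on ET)
characterises conditions where transpiration dominates ET (T ~ ET); its
*apparent* value (uWUE_a, a moving-window through-origin least-squares
slope) tracks the actual ratio.  The transpiration fraction follows as

    T / ET = uWUE_a / uWUE_p.

Rainy days and the day after each rain event are excluded beforehand
(canopy interception contaminates ET), as are quality-flagged records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "PartitionResult",
    "filter_rain_days",
    "uwue_potential",
    "uwue_apparent",
    "t_over_et",
    "transpiration",
    "partition_site",
    "benchmark_mean",
    "read_fluxnet_csv",
]

RAIN_THRESHOLD = 0.1  # mm day^-1; "rainfall" below this is treated as trace
MIN_FIT_POINTS = 50  # valid steps needed for an annual uWUE_p fit
MIN_WINDOW_POINTS = 8  # valid steps needed inside a moving window


@dataclass
class SiteRecord:
    """Flux-tower record with the variables the partitioning needs.

    ``data`` columns: timestamp, ET (mm day^-1), GPP (gC m^-2 step^-1),
    VPD (hPa), P (mm step^-1), QC (0 = measured/good gap-fill).
    """

    data: pd.DataFrame
    pft: str = "UNK"
    site_id: str = ""

    def __post_init__(self) -> None:
        required = {"timestamp", "ET", "GPP", "VPD", "P", "QC"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"site record missing columns: {sorted(missing)}")
        ts = pd.to_datetime(self.data["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        if (self.data["VPD"].dropna() < 0).any():
            raise ValueError("VPD must be non-negative")
        self.data = self.data.assign(timestamp=ts).reset_index(drop=True)
        if "valid" not in self.data.columns:
            self.data["valid"] = self.data["QC"].to_numpy() == 0


@dataclass
class PartitionResult:
    """Per-site partitioning output."""

    timestamps: pd.Series
    uwue_p: dict  # year -> potential uWUE (or nan if the year failed)
    uwue_a: np.ndarray
    t_over_et: np.ndarray
    t: np.ndarray
    coverage: float
    n_clipped_high: int = 0
    n_clipped_low: int = 0


def filter_rain_days(record: SiteRecord, threshold: float = RAIN_THRESHOLD) -> SiteRecord:
    """Invalidate rainy days and the day following each rain event.

    Also drops steps whose quality flag is bad.  The record keeps its full
    time axis; exclusion happens through the ``valid`` column.
    """
    df = record.data.copy()
    rain = df["P"].to_numpy() > threshold
    drop = rain.copy()
    drop[1:] |= rain[:-1]
    df["valid"] = (df["QC"].to_numpy() == 0) & ~drop
    return SiteRecord(data=df, pft=record.pft, site_id=record.site_id)


def _quantile_slope_origin(x: np.ndarray, y: np.ndarray, q: float = 0.95) -> float:
    """Exact through-origin quantile-regression slope.

    Minimises the pinball loss sum_i rho_q(y_i - c * x_i) over c for a
    single non-negative regressor.  The minimiser is the weighted q-quantile
    of the ratios y_i / x_i with weights x_i: the smallest ratio r such that
    the x-weight of points with y/x <= r reaches q of the total x-weight.
    Deterministic; ties resolve to the lower breakpoint.
    """
    pos = x > 0
    x, y = x[pos], y[pos]
    if x.size == 0:
        raise ValueError("no points with positive regressor")
    ratios = y / x
    order = np.argsort(ratios, kind="stable")
    cum = np.cumsum(x[order])
    target = q * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(idx, x.size - 1)
    return float(ratios[order][idx])


def uwue_potential(
    record: SiteRecord,
    year: int | None = None,
    quantile: float = 0.95,
    min_fit_points: int = MIN_FIT_POINTS,
) -> float:
    """Annual potential uWUE: 95th-percentile through-origin slope.

    Fits GPP * sqrt(VPD) against ET over the valid steps of one calendar
    year (or the whole record when ``year`` is None).
    """
    df = record.data
    sel = df["valid"].to_numpy()
    if year is not None:
        sel = sel & (df["timestamp"].dt.year.to_numpy() == year)
    sel &= np.isfinite(df["ET"]) & np.isfinite(df["GPP"]) & np.isfinite(df["VPD"])
    n = int(sel.sum())
    if n < min_fit_points:
        raise ValueError(f"only {n} valid steps; need {min_fit_points}")
    et = df.loc[sel, "ET"].to_numpy()
    gv = (df.loc[sel, "GPP"] * np.sqrt(df.loc[sel, "VPD"])).to_numpy()
    if not np.any(et > 0):
        raise ValueError("all ET values are zero; slope undefined")
    slope = _quantile_slope_origin(et, gv, q=quantile)
    if slope <= 0:
        raise ValueError(f"non-positive potential uWUE ({slope:.3g})")
    return slope


def uwue_apparent(
    record: SiteRecord,
    window: int = 8,
    min_points: int = MIN_WINDOW_POINTS,
) -> np.ndarray:
    """Moving-window apparent uWUE: through-origin least-squares slope.

    The slope sum(x*y)/sum(x^2) of GPP*sqrt(VPD) on ET is computed in a
    centred window of ``window`` steps and assigned to the window centre;
    windows with fewer than ``min_points`` valid steps yield NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1 step")
    df = record.data
    et = df["ET"].to_numpy(dtype=float)
    gv = (df["GPP"] * np.sqrt(df["VPD"])).to_numpy(dtype=float)
    ok = (
        df["valid"].to_numpy()
        & np.isfinite(et)
        & np.isfinite(gv)
        & (et > 0)
    )
    xy = np.where(ok, et * gv, 0.0)
    xx = np.where(ok, et * et, 0.0)
    cnt = ok.astype(float)
    # centred rolling sums via pandas (min_periods=1; count enforced after)
    roll = lambda a: (
        pd.Series(a).rolling(window, center=True, min_periods=1).sum().to_numpy()
    )
    sxy, sxx, scnt = roll(xy), roll(xx), roll(cnt)
    out = np.full(et.size, np.nan)
    good = (scnt >= min_points) & (sxx > 0)
    out[good] = sxy[good] / sxx[good]
    return out


def t_over_et(
    uwue_a: np.ndarray,
    uwue_p_by_step: np.ndarray,
    clip: bool = True,
):
    """Transpiration fraction uWUE_a / uWUE_p, optionally clipped into [0, 1].

    Returns ``(ratio, n_clipped_high, n_clipped_low)``; clip counts are
    reported, not hidden.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.asarray(uwue_a, dtype=float) / np.asarray(
            uwue_p_by_step, dtype=float
        )
    n_hi = int(np.sum(ratio > 1))
    n_lo = int(np.sum(ratio < 0))
    if clip:
        ratio = np.clip(ratio, 0.0, 1.0)
    return ratio, n_hi, n_lo


def transpiration(record: SiteRecord, ratio: np.ndarray) -> np.ndarray:
    """T = (T/ET) * ET per step."""
    return np.asarray(ratio, dtype=float) * record.data["ET"].to_numpy(dtype=float)


def partition_site(
    record: SiteRecord,
    window: int = 8,
    quantile: float = 0.95,
    rain_threshold: float = RAIN_THRESHOLD,
    min_fit_points: int = MIN_FIT_POINTS,
    min_window_points: int = MIN_WINDOW_POINTS,
    clip: bool = True,
) -> PartitionResult:
    """Full uWUE pipeline: rain filter -> uWUE_p per year -> uWUE_a -> T/ET -> T."""
    rec = filter_rain_days(record, threshold=rain_threshold)
    years = rec.data["timestamp"].dt.year.to_numpy()
    uwue_p = {}
    for yr in np.unique(years):
        try:
            uwue_p[int(yr)] = uwue_potential(
                rec, year=int(yr), quantile=quantile, min_fit_points=min_fit_points
            )
        except ValueError:
            uwue_p[int(yr)] = np.nan
    p_by_step = np.array([uwue_p[int(y)] for y in years])
    ua = uwue_apparent(rec, window=window, min_points=min_window_points)
    ratio, n_hi, n_lo = t_over_et(ua, p_by_step, clip=clip)
    t = transpiration(rec, ratio)
    coverage = float(np.isfinite(t).mean())
    return PartitionResult(
        timestamps=rec.data["timestamp"],
        uwue_p=uwue_p,
        uwue_a=ua,
        t_over_et=ratio,
        t=t,
        coverage=coverage,
        n_clipped_high=n_hi,
        n_clipped_low=n_lo,
    )


def benchmark_mean(methods: dict) -> np.ndarray:
    """Per-step mean of the T series from several partitioning methods.

    At each step the mean runs over the methods that have a value there, so
    periods covered by only a subset of methods remain usable.  Accepts a
    mapping of method name to equal-length series.
    """
    if not methods:
        raise ValueError("need at least one method series")
    stack = np.vstack([np.asarray(v, dtype=float) for v in methods.values()])
    ok = np.isfinite(stack)
    count = ok.sum(axis=0)
    total = np.where(ok, stack, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


DEFAULT_FLUXNET_COLUMNS = {
    "timestamp": "TIMESTAMP",
    "ET": "ET",
    "GPP": "GPP_NT_VUT_REF",
    "VPD": "VPD_F",
    "P": "P_F",
    "QC": "NEE_VUT_REF_QC",
}


def read_fluxnet_csv(
    path: str | Path,
    pft: str = "UNK",
    site_id: str = "",
    column_map: dict | None = None,
) -> SiteRecord:
    """Read a FLUXNET-2015-style daily CSV into a SiteRecord.

    ``column_map`` maps the canonical names (timestamp, ET, GPP, VPD, P, QC)
    to the file's column names; defaults follow the FULLSET convention.
    """
    cmap = {**DEFAULT_FLUXNET_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    out = pd.DataFrame({k: df[v] for k, v in cmap.items()})
    out["timestamp"] = pd.to_datetime(out["timestamp"].astype(str))
    return SiteRecord(data=out, pft=pft, site_id=site_id or Path(path).stem)


def write_partition_csv(result: PartitionResult, path: str | Path) -> Path:
    """Write a PartitionResult as a tidy per-step CSV."""
    path = Path(path)
    pd.DataFrame(
        {
            "timestamp": result.timestamps,
            "uwue_a": result.uwue_a,
            "t_over_et": result.t_over_et,
            "T": result.t,
        }
    ).to_csv(path, index=False)
    return path
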