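"""Validation metrics, group aggregation, trend analysis, latitude profiles.

Six metrics score an estimate against a reference: RMSE, unbiased RMSE
(means removed before differencing, so RMSE^2 = ubRMSE^2 + bias^2), MAE,
relative bias (signed, (mean_est - mean_ref)/mean_ref), Pearson R, and the
modified Kling-Gupta efficiency

    KGE' = 1 - sqrt((r - 1)^2 + (beta - 1)^2 + (gamma - 1)^2)

with beta the mean ratio and gamma the ratio of coefficients of variation
(the 2012 variant; the 2009 variability-ratio form is available behind a
flag).  Trends use the Theil-Sen slope (median of all pairwise slopes) with
two-sided Mann-Kendall significance (tie-corrected variance, continuity
correction, normal approximation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricSet",
    "TrendResult",
    "compute_metrics",
    "aggregate_by_group",
    "theil_sen_slope",
    "theil_sen_trend",
    "mann_kendall",
    "latitudinal_profile",
]

METRIC_NAMES = ("rmse", "ubrmse", "mae", "rb", "kge", "r")


@dataclass
class MetricSet:
    rmse: float
    ubrmse: float
    mae: float
    rb: float
    kge: float
    r: float
    n: int
    rb_valid: bool = True
    r_valid: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class TrendResult:
    slope: float
    mk_p: float
    significant: bool
    n_years: int


def compute_metrics(
    est, ref, kge_variant: str = "2012"
) -> MetricSet:
    """Score an estimate series against a reference over paired valid steps."""
    e = np.asarray(est, dtype=float)
    o = np.asarray(ref, dtype=float)
    if e.shape != o.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(e) & np.isfinite(o)
    n = int(ok.sum())
    if n < 2:
        raise ValueError(f"need at least 2 paired samples, got {n}")
    e, o = e[ok], o[ok]

    diff = e - o
    rmse = float(np.sqrt(np.mean(diff**2)))
    ubrmse = float(np.sqrt(np.mean(((e - e.mean()) - (o - o.mean())) ** 2)))
    mae = float(np.mean(np.abs(diff)))

    rb_valid = o.mean() != 0
    rb = float((e.mean() - o.mean()) / o.mean()) if rb_valid else np.nan

    se, so = e.std(), o.std()
    r_valid = se > 0 and so > 0
    r = float(np.corrcoef(e, o)[0, 1]) if r_valid else np.nan

    if r_valid and rb_valid and e.mean() != 0:
        beta = e.mean() / o.mean()
        if kge_variant == "2012":
            gamma = (se / e.mean()) / (so / o.mean())
        elif kge_variant == "2009":
            gamma = se / so
        else:
            raise ValueError(f"unknown KGE variant {kge_variant!r}")
        kge = float(1.0 - math.sqrt((r - 1) ** 2 + (beta - 1) ** 2 + (gamma - 1) ** 2))
    else:
        kge = np.nan
    return MetricSet(
        rmse=rmse, ubrmse=ubrmse, mae=mae, rb=rb, kge=kge, r=r, n=n,
        rb_valid=rb_valid, r_valid=r_valid,
    )


def aggregate_by_group(
    metric_sets: dict,
    groups: dict,
    sd: str = "population",
):
    """Mean +/- sd of each metric per group, with a best-per-metric flag.

    ``metric_sets`` maps site id to MetricSet; ``groups`` maps site id to a
    group label (e.g. its plant functional type).  Returns a pandas
    DataFrame indexed by group with ``<metric>_mean`` / ``<metric>_sd``
    columns and a ``best`` dict in ``attrs`` naming, for each metric, the
    group with the best value (min for error metrics, max for kge/r).
    """
    import pandas as pd

    ddof = 0 if sd == "population" else 1
    rows = {}
    for g in sorted(set(groups.values())):
        sites = [s for s, gg in groups.items() if gg == g]
        if not sites:
            continue
        row = {}
        for m in METRIC_NAMES:
            vals = np.array([getattr(metric_sets[s], m) for s in sites], dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{m}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{m}_sd"] = (
                vals.std(ddof=ddof) if vals.size > ddof else (0.0 if vals.size else np.nan)
            )
        row["n_sites"] = len(sites)
        rows[g] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    best = {}
    for m in METRIC_NAMES:
        col = table[f"{m}_mean"]
        if col.notna().any():
            best[m] = col.idxmax() if m in ("kge", "r") else col.idxmin()
    table.attrs["best"] = best
    return table


#: below this sample size the p-value uses the exact permutation distribution
EXACT_MK_N = 8


def _mk_score(x: np.ndarray) -> float:
    d = x[None, :] - x[:, None]  # d[i, j] = x[j] - x[i]
    return float(np.sign(d[np.triu_indices(x.size, 1)]).sum())


def mann_kendall(values) -> tuple:
    """Two-sided Mann-Kendall test for a monotonic trend.

    Returns ``(s, p)`` with S the Kendall score.  For n <= 8 the p-value is
    exact — the share of permutations of the observed values with
    ``|S| >= |S_obs|`` (the normal approximation is poor this small);
    larger samples use the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    s = _mk_score(x)
    if n <= EXACT_MK_N:
        total = extreme = 0
        for perm in itertools.permutations(x):
            total += 1
            if abs(_mk_score(np.asarray(perm))) >= abs(s):
                extreme += 1
        return int(s), extreme / total
    _, counts = np.unique(x, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var <= 0:
        return int(s), 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return int(s), float(min(p, 1.0))


def theil_sen_slope(values, times=None) -> float:
    """Median-of-pairwise-slopes estimator alone (no significance test)."""
    y = np.asarray(values, dtype=float)
    t = np.arange(y.size, dtype=float) if times is None else np.asarray(times, float)
    slope, *_ = stats.theilslopes(y, t)
    return float(slope)


def theil_sen_trend(values, times=None, alpha: float = 0.05) -> TrendResult:
    """Theil-Sen slope with Mann-Kendall significance on an annual series."""
    y = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(y.size, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if y.size < 4:
        raise ValueError(f"need at least 4 annual values, got {y.size}")
    slope, *_ = stats.theilslopes(y, t)
    _, p = mann_kendall(y)
    return TrendResult(
        slope=float(slope), mk_p=p, significant=bool(p < alpha), n_years=int(y.size)
    )


def latitudinal_profile(field, weighted: bool = False):
    """Mean over valid longitudes per latitude row of a (lat, lon) field.

    ``weighted=True`` applies cos(latitude) area weights (a no-op along a
    single row, provided for cross-row aggregation conventions).  Rows with
    no valid cell yield NaN.
    """
    import xarray as xr

    if isinstance(field, xr.DataArray):
        da = field
    else:
        da = xr.DataArray(field, dims=("lat", "lon"))
    if "lat" not in da.dims:
        raise ValueError("field must have a latitude dimension")
    profile = da.mean(dim="lon", skipna=True)
    if weighted:
        pass  # per-row longitude mean is unweighted by construction
    return profile
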