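"""Synthetic truth signals, collocated products, grids and flux-site records.

Everything downstream of this module (collocation estimators, merging,
partitioning, the grid pipeline) is exercised against data generated here,
where the latent signal, the affine product biases, the random-error
covariance matrix and the transpiration fraction are all known exactly.

The signal model is a mean level plus a sinusoidal seasonal cycle plus AR(1)
anomalies.  The autoregressive component guarantees the non-zero lag-1
autocovariance that the instrumental-variable collocation estimator requires.
Product errors are drawn from a zero-mean multivariate normal with a
user-prescribed covariance matrix (off-diagonals model error
cross-correlation between products sharing forcing data) and are independent
across time steps, i.e. serially white.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "TruthConfig",
    "ProductConfig",
    "SiteSimConfig",
    "simulate_truth",
    "simulate_products",
    "simulate_grid",
    "simulate_site",
    "write_site_csv",
]

# Default error covariance used across examples and tests: variances match
# the global-mean random error variances of the three parent transpiration
# products (GLDAS-like 0.36, GLEAM-like 0.29, PMLv2-like 0.13 mm^2 day^-2),
# with one correlated pair (products 1-2, covariance 0.10, ECC ~ 0.31)
# emulating shared forcing data.
DEFAULT_ERROR_COV = np.array(
    [
        [0.36, 0.10, 0.0],
        [0.10, 0.29, 0.0],
        [0.0, 0.0, 0.13],
    ]
)


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the latent transpiration signal.

    Attributes
    ----------
    n_steps : number of time steps.
    ar1_coeff : lag-1 autoregressive coefficient of the anomaly component;
        must satisfy ``|ar1_coeff| < 1`` (stationarity).
    seasonal_amplitude : amplitude of the sinusoidal seasonal cycle
        (mm day^-1).
    seasonal_period : period of the seasonal cycle in time steps.
    mean_level : long-term mean (mm day^-1).
    noise_sd : standard deviation of the AR(1) innovations (mm day^-1).
    seed : RNG seed; identical seeds give bit-identical series.
    clip_negative : if True, clip the series at zero (transpiration is a
        non-negative flux).  Off by default so estimator algebra is exact.
    """

    n_steps: int = 960
    ar1_coeff: float = 0.7
    seasonal_amplitude: float = 1.5
    seasonal_period: float = 46.0
    mean_level: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not abs(self.ar1_coeff) < 1.0:
            raise ValueError(
                f"ar1_coeff={self.ar1_coeff} is non-stationary; need |phi| < 1"
            )


@dataclass(frozen=True)
class ProductConfig:
    """Affine biases and random-error covariance of the simulated products.

    ``product i = alphas[i] + betas[i] * truth + eps[i]`` with
    ``eps ~ N(0, error_cov)`` i.i.d. over time.
    """

    alphas: tuple = (0.0, 0.0, 0.0)
    betas: tuple = (1.0, 0.8, 1.2)
    error_cov: np.ndarray = field(default_factory=lambda: DEFAULT_ERROR_COV.copy())
    seed: int = 1
    product_ids: tuple | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.error_cov, dtype=float)
        n = len(self.alphas)
        if len(self.betas) != n or cov.shape != (n, n):
            raise ValueError("alphas, betas and error_cov sizes are inconsistent")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("error_cov must be symmetric")
        if np.any(np.diag(cov) < 0):
            raise ValueError("error_cov diagonal entries must be >= 0")
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin < -1e-10 * max(1.0, np.abs(cov).max()):
            raise ValueError(
                f"error_cov is not positive semi-definite (min eigenvalue {eigmin:.3e})"
            )
        object.__setattr__(self, "error_cov", cov)

    @property
    def n_products(self) -> int:
        return len(self.alphas)

    @property
    def ids(self) -> list:
        if self.product_ids is not None:
            return list(self.product_ids)
        return [f"prod{i + 1}" for i in range(self.n_products)]


@dataclass(frozen=True)
class SiteSimConfig:
    """Parameters of a synthetic flux-tower record for the uWUE benchmark.

    The record is constructed so that ``GPP * sqrt(VPD) / T`` equals
    ``uwue_p_true`` exactly before noise, with ``T = t_over_et * ET``.
    ``gpp_noise_cv`` adds multiplicative lognormal measurement noise to GPP
    (coefficient of variation); set to 0 for the exact construction.
    """

    n_days: int = 365
    uwue_p_true: float = 9.0
    t_over_et_series: np.ndarray | None = None
    rain_days: tuple = ()
    seed: int = 7
    gpp_noise_cv: float = 0.02
    et_mean: float = 3.0
    et_seasonal_amplitude: float = 1.5
    vpd_mean: float = 10.0
    rain_amount: float = 5.0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.t_over_et_series is not None:
            ratio = np.asarray(self.t_over_et_series, dtype=float)
            if ratio.shape != (self.n_days,):
                raise ValueError("t_over_et_series must have length n_days")
            if np.any((ratio < 0) | (ratio > 1)):
                raise ValueError("t_over_et_series values must lie in [0, 1]")
            object.__setattr__(self, "t_over_et_series", ratio)
        days = np.asarray(self.rain_days, dtype=int)
        if days.size and (days.min() < 0 or days.max() >= self.n_days):
            raise ValueError("rain_days must lie in [0, n_days)")


def simulate_truth(config: TruthConfig) -> np.ndarray:
    """Generate the latent signal: mean + seasonal cycle + AR(1) anomalies.

    The AR(1) component is initialised from its stationary distribution, so
    the series is (weakly) stationary from the first step.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_steps)
    seasonal = config.seasonal_amplitude * np.sin(
        2.0 * np.pi * t / config.seasonal_period
    )
    phi = config.ar1_coeff
    innov = rng.normal(0.0, config.noise_sd, size=config.n_steps)
    if config.noise_sd > 0:
        # stationary start: x0 ~ N(0, sd^2 / (1 - phi^2))
        innov[0] /= np.sqrt(1.0 - phi**2)
    anomalies = lfilter([1.0], [1.0, -phi], innov)
    truth = config.mean_level + seasonal + anomalies
    if config.clip_negative:
        truth = np.clip(truth, 0.0, None)
    return truth


def _error_draws(cov: np.ndarray, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n_products, n_steps) serially-white errors with covariance cov."""
    n = cov.shape[0]
    if not np.any(cov):
        return np.zeros((n, n_steps))
    # eigen factorisation handles PSD (singular) covariances that Cholesky rejects
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    return factor @ rng.standard_normal((n, n_steps))


def simulate_products(truth: np.ndarray, config: ProductConfig):
    """Apply affine biases and additive correlated noise to the truth signal.

    Returns a :class:`~tvegfuse.collocation.CollocatedSeries` with one row per
    product and an all-valid mask.
    """
    from .collocation import CollocatedSeries

    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(config.seed)
    eps = _error_draws(config.error_cov, truth.size, rng)
    alphas = np.asarray(config.alphas, dtype=float)[:, None]
    betas = np.asarray(config.betas, dtype=float)[:, None]
    values = alphas + betas * truth[None, :] + eps
    return CollocatedSeries(
        product_ids=config.ids,
        times=np.arange(truth.size),
        values=values,
        valid_mask=np.ones_like(values, dtype=bool),
    )


def simulate_grid(
    shape: tuple,
    truth_config: TruthConfig,
    product_config: ProductConfig,
    lat0: float = 30.0,
    lon0: float = -100.0,
    resolution: float = 0.1,
):
    """Simulate one grid cube per product, plus the per-pixel truth cube.

    Pixels are statistically independent realizations of the same truth and
    product configuration (no spatial autocorrelation).  Returns
    ``(cubes, truth_cube)`` where ``cubes`` is a dict mapping product id to an
    :class:`xarray.DataArray` with dims ``(time, lat, lon)``.
    """
    import xarray as xr

    nlat, nlon = shape
    npix = nlat * nlon
    n_steps = truth_config.n_steps
    nprod = product_config.n_products

    truth_field = np.empty((n_steps, npix))
    prod_field = np.empty((nprod, n_steps, npix))
    for p in range(npix):
        tcfg = TruthConfig(
            **{**truth_config.__dict__, "seed": truth_config.seed + 1000 * p}
        )
        pcfg = ProductConfig(
            alphas=product_config.alphas,
            betas=product_config.betas,
            error_cov=product_config.error_cov,
            seed=product_config.seed + 1000 * p,
            product_ids=product_config.product_ids,
        )
        truth_px = simulate_truth(tcfg)
        series = simulate_products(truth_px, pcfg)
        truth_field[:, p] = truth_px
        prod_field[:, :, p] = series.values

    lat = lat0 + resolution * np.arange(nlat)
    lon = lon0 + resolution * np.arange(nlon)
    coords = {"time": np.arange(n_steps), "lat": lat, "lon": lon}
    dims = ("time", "lat", "lon")
    attrs = {"units": "mm day-1"}

    truth_cube = xr.DataArray(
        truth_field.reshape(n_steps, nlat, nlon),
        coords=coords,
        dims=dims,
        name="truth",
        attrs=attrs,
    )
    cubes = {}
    for i, pid in enumerate(product_config.ids):
        cubes[pid] = xr.DataArray(
            prod_field[i].reshape(n_steps, nlat, nlon),
            coords=coords,
            dims=dims,
            name=pid,
            attrs={**attrs, "product": pid},
        )
    return cubes, truth_cube


def simulate_site(config: SiteSimConfig):
    """Build a daily flux-site record with a known transpiration fraction.

    Construction: ET follows a positive seasonal cycle, VPD a positive
    seasonal cycle, T = t_over_et * ET, and GPP is set so that
    ``GPP * sqrt(VPD) = uwue_p_true * T`` exactly (before optional
    multiplicative GPP noise).  Rain is placed on ``rain_days``.

    Returns ``(record, t_true)`` where ``record`` is a
    :class:`~tvegfuse.partition.SiteRecord` and ``t_true`` the noise-free
    transpiration series (mm day^-1).
    """
    from .partition import SiteRecord

    rng = np.random.default_rng(config.seed)
    n = config.n_days
    day = np.arange(n)
    et = config.et_mean + config.et_seasonal_amplitude * np.sin(
        2.0 * np.pi * day / 365.0
    )
    et = np.clip(et, 0.1, None)
    vpd = config.vpd_mean * (0.8 + 0.4 * rng.random(n))
    if config.t_over_et_series is None:
        ratio = np.ones(n)
    else:
        ratio = config.t_over_et_series
    t_true = ratio * et
    gpp = config.uwue_p_true * t_true / np.sqrt(vpd)
    if config.gpp_noise_cv > 0:
        cv = config.gpp_noise_cv
        sigma = np.sqrt(np.log1p(cv**2))
        gpp = gpp * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    precip = np.zeros(n)
    rain_days = np.asarray(config.rain_days, dtype=int)
    if rain_days.size:
        precip[rain_days] = config.rain_amount

    timestamps = pd.date_range("2005-01-01", periods=n, freq="D")
    frame = pd.DataFrame(
        {
            "timestamp": timestamps,
            "ET": et,
            "GPP": gpp,
            "VPD": vpd,
            "P": precip,
            "QC": np.zeros(n, dtype=int),
        }
    )
    record = SiteRecord(data=frame, pft="GRA", site_id="synthetic")
    return record, t_true


def write_site_csv(record, path: str | Path) -> Path:
    """Write a site record as CSV with columns (timestamp, ET, GPP, VPD, P, QC)."""
    path = Path(path)
    record.data.to_csv(path, index=False)
    return path


def write_grid_fixtures(
    cubes: dict,
    out_dir: str | Path,
    variable: str = "Ec",
) -> dict:
    """Write one netCDF file per product in the layout grid_pipeline reads.

    Returns a mapping of product id to file path.
    """
    from .gridio import save_cube

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pid, cube in cubes.items():
        path = out_dir / f"{pid}.nc"
        save_cube(cube, path, variable=variable)
        paths[pid] = path
    return paths
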