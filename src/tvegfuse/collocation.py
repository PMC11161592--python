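"""Collocation error estimators: triple collocation, extended collocation and
the double instrumental-variable (EIVD) estimator.

All three estimators operate on N spatially/temporally collocated series
assumed to follow the affine error model

    x_i = alpha_i + beta_i * theta + eps_i,

with ``theta`` the unobserved true signal and ``eps_i`` zero-mean random
errors orthogonal to the signal.  Classic triple collocation (TC, N = 3)
additionally assumes all error pairs uncorrelated; extended collocation
(EC, N = 4 here) and EIVD (N = 3 with lag-1 instruments) relax that
assumption for declared product pairs, returning the error covariance and
its correlation (ECC) alongside the error variances.

Conventions (documented, switchable where noted):

* covariances use the population denominator (divide by n), so the
  closed-form and cross-multiplied-difference identities of the TC algebra
  hold exactly on finite samples;
* a time step is "complete" only when every product is valid there
  (listwise completeness), and all moments are computed over complete steps;
* negative variance estimates are *flagged* invalid, never clipped, so the
  merging stage can apply explicit fallbacks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CollocatedSeries",
    "ErrorModel",
    "CollocationError",
    "pairwise_covariances",
    "tc_rescale",
    "tc_error_variances",
    "lag1_autocovariance",
    "eivd_estimate",
    "ec_quadruplet_estimate",
    "grid_error_estimation",
]

#: below this many complete steps a pixel is flagged invalid
MIN_SAMPLES = 100

#: reciprocal-condition threshold for the least-squares systems
RCOND_LIMIT = 1e-10


class CollocationError(ValueError):
    """Raised when an estimator's preconditions are violated."""


@dataclass
class CollocatedSeries:
    """Time-aligned values of N products at one pixel or site.

    ``values`` has shape (N, T); ``valid_mask`` marks usable entries per
    product and step.  A step enters the moment computations only when all
    products are valid there.
    """

    product_ids: list
    times: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.times = np.asarray(self.times)
        n, t = self.values.shape
        if len(self.product_ids) != n:
            raise ValueError("product_ids length does not match values rows")
        if self.valid_mask.shape != (n, t) or self.times.shape != (t,):
            raise ValueError("values, valid_mask and times shapes are inconsistent")
        if n < 2:
            raise ValueError("need at least two products")

    @property
    def n_products(self) -> int:
        return self.values.shape[0]

    @property
    def complete_mask(self) -> np.ndarray:
        """Steps where every product is valid (finite and unmasked)."""
        return self.valid_mask.all(axis=0) & np.isfinite(self.values).all(axis=0)

    @property
    def n_complete(self) -> int:
        return int(self.complete_mask.sum())

    def index(self, product_id) -> int:
        return self.product_ids.index(product_id)

    def subset(self, product_ids) -> "CollocatedSeries":
        idx = [self.index(p) for p in product_ids]
        return CollocatedSeries(
            product_ids=list(product_ids),
            times=self.times,
            values=self.values[idx],
            valid_mask=self.valid_mask[idx],
        )


@dataclass
class ErrorModel:
    """Estimated random-error structure of N collocated products.

    ``error_variance`` and ``sensitivity`` (beta_i^2 sigma_theta^2) are
    per-product arrays with companion validity flags; ``error_covariance``
    and ``ecc`` hold entries for the declared non-zero pairs only.  Invalid
    estimates (negative variances, |ECC| > 1, failed preconditions) keep
    their raw values but are flagged, never silently repaired.
    """

    product_ids: list
    error_variance: np.ndarray
    sensitivity: np.ndarray
    variance_valid: np.ndarray
    sensitivity_valid: np.ndarray
    error_covariance: dict = field(default_factory=dict)
    ecc: dict = field(default_factory=dict)
    ecc_valid: dict = field(default_factory=dict)
    scaling_factors: dict = field(default_factory=dict)
    n_samples: int = 0
    method: str = "tc"
    valid: bool = True
    reason: str = ""

    def variance_of(self, product_id) -> float:
        return float(self.error_variance[self.product_ids.index(product_id)])

    def covariance_matrix(self) -> np.ndarray:
        """Full N x N error covariance matrix (declared pairs off-diagonal)."""
        n = len(self.product_ids)
        cov = np.diag(self.error_variance.astype(float))
        for (a, b), val in self.error_covariance.items():
            i, j = self.product_ids.index(a), self.product_ids.index(b)
            cov[i, j] = cov[j, i] = val
        return cov

    @classmethod
    def invalid(cls, product_ids, method: str, reason: str) -> "ErrorModel":
        n = len(product_ids)
        nan = np.full(n, np.nan)
        false = np.zeros(n, dtype=bool)
        return cls(
            product_ids=list(product_ids),
            error_variance=nan.copy(),
            sensitivity=nan.copy(),
            variance_valid=false.copy(),
            sensitivity_valid=false.copy(),
            method=method,
            valid=False,
            reason=reason,
        )


def pairwise_covariances(
    series: CollocatedSeries, min_samples: int = MIN_SAMPLES, ddof: int = 0
):
    """Sample covariance matrix and means over complete steps.

    Returns ``(cov, means, n)``.  Population denominator (ddof=0) by default
    so the TC closed-form identities hold exactly.
    """
    mask = series.complete_mask
    n = int(mask.sum())
    if n < min_samples:
        raise CollocationError(
            f"only {n} complete steps; need at least {min_samples}"
        )
    data = series.values[:, mask]
    means = data.mean(axis=1)
    cov = np.cov(data, ddof=ddof)
    return cov, means, n


def tc_rescale(
    series: CollocatedSeries, reference, min_samples: int = MIN_SAMPLES
):
    """Rescale a triplet into the reference product's data space.

    With reference X, product Y maps to ``beta * (Y - mean(Y)) + mean(X)``
    where ``beta = cov(X, Z) / cov(Y, Z)`` and Z is the remaining product
    (covariance-ratio scaling).  Returns the rescaled series and the scaling
    factors keyed by product id (reference maps to 1).
    """
    if series.n_products != 3:
        raise CollocationError("TC rescaling requires exactly three products")
    cov, means, n = pairwise_covariances(series, min_samples=min_samples)
    ref = series.index(reference)
    others = [i for i in range(3) if i != ref]
    scaled = series.values.copy()
    factors = {series.product_ids[ref]: 1.0}
    for i in others:
        (k,) = [j for j in others if j != i]
        denom = cov[i, k]
        if denom == 0.0:
            raise CollocationError(
                f"zero covariance between {series.product_ids[i]} and "
                f"{series.product_ids[k]}: scaling undefined"
            )
        beta = cov[ref, k] / denom
        scaled[i] = beta * (series.values[i] - means[i]) + means[ref]
        factors[series.product_ids[i]] = float(beta)
    return (
        CollocatedSeries(
            product_ids=list(series.product_ids),
            times=series.times,
            values=scaled,
            valid_mask=series.valid_mask.copy(),
        ),
        factors,
    )


def tc_error_variances(
    series: CollocatedSeries, min_samples: int = MIN_SAMPLES
) -> ErrorModel:
    """Classic triple collocation under the zero-ECC assumption.

    Closed forms: ``var(eps_X) = var(X) - cov(X,Y) cov(X,Z) / cov(Y,Z)`` and
    cyclic permutations; sensitivities are the subtracted signal terms.
    """
    if series.n_products != 3:
        raise CollocationError("triple collocation requires exactly three products")
    try:
        cov, _, n = pairwise_covariances(series, min_samples=min_samples)
    except CollocationError as exc:
        return ErrorModel.invalid(series.product_ids, "tc", str(exc))

    err_var = np.empty(3)
    sens = np.empty(3)
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        if cov[j, k] == 0.0:
            return ErrorModel.invalid(
                series.product_ids, "tc",
                f"zero covariance between products {j} and {k}",
            )
        signal = cov[i, j] * cov[i, k] / cov[j, k]
        sens[i] = signal
        err_var[i] = cov[i, i] - signal
    return ErrorModel(
        product_ids=list(series.product_ids),
        error_variance=err_var,
        sensitivity=sens,
        variance_valid=err_var >= 0,
        sensitivity_valid=sens >= 0,
        n_samples=n,
        method="tc",
    )


def lag1_autocovariance(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    min_pairs: int = MIN_SAMPLES,
) -> float:
    """Lag-1 autocovariance of one series, computed on anomalies.

    Only pairs of *adjacent* steps where both entries are valid contribute;
    the mean is taken over the valid entries and the average over pairs uses
    the population denominator.
    """
    x = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    pair_ok = valid[1:] & valid[:-1]
    n_pairs = int(pair_ok.sum())
    if n_pairs < min_pairs:
        raise CollocationError(f"only {n_pairs} adjacent valid pairs; need {min_pairs}")
    mean = x[valid].mean()
    a = x - mean
    return float(np.mean(a[1:][pair_ok] * a[:-1][pair_ok]))


def _eivd_system(cov: np.ndarray, lags: np.ndarray):
    """Observation vector (10,) and design matrix (10, 8) of the EIVD system.

    Product order is (X, Y, Z) with the declared ECC pair in positions
    (X, Y).  Unknowns: [bX^2 s2, bY^2 s2, bZ^2 s2, bX bY s2,
    var_eX, var_eY, var_eZ, cov_eXeY].
    """
    lxx, lyy, lzz = lags
    y = np.array(
        [
            cov[0, 0],
            cov[1, 1],
            cov[2, 2],
            cov[0, 1],
            cov[0, 2] * np.sqrt(lxx / lzz),
            cov[1, 2] * np.sqrt(lyy / lzz),
            cov[2, 0] * np.sqrt(lzz / lxx),
            cov[2, 1] * np.sqrt(lzz / lyy),
            cov[0, 2] * np.sqrt(lyy / lzz),
            cov[1, 2] * np.sqrt(lxx / lzz),
        ]
    )
    a = np.zeros((10, 8))
    a[:4, :4] = np.eye(4)
    a[:4, 4:] = np.eye(4)
    a[4, 0] = 1.0
    a[5, 1] = 1.0
    a[6, 2] = 1.0
    a[7, 2] = 1.0
    a[8, 3] = 1.0
    a[9, 3] = 1.0
    return y, a


def _solve_ls(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with a conditioning guard on the normal matrix."""
    gram = a.T @ a
    sv = np.linalg.svd(gram, compute_uv=False)
    if sv[-1] / sv[0] < RCOND_LIMIT:
        raise CollocationError(
            "collocation system is rank-deficient (normal matrix ill-conditioned)"
        )
    sol, *_ = np.linalg.lstsq(a, y, rcond=None)
    return sol


def eivd_estimate(
    series: CollocatedSeries,
    ecc_pair: tuple,
    min_samples: int = MIN_SAMPLES,
) -> ErrorModel:
    """Double instrumental-variable estimator with one non-zero ECC pair.

    Uses each product's lag-1 shifted series as its instrument: the lag-1
    autocovariances L_ii estimate beta_i^2 times the signal autocovariance
    (errors being serially white), so sqrt(L_ii / L_jj) recovers the
    dynamic-range ratio beta_i / beta_j.  These ratios scale the cross
    covariances into a 10-equation linear system whose least-squares
    solution yields per-product sensitivities, error variances, and the
    error covariance of the declared pair.

    Requires a signal with non-zero lag-1 autocovariance (L_ii > 0 for all
    products); white-noise inputs violate the instrumental-variable
    assumption and are rejected.
    """
    if series.n_products != 3:
        raise CollocationError("EIVD requires exactly three products")
    if len(set(ecc_pair)) != 2 or any(p not in series.product_ids for p in ecc_pair):
        raise CollocationError(f"ecc_pair {ecc_pair} must name two distinct products")

    # reorder so the declared pair occupies positions (X, Y)
    third = [p for p in series.product_ids if p not in ecc_pair]
    order = [ecc_pair[0], ecc_pair[1], third[0]]
    s = series.subset(order)

    try:
        cov, _, n = pairwise_covariances(s, min_samples=min_samples)
        mask = s.complete_mask
        lags = np.array(
            [
                lag1_autocovariance(s.values[i], mask, min_pairs=2)
                for i in range(3)
            ]
        )
    except CollocationError as exc:
        return ErrorModel.invalid(order, "eivd", str(exc))

    # the instruments carry information only if the signal autocovariance is
    # significantly positive: under a serially white series the sample lag-1
    # autocorrelation has sd ~ 1/sqrt(n), so require > 3 sds
    variances = np.array([np.var(s.values[i][s.complete_mask]) for i in range(3)])
    lag_ratio = lags / variances
    if np.any(lag_ratio <= 3.0 / np.sqrt(max(n - 1, 1))):
        return ErrorModel.invalid(
            order, "eivd",
            "non-positive lag-1 autocovariance: signal autocorrelation absent, "
            "instrumental-variable assumption violated",
        )

    yvec, amat = _eivd_system(cov, lags)
    try:
        x = _solve_ls(amat, yvec)
    except CollocationError as exc:
        return ErrorModel.invalid(order, "eivd", str(exc))

    sens = x[:3]
    err_var = x[4:7]
    err_cov = x[7]
    with np.errstate(invalid="ignore"):
        rho = err_cov / np.sqrt(err_var[0] * err_var[1])
    pair = (order[0], order[1])
    var_ok = err_var >= 0
    ecc_ok = bool(var_ok[0] and var_ok[1] and np.isfinite(rho) and abs(rho) <= 1)
    scaling = {
        (order[i], order[j]): float(np.sqrt(lags[i] / lags[j]))
        for i in range(3)
        for j in range(3)
        if i != j
    }
    return ErrorModel(
        product_ids=order,
        error_variance=err_var,
        sensitivity=sens,
        variance_valid=var_ok,
        sensitivity_valid=sens >= 0,
        error_covariance={pair: float(err_cov)},
        ecc={pair: float(rho)},
        ecc_valid={pair: ecc_ok},
        scaling_factors=scaling,
        n_samples=n,
        method="eivd",
    )


def _clean_triplets(products, ecc_pairs):
    """For each product, the (k, l) choices forming a mutually zero-ECC triplet."""
    declared = {frozenset(p) for p in ecc_pairs}

    def zero(a, b):
        return frozenset((a, b)) not in declared

    out = {}
    for m in products:
        rest = [p for p in products if p != m]
        out[m] = [
            (k, l)
            for k, l in itertools.combinations(rest, 2)
            if zero(m, k) and zero(m, l) and zero(k, l)
        ]
    return out


def ec_quadruplet_estimate(
    series: CollocatedSeries,
    ecc_pairs,
    min_samples: int = MIN_SAMPLES,
) -> ErrorModel:
    """Extended collocation for four products with declared non-zero ECC pairs.

    Solvability requires every product to belong to at least one triplet with
    mutually zero declared ECC; configurations violating the rule are
    rejected before any computation.  The estimator assembles, for every
    admissible triplet, the moment identities

        sensitivity:   S_m = cov(m,k) cov(m,l) / cov(k,l)
        cross term:    C_ab = cov(a,k) cov(b,l) / cov(k,l)

    together with the variance/covariance decompositions
    ``var(m) = S_m + var_eps_m`` and ``cov(a,b) = C_ab + cov_eps_ab`` for
    declared pairs, and solves the stacked linear system by least squares.
    """
    if series.n_products != 4:
        raise CollocationError("quadruplet extended collocation requires four products")
    products = list(series.product_ids)
    pairs = [tuple(p) for p in ecc_pairs]
    for p in pairs:
        if len(set(p)) != 2 or any(q not in products for q in p):
            raise CollocationError(f"declared pair {p} must name two distinct products")

    triplets = _clean_triplets(products, pairs)
    bad = [m for m, t in triplets.items() if not t]
    if bad:
        raise CollocationError(
            f"declared ECC pairs {pairs} leave product(s) {bad} without any "
            "mutually zero-ECC triplet; system unsolvable"
        )

    try:
        cov, _, n = pairwise_covariances(series, min_samples=min_samples)
    except CollocationError as exc:
        return ErrorModel.invalid(products, "ec", str(exc))

    idx = {p: i for i, p in enumerate(products)}
    npr = len(products)
    # unknown layout: [S_1..S_4, var_e1..var_e4, C_p1.., cov_e_p1..]
    npairs = len(pairs)
    nunk = 2 * npr + 2 * npairs
    rows, ys = [], []

    def row():
        return np.zeros(nunk)

    # variance decompositions: var(m) = S_m + var_eps_m
    for m in products:
        r = row()
        r[idx[m]] = 1.0
        r[npr + idx[m]] = 1.0
        rows.append(r)
        ys.append(cov[idx[m], idx[m]])
    # declared-pair decompositions: cov(a,b) = C_ab + cov_eps_ab
    for q, (a, b) in enumerate(pairs):
        r = row()
        r[2 * npr + q] = 1.0
        r[2 * npr + npairs + q] = 1.0
        rows.append(r)
        ys.append(cov[idx[a], idx[b]])
    # sensitivities from clean triplets
    for m in products:
        for k, l in triplets[m]:
            denom = cov[idx[k], idx[l]]
            if denom == 0.0:
                continue
            r = row()
            r[idx[m]] = 1.0
            rows.append(r)
            ys.append(cov[idx[m], idx[k]] * cov[idx[m], idx[l]] / denom)
    # undeclared cross covariances give cross-sensitivity information only
    # through declared-pair cross terms C_ab = cov(a,k) cov(b,l) / cov(k,l)
    declared = {frozenset(p) for p in pairs}
    for q, (a, b) in enumerate(pairs):
        rest = [p for p in products if p not in (a, b)]
        for k, l in itertools.permutations(rest, 2):
            if any(
                frozenset(x) in declared
                for x in ((a, k), (b, l), (k, l))
            ):
                continue
            denom = cov[idx[k], idx[l]]
            if denom == 0.0:
                continue
            r = row()
            r[2 * npr + q] = 1.0
            rows.append(r)
            ys.append(cov[idx[a], idx[k]] * cov[idx[b], idx[l]] / denom)

    amat = np.array(rows)
    yvec = np.array(ys)
    try:
        x = _solve_ls(amat, yvec)
    except CollocationError as exc:
        return ErrorModel.invalid(products, "ec", str(exc))

    sens = x[:npr]
    err_var = x[npr : 2 * npr]
    err_cov = {}
    ecc = {}
    ecc_ok = {}
    for q, (a, b) in enumerate(pairs):
        c = float(x[2 * npr + npairs + q])
        err_cov[(a, b)] = c
        va, vb = err_var[idx[a]], err_var[idx[b]]
        with np.errstate(invalid="ignore"):
            rho = c / np.sqrt(va * vb) if va > 0 and vb > 0 else np.nan
        ecc[(a, b)] = float(rho)
        ecc_ok[(a, b)] = bool(np.isfinite(rho) and abs(rho) <= 1)
    return ErrorModel(
        product_ids=products,
        error_variance=err_var,
        sensitivity=sens,
        variance_valid=err_var >= 0,
        sensitivity_valid=sens >= 0,
        error_covariance=err_cov,
        ecc=ecc,
        ecc_valid=ecc_ok,
        n_samples=n,
        method="ec",
    )


def grid_error_estimation(
    cubes: dict,
    method: str = "eivd",
    ecc_pair: tuple | None = None,
    ecc_pairs=None,
    min_samples: int = MIN_SAMPLES,
):
    """Run a collocation estimator independently at every grid pixel.

    ``cubes`` maps product id to an (time, lat, lon) :class:`xarray.DataArray`
    on a shared grid.  Returns an :class:`xarray.Dataset` with per-product
    ``error_variance_<id>`` and ``sensitivity_<id>`` layers, an ``ecc`` layer
    when a pair is declared, a ``valid`` mask, and summary statistics
    (mean +/- sd over valid pixels) in ``attrs``.
    """
    import xarray as xr

    ids = list(cubes)
    first = cubes[ids[0]]
    for pid in ids[1:]:
        c = cubes[pid]
        if c.shape != first.shape or not (
            np.array_equal(c["lat"], first["lat"])
            and np.array_equal(c["lon"], first["lon"])
        ):
            raise CollocationError(f"grid mismatch between {ids[0]} and {pid}")

    nlat, nlon = first.sizes["lat"], first.sizes["lon"]
    stack = np.stack([cubes[pid].values for pid in ids])  # (N, T, lat, lon)

    var_maps = np.full((len(ids), nlat, nlon), np.nan)
    sens_maps = np.full((len(ids), nlat, nlon), np.nan)
    ecc_map = np.full((nlat, nlon), np.nan)
    valid_map = np.zeros((nlat, nlon), dtype=bool)

    for i in range(nlat):
        for j in range(nlon):
            vals = stack[:, :, i, j]
            mask = np.isfinite(vals)
            if not mask.all(axis=0).sum():
                continue
            series = CollocatedSeries(
                product_ids=ids,
                times=np.arange(vals.shape[1]),
                values=np.where(mask, vals, np.nan),
                valid_mask=mask,
            )
            try:
                if method == "tc":
                    em = tc_error_variances(series, min_samples=min_samples)
                elif method == "eivd":
                    em = eivd_estimate(series, ecc_pair, min_samples=min_samples)
                elif method == "ec":
                    em = ec_quadruplet_estimate(
                        series, ecc_pairs or [], min_samples=min_samples
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except CollocationError:
                continue
            if not em.valid:
                continue
            for k, pid in enumerate(ids):
                m = em.product_ids.index(pid)
                var_maps[k, i, j] = em.error_variance[m]
                sens_maps[k, i, j] = em.sensitivity[m]
            if em.ecc:
                ecc_map[i, j] = next(iter(em.ecc.values()))
            valid_map[i, j] = bool(em.variance_valid.all())

    coords = {"lat": first["lat"].values, "lon": first["lon"].values}
    data = {}
    for k, pid in enumerate(ids):
        data[f"error_variance_{pid}"] = (("lat", "lon"), var_maps[k])
        data[f"sensitivity_{pid}"] = (("lat", "lon"), sens_maps[k])
    data["ecc"] = (("lat", "lon"), ecc_map)
    data["valid"] = (("lat", "lon"), valid_map)
    ds = xr.Dataset(data, coords=coords)
    summary = {}
    for k, pid in enumerate(ids):
        vals = var_maps[k][valid_map]
        if vals.size:
            summary[f"error_variance_{pid}_mean"] = float(np.mean(vals))
            summary[f"error_variance_{pid}_sd"] = float(np.std(vals))
    ds.attrs.update(summary)
    ds.attrs["method"] = method
    return ds
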