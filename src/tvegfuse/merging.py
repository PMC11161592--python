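"""MSE-optimal merging of collocated products from their error covariance.

Given the error covariance matrix Sigma of N products (diagonal: random
error variances; off-diagonal: error covariances of correlated pairs), the
weights minimising the merged estimate's error variance subject to
sum(w) = 1 are

    W = Sigma^-1 1 / (1^T Sigma^-1 1),      var_merged = (1^T Sigma^-1 1)^-1.

Closed forms for the two-product (independent errors) and three-product
(one correlated pair) cases are provided and agree with the matrix solution
to machine precision.  Products are rescaled into a common data space before
weighting; weights falling outside [0, 1] or built from invalid error
estimates are repaired by explicit, recorded fallbacks (subset recompute,
then equal weights), never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collocation import CollocatedSeries, CollocationError, ErrorModel, tc_rescale

__all__ = [
    "WeightVector",
    "optimal_weights",
    "weights_duo",
    "weights_trio_ecc",
    "sanitize_weights",
    "merge_series",
    "merge_grid",
]


@dataclass
class WeightVector:
    """Merging weights with provenance.

    ``weights`` sum to 1 over the products listed in ``product_ids``;
    ``predicted_error_variance`` is the merged random-error variance implied
    by the covariance matrix the weights were derived from.
    """

    product_ids: list
    weights: np.ndarray
    method: str = "general"
    fallback_applied: bool = False
    fallback_reason: str = ""
    predicted_error_variance: float = np.nan
    reference_product: object = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def weight_of(self, product_id) -> float:
        return float(self.weights[self.product_ids.index(product_id)])

    @property
    def in_range(self) -> bool:
        return bool(np.all((self.weights >= 0) & (self.weights <= 1)))


def optimal_weights(error_cov: np.ndarray, product_ids=None) -> WeightVector:
    """Minimum-MSE weights from a full N x N error covariance matrix.

    Falls back to equal weights (recorded) when the matrix is singular or
    not positive definite enough to invert reliably.
    """
    cov = np.asarray(error_cov, dtype=float)
    n = cov.shape[0]
    ids = list(product_ids) if product_ids is not None else list(range(n))
    ones = np.ones(n)
    if not np.all(np.isfinite(cov)):
        return WeightVector(
            ids, ones / n, method="simple_average",
            fallback_applied=True, fallback_reason="non-finite covariance matrix",
        )
    sv = np.linalg.svd(cov, compute_uv=False)
    if sv[-1] <= 1e-12 * max(sv[0], 1e-300):
        return WeightVector(
            ids, ones / n, method="simple_average",
            fallback_applied=True, fallback_reason="singular covariance matrix",
        )
    sol = np.linalg.solve(cov, ones)
    denom = ones @ sol
    w = sol / denom
    return WeightVector(
        ids, w, method="general",
        predicted_error_variance=float(1.0 / denom),
    )


def weights_duo(var1: float, var2: float, product_ids=None) -> WeightVector:
    """Inverse-variance weights for two products with independent errors."""
    ids = list(product_ids) if product_ids is not None else [0, 1]
    if not (var1 > 0 and var2 > 0) or not np.isfinite(var1 + var2):
        return WeightVector(
            ids, np.array([0.5, 0.5]), method="simple_average",
            fallback_applied=True, fallback_reason="non-positive error variance",
        )
    total = var1 + var2
    w = np.array([var2 / total, var1 / total])
    return WeightVector(
        ids, w, method="duo",
        predicted_error_variance=float(var1 * var2 / total),
    )


def weights_trio_ecc(
    var1: float, var2: float, var3: float, cov12: float, product_ids=None
) -> WeightVector:
    """Closed-form weights for three products with one correlated pair (1, 2).

    With d = var1*var2 - cov12^2 and normaliser
    z = (var1 + var2 - 2 cov12)/d + 1/var3:

        w1 = (var2 - cov12) / (d z),  w2 = (var1 - cov12) / (d z),
        w3 = 1 / (var3 z).

    Identical to :func:`optimal_weights` on the block covariance matrix.
    """
    ids = list(product_ids) if product_ids is not None else [0, 1, 2]
    det = var1 * var2 - cov12**2
    if not (var1 > 0 and var2 > 0 and var3 > 0) or det <= 0:
        return WeightVector(
            ids, np.full(3, 1.0 / 3.0), method="simple_average",
            fallback_applied=True,
            fallback_reason="degenerate error covariance block",
        )
    z = (var1 + var2 - 2.0 * cov12) / det + 1.0 / var3
    w = np.array(
        [
            (var2 - cov12) / (det * z),
            (var1 - cov12) / (det * z),
            1.0 / (var3 * z),
        ]
    )
    return WeightVector(
        ids, w, method="trio_ecc",
        predicted_error_variance=float(1.0 / z),
    )


def sanitize_weights(
    raw: WeightVector,
    error_model: ErrorModel,
    covariance: np.ndarray | None = None,
) -> WeightVector:
    """Repair weights built from invalid estimates or falling outside [0, 1].

    Policy: drop products whose error-variance estimate is flagged invalid;
    if at least two remain, recompute optimal weights on the valid subset of
    the covariance matrix; if the result still leaves any weight outside
    [0, 1], fall back to equal weights over the valid products (the
    simple-average baseline).  Dropped products keep weight 0.  Every repair
    is recorded in ``fallback_applied`` / ``fallback_reason``.

    ``covariance`` overrides the error model's raw covariance matrix for the
    subset recompute (pass the reference-space matrix when the weights were
    derived there).
    """
    ids = list(raw.product_ids)
    valid = np.array(
        [
            bool(error_model.variance_valid[error_model.product_ids.index(p)])
            for p in ids
        ]
    )
    if valid.all() and raw.in_range and not raw.fallback_applied:
        return raw
    if not valid.any():
        raise CollocationError("no product has a valid error variance estimate")

    keep = [p for p, ok in zip(ids, valid) if ok]
    if len(keep) == 1:
        w = np.where(valid, 1.0, 0.0)
        return WeightVector(
            ids, w, method="simple_average", fallback_applied=True,
            fallback_reason="single valid product",
            predicted_error_variance=error_model.variance_of(keep[0]),
            reference_product=raw.reference_product,
        )

    full = covariance if covariance is not None else error_model.covariance_matrix()
    kidx = [error_model.product_ids.index(p) for p in keep]
    sub = full[np.ix_(kidx, kidx)]
    cand = optimal_weights(sub, product_ids=keep)
    if cand.in_range and not cand.fallback_applied:
        w = np.zeros(len(ids))
        for p, wi in zip(keep, cand.weights):
            w[ids.index(p)] = wi
        return WeightVector(
            ids, w, method=cand.method, fallback_applied=True,
            fallback_reason="recomputed on valid subset",
            predicted_error_variance=cand.predicted_error_variance,
            reference_product=raw.reference_product,
        )

    w = np.where(valid, 1.0 / valid.sum(), 0.0)
    sub_equal = w[valid] @ sub @ w[valid]
    return WeightVector(
        ids, w, method="simple_average", fallback_applied=True,
        fallback_reason="weights outside [0, 1]; equal-weight fallback",
        predicted_error_variance=float(sub_equal),
        reference_product=raw.reference_product,
    )


def rescale_covariance(error_model: ErrorModel, reference) -> np.ndarray:
    """Error covariance of the products after rescaling into a reference space.

    Rescaling product i into the data space of the reference multiplies its
    error by beta_ref / beta_i; the ratio is recovered from the estimated
    sensitivities as sqrt(sens_ref / sens_i).  Weights must be derived from
    this rescaled covariance so the merged variance prediction lives in the
    same space as the merged series.
    """
    sens = np.asarray(error_model.sensitivity, dtype=float)
    ref = error_model.product_ids.index(reference)
    if np.any(~np.isfinite(sens)) or np.any(sens <= 0):
        raise CollocationError("rescaling needs positive sensitivities for all products")
    d = np.sqrt(sens[ref] / sens)
    return d[:, None] * error_model.covariance_matrix() * d[None, :]


def choose_reference(error_model: ErrorModel):
    """Default reference data space: the product with largest sensitivity."""
    sens = np.where(
        error_model.sensitivity_valid, error_model.sensitivity, -np.inf
    )
    return error_model.product_ids[int(np.argmax(sens))]


def merge_series(
    series: CollocatedSeries,
    weights: WeightVector,
    reference,
    policy: str = "renormalize",
    min_samples: int = 2,
) -> np.ndarray:
    """Weighted combination of products after rescaling to a reference space.

    For three products the rescaling uses the covariance-ratio scheme; for
    other N, mean matching only.  Missing-data policy at each step:
    ``renormalize`` re-spreads the weights over the products present (keeps
    coverage), ``strict`` drops the step.  Steps with no product present are
    missing in the output.
    """
    if series.n_products == 3:
        scaled, _ = tc_rescale(series, reference, min_samples=min_samples)
        values = scaled.values
    else:
        mask = series.complete_mask
        means = np.array(
            [series.values[i, mask].mean() for i in range(series.n_products)]
        )
        ref_mean = means[series.index(reference)]
        values = series.values - means[:, None] + ref_mean

    w = np.array([weights.weight_of(p) for p in series.product_ids])
    ok = series.valid_mask & np.isfinite(values)
    vals = np.where(ok, values, 0.0)
    wmat = np.where(ok, w[:, None], 0.0)
    wsum = wmat.sum(axis=0)
    merged = np.full(series.values.shape[1], np.nan)
    if policy == "renormalize":
        use = wsum > 0
        merged[use] = (wmat[:, use] * vals[:, use]).sum(axis=0) / wsum[use]
    elif policy == "strict":
        use = ok.all(axis=0)
        merged[use] = (w[:, None] * vals[:, use].reshape(len(w), -1)).sum(axis=0)
    else:
        raise ValueError(f"unknown missing-data policy {policy!r}")
    return merged


def merge_grid(
    cubes: dict,
    error_field,
    ecc_pair: tuple | None = None,
    policy: str = "renormalize",
    min_samples: int = 2,
):
    """Merge gridded products with static per-pixel weights.

    ``error_field`` is the Dataset produced by
    :func:`~tvegfuse.collocation.grid_error_estimation`.  Returns
    ``(merged, weight_maps, dominant)``: the merged cube, one weight layer
    per product, and the argmax-weight dominance layer (integer index into
    the product list, -1 where masked).  Pixels whose error estimation
    failed are masked in the output.
    """
    import xarray as xr

    ids = list(cubes)
    first = cubes[ids[0]]
    nlat, nlon = first.sizes["lat"], first.sizes["lon"]
    nt = first.sizes["time"]
    stack = np.stack([cubes[pid].values for pid in ids])

    merged = np.full((nt, nlat, nlon), np.nan)
    wmaps = np.full((len(ids), nlat, nlon), np.nan)
    dominant = np.full((nlat, nlon), -1, dtype=int)
    pred_var = np.full((nlat, nlon), np.nan)
    n_fallback = 0

    for i in range(nlat):
        for j in range(nlon):
            if not bool(error_field["valid"].values[i, j]):
                continue
            var = np.array(
                [float(error_field[f"error_variance_{p}"].values[i, j]) for p in ids]
            )
            sens = np.array(
                [float(error_field[f"sensitivity_{p}"].values[i, j]) for p in ids]
            )
            var_ok = np.isfinite(var) & (var > 0)
            if var_ok.sum() < 2:
                continue
            cov = np.diag(np.where(var_ok, var, np.nan))
            if ecc_pair is not None:
                a, b = ids.index(ecc_pair[0]), ids.index(ecc_pair[1])
                c = float(error_field["ecc"].values[i, j]) * np.sqrt(var[a] * var[b])
                if np.isfinite(c):
                    cov[a, b] = cov[b, a] = c
            em = ErrorModel(
                product_ids=ids,
                error_variance=var,
                sensitivity=sens,
                variance_valid=var_ok,
                sensitivity_valid=np.isfinite(sens) & (sens > 0),
                error_covariance=(
                    {tuple(ecc_pair): cov[a, b]}
                    if ecc_pair is not None and np.isfinite(cov[a, b])
                    else {}
                ),
            )
            ref = ids[int(np.argmax(np.where(np.isfinite(sens), sens, -np.inf)))]
            try:
                wcov = rescale_covariance(em, ref)
            except CollocationError:
                wcov = np.nan_to_num(cov, nan=0.0)
            raw = optimal_weights(np.nan_to_num(wcov, nan=0.0), product_ids=ids)
            try:
                w = sanitize_weights(raw, em, covariance=np.nan_to_num(wcov, nan=0.0))
            except CollocationError:
                continue
            if w.fallback_applied:
                n_fallback += 1
            vals = stack[:, :, i, j]
            series = CollocatedSeries(
                product_ids=ids,
                times=np.arange(nt),
                values=vals,
                valid_mask=np.isfinite(vals),
            )
            try:
                merged[:, i, j] = merge_series(
                    series, w, ref, policy=policy, min_samples=min_samples
                )
            except CollocationError:
                continue
            wmaps[:, i, j] = w.weights
            dominant[i, j] = int(np.argmax(w.weights))
            pred_var[i, j] = w.predicted_error_variance

    coords = {
        "time": first["time"].values,
        "lat": first["lat"].values,
        "lon": first["lon"].values,
    }
    merged_da = xr.DataArray(
        merged, coords=coords, dims=("time", "lat", "lon"), name="Ec",
        attrs={"units": "mm day-1", "long_name": "merged vegetation transpiration"},
    )
    wds = {}
    for k, pid in enumerate(ids):
        wds[f"weight_{pid}"] = (("lat", "lon"), wmaps[k])
    wds["predicted_error_variance"] = (("lat", "lon"), pred_var)
    weight_maps = xr.Dataset(
        wds, coords={"lat": coords["lat"], "lon": coords["lon"]},
        attrs={"n_fallback_pixels": n_fallback, "products": ids},
    )
    dominant_da = xr.DataArray(
        dominant, coords={"lat": coords["lat"], "lon": coords["lon"]},
        dims=("lat", "lon"), name="dominant_product",
        attrs={"legend": {str(k): pid for k, pid in enumerate(ids)}},
    )
    return merged_da, weight_maps, dominant_da
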