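"""End-to-end merging pipeline: harmonize -> estimate -> weight -> merge -> write.

Driven by a YAML/dict config::

    products:               # >= 2 entries; >= 3 for collocation estimation
      gldas: {path: gldas.nc, variable: Ec}
      gleam: {path: gleam.nc, variable: Ec}
      pmlv2: {path: pmlv2.nc, variable: Ec}
    ecc_pair: [gldas, gleam]   # the declared correlated-error pair
    method: eivd               # eivd | tc
    step_days: 8               # native time step, days
    start_year: 2000
    output_dir: out/
    min_samples: 100
    policy: renormalize        # missing-data policy at merge time
    daily_output: false

Outputs: one ``Merged.Tveg.<year>.nc`` per calendar year covered, weight and
dominance maps (``weights.nc``), the per-pixel error field (``errors.nc``)
and a JSON run report with validity and fallback counters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from . import collocation, gridio, merging

__all__ = ["PipelineConfigError", "load_config", "run_pipeline"]


class PipelineConfigError(ValueError):
    """Configuration problems detected before any computation."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> dict:
    cfg = dict(config)
    products = cfg.get("products")
    if not products or len(products) < 2:
        raise PipelineConfigError("config must name at least two products")
    cfg.setdefault("method", "eivd")
    cfg.setdefault("step_days", 8)
    cfg.setdefault("start_year", 2000)
    cfg.setdefault("min_samples", collocation.MIN_SAMPLES)
    cfg.setdefault("policy", "renormalize")
    cfg.setdefault("daily_output", False)
    cfg.setdefault("variable", "Ec")
    if "output_dir" not in cfg:
        raise PipelineConfigError("config must set output_dir")
    pair = cfg.get("ecc_pair")
    if cfg["method"] == "eivd":
        if len(products) != 3:
            raise PipelineConfigError("EIVD estimation needs exactly three products")
        if not pair or len(pair) != 2 or any(p not in products for p in pair):
            raise PipelineConfigError(
                f"ecc_pair {pair} must name two of the configured products "
                f"{sorted(products)}"
            )
    return cfg


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the full merging chain; returns the run report dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate(config)

    products = cfg["products"]
    ids = list(products)
    cubes = {}
    for pid, spec in products.items():
        if isinstance(spec, (str, Path)):
            spec = {"path": spec}
        cubes[pid] = gridio.read_product(
            spec["path"], spec.get("variable", cfg["variable"])
        )

    # harmonize onto the first product's grid when needed
    ref = cubes[ids[0]]
    for pid in ids[1:]:
        c = cubes[pid]
        if c.sizes["lat"] != ref.sizes["lat"] or c.sizes["lon"] != ref.sizes["lon"] or not (
            np.allclose(c["lat"], ref["lat"]) and np.allclose(c["lon"], ref["lon"])
        ):
            cubes[pid] = gridio.regrid(c, ref["lat"].values, ref["lon"].values)

    report = {"products": ids, "method": cfg["method"], "config": {
        k: v for k, v in cfg.items() if k != "products"
    }}

    if len(ids) == 2:
        # duo path: no collocation estimate possible; equal-information duo
        # weights need externally supplied variances, so fall back to the
        # simple average with a recorded reason.
        merged = (cubes[ids[0]] + cubes[ids[1]]) / 2.0
        report.update({"weight_method": "duo", "note": "two products: simple average"})
        error_field = None
        weight_maps = None
        dominant = None
    else:
        error_field = collocation.grid_error_estimation(
            cubes,
            method=cfg["method"],
            ecc_pair=tuple(cfg["ecc_pair"]) if cfg.get("ecc_pair") else None,
            min_samples=cfg["min_samples"],
        )
        merged, weight_maps, dominant = merging.merge_grid(
            cubes,
            error_field,
            ecc_pair=tuple(cfg["ecc_pair"]) if cfg.get("ecc_pair") else None,
            policy=cfg["policy"],
        )
        n_pix = error_field["valid"].size
        n_valid = int(error_field["valid"].values.sum())
        report.update(
            {
                "weight_method": "trio_ecc" if cfg.get("ecc_pair") else "general",
                "pixels_total": int(n_pix),
                "pixels_valid": n_valid,
                "pixels_masked": int(n_pix - n_valid),
                "pixels_fallback": int(weight_maps.attrs["n_fallback_pixels"]),
                "error_summary": {
                    k: v for k, v in error_field.attrs.items() if k != "method"
                },
            }
        )

    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    step = int(cfg["step_days"])
    steps_per_year = max(1, int(np.ceil(365 / step)))
    n_steps = merged.sizes["time"]
    paths = []
    for chunk_start in range(0, n_steps, steps_per_year):
        year = cfg["start_year"] + chunk_start // steps_per_year
        chunk = merged.isel(time=slice(chunk_start, chunk_start + steps_per_year))
        days = 1 + step * np.arange(chunk.sizes["time"])
        chunk = chunk.assign_coords(time=days)
        path = gridio.write_merged(
            chunk, out_dir, year, overwrite=True, daily=cfg["daily_output"]
        )
        paths.append(str(path))

    if error_field is not None:
        gridio._to_netcdf(error_field, out_dir / "errors.nc")
        wm = weight_maps.copy()
        wm.attrs = {"products": " ".join(ids)}
        wm["dominant_product"] = dominant.reset_coords(drop=True).astype(np.int32)
        wm["dominant_product"].attrs = {}
        gridio._to_netcdf(wm, out_dir / "weights.nc")

    report["merged_files"] = paths
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
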