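"""End-to-end pipeline driver.

Sequences the stages simulate/ingest -> preprocess -> TVDI -> trend ->
sensitivity and writes every product (rasters, tables, manifest) under
one output directory. The manifest records the configuration, the seed
and a checksum per output file so a run can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from . import preprocess, sensitivity, synthetic, trend, tvdi
from .stacks import MonthlyStack, SynthConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

_CONFIG_FIELDS = {
    "input_dir": str,
    "out_dir": str,
    "seed": int,
    "n_rows": int,
    "n_cols": int,
    "n_years": int,
    "sg_enabled": bool,
    "sg_window": int,
    "sg_order": int,
    "ndvi_threshold": float,
    "resample_factor": int,
    "bin_width": float,
    "min_count": int,
    "z_threshold": float,
    "p_threshold": float,
    "min_months": int,
    "normalize_weights": bool,
    "gs_months": str,
    "gapfill_n_s": int,
    "log_level": str,
}


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    ``input_dir`` empty means "simulate": synthetic stacks are generated
    from the grid/seed fields. ``gs_months`` is the growing-season month
    set for the memory-gradient regressions.
    """

    input_dir: str = ""
    out_dir: str = "ecosens_out"
    seed: int = 0
    n_rows: int = 30
    n_cols: int = 30
    n_years: int = 19
    #: Savitzky-Golay smoothing targets sub-monthly composites; monthly
    #: inputs (including synthetic scenes) are already composited, and a
    #: multi-month filter would inject artificial lag-1 autocorrelation
    #: into the memory estimate, so it is off by default here.
    sg_enabled: bool = False
    sg_window: int = 7
    sg_order: int = 2
    ndvi_threshold: float = 0.1
    resample_factor: int = 1
    bin_width: float = 0.02
    min_count: int = 10
    z_threshold: float = 1.96
    p_threshold: float = 0.1
    min_months: int = 36
    normalize_weights: bool = True
    gs_months: str = "5,6,7,8,9"
    gapfill_n_s: int = 61
    log_level: str = "INFO"

    def gs_month_list(self) -> list[int]:
        return [int(m) for m in self.gs_months.split(",") if m.strip()]

    # -- plain key-value config file --------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{name} = {getattr(self, name)}" for name in _CONFIG_FIELDS
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _CONFIG_FIELDS:
                raise ValueError(f"line {lineno}: unknown key {key!r}")
            caster = _CONFIG_FIELDS[key]
            if caster is bool:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = caster(value)
        return cls(**kwargs)

    def params_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_grid(grid: np.ndarray, time_like: MonthlyStack, tag: str, path: Path) -> Path:
    stack = MonthlyStack(
        values=np.asarray(grid, dtype=float)[None, :, :],
        time_index=[time_like.time_index[0]],
        geotransform=time_like.geotransform,
        variable_tag=tag,
    )
    return eio.write_stack(stack, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory results dict.

    Results include the manifest path, all intermediate stacks and the
    final rasters (alpha, climate weights, variability and sensitivity
    scores, VSI). Outputs are written under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    results: dict = {"config": config}

    # -- stage 1: simulate or ingest --------------------------------
    if config.input_dir:
        src = Path(config.input_dir)
        stacks = {
            tag: eio.read_stack(src / f"{tag}.tif")
            for tag in ("ndvi", "tem", "pre", "lst")
        }
        logger.info("ingested 4 stacks from %s", src)
    else:
        synth_cfg = SynthConfig(
            n_rows=config.n_rows,
            n_cols=config.n_cols,
            n_years=config.n_years,
            seed=derive_seed(config.seed, "simulate"),
        )
        scene = synthetic.generate_scene(synth_cfg)
        stacks = {
            "ndvi": scene["ndvi"],
            "tem": scene["tem"],
            "pre": scene["pre"],
            "lst": scene["lst_gapped"],
        }
        results["truth"] = scene["truth"]
        truth_path = out_dir / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "alpha": float(np.mean(scene["truth"]["alpha"])),
                    "beta": float(np.mean(scene["truth"]["beta"])),
                    "gamma": float(np.mean(scene["truth"]["gamma"])),
                    "delta": float(np.mean(scene["truth"]["delta"])),
                    "seed": synth_cfg.seed,
                },
                indent=2,
            )
        )
        files.append(truth_path)
        logger.info("simulated %dx%d scene, %d months", config.n_rows, config.n_cols, synth_cfg.n_time)
    for tag, stack in stacks.items():
        files.append(eio.write_stack(stack, out_dir / f"{tag}.tif"))
        files.append(eio.sidecar_path(out_dir / f"{tag}.tif"))

    # -- stage 2: preprocess -----------------------------------------
    if config.sg_enabled:
        sg_spec = preprocess.SmoothingSpec(config.sg_window, config.sg_order)
        ndvi_s = preprocess.smooth_stack(stacks["ndvi"], sg_spec)
        ndvi_s = ndvi_s.copy_with(values=np.clip(ndvi_s.values, -1.0, 1.0))
    else:
        ndvi_s = stacks["ndvi"]
    lst_filled = preprocess.fill_stack(stacks["lst"], n_s=config.gapfill_n_s)
    if config.resample_factor > 1:
        lst_filled = preprocess.resample_stack(lst_filled, config.resample_factor)
    exclusion = preprocess.low_cover_month_mask(ndvi_s, config.ndvi_threshold)
    files.append(eio.write_stack(ndvi_s, out_dir / "ndvi_smoothed.tif"))
    files.append(eio.write_stack(lst_filled, out_dir / "lst_filled.tif"))
    logger.info(
        "preprocess: %d pixel-months excluded by NDVI<%g rule",
        int(exclusion.sum()), config.ndvi_threshold,
    )

    # -- stage 3: TVDI ------------------------------------------------
    tvdi_stack_, edge_rows = tvdi.tvdi_stack(
        ndvi_s, lst_filled, config.bin_width, config.min_count
    )
    files.append(eio.write_stack(tvdi_stack_, out_dir / "tvdi.tif"))
    edges_path = out_dir / "tvdi_edges.csv"
    pd.DataFrame(edge_rows).to_csv(edges_path, index=False)
    files.append(edges_path)
    results["tvdi"] = tvdi_stack_

    # -- stage 4: trend ------------------------------------------------
    annual = preprocess.maximum_value_composite(ndvi_s, period="year")
    rasters, summary = trend.trend_map(annual, config.z_threshold)
    mean_annual = np.nanmean(annual.masked(), axis=0)
    levels, level_summary = trend.level_map(mean_annual)
    for name in ("zc", "beta"):
        files.append(_write_grid(rasters[name], annual, name, out_dir / f"trend_{name}.tif"))
    trend_path = out_dir / "trend_summary.csv"
    pd.concat(
        [summary, level_summary.rename(columns={"level": "band"}).assign(partition="ndvi_level")[
            ["partition", "band", "fraction"]
        ]]
    ).to_csv(trend_path, index=False)
    files.append(trend_path)
    results["trend"] = {"rasters": rasters, "summary": summary, "levels": level_summary}

    # basin-mean climate trends (annual means; annual max NDVI handled above)
    climate_rows = []
    for tag, stack in (("tem", stacks["tem"]), ("pre", stacks["pre"]), ("tvdi", tvdi_stack_)):
        series = np.nanmean(stack.masked(), axis=(1, 2))
        years = sorted({y for y, _ in stack.time_index})
        annual_means = np.array(
            [np.nanmean(series[[i for i, (y, _) in enumerate(stack.time_index) if y == yr]]) for yr in years]
        )
        zc = trend.mk_z(annual_means)
        climate_rows.append(
            {"variable": tag, "zc": zc, "beta": trend.theil_sen(annual_means),
             "class": trend.classify_trend(zc, trend.theil_sen(annual_means), config.z_threshold)}
        )
    climate_path = out_dir / "climate_trends.csv"
    pd.DataFrame(climate_rows).to_csv(climate_path, index=False)
    files.append(climate_path)

    # -- stage 5: sensitivity / VSI -----------------------------------
    ndvi_z = sensitivity.detrend_and_standardize(ndvi_s, exclusion)
    tem_z = sensitivity.detrend_and_standardize(stacks["tem"])
    pre_z = sensitivity.detrend_and_standardize(stacks["pre"])
    tvdi_z = sensitivity.detrend_and_standardize(tvdi_stack_)
    ar1 = sensitivity.fit_ar1(ndvi_z, tem_z, pre_z, tvdi_z, config.min_months)
    raw_w, zero_flag = sensitivity.pcr_weights(
        ndvi_z, tem_z, pre_z, tvdi_z, config.p_threshold, config.min_months
    )
    weights = sensitivity.rescale_weights(raw_w, normalize=config.normalize_weights)

    used_mask = ndvi_z.used
    var_scores = {
        "ndvi": sensitivity.variability_scores(ndvi_s, used_mask),
        "tem": sensitivity.variability_scores(stacks["tem"], used_mask),
        "pre": sensitivity.variability_scores(stacks["pre"], used_mask),
        "tvdi": sensitivity.variability_scores(tvdi_stack_, used_mask),
    }
    sens = {
        var: sensitivity.sensitivity_scores(var_scores["ndvi"], var_scores[var])
        for var in sensitivity.CLIMATE_VARS
    }
    vsi, vsi_raw = sensitivity.compute_vsi(weights, sens)
    memory_classes, memory_fracs = sensitivity.memory_map(ar1.alpha)

    # growing-season covariates for the gradient regressions
    gs = set(config.gs_month_list())
    gradient_fits = []
    gs_cov = {}
    for tag, stack in (
        ("ndvi", ndvi_s), ("pre", stacks["pre"]), ("tem", stacks["tem"]), ("tvdi", tvdi_stack_)
    ):
        sel = [i for i, (_, m) in enumerate(stack.time_index) if m in gs]
        gs_cov[tag] = np.nanmean(stack.masked()[sel], axis=0)
    for tag, form in (
        ("ndvi", "logarithmic"), ("tvdi", "logarithmic"),
        ("pre", "quadratic"), ("tem", "quadratic"),
    ):
        try:
            fit = sensitivity.gradient_regression(ar1.alpha, gs_cov[tag], form)
        except ValueError as exc:
            logger.warning("gradient regression (%s) skipped: %s", tag, exc)
            continue
        gradient_fits.append(
            {"covariate": tag, "form": form, "r2": fit["r2"], "p_value": fit["p_value"],
             **{f"c{i}": c for i, c in enumerate(fit["coefficients"])}}
        )
    grad_path = out_dir / "gradient_fits.csv"
    pd.DataFrame(gradient_fits).to_csv(grad_path, index=False)
    files.append(grad_path)

    for name, grid in (
        ("alpha", ar1.alpha), ("beta_tem", ar1.beta_tem),
        ("gamma_pre", ar1.gamma_pre), ("delta_tvdi", ar1.delta_tvdi),
        ("vsi", vsi),
    ):
        files.append(_write_grid(grid, ndvi_s, name, out_dir / f"{name}.tif"))
    for k, var in enumerate(sensitivity.CLIMATE_VARS):
        files.append(_write_grid(weights.normalized[k], ndvi_s, f"{var}_wei", out_dir / f"weight_{var}.tif"))
        files.append(_write_grid(sens[var], ndvi_s, f"{var}_sens", out_dir / f"sens_{var}.tif"))

    rgb = eio.weights_rgb(weights)
    rgb_path = out_dir / "weights_rgb.tif"
    import tifffile as _tf

    _tf.imwrite(rgb_path, np.moveaxis(rgb, 0, -1))
    files.append(rgb_path)

    # VSI histogram (counts per 5-unit bin) and summary table
    valid_vsi = vsi[np.isfinite(vsi)]
    hist, edges_h = np.histogram(valid_vsi, bins=20, range=(0, 100))
    hist_path = out_dir / "vsi_histogram.csv"
    pd.DataFrame({"bin_lower": edges_h[:-1], "bin_upper": edges_h[1:], "count": hist}).to_csv(
        hist_path, index=False
    )
    files.append(hist_path)
    summary_path = out_dir / "vsi_summary.csv"
    pd.DataFrame(
        [
            {"metric": "vsi_min", "value": float(valid_vsi.min())},
            {"metric": "vsi_max", "value": float(valid_vsi.max())},
            {"metric": "vsi_mean", "value": float(valid_vsi.mean())},
            {"metric": "vsi_share_below_30", "value": float(np.mean(valid_vsi < 30))},
            {"metric": "n_valid_pixels", "value": int(valid_vsi.size)},
            {"metric": "n_zero_weight_pixels", "value": int(zero_flag.sum())},
            {"metric": "n_ar1_dropped", "value": int(ar1.n_dropped)},
            *[
                {"metric": f"memory_frac_{name}", "value": frac}
                for name, frac in memory_fracs.items()
            ],
        ]
    ).to_csv(summary_path, index=False)
    files.append(summary_path)

    results.update(
        {
            "stacks": stacks,
            "ndvi_smoothed": ndvi_s,
            "lst_filled": lst_filled,
            "exclusion": exclusion,
            "standardized": {"ndvi": ndvi_z, "tem": tem_z, "pre": pre_z, "tvdi": tvdi_z},
            "ar1": ar1,
            "raw_weights": raw_w,
            "weights": weights,
            "variability": var_scores,
            "sensitivity": sens,
            "vsi": vsi,
            "vsi_raw": vsi_raw,
            "memory": {"classes": memory_classes, "fractions": memory_fracs},
            "gradient_fits": gradient_fits,
        }
    )

    manifest = {
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(set(files))},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    return results
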