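"""Synthetic monthly climate/NDVI/LST scenes with known ground truth.

The generator emulates the study conditions of a mid-latitude arid basin
observed for 19 years (228 months): an elevation gradient that organises
all spatial fields (greener, wetter, cooler towards the "mountain" rows),
seasonal cycles peaking in July, weak linear trends, white observation
noise, random data gaps in LST, and NDVI anomalies produced by the same
lag-1 (AR1) regression that the analysis pipeline later fits::

    a_t = alpha * a_{t-1} + beta * z_tem_t + gamma * z_pre_t
          + delta * z_moist_t + eps_t,     eps_t ~ N(0, noise_sd^2)

where the ``z`` drivers are the per-calendar-month standardized anomalies
of the generated climate stacks and ``z_moist`` is either TVDI computed
from the generated LST/NDVI climatology (default) or the LST anomaly
itself. Anomalies are re-embedded as
``NDVI = climatology + a_t * climatological_SD`` so that the downstream
de-trend/z-score standardization recovers them (up to the per-month
re-normalization inherent in z-scoring).

Every output is a deterministic function of the :class:`SynthConfig` seed.
"""

from __future__ import annotations

import numpy as np

from .stacks import IDENTITY_TRANSFORM, MonthlyStack, SynthConfig
from . import tvdi as tvdi_mod

__all__ = [
    "generate_climate_stacks",
    "generate_ndvi",
    "generate_scene",
    "inject_gaps",
    "ndvi_climatology",
]

_PEAK_MONTH = 7  # seasonal maximum (July, northern hemisphere)


def _seasonal_factor(months: np.ndarray) -> np.ndarray:
    """Cosine annual cycle in [-1, 1] peaking at July."""
    return np.cos(2.0 * np.pi * (months - _PEAK_MONTH) / 12.0)


def _elevation_field(config: SynthConfig) -> np.ndarray:
    """Normalized elevation in [0, 1], high at row 0 (north), low in the south."""
    rows = np.linspace(1.0, 0.0, config.n_rows)[:, None]
    ramp = np.broadcast_to(rows, (config.n_rows, config.n_cols)).copy()
    # mild deterministic east-west undulation so fields are not rank-1
    cols = np.linspace(0.0, 1.0, config.n_cols)[None, :]
    ramp += 0.08 * np.sin(2.0 * np.pi * cols * 1.5)
    ramp *= config.elevation_gradient
    lo, hi = ramp.min(), ramp.max()
    return (ramp - lo) / (hi - lo) if hi > lo else np.zeros_like(ramp)


def _greenness_field(config: SynthConfig) -> np.ndarray:
    """Long-term vegetation cover in [0.15, 0.8]; greener at high elevation."""
    elev = _elevation_field(config)
    return 0.15 + 0.65 * elev


def ndvi_climatology(config: SynthConfig) -> np.ndarray:
    """Seasonal NDVI climatology cube (n_time, rows, cols).

    Winter values at sparsely vegetated pixels drop below the 0.1
    low-cover threshold, exercising the month-exclusion rule downstream.
    """
    g = _greenness_field(config)
    months = np.array([m for _, m in config.time_index()])
    season = _seasonal_factor(months)[:, None, None]
    amp = config.seasonal_amplitude.get("ndvi", 0.25)
    clim = g[None, :, :] * (1.0 - amp + amp * season)
    return np.clip(clim, -1.0, 1.0)


def _anomaly_sd(config: SynthConfig) -> np.ndarray:
    """Climatological SD cube used to re-embed NDVI anomalies."""
    g = _greenness_field(config)
    months = np.array([m for _, m in config.time_index()])
    season = _seasonal_factor(months)[:, None, None]
    # variability scales with cover and season, floors at 0.01
    return 0.01 + 0.05 * g[None, :, :] * (0.6 + 0.4 * season)


def generate_climate_stacks(
    config: SynthConfig,
) -> tuple[MonthlyStack, MonthlyStack, MonthlyStack]:
    """Generate air-temperature (degC), precipitation (mm/month) and LST (K).

    Each stack is ``spatial base + seasonal cycle + linear trend + noise``.
    LST carries a negative dependence on the vegetation base field so a
    dry edge exists in NDVI-LST space; precipitation is clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    elev = _elevation_field(config)
    g = _greenness_field(config)
    tidx = config.time_index()
    months = np.array([m for _, m in tidx])
    n_t = config.n_time
    years_frac = np.arange(n_t) / 12.0
    season = _seasonal_factor(months)

    bases = {
        "tem": 12.0 - 14.0 * elev,  # warm plains, cold mountains
        "pre": 8.0 + 25.0 * elev,  # orographic precipitation gradient
        "lst": 300.0 + 12.0 * (1.0 - g),  # bare ground runs hot: dry edge
    }
    stacks = []
    for tag in ("tem", "pre", "lst"):
        amp = config.seasonal_amplitude.get(tag, 0.0)
        trend = config.linear_trend.get(tag, 0.0)
        sd = config.climate_noise_sd.get(tag, 0.0)
        cube = (
            bases[tag][None, :, :]
            + amp * season[:, None, None]
            + trend * years_frac[:, None, None]
        )
        if sd > 0:
            cube = cube + rng.normal(0.0, sd, size=cube.shape)
        if tag == "pre":
            cube = np.clip(cube, 0.0, None)
        stacks.append(
            MonthlyStack(
                values=cube,
                time_index=tidx,
                geotransform=IDENTITY_TRANSFORM,
                variable_tag=tag,
            )
        )
    return tuple(stacks)


def _standardize_cube(values: np.ndarray) -> np.ndarray:
    """De-trend each pixel series then z-score per calendar month.

    Generative counterpart of the pipeline's standardization; operates on
    gap-free cubes whose length is a whole number of years.
    """
    n_t = values.shape[0]
    t = np.arange(n_t, dtype=float)
    t_c = t - t.mean()
    flat = values.reshape(n_t, -1)
    slope = (t_c @ (flat - flat.mean(axis=0))) / (t_c @ t_c)
    detr = flat - flat.mean(axis=0) - np.outer(t_c, slope)
    detr = detr.reshape(values.shape)
    z = np.empty_like(detr)
    months = np.arange(n_t) % 12
    for m in range(12):
        sel = months == m
        block = detr[sel]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        z[sel] = (block - mu) / sd
    return z


def generate_ndvi(
    config: SynthConfig,
    tem: MonthlyStack,
    pre: MonthlyStack,
    moisture: MonthlyStack,
) -> tuple[MonthlyStack, dict]:
    """Generate NDVI by running the lag-1 anomaly recursion forward.

    ``moisture`` is a TVDI stack (default driver) or the LST stack.
    Returns the NDVI stack and a ``truth`` dict holding the raw anomaly
    cube, the standardized driver cubes and the coefficient grids —
    the oracle surface for parameter-recovery tests.
    """
    for stk in (tem, pre, moisture):
        if stk.shape != (config.n_time, config.n_rows, config.n_cols):
            raise ValueError("predictor stacks must match the configured grid")
    rng = np.random.default_rng(config.seed + 1)
    alpha = config.coeff_grid("alpha")
    beta = config.coeff_grid("beta")
    gamma = config.coeff_grid("gamma")
    delta = config.coeff_grid("delta")

    z_tem = _standardize_cube(tem.values)
    z_pre = _standardize_cube(pre.values)
    z_moist = _standardize_cube(moisture.values)

    n_t = config.n_time
    shape2d = (config.n_rows, config.n_cols)
    a = np.zeros((n_t, *shape2d))
    # stationary spin-up value (drivers treated as unit-variance white noise)
    stat_var = (beta**2 + gamma**2 + delta**2 + config.noise_sd**2) / (
        1.0 - alpha**2
    )
    a_prev = rng.normal(0.0, 1.0, size=shape2d) * np.sqrt(stat_var)
    eps = (
        rng.normal(0.0, config.noise_sd, size=(n_t, *shape2d))
        if config.noise_sd > 0
        else np.zeros((n_t, *shape2d))
    )
    for t in range(n_t):
        a_prev = (
            alpha * a_prev
            + beta * z_tem[t]
            + gamma * z_pre[t]
            + delta * z_moist[t]
            + eps[t]
        )
        a[t] = a_prev

    clim = ndvi_climatology(config)
    sd_cube = _anomaly_sd(config)
    ndvi_values = np.clip(clim + a * sd_cube, -1.0, 1.0)
    stack = MonthlyStack(
        values=ndvi_values,
        time_index=config.time_index(),
        geotransform=IDENTITY_TRANSFORM,
        variable_tag="ndvi",
    )
    truth = {
        "anomalies": a,
        "z_tem": z_tem,
        "z_pre": z_pre,
        "z_moist": z_moist,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "delta": delta,
        "climatology": clim,
        "anomaly_sd": sd_cube,
    }
    return stack, truth


def generate_scene(config: SynthConfig) -> dict:
    """Full synthetic scene: climate stacks, moisture driver, NDVI, gapped LST.

    Returns a dict with keys ``tem, pre, lst, lst_gapped, tvdi, ndvi,
    truth, gap_mask``. ``tvdi`` is present when the moisture driver is
    TVDI; it is computed scene-by-scene from the generated LST and the
    NDVI seasonal climatology, closing the loop the downstream
    regression assumes.
    """
    tem, pre, lst = generate_climate_stacks(config)
    out: dict = {"tem": tem, "pre": pre, "lst": lst}
    if config.moisture_driver == "tvdi":
        clim = ndvi_climatology(config)
        tvdi_vals = np.empty_like(lst.values)
        # per-bin pixel requirement scales with scene size; TVDI driving
        # needs a reasonably populated NDVI-LST scatter (>= ~100 pixels)
        min_count = max(2, (config.n_rows * config.n_cols) // 150)
        for t in range(config.n_time):
            edges = tvdi_mod.fit_edges(
                clim[t], lst.values[t], bin_width=0.02, min_count=min_count
            )
            tvdi_vals[t] = tvdi_mod.compute_tvdi(clim[t], lst.values[t], edges)
        moisture = MonthlyStack(
            values=tvdi_vals,
            time_index=config.time_index(),
            geotransform=IDENTITY_TRANSFORM,
            variable_tag="tvdi",
        )
        out["tvdi"] = moisture
    else:
        moisture = lst
    ndvi, truth = generate_ndvi(config, tem, pre, moisture)
    out["ndvi"] = ndvi
    out["truth"] = truth
    if config.gap_fraction > 0:
        gapped, gap_mask = inject_gaps(lst, config.gap_fraction, config.seed + 2)
        out["lst_gapped"] = gapped
        out["gap_mask"] = gap_mask
    else:
        out["lst_gapped"] = lst
        out["gap_mask"] = np.zeros(lst.shape, dtype=bool)
    return out


def truth_standardized(scene: dict) -> dict:
    """Wrap a scene's truth surface as standardized stacks for fitting.

    Returns ``{"ndvi", "tem", "pre", "moist"}`` mapped to
    :class:`~ecosens.sensitivity.StandardizedStack` objects built from the
    generative anomaly cube and driver z-scores. Fitting the lag-1
    regression on these recovers the configured coefficients on their
    native scale (exactly so when ``noise_sd = 0``), independent of the
    per-month re-normalization that Eq.-style z-scoring of the re-embedded
    NDVI would introduce.
    """
    from .sensitivity import StandardizedStack

    truth = scene["truth"]
    n_t, nr, nc = truth["anomalies"].shape
    tidx = list(scene["ndvi"].time_index)
    all_used = np.ones((n_t, nr, nc), dtype=bool)

    def _wrap(cube: np.ndarray) -> StandardizedStack:
        return StandardizedStack(
            z=cube,
            used=all_used,
            detrend_slopes=np.zeros((nr, nc)),
            time_index=tidx,
        )

    return {
        "ndvi": _wrap(truth["anomalies"]),
        "tem": _wrap(truth["z_tem"]),
        "pre": _wrap(truth["z_pre"]),
        "moist": _wrap(truth["z_moist"]),
    }


def inject_gaps(
    stack: MonthlyStack, gap_fraction: float, seed: int
) -> tuple[MonthlyStack, np.ndarray]:
    """Flag an exact count of uniformly random cells as nodata.

    The number of newly flagged cells is ``round(gap_fraction * n_cells)``
    (exact-count sampling without replacement, not Bernoulli trials).
    Returns the gapped stack and the boolean mask of injected gaps so
    tests can compare filled values against the withheld truth.
    """
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap_fraction must be in [0, 1)")
    gap_mask = np.zeros(stack.shape, dtype=bool)
    if gap_fraction > 0:
        rng = np.random.default_rng(seed)
        n_cells = int(np.prod(stack.shape))
        n_gaps = int(round(gap_fraction * n_cells))
        flat_idx = rng.choice(n_cells, size=n_gaps, replace=False)
        gap_mask.flat[flat_idx] = True
    return (
        stack.copy_with(nodata_mask=stack.nodata_mask | gap_mask),
        gap_mask,
    )
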