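"""Vegetation Sensitivity Index core.

Pipeline stages implemented here, per pixel unless stated otherwise:

1. **Standardization** — remove the linear trend from each monthly series,
   then z-score each calendar month across years:
   ``Z_{i,j} = (x_{i,j} - mean_j) / sd_j`` with ``j`` the calendar month
   and ``i`` the year. Months excluded by the low-NDVI rule become nodata.
2. **Lag-1 (AR1) regression** — ``NDVI_t = alpha*NDVI_{t-1} + beta*Tem_t
   + gamma*Pre_t + delta*TVDI_t + eps_t`` on standardized series, no
   intercept. ``alpha`` is the vegetation-memory coefficient (large
   |alpha| = strong memory = low resilience); beta/gamma/delta measure the
   immediate response to each climate variable.
3. **Climate weights** — principal-components regression of NDVI on the
   four predictors; components significant at p < 0.1 are kept, variable
   importance is |sum of loading x coefficient| over kept components.
   Importances are min-max rescaled to [0, 1] globally (one min and max
   over all three climate variables and all pixels) and then normalized
   per pixel to sum to 1.
4. **Variability scores** — residuals of the across-pixel mean-variance
   regression of each variable's de-trended monthly series, min-max
   standardized to [0, 100].
5. **Sensitivity scores** — ``log10((V_NDVI + 1) / (V_climate + 1))``
   per climate variable (the +1 offset guards zero scores).
6. **VSI** — ``VSI = Tem_wei*Tem_sens + Pre_wei*Pre_sens +
   TVDI_wei*TVDI_sens``, min-max rescaled to [0, 100] over the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .stacks import MonthlyStack

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedStack",
    "AR1FitRaster",
    "ClimateWeights",
    "detrend_and_standardize",
    "fit_ar1",
    "pcr_weights",
    "rescale_weights",
    "variability_scores",
    "sensitivity_scores",
    "compute_vsi",
    "memory_map",
    "gradient_regression",
]

#: fixed ordering of the climate variables throughout this module
CLIMATE_VARS = ("tem", "pre", "tvdi")

MEMORY_CLASSES = ("alpha<0.4", "0.4<=alpha<0.6", "alpha>=0.6")


@dataclass
class StandardizedStack:
    """Per-month z-scores of a de-trended monthly stack."""

    z: np.ndarray  # (n_time, nr, nc), NaN where unused
    used: np.ndarray  # boolean cube, True where a z-value exists
    detrend_slopes: np.ndarray  # (nr, nc) slope of the removed linear fit
    time_index: list[tuple[int, int]]
    n_zero_sd_dropped: int = 0


@dataclass
class AR1FitRaster:
    """Per-pixel coefficients of the lag-1 sensitivity regression."""

    alpha: np.ndarray
    beta_tem: np.ndarray
    gamma_pre: np.ndarray
    delta_tvdi: np.ndarray
    se: dict = field(default_factory=dict)  # same keys, standard errors
    resid_var: np.ndarray | None = None
    n_months: np.ndarray | None = None
    r2: np.ndarray | None = None
    n_dropped: int = 0


@dataclass
class ClimateWeights:
    """Rescaled relative importances of temperature, precipitation, TVDI.

    ``rescaled`` is the [0, 1] global min-max rescaling of the raw PCR
    importances; ``normalized`` additionally sums to 1 per pixel so the
    VSI is a convex combination of the three sensitivity scores.
    """

    rescaled: np.ndarray  # (3, nr, nc), order CLIMATE_VARS
    normalized: np.ndarray  # (3, nr, nc)
    is_normalized: bool = True
    degenerate: bool = False


def detrend_and_standardize(
    stack: MonthlyStack,
    exclusion_mask: np.ndarray | None = None,
    min_years: int = 3,
) -> StandardizedStack:
    """De-trend each pixel's monthly series and z-score per calendar month.

    ``exclusion_mask`` is a ``(12, nr, nc)`` boolean array (True =
    calendar month excluded at that pixel, e.g. the low-NDVI rule).
    Calendar months with zero across-year variance, or fewer than
    ``min_years`` usable years, are set nodata and counted.
    """
    vals = stack.masked()
    n_t, nr, nc = vals.shape
    months = stack.months
    t_axis = np.arange(n_t, dtype=float)
    z = np.full(vals.shape, np.nan)
    used = np.zeros(vals.shape, dtype=bool)
    slopes = np.full((nr, nc), np.nan)
    n_zero_sd = 0

    flat = vals.reshape(n_t, -1)
    z_flat = z.reshape(n_t, -1)
    used_flat = used.reshape(n_t, -1)
    excl = (
        exclusion_mask.reshape(12, -1)
        if exclusion_mask is not None
        else np.zeros((12, nr * nc), dtype=bool)
    )
    for p in range(nr * nc):
        y = flat[:, p].copy()
        # apply the per-calendar-month exclusion before anything else
        for m in range(12):
            if excl[m, p]:
                y[months == m + 1] = np.nan
        ok = np.isfinite(y)
        if ok.sum() < min_years * 2:
            continue
        t_ok = t_axis[ok]
        slope, intercept = np.polyfit(t_ok, y[ok], 1)
        slopes.flat[p] = slope
        detr = y - (slope * t_axis + intercept)
        sd_floor = 1e-9 * max(1.0, float(np.abs(y[ok]).max()))
        for m in range(12):
            sel = (months == m + 1) & ok
            n_m = int(sel.sum())
            if n_m < min_years:
                continue
            block = detr[sel]
            sd = block.std(ddof=1)
            if sd <= sd_floor:
                # constant month after detrending: every deviation is 0, so
                # the natural z-value is 0, but the month carries no signal
                # and is excluded from downstream regressions
                z_flat[sel, p] = 0.0
                n_zero_sd += 1
                continue
            z_flat[sel, p] = (block - block.mean()) / sd
            used_flat[sel, p] = True
    if n_zero_sd:
        logger.info("standardization dropped %d zero-variance months", n_zero_sd)
    return StandardizedStack(
        z=z,
        used=used,
        detrend_slopes=slopes,
        time_index=list(stack.time_index),
        n_zero_sd_dropped=n_zero_sd,
    )


def _lag_pairs(used_ndvi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (t, t-1) of consecutive usable months (no gap bridging)."""
    t = np.arange(1, used_ndvi.shape[0])
    return t, t - 1


def fit_ar1(
    ndvi_z: StandardizedStack,
    tem_z: StandardizedStack,
    pre_z: StandardizedStack,
    tvdi_z: StandardizedStack,
    min_months: int = 36,
) -> AR1FitRaster:
    """Least-squares fit of the lag-1 sensitivity regression at every pixel.

    Uses only lag pairs where month t-1 NDVI and all four variables at
    month t are valid (pairs spanning an excluded month are dropped).
    Pixels with fewer than ``min_months`` usable pairs, or a
    rank-deficient design, become nodata.
    """
    n_t, nr, nc = ndvi_z.z.shape
    coefs = {k: np.full((nr, nc), np.nan) for k in ("alpha", "beta_tem", "gamma_pre", "delta_tvdi")}
    ses = {k: np.full((nr, nc), np.nan) for k in coefs}
    resid_var = np.full((nr, nc), np.nan)
    n_months = np.zeros((nr, nc), dtype=int)
    r2 = np.full((nr, nc), np.nan)
    n_dropped = 0

    t_idx, lag_idx = _lag_pairs(ndvi_z.used)
    for r in range(nr):
        for c in range(nc):
            y_all = ndvi_z.z[:, r, c]
            ok = (
                ndvi_z.used[t_idx, r, c]
                & ndvi_z.used[lag_idx, r, c]
                & tem_z.used[t_idx, r, c]
                & pre_z.used[t_idx, r, c]
                & tvdi_z.used[t_idx, r, c]
            )
            n = int(ok.sum())
            if n < min_months:
                n_dropped += 1
                continue
            tt = t_idx[ok]
            X = np.column_stack(
                [
                    y_all[tt - 1],
                    tem_z.z[tt, r, c],
                    pre_z.z[tt, r, c],
                    tvdi_z.z[tt, r, c],
                ]
            )
            y = y_all[tt]
            xtx = X.T @ X
            if np.linalg.matrix_rank(xtx) < 4:
                n_dropped += 1
                continue
            b, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ b
            rss = float(resid @ resid)
            dof = n - 4
            sigma2 = rss / dof if dof > 0 else np.nan
            cov = sigma2 * np.linalg.inv(xtx)
            for k, key in enumerate(coefs):
                coefs[key][r, c] = b[k]
                ses[key][r, c] = np.sqrt(cov[k, k])
            resid_var[r, c] = sigma2
            n_months[r, c] = n
            tss = float(y @ y)  # no-intercept R^2 about zero
            r2[r, c] = 1.0 - rss / tss if tss > 0 else np.nan
    if n_dropped:
        logger.info("AR1 fit: %d pixels dropped (too few months or rank-deficient)", n_dropped)
    return AR1FitRaster(
        alpha=coefs["alpha"],
        beta_tem=coefs["beta_tem"],
        gamma_pre=coefs["gamma_pre"],
        delta_tvdi=coefs["delta_tvdi"],
        se=ses,
        resid_var=resid_var,
        n_months=n_months,
        r2=r2,
        n_dropped=n_dropped,
    )


def pcr_weights(
    ndvi_z: StandardizedStack,
    tem_z: StandardizedStack,
    pre_z: StandardizedStack,
    tvdi_z: StandardizedStack,
    p_threshold: float = 0.1,
    min_months: int = 36,
    include_lag: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-pixel climate importances by principal-components regression.

    Per pixel: principal components of the standardized predictors
    (lag-NDVI plus the three climate variables by default); NDVI_t is
    regressed on the component scores; components with coefficient
    p < ``p_threshold`` are selected; each variable's importance is
    ``|sum over selected components of loading x coefficient|``. Only
    the three climate importances are returned, in CLIMATE_VARS order,
    shape ``(3, nr, nc)``; the second return is a boolean raster flagging
    pixels where no component was significant (all-zero weights).
    """
    n_t, nr, nc = ndvi_z.z.shape
    raw = np.full((3, nr, nc), np.nan)
    zero_flag = np.zeros((nr, nc), dtype=bool)
    t_idx, lag_idx = _lag_pairs(ndvi_z.used)
    climate_rows = slice(1, 4) if include_lag else slice(0, 3)
    for r in range(nr):
        for c in range(nc):
            y_all = ndvi_z.z[:, r, c]
            ok = (
                ndvi_z.used[t_idx, r, c]
                & ndvi_z.used[lag_idx, r, c]
                & tem_z.used[t_idx, r, c]
                & pre_z.used[t_idx, r, c]
                & tvdi_z.used[t_idx, r, c]
            )
            n = int(ok.sum())
            if n < min_months:
                continue
            tt = t_idx[ok]
            cols = [
                tem_z.z[tt, r, c],
                pre_z.z[tt, r, c],
                tvdi_z.z[tt, r, c],
            ]
            if include_lag:
                cols = [y_all[tt - 1]] + cols
            X = np.column_stack(cols)
            y = y_all[tt]
            Xc = X - X.mean(axis=0)
            # principal components via SVD; loadings in columns of V
            U, s_vals, Vt = np.linalg.svd(Xc, full_matrices=False)
            nonzero = s_vals > 1e-12 * s_vals.max() if s_vals.max() > 0 else s_vals > 0
            if not nonzero.any():
                zero_flag[r, c] = True
                raw[:, r, c] = 0.0
                continue
            scores = (U * s_vals)[:, nonzero]
            loadings = Vt.T[:, nonzero]
            k = scores.shape[1]
            coef, _, _, _ = np.linalg.lstsq(scores, y, rcond=None)
            resid = y - scores @ coef
            dof = n - k
            sigma2 = float(resid @ resid) / dof if dof > 0 else np.inf
            # component scores are orthogonal: var(coef_j) = sigma2 / (s_j^2)
            se = np.sqrt(sigma2 / (s_vals[nonzero] ** 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, coef / se, np.inf)
            pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
            selected = pvals < p_threshold
            if not selected.any():
                zero_flag[r, c] = True
                raw[:, r, c] = 0.0
                continue
            importance = np.abs(loadings[:, selected] @ coef[selected])
            raw[:, r, c] = importance[climate_rows]
    return raw, zero_flag


def rescale_weights(raw: np.ndarray, normalize: bool = True) -> ClimateWeights:
    """Global min-max rescale of raw importances, then per-pixel sum-to-1.

    The min and max are taken jointly over all three climate variables
    and all valid pixels, so the largest raw importance anywhere on the
    map becomes exactly 1. A degenerate global range yields equal thirds.
    """
    raw = np.asarray(raw, dtype=float)
    valid = np.isfinite(raw)
    if not valid.any():
        raise ValueError("no valid pixels in raw importances")
    lo = float(np.nanmin(raw))
    hi = float(np.nanmax(raw))
    degenerate = not hi > lo
    if degenerate:
        logger.warning("degenerate importance range [%g, %g]; equal thirds", lo, hi)
        rescaled = np.where(valid, 1.0, np.nan)
    else:
        rescaled = (raw - lo) / (hi - lo)
    if normalize:
        total = rescaled.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            normalized = np.where(total > 0, rescaled / total, 1.0 / 3.0)
        normalized[:, ~np.isfinite(total)] = np.nan
    else:
        normalized = rescaled.copy()
    return ClimateWeights(
        rescaled=rescaled if not degenerate else np.where(valid, 1.0, np.nan),
        normalized=normalized,
        is_normalized=normalize,
        degenerate=degenerate,
    )


def _detrended_keep_mean(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Remove the linear trend component but keep the series mean."""
    t_c = t - t.mean()
    slope = float(t_c @ (y - y.mean())) / float(t_c @ t_c)
    return y - slope * t_c


def variability_scores(
    stack: MonthlyStack,
    used: np.ndarray | None = None,
    min_pixels: int = 10,
) -> np.ndarray:
    """Mean-variance-residual variability score in [0, 100] per pixel.

    Per pixel: the mean and variance of the de-trended monthly series
    (trend removed, mean retained). Across pixels: OLS of variance on
    mean; the residual, min-max standardized to [0, 100], is the score.
    A degenerate residual range maps every pixel to 50.
    """
    vals = stack.masked()
    if used is not None:
        vals = np.where(used, vals, np.nan)
    n_t, nr, nc = vals.shape
    t_axis = np.arange(n_t, dtype=float)
    means = np.full((nr, nc), np.nan)
    variances = np.full((nr, nc), np.nan)
    flat = vals.reshape(n_t, -1)
    for p in range(nr * nc):
        y = flat[:, p]
        ok = np.isfinite(y)
        if ok.sum() < 4:
            continue
        detr = _detrended_keep_mean(y[ok], t_axis[ok])
        means.flat[p] = detr.mean()
        variances.flat[p] = detr.var(ddof=1)
    valid = np.isfinite(means) & np.isfinite(variances)
    n_valid = int(valid.sum())
    if n_valid < min_pixels:
        raise ValueError(f"only {n_valid} valid pixels; need {min_pixels}")
    slope, intercept = np.polyfit(means[valid], variances[valid], 1)
    resid = np.full((nr, nc), np.nan)
    resid[valid] = variances[valid] - (intercept + slope * means[valid])
    lo, hi = np.nanmin(resid), np.nanmax(resid)
    scores = np.full((nr, nc), np.nan)
    if hi > lo:
        scores[valid] = np.clip(100.0 * (resid[valid] - lo) / (hi - lo), 0.0, 100.0)
    else:
        logger.warning("degenerate residual range; all variability scores = 50")
        scores[valid] = 50.0
    return scores


def sensitivity_scores(
    ndvi_score: np.ndarray, climate_score: np.ndarray, offset: float = 1.0
) -> np.ndarray:
    """log10 ratio of NDVI variability to one climate variable's variability."""
    return np.log10((np.asarray(ndvi_score) + offset) / (np.asarray(climate_score) + offset))


def compute_vsi(
    weights: ClimateWeights, sens: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sum of sensitivity scores, then [0, 100] map rescale.

    ``sens`` maps each of CLIMATE_VARS to its log-ratio raster. Returns
    ``(vsi, raw)`` where ``raw`` is the pre-rescale weighted sum and
    ``vsi`` its global min-max rescale to [0, 100] over valid pixels.
    """
    raw = np.zeros_like(sens[CLIMATE_VARS[0]], dtype=float)
    for k, var in enumerate(CLIMATE_VARS):
        raw = raw + weights.normalized[k] * sens[var]
    valid = np.isfinite(raw)
    if not valid.any():
        raise ValueError("all-nodata VSI")
    lo, hi = raw[valid].min(), raw[valid].max()
    vsi = np.full(raw.shape, np.nan)
    if hi > lo:
        vsi[valid] = np.clip(100.0 * (raw[valid] - lo) / (hi - lo), 0.0, 100.0)
    else:
        vsi[valid] = 50.0
    return vsi, raw


def memory_map(alpha: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Memory-effect classes of the lag coefficient with area fractions.

    Half-open intervals: class 0 alpha < 0.4, class 1 0.4 <= alpha < 0.6,
    class 2 alpha >= 0.6. Fractions are over valid pixels and sum to 1.
    """
    a = np.asarray(alpha, dtype=float)
    classes = np.full(a.shape, -1, dtype=int)
    valid = np.isfinite(a)
    classes[valid & (a < 0.4)] = 0
    classes[valid & (a >= 0.4) & (a < 0.6)] = 1
    classes[valid & (a >= 0.6)] = 2
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid alpha pixels")
    fractions = {
        name: float(np.sum(classes == k)) / n_valid
        for k, name in enumerate(MEMORY_CLASSES)
    }
    return classes, fractions


def gradient_regression(
    alpha: np.ndarray,
    covariate: np.ndarray,
    form: str = "logarithmic",
    min_pixels: int = 10,
) -> dict:
    """Regress memory coefficient alpha on a growing-season covariate.

    ``form="logarithmic"`` fits ``alpha ~ 1 + ln(x)`` (non-positive
    covariates dropped and counted); ``form="quadratic"`` fits
    ``alpha ~ 1 + x + x^2``. Returns coefficients (intercept first),
    R^2 and the overall-F p-value.
    """
    a = np.asarray(alpha, dtype=float).ravel()
    x = np.asarray(covariate, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(x)
    n_dropped = 0
    if form == "logarithmic":
        pos = x > 0
        n_dropped = int((ok & ~pos).sum())
        ok &= pos
    if ok.sum() < min_pixels:
        raise ValueError("too few paired pixels for the gradient regression")
    if n_dropped:
        logger.info("gradient regression dropped %d non-positive covariates", n_dropped)
    a, x = a[ok], x[ok]
    if form == "logarithmic":
        X = sm.add_constant(np.log(x))
    elif form == "quadratic":
        X = sm.add_constant(np.column_stack([x, x**2]))
    else:
        raise ValueError("form must be 'logarithmic' or 'quadratic'")
    fit = sm.OLS(a, X).fit()
    return {
        "form": form,
        "coefficients": np.asarray(fit.params),
        "r2": float(fit.rsquared),
        "p_value": float(fit.f_pvalue),
        "n": int(ok.sum()),
        "n_dropped": n_dropped,
    }
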