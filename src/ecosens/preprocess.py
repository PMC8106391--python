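"""Data conditioning: smoothing, compositing, gap filling, resampling.

Mirrors the conditioning applied to satellite vegetation/temperature
products before any trend or sensitivity analysis:

* Savitzky-Golay filtering of NDVI time series (noise from cloud and
  atmosphere contamination);
* maximum-value compositing (MVC) to monthly and annual series;
* penalized-least-squares gap filling of LST scenes solved in the
  discrete-cosine basis with the smoothing parameter chosen by
  generalized cross-validation (DCT-PLS/GCV);
* nearest-neighbour resampling between the ~1 km LST grid and the
  ~250 m NDVI grid;
* the exclusion mask for calendar months whose across-years mean NDVI
  falls below 0.1 (sparse or absent vegetation cover).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn
from scipy.signal import savgol_filter

from .stacks import MonthlyStack

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingSpec",
    "GapFillResult",
    "savitzky_golay",
    "smooth_stack",
    "maximum_value_composite",
    "dct_pls_fill",
    "fill_stack",
    "resample_nearest",
    "low_cover_month_mask",
]

_EDGE_MODES = {"interp": "interp", "reflect": "mirror", "nearest": "nearest"}


@dataclass
class SmoothingSpec:
    """Savitzky-Golay window specification (in composites/time steps).

    ``edge_mode="interp"`` fits the edge polynomial to the terminal
    window, which keeps the filter exact on polynomials of degree
    <= ``poly_order`` over the whole series; "reflect" and "nearest"
    pad instead.
    """

    window_length: int = 7
    poly_order: int = 2
    edge_mode: str = "interp"

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be an odd integer >= 3")
        if not 0 <= self.poly_order < self.window_length:
            raise ValueError("poly_order must be < window_length")
        if self.edge_mode not in _EDGE_MODES:
            raise ValueError(f"edge_mode must be one of {sorted(_EDGE_MODES)}")


@dataclass
class GapFillResult:
    """Output of DCT-PLS gap filling of one scene."""

    filled: np.ndarray
    s_opt: float
    gcv_curve: list[tuple[float, float]] = field(repr=False, default_factory=list)
    iterations: int = 0


def savitzky_golay(series: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Smooth a 1-D series by local least-squares polynomial fitting.

    Exact on polynomials of degree <= ``poly_order``. Interior gaps (NaN)
    are linearly interpolated before filtering.
    """
    y = np.asarray(series, dtype=float).copy()
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    if y.size < spec.window_length:
        raise ValueError("series shorter than the smoothing window")
    bad = ~np.isfinite(y)
    if bad.all():
        raise ValueError("series is entirely missing")
    if bad.any():
        idx = np.arange(y.size)
        y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return savgol_filter(
        y, spec.window_length, spec.poly_order, mode=_EDGE_MODES[spec.edge_mode]
    )


def smooth_stack(stack: MonthlyStack, spec: SmoothingSpec) -> MonthlyStack:
    """Apply Savitzky-Golay filtering along time at every valid pixel."""
    vals = stack.masked()
    out = vals.copy()
    n_t = vals.shape[0]
    flat = vals.reshape(n_t, -1)
    out_flat = out.reshape(n_t, -1)
    for p in range(flat.shape[1]):
        col = flat[:, p]
        if np.isfinite(col).sum() >= max(2, spec.poly_order + 1):
            out_flat[:, p] = savitzky_golay(col, spec)
    out = out_flat.reshape(vals.shape)
    out[stack.nodata_mask] = np.nan
    return stack.copy_with(values=out, nodata_mask=stack.nodata_mask.copy())


def maximum_value_composite(stack: MonthlyStack, period: str = "year") -> MonthlyStack:
    """Per-pixel, per-period maximum over non-missing values.

    ``period="month"`` collapses duplicate (year, month) entries (sub-monthly
    composites); ``period="year"`` produces one band per year. Groups with
    no observations become nodata.
    """
    if stack.n_time == 0:
        raise ValueError("empty stack")
    if period not in ("month", "year"):
        raise ValueError("period must be 'month' or 'year'")
    if period == "month":
        keys = [(y, m) for y, m in stack.time_index]
    else:
        keys = [(y, 0) for y, _ in stack.time_index]
    uniq = sorted(set(keys))
    vals = stack.masked()
    out = np.full((len(uniq), *stack.grid_shape), np.nan)
    for i, key in enumerate(uniq):
        sel = [j for j, k in enumerate(keys) if k == key]
        with np.errstate(all="ignore"):
            out[i] = np.nanmax(vals[sel], axis=0)
    new_index = [(y, m if m else 1) for y, m in uniq]
    return MonthlyStack(
        values=out,
        time_index=new_index,
        geotransform=stack.geotransform,
        variable_tag=stack.variable_tag,
    )


def _laplacian_eigenvalues(shape: tuple[int, ...]) -> np.ndarray:
    """Eigenvalues of the grid-graph Laplacian in the DCT-II basis."""
    lam = np.zeros(shape)
    for axis, n in enumerate(shape):
        k = np.arange(n)
        lam_1d = 2.0 - 2.0 * np.cos(np.pi * k / n)
        lam = lam + lam_1d.reshape([-1 if a == axis else 1 for a in range(len(shape))])
    return lam


def dct_pls_smooth(grid: np.ndarray, s: float) -> np.ndarray:
    """Smooth a gap-free grid at a fixed roughness parameter ``s``.

    Applies filter factors ``1/(1 + s*lam^2)`` in the DCT-II basis;
    ``s = 0`` is the identity and constants pass through for any ``s``.
    """
    y = np.asarray(grid, dtype=float)
    gamma = 1.0 / (1.0 + s * _laplacian_eigenvalues(y.shape) ** 2)
    return idctn(gamma * dctn(y, norm="ortho"), norm="ortho")


def _smooth_once(
    y: np.ndarray,
    observed: np.ndarray,
    gamma: np.ndarray,
    fill0: np.ndarray | float,
    tol_abs: float,
    max_iter: int,
) -> tuple[np.ndarray, int]:
    """Fixed-point iteration: filter, re-impose observations, repeat.

    ``fill0`` seeds the missing cells (warm start from a smoother
    solution accelerates convergence at small s, where the filter is
    close to the identity and the iteration contracts slowly).
    """
    work = y.copy()
    work[~observed] = fill0 if np.isscalar(fill0) else fill0[~observed]
    z = work
    for it in range(1, max_iter + 1):
        z = idctn(gamma * dctn(work, norm="ortho"), norm="ortho")
        delta = np.max(np.abs(z[~observed] - work[~observed])) if (~observed).any() else 0.0
        work = y.copy()
        work[~observed] = z[~observed]
        if delta < tol_abs:
            break
    return z, it


def dct_pls_fill(
    grid: np.ndarray,
    nodata_mask: np.ndarray | None = None,
    n_s: int = 61,
    s_bounds: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GapFillResult:
    """Fill gaps in a 2-D scene by DCT-basis penalized least squares.

    The smoother applies filter factors ``1 / (1 + s * lam^2)`` to the
    cosine-transform coefficients, where ``lam`` are Laplacian eigenvalues
    of the grid graph; missing cells carry zero weight and are iterated to
    convergence (tolerance ``tol`` relative to the observed range). The
    roughness parameter ``s`` minimizes the generalized cross-validation
    score over ``n_s`` log-spaced candidates, searched from the smoothest
    candidate downward with warm-started gaps.

    Observed cells keep their original values in ``filled``; only the
    gaps receive the smooth estimate.
    """
    y = np.asarray(grid, dtype=float)
    if y.ndim != 2:
        raise ValueError("grid must be 2-D")
    observed = np.isfinite(y)
    if nodata_mask is not None:
        observed &= ~np.asarray(nodata_mask, dtype=bool)
    n_total = y.size
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("fully missing grid")
    if n_obs < 0.1 * n_total:
        raise ValueError("fewer than 10% of cells observed")

    lam2 = _laplacian_eigenvalues(y.shape) ** 2
    data_range = float(y[observed].max() - y[observed].min())
    tol_abs = tol * max(data_range, 1e-12)
    # search from smoothest s down, warm-starting gaps from the previous fit
    s_grid = np.logspace(np.log10(s_bounds[1]), np.log10(s_bounds[0]), n_s)
    gcv_curve: list[tuple[float, float]] = []
    best = (np.inf, None)  # (gcv, s)
    fill0: np.ndarray | float = y[observed].mean()
    search_iters = min(max_iter, 50)  # loose cap: candidates far from the
    # GCV minimum need no polish, and near-identity filters (tiny s) have
    # diverging GCV anyway
    for s in s_grid:
        gamma = 1.0 / (1.0 + s * lam2)
        z, _ = _smooth_once(y, observed, gamma, fill0, tol_abs, search_iters)
        fill0 = z
        rss = float(np.sum((y[observed] - z[observed]) ** 2))
        tr_h = float(gamma.sum())
        denom = 1.0 - tr_h / n_total
        gcv = np.inf if denom <= 0 else (rss / n_obs) / denom**2
        gcv_curve.append((float(s), float(gcv)))
        if gcv < best[0]:
            best = (gcv, float(s))
    gcv_curve.reverse()  # ascending s for the reported curve
    _, s_opt = best
    if s_opt is None:
        raise RuntimeError("GCV search failed on every candidate s")
    # fully converged solve at the selected s
    gamma = 1.0 / (1.0 + s_opt * lam2)
    z_opt, iters = _smooth_once(y, observed, gamma, y[observed].mean(), tol_abs, max_iter)
    if iters >= max_iter:
        raise RuntimeError(
            f"DCT-PLS did not converge within {max_iter} iterations at the "
            f"selected s={s_opt:g} (tol {tol_abs:g}, {n_obs}/{n_total} observed)"
        )
    filled = y.copy()
    filled[~observed] = z_opt[~observed]
    return GapFillResult(filled=filled, s_opt=s_opt, gcv_curve=gcv_curve, iterations=iters)


def fill_stack(stack: MonthlyStack, **kwargs) -> MonthlyStack:
    """DCT-PLS fill every monthly scene of a stack independently."""
    vals = stack.masked()
    out = np.empty_like(vals)
    for t in range(stack.n_time):
        if np.isfinite(vals[t]).all():
            out[t] = vals[t]
        else:
            out[t] = dct_pls_fill(vals[t], **kwargs).filled
    return MonthlyStack(
        values=out,
        time_index=stack.time_index,
        geotransform=stack.geotransform,
        variable_tag=stack.variable_tag,
    )


def resample_nearest(grid: np.ndarray, factor: int) -> np.ndarray:
    """Replicate every source cell ``factor x factor`` (nearest neighbour)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    g = np.asarray(grid)
    return np.repeat(np.repeat(g, factor, axis=-2), factor, axis=-1)


def resample_stack(stack: MonthlyStack, factor: int) -> MonthlyStack:
    """Nearest-neighbour upsample of every band; geotransform cell size shrinks."""
    vals = resample_nearest(stack.masked(), factor)
    x0, dx, rx, y0, ry, dy = stack.geotransform
    gt = (x0, dx / factor, rx, y0, ry, dy / factor)
    return MonthlyStack(
        values=vals,
        time_index=stack.time_index,
        geotransform=gt,
        variable_tag=stack.variable_tag,
    )


def low_cover_month_mask(ndvi: MonthlyStack, threshold: float = 0.1) -> np.ndarray:
    """Exclusion mask for sparsely vegetated calendar months.

    For each pixel and calendar month, True (excluded) iff the mean NDVI
    of that month across years is below ``threshold``. Shape
    ``(12, n_rows, n_cols)``, index 0 = January.
    """
    years = {y for y, _ in ndvi.time_index}
    if len(years) < 2:
        raise ValueError("need at least 2 years to form monthly climatology")
    vals = ndvi.masked()
    months = ndvi.months
    mask = np.zeros((12, *ndvi.grid_shape), dtype=bool)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            mask[m - 1] = True
            continue
        with np.errstate(all="ignore"):
            clim = np.nanmean(vals[sel], axis=0)
        mask[m - 1] = ~np.isfinite(clim) | (clim < threshold)
    return mask
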