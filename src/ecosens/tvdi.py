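"""Temperature Vegetation Dryness Index from the NDVI-LST feature space.

Per monthly scene, the NDVI axis is binned; the per-bin maximum LST points
trace the dry edge and the per-bin minima the wet edge. Straight lines are
fitted to each by ordinary least squares and every pixel's TVDI is its
normalized position between the edges::

    TVDI = (LST - wet(NDVI)) / (dry(NDVI) - wet(NDVI))

0 on the wet edge (wet soil), 1 on the dry edge (dry soil).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EdgeFit", "fit_edges", "compute_tvdi", "tvdi_stack"]


@dataclass
class EdgeFit:
    """Fitted dry/wet edges of one NDVI-LST scene (temperatures in K)."""

    dry_intercept: float
    dry_slope: float
    wet_intercept: float
    wet_slope: float
    n_bins_used: int
    r2_dry: float

    def dry(self, ndvi: np.ndarray) -> np.ndarray:
        return self.dry_intercept + self.dry_slope * np.asarray(ndvi, dtype=float)

    def wet(self, ndvi: np.ndarray) -> np.ndarray:
        return self.wet_intercept + self.wet_slope * np.asarray(ndvi, dtype=float)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (intercept, slope, r2)."""
    coeffs = np.polyfit(x, y, 1)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    pred = intercept + slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return intercept, slope, r2


def fit_edges(
    ndvi_scene: np.ndarray,
    lst_scene: np.ndarray,
    bin_width: float = 0.02,
    min_count: int = 10,
    wet_slope_tol: float = 5.0,
    min_bins: int = 5,
) -> EdgeFit:
    """Fit dry and wet edges on one co-registered NDVI/LST scene pair.

    NDVI is partitioned into bins of ``bin_width``; bins with fewer than
    ``min_count`` joint-valid pixels are skipped. The dry edge is the OLS
    line through the bin LST maxima, the wet edge through the minima. A
    wet edge whose fitted slope is positive beyond ``wet_slope_tol``
    (K per NDVI unit) falls back to the constant scene minimum.

    Raises
    ------
    ValueError
        If fewer than ``min_bins`` bins qualify, or the dry edge does not
        lie above the wet edge anywhere on the fitted NDVI range.
    """
    ndvi = np.asarray(ndvi_scene, dtype=float).ravel()
    lst = np.asarray(lst_scene, dtype=float).ravel()
    valid = np.isfinite(ndvi) & np.isfinite(lst)
    ndvi, lst = ndvi[valid], lst[valid]
    if ndvi.size < min_count * min_bins:
        raise ValueError("too few joint-valid pixels to fit edges")

    bins = np.floor(ndvi / bin_width).astype(int)
    centers, maxima, minima = [], [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < min_count:
            continue
        centers.append((b + 0.5) * bin_width)
        maxima.append(lst[sel].max())
        minima.append(lst[sel].min())
    if len(centers) < min_bins:
        raise ValueError(
            f"only {len(centers)} NDVI bins with >= {min_count} pixels; "
            f"need {min_bins}"
        )
    centers_a = np.array(centers)
    maxima_a = np.array(maxima)
    minima_a = np.array(minima)

    dry_int, dry_slope, r2_dry = _ols_line(centers_a, maxima_a)
    wet_int, wet_slope, _ = _ols_line(centers_a, minima_a)
    if wet_slope > wet_slope_tol:
        wet_int, wet_slope = float(minima_a.min()), 0.0
        logger.debug("wet edge fell back to constant minimum %.2f K", wet_int)

    fit = EdgeFit(dry_int, dry_slope, wet_int, wet_slope, len(centers), r2_dry)
    sep = fit.dry(centers_a) - fit.wet(centers_a)
    if np.all(sep <= 0):
        raise ValueError("degenerate edges: dry edge never above wet edge")
    return fit


def compute_tvdi(
    ndvi_scene: np.ndarray, lst_scene: np.ndarray, edges: EdgeFit
) -> np.ndarray:
    """Evaluate TVDI per pixel, clipped to [0, 1]; NaN propagates.

    Pixels where the fitted dry edge does not exceed the wet edge are set
    to NaN (their normalization is undefined); their count is logged.
    """
    ndvi = np.asarray(ndvi_scene, dtype=float)
    lst = np.asarray(lst_scene, dtype=float)
    wet = edges.wet(ndvi)
    denom = edges.dry(ndvi) - wet
    out = np.full(ndvi.shape, np.nan)
    ok = np.isfinite(ndvi) & np.isfinite(lst) & (denom > 0)
    out[ok] = np.clip((lst[ok] - wet[ok]) / denom[ok], 0.0, 1.0)
    n_bad = int(np.sum(np.isfinite(ndvi) & np.isfinite(lst) & (denom <= 0)))
    if n_bad:
        logger.info("TVDI: %d pixels with non-positive edge separation", n_bad)
    n_clipped = int(
        np.sum(((lst[ok] - wet[ok]) / denom[ok] < 0) | ((lst[ok] - wet[ok]) / denom[ok] > 1))
    )
    if n_clipped:
        logger.debug("TVDI: %d values clipped into [0, 1]", n_clipped)
    return out


def tvdi_stack(ndvi_stack, lst_stack, bin_width: float = 0.02, min_count: int = 10):
    """Monthly TVDI stack plus the per-scene edge-fit table.

    Edges are fitted independently per monthly scene (the dry edge drifts
    with season). Returns ``(MonthlyStack, list[dict])`` where each dict
    is one edge-fit row (year, month, edge parameters, r2_dry).
    """
    from .stacks import MonthlyStack

    if ndvi_stack.time_index != lst_stack.time_index:
        raise ValueError("NDVI and LST stacks must share a time index")
    ndvi_vals = ndvi_stack.masked()
    lst_vals = lst_stack.masked()
    out = np.full(ndvi_vals.shape, np.nan)
    rows = []
    for t, (year, month) in enumerate(ndvi_stack.time_index):
        edges = fit_edges(ndvi_vals[t], lst_vals[t], bin_width, min_count)
        out[t] = compute_tvdi(ndvi_vals[t], lst_vals[t], edges)
        rows.append(
            {
                "year": year,
                "month": month,
                "a_d": edges.dry_intercept,
                "b_d": edges.dry_slope,
                "a_w": edges.wet_intercept,
                "b_w": edges.wet_slope,
                "n_bins": edges.n_bins_used,
                "r2_dry": edges.r2_dry,
            }
        )
    stack = MonthlyStack(
        values=out,
        time_index=ndvi_stack.time_index,
        geotransform=ndvi_stack.geotransform,
        variable_tag="tvdi",
    )
    return stack, rows
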