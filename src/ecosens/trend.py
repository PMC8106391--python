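"""Per-pixel Mann-Kendall trend testing and Theil-Sen slope mapping.

The Mann-Kendall statistic for a series ``x_1..x_n`` is the signed pair
count ``S = sum_{i<k} sgn(x_k - x_i)`` with tie-corrected variance

    Var(S) = [ n(n-1)(2n+5) - sum_t t(t-1)(2t+5) ] / 18

(``t`` running over the extents of tied groups) and the continuity-
corrected normal deviate

    Zc = (S-1)/sqrt(Var(S))  if S > 0,   0 if S = 0,
         (S+1)/sqrt(Var(S))  if S < 0.

|Zc| > 1.96 marks a significant monotonic trend at the 95% level. The
trend magnitude is the Theil-Sen slope: the median of all pairwise
slopes, robust to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacks import MonthlyStack

__all__ = [
    "TrendResult",
    "mk_statistic",
    "mk_z",
    "theil_sen",
    "classify_trend",
    "trend_map",
    "level_map",
]

TREND_CLASSES = (
    "sig_decrease",
    "nonsig_decrease",
    "no_trend",
    "nonsig_increase",
    "sig_increase",
)

DEFAULT_BETA_BANDS = (0.0, 0.001, 0.002)
DEFAULT_NDVI_LEVELS = (0.1, 0.2, 0.4, 0.6, 0.8)


@dataclass
class TrendResult:
    S: float
    var_s: float
    zc: float
    beta: float
    trend_class: str


def mk_statistic(series: np.ndarray, min_n: int = 4) -> tuple[float, float]:
    """Mann-Kendall S and its tie-corrected variance."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < min_n:
        raise ValueError(f"series length {n} < minimum {min_n}")
    if not np.isfinite(x).all():
        raise ValueError("series contains missing values")
    diff = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var_s


def mk_z(series: np.ndarray) -> float:
    """Continuity-corrected standardized Mann-Kendall statistic Zc."""
    s, var_s = mk_statistic(series)
    if s == 0:
        return 0.0
    if var_s <= 0:
        raise ValueError("zero variance with nonzero S (degenerate series)")
    correction = -1.0 if s > 0 else 1.0
    return float((s + correction) / np.sqrt(var_s))


def theil_sen(series: np.ndarray) -> float:
    """Median of all pairwise slopes (x_i - x_j)/(i - j), i > j."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    i, j = np.triu_indices(n, k=1)
    slopes = (x[j] - x[i]) / (j - i)
    return float(np.median(slopes))


def classify_trend(zc: float, beta: float, z_threshold: float = 1.96) -> str:
    """Five-way trend class from the (Zc, beta) pair.

    Significance comes from |Zc| against the threshold; direction from the
    sign of Zc (beta breaks the tie only in the zero-Zc case, which maps
    to 'no_trend').
    """
    if not (np.isfinite(zc) and np.isfinite(beta)):
        raise ValueError("zc and beta must be finite")
    if zc == 0:
        return "no_trend"
    if zc > 0:
        return "sig_increase" if zc > z_threshold else "nonsig_increase"
    return "sig_decrease" if zc < -z_threshold else "nonsig_decrease"


def _fractions(labels: list[str], order: tuple[str, ...]) -> dict[str, float]:
    n = len(labels)
    return {c: labels.count(c) / n for c in order}


def trend_map(
    annual_stack: MonthlyStack,
    z_threshold: float = 1.96,
    beta_bands: tuple[float, ...] = DEFAULT_BETA_BANDS,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-pixel trend statistics on an annual stack plus area fractions.

    Returns ``(rasters, summary)`` where ``rasters`` holds 2-D arrays
    ``S, var_s, zc, beta`` and the string raster ``trend_class``, and
    ``summary`` tabulates the fraction of valid pixels per trend class
    and per beta band (each partition sums to 1). Missing years are
    dropped pixel-wise; pixels with fewer than 4 years become nodata.
    """
    if annual_stack.n_time < 4:
        raise ValueError("need at least 4 annual layers")
    vals = annual_stack.masked()
    nr, nc = annual_stack.grid_shape
    out = {
        "S": np.full((nr, nc), np.nan),
        "var_s": np.full((nr, nc), np.nan),
        "zc": np.full((nr, nc), np.nan),
        "beta": np.full((nr, nc), np.nan),
    }
    classes = np.full((nr, nc), "", dtype=object)
    labels: list[str] = []
    betas: list[float] = []
    for r in range(nr):
        for c in range(nc):
            series = vals[:, r, c]
            series = series[np.isfinite(series)]
            if series.size < 4:
                continue
            s, var_s = mk_statistic(series)
            if s != 0 and var_s <= 0:
                continue
            zc = 0.0 if s == 0 else (s - np.sign(s)) / np.sqrt(var_s)
            beta = theil_sen(series)
            out["S"][r, c] = s
            out["var_s"][r, c] = var_s
            out["zc"][r, c] = zc
            out["beta"][r, c] = beta
            cls = classify_trend(zc, beta, z_threshold)
            classes[r, c] = cls
            labels.append(cls)
            betas.append(beta)
    if not labels:
        raise ValueError("no valid pixels")
    out["trend_class"] = classes

    rows = [
        {"partition": "trend_class", "band": k, "fraction": v}
        for k, v in _fractions(labels, TREND_CLASSES).items()
    ]
    b = np.asarray(betas)
    lo, mid, hi = beta_bands
    band_fracs = {
        f"beta<={lo:g}": float(np.mean(b <= lo)),
        f"{lo:g}<beta<{mid:g}": float(np.mean((b > lo) & (b < mid))),
        f"{mid:g}<=beta<={hi:g}": float(np.mean((b >= mid) & (b <= hi))),
        f"beta>{hi:g}": float(np.mean(b > hi)),
    }
    rows += [
        {"partition": "beta_band", "band": k, "fraction": v}
        for k, v in band_fracs.items()
    ]
    return out, pd.DataFrame(rows)


def level_map(
    mean_annual_ndvi: np.ndarray,
    breaks: tuple[float, ...] = DEFAULT_NDVI_LEVELS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify mean annual NDVI into levels; returns class raster + fractions.

    Class k covers [breaks[k-1], breaks[k]); class 0 is below the first
    break, the top class at or above the last break. Nodata pixels get -1.
    """
    grid = np.asarray(mean_annual_ndvi, dtype=float)
    edges = np.asarray(breaks, dtype=float)
    classes = np.full(grid.shape, -1, dtype=int)
    valid = np.isfinite(grid)
    classes[valid] = np.searchsorted(edges, grid[valid], side="right")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels")
    rows = []
    bounds = [-np.inf, *edges, np.inf]
    for k in range(len(edges) + 1):
        frac = float(np.mean(classes[valid] == k))
        rows.append(
            {"level": k, "lower": bounds[k], "upper": bounds[k + 1], "fraction": frac}
        )
    return classes, pd.DataFrame(rows)
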