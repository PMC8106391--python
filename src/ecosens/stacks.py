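"""Core raster containers.

A :class:`MonthlyStack` is the package's in-memory currency: a
``time x row x col`` cube of one variable (NDVI, air temperature,
precipitation, land-surface temperature or TVDI) with a calendar index,
a nodata mask and a north-up affine geotransform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default north-up geotransform (x0, dx, 0, y0, 0, dy) with unit cells.
IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


@dataclass
class MonthlyStack:
    """One variable on a fixed grid, one band per time step.

    Parameters
    ----------
    values
        ``(n_time, n_rows, n_cols)`` float array in the variable's units
        (NDVI dimensionless in [-1, 1], Tem degC, Pre mm/month, LST K,
        TVDI dimensionless in [0, 1]).
    time_index
        List of ``(year, month)`` with 1-based months, strictly increasing.
    nodata_mask
        Boolean cube, True where the cell is missing. Defaults to all-valid.
    geotransform
        GDAL-style 6-tuple ``(x0, dx, rx, y0, ry, dy)``, north-up.
    variable_tag
        Short name of the variable ("ndvi", "tem", "pre", "lst", "tvdi").
    """

    values: np.ndarray
    time_index: list[tuple[int, int]]
    nodata_mask: np.ndarray | None = None
    geotransform: tuple[float, ...] = IDENTITY_TRANSFORM
    variable_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (time, row, col) cube")
        if len(self.time_index) != self.values.shape[0]:
            raise ValueError(
                f"time_index length {len(self.time_index)} does not match "
                f"time axis {self.values.shape[0]}"
            )
        self.time_index = [(int(y), int(m)) for y, m in self.time_index]
        keys = [y * 12 + (m - 1) for y, m in self.time_index]
        # equal consecutive keys are allowed: sub-monthly composites share
        # a (year, month) until collapsed by maximum-value compositing
        if any(b < a for a, b in zip(keys, keys[1:])):
            raise ValueError("time_index must be non-decreasing")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape must match values")
        # NaNs in values are always treated as missing
        self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    # -- convenience ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.time_index])

    @property
    def months(self) -> np.ndarray:
        """1-based calendar month of every band."""
        return np.array([m for _, m in self.time_index])

    def masked(self) -> np.ndarray:
        """Values with missing cells replaced by NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def copy_with(self, **changes) -> "MonthlyStack":
        return replace(self, **changes)


@dataclass
class SynthConfig:
    """Configuration of the synthetic scene generator.

    The anomaly recursion driving synthetic NDVI is
    ``a_t = alpha * a_{t-1} + beta * z_tem + gamma * z_pre
    + delta * z_tvdi + eps_t`` with ``eps_t ~ N(0, noise_sd^2)``, i.e. the
    generative counterpart of the lag-1 sensitivity regression fitted
    downstream. Coefficients may be scalars or ``(n_rows, n_cols)`` arrays.
    """

    n_rows: int = 30
    n_cols: int = 30
    n_years: int = 19
    start_year: int = 2000
    seed: int = 0
    true_alpha: float | np.ndarray = 0.5
    true_beta: float | np.ndarray = 0.2
    true_gamma: float | np.ndarray = 0.3
    true_delta: float | np.ndarray = -0.2
    noise_sd: float = 0.3
    # per-variable seasonal half-amplitudes
    seasonal_amplitude: dict = field(
        default_factory=lambda: {"tem": 15.0, "pre": 20.0, "lst": 18.0, "ndvi": 0.25}
    )
    # per-variable linear trends, units per year
    linear_trend: dict = field(
        default_factory=lambda: {"tem": 0.03, "pre": 0.3, "lst": 0.03, "ndvi": 0.0}
    )
    # per-variable white-noise SD, in native units
    climate_noise_sd: dict = field(
        default_factory=lambda: {"tem": 1.5, "pre": 8.0, "lst": 2.0}
    )
    gap_fraction: float = 0.1
    elevation_gradient: float = 1.0
    #: drive NDVI anomalies by TVDI computed from generated LST ("tvdi")
    #: or by the LST anomaly directly ("lst")
    moisture_driver: str = "tvdi"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_years <= 0:
            raise ValueError("grid dimensions and n_years must be positive")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.any(np.abs(np.asarray(self.true_alpha, dtype=float)) >= 1.0):
            raise ValueError("|true_alpha| must be < 1 (stationary memory)")
        if self.moisture_driver not in ("tvdi", "lst"):
            raise ValueError("moisture_driver must be 'tvdi' or 'lst'")

    @property
    def n_time(self) -> int:
        return self.n_years * 12

    def time_index(self) -> list[tuple[int, int]]:
        return [
            (self.start_year + t // 12, t % 12 + 1) for t in range(self.n_time)
        ]

    def coeff_grid(self, name: str) -> np.ndarray:
        """Coefficient broadcast to the (n_rows, n_cols) grid."""
        value = getattr(self, f"true_{name}")
        return np.broadcast_to(
            np.asarray(value, dtype=float), (self.n_rows, self.n_cols)
        ).copy()
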