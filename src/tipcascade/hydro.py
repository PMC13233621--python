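"""Hydrological-year rainfall metrics: MAP and the maximum cumulative water deficit.

MAP (mean annual precipitation) is the total precipitation over a
hydrological year, which runs from October of one calendar year to
September of the next so that a full dry season is never split across
accounting years.  The cumulative water deficit (CWD) integrates monthly
precipitation minus evaporation and is capped at zero from above::

    CWD_m = min(0, CWD_{m-1} + P_m - E_m),   CWD_0 = 0

MCWD is the absolute value of the deepest deficit reached within the
year -- a standard measure of dry-season intensity, reported here as a
positive magnitude in mm/yr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyField",
    "HydroSeries",
    "hydrological_years",
    "compute_map",
    "compute_mcwd",
    "windowed_means",
    "constant_et_transform",
    "hydro_series",
]


@dataclass
class MonthlyField:
    """Per-cell monthly series of a hydrological quantity (mm/month).

    ``values`` has shape ``(n_cells, n_time)``; ``years``/``months`` label
    the time axis with calendar year and month (1..12).  Months must be
    contiguous.
    """

    values: np.ndarray
    years: np.ndarray
    months: np.ndarray
    name: str = "precipitation"
    units: str = "mm/month"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_cells, n_time)")
        n_time = self.values.shape[1]
        if self.years.shape != (n_time,) or self.months.shape != (n_time,):
            raise ValueError("years/months must match the time axis length")
        if np.any((self.months < 1) | (self.months > 12)):
            raise ValueError("months must be in 1..12")
        # contiguity: each step advances by exactly one calendar month
        lin = self.years * 12 + (self.months - 1)
        if n_time > 1 and not np.all(np.diff(lin) == 1):
            raise ValueError(f"{self.name}: months are not contiguous")
        if self.name == "precipitation" and np.any(self.values < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def year_slice(self, first: int, last: int) -> "MonthlyField":
        """Restrict to calendar years in [first, last]."""
        sel = (self.years >= first) & (self.years <= last)
        return MonthlyField(
            self.values[:, sel], self.years[sel], self.months[sel],
            name=self.name, units=self.units,
        )

    def same_time_axis(self, other: "MonthlyField") -> bool:
        return (
            self.n_time == other.n_time
            and bool(np.all(self.years == other.years))
            and bool(np.all(self.months == other.months))
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, year, month, value)."""
        n_cells, n_time = self.values.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_cells), n_time),
                "year": np.tile(self.years, n_cells),
                "month": np.tile(self.months, n_cells),
                "value": self.values.ravel(),
            }
        )


def hydro_year_index(
    years: np.ndarray, months: np.ndarray, start_month: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Index complete 12-month hydrological years on a contiguous time axis.

    Returns ``(labels, idx)`` where ``labels[j]`` is the calendar year of the
    block's first month and ``idx`` has shape ``(n_years, 12)`` with column
    positions into the time axis.  Leading/trailing partial years are
    dropped.
    """
    if not 1 <= start_month <= 12:
        raise ValueError("start_month must be in 1..12")
    starts = np.flatnonzero(months == start_month)
    starts = starts[starts + 12 <= len(months)]
    if len(starts) == 0:
        warnings.warn("no complete hydrological year in series", stacklevel=2)
        return np.empty(0, dtype=int), np.empty((0, 12), dtype=int)
    idx = starts[:, None] + np.arange(12)[None, :]
    return years[starts], idx


def hydrological_years(
    field: MonthlyField, start_month: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Split a field into complete hydrological-year blocks.

    Returns ``(labels, blocks)`` with ``blocks`` of shape
    ``(n_cells, n_years, 12)``; each block holds the 12 months starting at
    ``start_month`` (Oct..Sep by default).  A block is labelled by the
    calendar year of its October start.
    """
    labels, idx = hydro_year_index(field.years, field.months, start_month)
    return labels, field.values[:, idx]


def compute_map(block: np.ndarray) -> np.ndarray:
    """Annual precipitation: the sum of a 12-month block (mm/yr).

    ``block`` may be any array whose last axis has length 12.
    """
    block = np.asarray(block, dtype=float)
    if block.shape[-1] != 12:
        raise ValueError("block must have 12 months on its last axis")
    if np.any(block < 0):
        raise ValueError("precipitation must be non-negative")
    return block.sum(axis=-1)


def _cwd_min(deficit: np.ndarray) -> np.ndarray:
    """Deepest capped cumulative deficit along the last axis (negative)."""
    cur = np.zeros(deficit.shape[:-1], dtype=float)
    low = np.zeros_like(cur)
    for m in range(deficit.shape[-1]):
        cur = np.minimum(0.0, cur + deficit[..., m])
        low = np.minimum(low, cur)
    return low


def compute_mcwd(
    p_block: np.ndarray, e_block: np.ndarray, carry_over: bool = False
) -> np.ndarray:
    """Maximum cumulative water deficit of aligned 12-month blocks (mm/yr).

    The deficit recursion is ``CWD_m = min(0, CWD_{m-1} + P_m - E_m)`` with
    ``CWD_0 = 0``; the result is ``abs(min_m CWD_m)`` per year, always >= 0.

    With ``carry_over=True`` and blocks shaped ``(..., n_years, 12)`` the
    deficit is carried across year boundaries instead of resetting each
    October (an alternative accounting convention; default is the reset).
    """
    p_block = np.asarray(p_block, dtype=float)
    e_block = np.asarray(e_block, dtype=float)
    if p_block.shape != e_block.shape:
        raise ValueError("P and E blocks must be aligned")
    if p_block.shape[-1] != 12:
        raise ValueError("blocks must have 12 months on the last axis")
    deficit = p_block - e_block
    if carry_over and deficit.ndim >= 2:
        n_years = deficit.shape[-2]
        flat = deficit.reshape(*deficit.shape[:-2], n_years * 12)
        cur = np.zeros(flat.shape[:-1], dtype=float)
        lows = np.empty(deficit.shape[:-1], dtype=float)
        for y in range(n_years):
            low = np.full_like(cur, 0.0)
            for m in range(12):
                cur = np.minimum(0.0, cur + flat[..., y * 12 + m])
                low = np.minimum(low, cur)
            lows[..., y] = low
        return np.abs(lows)
    return np.abs(_cwd_min(deficit))


def windowed_means(
    values: np.ndarray, years: np.ndarray, window: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Running ``window``-year means of per-year values.

    ``values`` has years on its last axis.  Each mean is labelled by the
    year at offset ``window // 2`` from the window start (so the 2021-2030
    mean carries the label 2026, window 1 is the identity).  Windows that
    would run past the series are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    n = values.shape[-1]
    if window > n:
        warnings.warn("window longer than series; empty result", stacklevel=2)
        return np.empty(0, dtype=int), np.empty((*values.shape[:-1], 0))
    kernel = np.ones(window) / window
    means = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), -1, values
    )
    labels = years[np.arange(n - window + 1) + window // 2]
    return labels, means


def constant_et_transform(e: MonthlyField, value: float = 100.0) -> MonthlyField:
    """Replace evaporation by a constant (mm/month) everywhere.

    A conservative sensitivity mode: observed evaporation is limited by
    water availability, so fixing it at a typical potential rate (100
    mm/month) bounds the deficit from above.  Idempotent.
    """
    if value < 0:
        raise ValueError("evaporation must be non-negative")
    return MonthlyField(
        np.full_like(e.values, float(value)),
        e.years.copy(),
        e.months.copy(),
        name=e.name,
        units=e.units,
    )


@dataclass
class HydroSeries:
    """Per-cell, per-hydrological-year MAP and MCWD (mm/yr)."""

    hydro_years: np.ndarray  # (n_years,) labels (October start year)
    map: np.ndarray  # (n_cells, n_years)
    mcwd: np.ndarray  # (n_cells, n_years)
    start_month: int = 10
    carry_over: bool = False
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_cells(self) -> int:
        return self.map.shape[0]

    def windowed(self, window: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Running decadal means of MAP and MCWD: (labels, map_w, mcwd_w)."""
        key = ("w", window)
        if key not in self._cache:
            labels, map_w = windowed_means(self.map, self.hydro_years, window)
            _, mcwd_w = windowed_means(self.mcwd, self.hydro_years, window)
            self._cache[key] = (labels, map_w, mcwd_w)
        return self._cache[key]

    def year_slice(self, first: int, last: int) -> "HydroSeries":
        """Restrict to hydro-year labels in [first, last]."""
        sel = (self.hydro_years >= first) & (self.hydro_years <= last)
        return HydroSeries(
            self.hydro_years[sel],
            self.map[:, sel],
            self.mcwd[:, sel],
            self.start_month,
            self.carry_over,
        )

    def to_frame(self) -> pd.DataFrame:
        n_cells, n_years = self.map.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_cells), n_years),
                "hydro_year": np.tile(self.hydro_years, n_cells),
                "map": self.map.ravel(),
                "mcwd": self.mcwd.ravel(),
            }
        )


def hydro_series(
    p: MonthlyField,
    e: MonthlyField,
    start_month: int = 10,
    carry_over: bool = False,
) -> HydroSeries:
    """Compute per-cell MAP and MCWD for every complete hydrological year."""
    if not p.same_time_axis(e):
        raise ValueError("P and E must share the same time axis")
    labels, p_blocks = hydrological_years(p, start_month)
    _, e_blocks = hydrological_years(e, start_month)
    return HydroSeries(
        hydro_years=labels,
        map=compute_map(p_blocks),
        mcwd=compute_mcwd(p_blocks, e_blocks, carry_over=carry_over),
        start_month=start_month,
        carry_over=carry_over,
    )
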