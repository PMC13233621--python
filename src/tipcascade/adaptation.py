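"""Per-cell adaptation statistics and critical thresholds.

Each grid cell is assumed adapted to the climate it experienced over a
historical window: its mean MAP and MCWD (mu) and their interannual
standard deviations (delta) define a local safety margin.  A cell's
tipping thresholds sit sigma standard deviations into drier-than-mean
territory::

    MAP_crit  = mu_MAP  - sigma * delta_MAP     (less rain)
    MCWD_crit = mu_MCWD + sigma * delta_MCWD    (deeper deficit)

sigma is the uncertain adaptive-capacity multiplier; ensembles draw it
uniformly from [0.75, 1.25] per cell (an alternative fixed-threshold
mode uses [0.50, 1.00]), or scale it with basin wetness rank in the
sensitivity modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hydro import HydroSeries, MonthlyField, hydro_series

__all__ = [
    "AdaptationProfile",
    "fit_adaptation",
    "sample_sigma",
    "compute_thresholds",
    "guard_mask",
    "SIGMA_BOUNDS_DEFAULT",
    "SIGMA_BOUNDS_FIXED_THRESHOLD",
    "MAP_GUARD_DEFAULT",
    "MCWD_GUARD_DEFAULT",
]

SIGMA_BOUNDS_DEFAULT = (0.75, 1.25)
SIGMA_BOUNDS_FIXED_THRESHOLD = (0.50, 1.00)
MAP_GUARD_DEFAULT = 1850.0  # mm/yr: wetter cells are forbidden to tip
MCWD_GUARD_DEFAULT = 350.0  # mm/yr: cells with shallower deficits likewise


@dataclass
class AdaptationProfile:
    """Per-cell historical statistics, sampled sigma and thresholds."""

    mu_map: np.ndarray
    delta_map: np.ndarray
    mu_mcwd: np.ndarray
    delta_mcwd: np.ndarray
    sigma: np.ndarray | None = None
    map_crit: np.ndarray | None = None
    mcwd_crit: np.ndarray | None = None
    tippable: np.ndarray | None = None  # False where thresholds degenerate
    guard: np.ndarray | None = None  # True where forbidden to tip

    @property
    def n_cells(self) -> int:
        return len(self.mu_map)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cells
        def col(a, fill=np.nan):
            return a if a is not None else np.full(n, fill)
        return pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "mu_map": self.mu_map,
                "delta_map": self.delta_map,
                "mu_mcwd": self.mu_mcwd,
                "delta_mcwd": self.delta_mcwd,
                "sigma": col(self.sigma),
                "map_crit": col(self.map_crit),
                "mcwd_crit": col(self.mcwd_crit),
                "guard": col(self.guard, False).astype(bool),
            }
        )


def fit_adaptation(
    p: MonthlyField,
    e: MonthlyField,
    window: tuple[int, int] | None = None,
    start_month: int = 10,
    ddof: int = 0,
    carry_over: bool = False,
) -> AdaptationProfile:
    """Historical mean and s.d. of per-year MAP and MCWD for every cell.

    ``window`` restricts to hydro-year labels ``[first, last]``
    inclusive.  The s.d. divides by n (population convention) by
    default: the window is treated as the cell's complete adaptation
    history; pass ``ddof=1`` for the sample convention.
    """
    series = hydro_series(p, e, start_month=start_month, carry_over=carry_over)
    if window is not None:
        series = series.year_slice(*window)
    return fit_adaptation_series(series, ddof=ddof)


def fit_adaptation_series(series: HydroSeries, ddof: int = 0) -> AdaptationProfile:
    """As :func:`fit_adaptation`, from an already-computed HydroSeries."""
    if series.map.shape[1] < 2:
        raise ValueError(
            "adaptation window must contain at least 2 complete hydrological "
            "years (s.d. undefined otherwise)"
        )
    return AdaptationProfile(
        mu_map=series.map.mean(axis=1),
        delta_map=series.map.std(axis=1, ddof=ddof),
        mu_mcwd=series.mcwd.mean(axis=1),
        delta_mcwd=series.mcwd.std(axis=1, ddof=ddof),
    )


def sample_sigma(
    n_cells: int,
    bounds: tuple[float, float] = SIGMA_BOUNDS_DEFAULT,
    mode: str = "uniform_iid",
    map_reference: np.ndarray | None = None,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the per-cell adaptive-capacity multiplier sigma.

    Modes:

    * ``uniform_iid`` -- i.i.d. uniform draws in ``bounds`` (the ensemble
      default);
    * ``wet_high`` -- sigma deterministic, linear in the basin percentile
      rank of ``map_reference``: wettest cell gets the upper bound
      (wet regions most resilient), driest the lower;
    * ``wet_low`` -- the reverse ranking.
    """
    low, high = bounds
    if low > high:
        raise ValueError("sigma bounds must satisfy low <= high")
    if mode == "uniform_iid":
        if rng is None:
            rng = np.random.default_rng(seed)
        return rng.uniform(low, high, size=n_cells)
    if mode in ("wet_high", "wet_low"):
        if map_reference is None:
            raise ValueError(f"mode {mode!r} requires map_reference")
        map_reference = np.asarray(map_reference, dtype=float)
        if len(map_reference) != n_cells:
            raise ValueError("map_reference length must equal n_cells")
        if n_cells == 1:
            pct = np.array([0.5])
        else:
            pct = (rankdata(map_reference, method="average") - 1) / (n_cells - 1)
        if mode == "wet_low":
            pct = 1.0 - pct
        return low + (high - low) * pct
    raise ValueError(f"unknown sigma mode {mode!r}")


def compute_thresholds(
    profile: AdaptationProfile, sigma: np.ndarray
) -> AdaptationProfile:
    """Fill per-cell critical thresholds from (mu, delta) and sigma.

    Cells with a vanishing adaptive range (sigma*delta == 0 for either
    driver) get degenerate thresholds at mu and are flagged
    non-tippable; the dynamics clamp them to the forest state.
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (profile.n_cells,))
    if np.any(profile.delta_map < 0) or np.any(profile.delta_mcwd < 0):
        raise ValueError("delta must be non-negative")
    range_map = sigma * profile.delta_map
    range_mcwd = sigma * profile.delta_mcwd
    tippable = (range_map > 0) & (range_mcwd > 0)
    if not tippable.all():
        warnings.warn(
            f"{int((~tippable).sum())} cell(s) have a degenerate adaptive "
            "range and are flagged non-tippable",
            stacklevel=2,
        )
    return replace(
        profile,
        sigma=sigma.copy(),
        map_crit=profile.mu_map - range_map,
        mcwd_crit=profile.mu_mcwd + range_mcwd,
        tippable=tippable,
        guard=profile.guard,
    )


def guard_mask(
    decadal_map: np.ndarray,
    decadal_mcwd: np.ndarray,
    map_guard: float = MAP_GUARD_DEFAULT,
    mcwd_guard: float = MCWD_GUARD_DEFAULT,
    combine: str = "and",
) -> np.ndarray:
    """Cells forbidden to tip on absolute-threshold grounds.

    With the default ``combine="and"``, a cell is guarded when its
    decadal MAP exceeds ``map_guard`` AND its decadal MCWD stays below
    ``mcwd_guard`` (both conditions indicate a safely wet cell);
    ``combine="or"`` guards on either condition.
    """
    wet = np.asarray(decadal_map, dtype=float) > map_guard
    shallow = np.asarray(decadal_mcwd, dtype=float) < mcwd_guard
    if combine == "and":
        return wet & shallow
    if combine == "or":
        return wet | shallow
    raise ValueError(f"unknown combine {combine!r}")
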