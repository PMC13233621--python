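"""Directed moisture-recycling networks and their hydrological link effects.

A link (k -> i, month) carries the precipitation (mm/month) deposited at
cell i that originated as evapotranspiration from cell k.  For the coupled
dynamics each link is summarised over an evaluation window by two numbers:

* ``delta_map``  -- the mean annual moisture delivered over the link
  (mm/yr), i.e. the MAP that cell i loses if cell k stops transpiring;
* ``delta_mcwd`` -- how much deeper cell i's maximum cumulative water
  deficit becomes if the link's monthly deliveries are removed (mm/yr),
  computed by counterfactual recomputation of the deficit recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hydro import MonthlyField, compute_mcwd, hydro_year_index

__all__ = [
    "MoistureNetwork",
    "LinkEffects",
    "link_effects",
    "annual_link_map",
    "link_mcwd_effect",
    "apply_landuse",
]


@dataclass
class MoistureNetwork:
    """Sparse directed monthly moisture links on a shared time axis.

    ``weights[l, t]`` is the moisture (mm/month) deposited at ``target[l]``
    from evapotranspiration at ``source[l]`` during time step ``t``.
    """

    source: np.ndarray  # (n_links,) int
    target: np.ndarray  # (n_links,) int
    weights: np.ndarray  # (n_links, n_time) mm/month
    years: np.ndarray  # (n_time,)
    months: np.ndarray  # (n_time,)
    n_cells: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=int)
        self.target = np.asarray(self.target, dtype=int)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        if self.weights.shape != (len(self.source), len(self.years)):
            raise ValueError("weights must be (n_links, n_time)")
        if np.any(self.weights < 0):
            raise ValueError("link weights must be non-negative")
        if np.any(self.source == self.target):
            raise ValueError("self-links are not part of the recycling network")

    @property
    def n_links(self) -> int:
        return len(self.source)

    def incoming_sum(self) -> np.ndarray:
        """Total moisture received per (cell, time step), mm/month."""
        out = np.zeros((self.n_cells, len(self.years)))
        np.add.at(out, self.target, self.weights)
        return out

    def to_frame(self, drop_zero: bool = True) -> pd.DataFrame:
        """Edge list (source_cell, target_cell, year, month, mm_month)."""
        n_links, n_time = self.weights.shape
        df = pd.DataFrame(
            {
                "source_cell": np.repeat(self.source, n_time),
                "target_cell": np.repeat(self.target, n_time),
                "year": np.tile(self.years, n_links),
                "month": np.tile(self.months, n_links),
                "mm_month": self.weights.ravel(),
            }
        )
        if drop_zero:
            df = df[df["mm_month"] > 0].reset_index(drop=True)
        return df


@dataclass
class LinkEffects:
    """Window-averaged hydrological effect of each link (mm/yr)."""

    source: np.ndarray
    target: np.ndarray
    delta_map: np.ndarray
    delta_mcwd: np.ndarray
    n_cells: int
    recycling_fraction: np.ndarray | None = None  # per-cell diagnostic

    @property
    def n_links(self) -> int:
        return len(self.source)

    def scaled(self, factor_per_source: np.ndarray) -> "LinkEffects":
        f = np.asarray(factor_per_source, dtype=float)[self.source]
        return replace(
            self, delta_map=self.delta_map * f, delta_mcwd=self.delta_mcwd * f
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_cell": self.source,
                "target_cell": self.target,
                "delta_map": self.delta_map,
                "delta_mcwd": self.delta_mcwd,
            }
        )


def _select_years(
    net: MoistureNetwork,
    p: MonthlyField,
    start_month: int,
    hydro_years: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    if not (
        len(net.years) == p.n_time
        and np.all(net.years == p.years)
        and np.all(net.months == p.months)
    ):
        raise ValueError("network and fields must share the same time axis")
    labels, idx = hydro_year_index(p.years, p.months, start_month)
    if len(labels) == 0:
        raise ValueError("window contains no complete hydrological year")
    if hydro_years is not None:
        sel = np.isin(labels, np.asarray(hydro_years))
        if not sel.any():
            raise ValueError("requested hydro years not covered by the fields")
        labels, idx = labels[sel], idx[sel]
    return labels, idx


def link_effects(
    net: MoistureNetwork,
    p: MonthlyField,
    e: MonthlyField,
    hydro_years: np.ndarray | None = None,
    start_month: int = 10,
    mode: str = "counterfactual",
) -> LinkEffects:
    """Window-averaged ``delta_map``/``delta_mcwd`` for every link.

    ``delta_map`` is the mean annual link delivery.  ``delta_mcwd`` is, per
    hydrological year, the deepening of the target's MCWD when the link's
    monthly deliveries are subtracted from its precipitation, averaged over
    the window (``mode="counterfactual"``, the default).  The cheaper
    ``mode="deficit_month_proxy"`` instead sums the link's deliveries over
    months in which the target's capped deficit is already negative.

    Also returns the per-cell internal recycling fraction
    ``sum_k delta_map_ki / MAP_i`` as a diagnostic.
    """
    if not p.same_time_axis(e):
        raise ValueError("P and E must share the same time axis")
    labels, idx = _select_years(net, p, start_month, hydro_years)
    n_years = len(labels)
    n_links = net.n_links

    delta_map = np.zeros(n_links)
    delta_mcwd = np.zeros(n_links)
    map_win = np.zeros(net.n_cells)

    for j in range(n_years):
        cols = idx[j]
        p_blk = p.values[:, cols]  # (n_cells, 12)
        e_blk = e.values[:, cols]
        m_blk = net.weights[:, cols]  # (n_links, 12)
        map_win += p_blk.sum(axis=1)
        delta_map += m_blk.sum(axis=1)
        base_mcwd = compute_mcwd(p_blk, e_blk)
        if mode == "counterfactual":
            p_red = p_blk[net.target] - m_blk
            if np.any(p_red < -1e-9):
                warnings.warn(
                    "link removal drives precipitation negative; clamping at 0",
                    stacklevel=2,
                )
            p_red = np.maximum(p_red, 0.0)
            cf_mcwd = compute_mcwd(p_red, e_blk[net.target])
            delta_mcwd += np.maximum(cf_mcwd - base_mcwd[net.target], 0.0)
        elif mode == "deficit_month_proxy":
            deficit = p_blk - e_blk
            cwd = np.zeros(net.n_cells)
            in_deficit = np.zeros((net.n_cells, 12), dtype=bool)
            for m in range(12):
                cwd = np.minimum(0.0, cwd + deficit[:, m])
                in_deficit[:, m] = cwd < 0
            delta_mcwd += (m_blk * in_deficit[net.target]).sum(axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")

    delta_map /= n_years
    delta_mcwd /= n_years
    map_win /= n_years
    incoming = np.zeros(net.n_cells)
    np.add.at(incoming, net.target, delta_map)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(map_win > 0, incoming / map_win, 0.0)
    return LinkEffects(
        source=net.source.copy(),
        target=net.target.copy(),
        delta_map=delta_map,
        delta_mcwd=delta_mcwd,
        n_cells=net.n_cells,
        recycling_fraction=frac,
    )


def annual_link_map(
    net: MoistureNetwork,
    p: MonthlyField | None = None,
    hydro_years: np.ndarray | None = None,
    start_month: int = 10,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Mean annual delivery per link and the per-cell recycling fraction.

    Without a precipitation field the recycling fraction (which needs
    MAP_i) is None.
    """
    if p is None:
        labels, idx = hydro_year_index(net.years, net.months, start_month)
        if len(labels) == 0:
            raise ValueError("window contains no complete hydrological year")
        if hydro_years is not None:
            sel = np.isin(labels, np.asarray(hydro_years))
            labels, idx = labels[sel], idx[sel]
        delta_map = net.weights[:, idx.ravel()].reshape(net.n_links, -1, 12)
        return delta_map.sum(axis=2).mean(axis=1), None
    eff = link_effects(
        net, p, p, hydro_years=hydro_years, start_month=start_month,
        mode="deficit_month_proxy",
    )
    return eff.delta_map, eff.recycling_fraction


def link_mcwd_effect(
    net: MoistureNetwork,
    p: MonthlyField,
    e: MonthlyField,
    k: int,
    i: int,
    hydro_years: np.ndarray | None = None,
    start_month: int = 10,
) -> float:
    """Counterfactual MCWD deepening at cell ``i`` from removing link k->i."""
    sel = (net.source == k) & (net.target == i)
    if not sel.any():
        return 0.0
    sub = MoistureNetwork(
        net.source[sel], net.target[sel], net.weights[sel],
        net.years, net.months, net.n_cells,
    )
    eff = link_effects(sub, p, e, hydro_years=hydro_years, start_month=start_month)
    return float(eff.delta_mcwd.sum())


def apply_landuse(
    net: MoistureNetwork, fractions: np.ndarray, retention: float = 0.0
) -> MoistureNetwork:
    """Scale each cell's outgoing links for a cleared fraction of the cell.

    Outgoing links of cell k are multiplied by ``1 - f_k * (1 - r)`` where
    ``r`` is the evapotranspiration retained by secondary vegetation
    (default 0: full removal).  Incoming links are untouched.  Composes
    multiplicatively.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("deforested fractions must lie in [0, 1]")
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must lie in [0, 1]")
    factor = 1.0 - fractions * (1.0 - retention)
    return replace(
        net,
        weights=net.weights * factor[net.source, None],
        meta={**net.meta, "landuse_applied": True},
    )
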