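"""Monte Carlo ensembles, transition-risk maps and cause attribution.

A *snapshot* is a committed-equilibrium experiment: the windowed (decadal)
climate of one period is held fixed, thresholds are drawn for one
ensemble member, and the coupled system is integrated from the all-forest
state.  The ensemble redraws the adaptive-capacity multiplier sigma per
snapshot and member; transition risk is the fraction of members in which
a cell ends in the transitioned regime.

Every transitioned cell is attributed to one cause:

* ``deforested`` -- held in the transitioned state by land use;
* ``map``        -- its own MAP forcing reached the critical value;
* ``mcwd``       -- its own drought-intensity forcing did (the larger
  component wins when both exceed the threshold);
* ``network``    -- neither local driver reached threshold: the cell was
  carried over by the loss of upwind moisture (a cascading transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .adaptation import (
    SIGMA_BOUNDS_DEFAULT,
    AdaptationProfile,
    compute_thresholds,
    fit_adaptation_series,
    guard_mask,
    sample_sigma,
)
from .dynamics import (
    ForcingComponents,
    ModelConfig,
    SnapshotResult,
    coupling_matrix,
    discrete_cascade,
    forcing_components,
    integrate_network,
)
from .hydro import hydro_series
from .network import LinkEffects, link_effects
from .synthetic import ScenarioBundle

__all__ = [
    "EnsembleResult",
    "run_snapshot",
    "run_ensemble",
    "attribute",
    "risk_plane",
    "REASONS",
]

REASONS = ("none", "map", "mcwd", "network", "deforested")


def attribute(
    snapshot: SnapshotResult,
    coupling: sp.spmatrix,
    forced_tipped: np.ndarray | None = None,
    removed_fraction: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-cell transition reasons and the three-way attribution shares.

    Deforestation-forced cells are labelled ``deforested`` and excluded
    from the shares; the remaining transitioned cells split into ``map``,
    ``mcwd`` and ``network`` (shares sum to 100% of attributed cells).
    A transitioned cell with stabilizing local forcing and no tipped or
    cleared in-neighbour is flagged inconsistent.
    """
    config = config or ModelConfig()
    n = snapshot.n_cells
    f = snapshot.forcing
    forced = (
        np.zeros(n, dtype=bool) if forced_tipped is None
        else np.asarray(forced_tipped, dtype=bool)
    )
    removed = (
        np.zeros(n) if removed_fraction is None
        else np.asarray(removed_fraction, dtype=float)
    )
    reason = np.array(["none"] * n, dtype=object)
    tr = snapshot.transitioned
    map_hit = (f.c_map >= config.c_star) & (f.c_map >= f.c_mcwd)
    mcwd_hit = f.c_mcwd >= config.c_star
    reason[tr] = "network"
    reason[tr & mcwd_hit] = "mcwd"
    reason[tr & map_hit] = "map"
    reason[forced] = "deforested"

    coupling = sp.csr_matrix(coupling)
    upstream = coupling @ (
        np.where(tr, 1.0, 0.0) + removed
    )  # any tipped or cleared in-neighbour mass
    inconsistent = (
        tr & ~forced & (reason == "network") & (f.c_crit <= 0) & (upstream <= 0)
    )
    if inconsistent.any():
        warnings.warn(
            f"{int(inconsistent.sum())} transitioned cell(s) have stabilizing "
            "local forcing and no tipped/cleared in-neighbour",
            stacklevel=2,
        )

    counts = {
        k: int(((reason == k)).sum()) for k in ("map", "mcwd", "network")
    }
    total = sum(counts.values())
    shares = {
        k: (100.0 * v / total if total else 0.0) for k, v in counts.items()
    }
    summary = {
        "counts": counts,
        "shares_pct": shares,
        "deforested_count": int(forced.sum()),
        "inconsistent": int(inconsistent.sum()),
    }
    return reason, summary


def run_snapshot(
    map_windowed: np.ndarray,
    mcwd_windowed: np.ndarray,
    effects: LinkEffects,
    profile: AdaptationProfile,
    landuse_fraction: np.ndarray | None = None,
    config: ModelConfig | None = None,
    retention: float = 0.0,
    forced_threshold: float = 0.5,
) -> SnapshotResult:
    """One committed-equilibrium run for a thresholded profile.

    Cells cleared beyond ``forced_threshold`` of their area are held in
    the transitioned state; every cell's cleared fraction (times
    ``1 - retention``) additionally counts as already-withdrawn moisture
    in the coupling term.  The result carries per-cell reasons.
    """
    config = config or ModelConfig()
    n = profile.n_cells
    f = (
        np.zeros(n) if landuse_fraction is None
        else np.asarray(landuse_fraction, dtype=float)
    )
    removed = f * (1.0 - retention)
    forced = f >= forced_threshold
    guard = profile.guard if profile.guard is not None else np.zeros(n, dtype=bool)
    tippable = (
        profile.tippable if profile.tippable is not None
        else np.ones(n, dtype=bool)
    )
    clamp = (guard | ~tippable) & ~forced

    forcing = forcing_components(map_windowed, mcwd_windowed, profile, config)
    coupling = coupling_matrix(effects, profile, config)
    result = integrate_network(
        forcing,
        coupling,
        config=config,
        forced_tipped=forced,
        removed_fraction=removed,
        guard=clamp,
    )
    reason, summary = attribute(result, coupling, forced, removed, config)
    result.reason = reason
    result.meta["attribution"] = summary
    result.meta["deforested_fraction"] = f
    return result


@dataclass
class EnsembleResult:
    """Aggregated Monte Carlo output over snapshots and members.

    ``risk[s, i]`` is the fraction of members in which cell i ended
    transitioned in snapshot s.  Area series are area-weighted
    percentages of the basin; ``area_forest_rel_*`` uses the initially
    forested (non-forced) area as denominator instead.
    """

    snapshot_labels: np.ndarray
    risk: np.ndarray  # (n_snapshots, n_cells)
    transitioned: np.ndarray  # (n_snapshots, n_members, n_cells) bool
    area_mean: np.ndarray  # (n_snapshots,) % of basin
    area_sd: np.ndarray
    area_forest_rel_mean: np.ndarray  # % of initially forested area
    deforested_pct: np.ndarray  # (n_snapshots,) % of basin area cleared
    attribution: list[dict]  # per snapshot, counts summed over members
    reasons: np.ndarray  # (n_snapshots, n_members, n_cells) object
    windowed_map: np.ndarray  # (n_snapshots, n_cells)
    windowed_mcwd: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return self.transitioned.shape[1]

    def area_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snapshot_label": self.snapshot_labels,
                "area_mean_pct": self.area_mean,
                "area_sd_pct": self.area_sd,
                "area_forest_rel_mean_pct": self.area_forest_rel_mean,
                "deforested_pct": self.deforested_pct,
            }
        )

    def risk_frame(self) -> pd.DataFrame:
        n_snap, n_cells = self.risk.shape
        return pd.DataFrame(
            {
                "snapshot_label": np.repeat(self.snapshot_labels, n_cells),
                "cell_id": np.tile(np.arange(n_cells), n_snap),
                "risk": self.risk.ravel(),
            }
        )


def _snapshot_starts(hydro_years: np.ndarray, window: int, n_snapshots: int):
    first = int(hydro_years[0])
    last_possible = int(hydro_years[-1]) - window + 1
    starts = [first + j * window for j in range(n_snapshots)]
    if starts[-1] > last_possible:
        raise ValueError(
            f"scenario years support snapshots starting at most {last_possible}"
        )
    return starts


def run_ensemble(
    bundle: ScenarioBundle,
    n_members: int = 10,
    window: int = 10,
    n_snapshots: int = 8,
    snapshot_starts: list[int] | None = None,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS_DEFAULT,
    sigma_mode: str = "uniform_iid",
    master_seed: int = 0,
    config: ModelConfig | None = None,
    use_guards: bool = False,
    retention: float = 0.0,
    adaptation_window: tuple[int, int] | None = None,
    effects_mode: str = "counterfactual",
    zero_network: bool = False,
) -> EnsembleResult:
    """Run the full Monte Carlo ensemble over decadal snapshots.

    Per snapshot, windowed MAP/MCWD and the link effects are computed
    once; per member, sigma is redrawn from
    ``(master_seed, snapshot, member)`` and the coupled system is
    integrated to its committed equilibrium.  ``zero_network`` ablates
    all couplings (cascade-free reference run).  Fully reproducible from
    ``master_seed``.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    config = config or ModelConfig()
    grid = bundle.grid
    hist = hydro_series(bundle.p_hist, bundle.e_hist)
    if adaptation_window is not None:
        hist = hist.year_slice(*adaptation_window)
    base_profile = fit_adaptation_series(hist)

    scen = hydro_series(bundle.p_scen, bundle.e_scen)
    starts = (
        snapshot_starts
        if snapshot_starts is not None
        else _snapshot_starts(scen.hydro_years, window, n_snapshots)
    )
    n_snap = len(starts)
    n_cells = grid.n_cells
    area = grid.area * grid.basin_mask
    basin_area = area.sum()

    transitioned = np.zeros((n_snap, n_members, n_cells), dtype=bool)
    reasons = np.empty((n_snap, n_members, n_cells), dtype=object)
    map_w_all = np.zeros((n_snap, n_cells))
    mcwd_w_all = np.zeros((n_snap, n_cells))
    deforested_pct = np.zeros(n_snap)
    attribution: list[dict] = []
    unconverged = 0

    for s, start in enumerate(starts):
        yrs = np.arange(start, start + window)
        sel = np.isin(scen.hydro_years, yrs)
        if sel.sum() < window:
            raise ValueError(f"snapshot window {start}-{start+window-1} incomplete")
        map_w = scen.map[:, sel].mean(axis=1)
        mcwd_w = scen.mcwd[:, sel].mean(axis=1)
        map_w_all[s], mcwd_w_all[s] = map_w, mcwd_w

        effects = link_effects(
            bundle.net, bundle.p_scen, bundle.e_scen,
            hydro_years=yrs, mode=effects_mode,
        )
        if zero_network:
            effects = LinkEffects(
                effects.source, effects.target,
                np.zeros_like(effects.delta_map),
                np.zeros_like(effects.delta_mcwd),
                effects.n_cells,
            )
        landuse_f = (
            bundle.landuse.fraction_at(int(yrs[-1]))
            if bundle.landuse is not None
            else None
        )
        deforested_pct[s] = (
            100.0 * float((landuse_f * area).sum() / basin_area)
            if landuse_f is not None
            else 0.0
        )
        guard = (
            guard_mask(map_w, mcwd_w) if use_guards else None
        )

        snap_counts = {"map": 0, "mcwd": 0, "network": 0, "deforested": 0}
        for m in range(n_members):
            rng = np.random.default_rng([master_seed, s, m])
            sigma = sample_sigma(
                n_cells, bounds=sigma_bounds, mode=sigma_mode,
                map_reference=base_profile.mu_map, rng=rng,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profile = compute_thresholds(base_profile, sigma)
            if guard is not None:
                profile.guard = guard
            result = run_snapshot(
                map_w, mcwd_w, effects, profile,
                landuse_fraction=landuse_f, config=config,
                retention=retention,
            )
            transitioned[s, m] = result.transitioned
            reasons[s, m] = result.reason
            if not result.converged:
                unconverged += 1
            for k in ("map", "mcwd", "network"):
                snap_counts[k] += result.meta["attribution"]["counts"][k]
            snap_counts["deforested"] += result.meta["attribution"][
                "deforested_count"
            ]
        attribution.append(snap_counts)

    member_area_pct = 100.0 * (transitioned @ area) / basin_area  # (s, m)
    forest_area = np.maximum(basin_area * (1 - deforested_pct / 100.0), 1e-12)
    forced_like = transitioned & (reasons == "deforested")
    nonforced_area = ((transitioned & ~forced_like) @ area)  # (s, m)
    return EnsembleResult(
        snapshot_labels=np.asarray(starts),
        risk=transitioned.mean(axis=1),
        transitioned=transitioned,
        area_mean=member_area_pct.mean(axis=1),
        area_sd=member_area_pct.std(axis=1),
        area_forest_rel_mean=(
            100.0 * nonforced_area.mean(axis=1) / forest_area
        ),
        deforested_pct=deforested_pct,
        attribution=attribution,
        reasons=reasons,
        windowed_map=map_w_all,
        windowed_mcwd=mcwd_w_all,
        meta={
            "master_seed": master_seed,
            "n_members": n_members,
            "sigma_bounds": tuple(sigma_bounds),
            "sigma_mode": sigma_mode,
            "window": window,
            "config": config.to_dict(),
            "use_guards": use_guards,
            "retention": retention,
            "zero_network": zero_network,
            "unconverged_runs": unconverged,
            "scenario": dict(bundle.meta),
        },
    )


def risk_plane(
    records, high_risk_pct: float = 10.0
) -> pd.DataFrame:
    """Tabulate scenario points in the MAP-MCWD plane.

    ``records`` is an iterable of (label, basin-mean windowed MAP,
    basin-mean windowed MCWD, transitioned area %).  A point is
    high-risk iff its transitioned area is at least ``high_risk_pct``
    (inclusive boundary).
    """
    rows = list(records)
    if len(rows) == 0:
        raise ValueError("need at least one scenario point")
    df = pd.DataFrame(
        rows, columns=["label", "map_mean", "mcwd_mean", "transitioned_pct"]
    )
    df["high_risk"] = df["transitioned_pct"] >= high_risk_pct
    return df
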