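"""Coupled bistable cell dynamics on the moisture-recycling network.

Each grid cell follows the normal form of a fold bifurcation::

    dx_i/dt = -x_i^3 + x_i + c_i(t)

with x = -1 the forest state and x = +1 the open/degraded state.  The
uncoupled cell loses its forest equilibrium exactly when the total
forcing c exceeds c* = sqrt(4/27) ~= 0.3849.  The forcing has a local
climatic part (how far the cell's decadal MAP and MCWD have moved from
the adaptation mean toward the critical thresholds, each scaled so the
threshold maps onto c*) and a network part: directed couplings R_ki
measuring how much of cell i's safety margin the moisture delivered by
cell k is worth, activated as upwind cells transition (or are cleared)
and their evapotranspiration is removed.

Two forcing components a, b combine as ``a + b - a*b/c*`` -- the
symmetric form of ``max + (1 - max/c*) * min`` -- which is capped at c*
whenever both components are below it, so a single driver at threshold
is exactly tipping-equivalent to any mixture at threshold.

The module also provides a discrete threshold-cascade oracle (fixed-point
iteration on tipped sets) used to cross-check the ODE steady states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .adaptation import AdaptationProfile
from .network import LinkEffects

__all__ = [
    "C_STAR",
    "ModelConfig",
    "ForcingComponents",
    "SnapshotResult",
    "c_map",
    "c_mcwd",
    "combine_components",
    "forcing_components",
    "coupling_matrix",
    "integrate_network",
    "discrete_cascade",
    "classify_states",
    "equilibrium_roots",
]

#: Critical forcing of the fold normal form -x^3 + x + c.
C_STAR = math.sqrt(4.0 / 27.0)


@dataclass
class ModelConfig:
    """Numerical and structural switches of the coupled model.

    ``map_form``: ``monotone_ramp`` (default) maps MAP linearly onto the
    forcing axis with the anchor points 0 at mu and c* at MAP_crit;
    ``literal_reciprocal`` uses the reciprocal-ratio form (which
    diverges at MAP = mu and is kept for comparison runs only).

    ``coupling_baseline``: ``zero_baseline`` (default) weights a source
    by w(x) = (x+1)/2, so an intact forest contributes nothing and the
    local climatic forcing is referenced to the realized climate, which
    already includes delivered moisture; ``literal_half_x`` uses
    w(x) = x/2, shifting the reference by the all-forest stabilization.
    """

    c_star: float = C_STAR
    map_form: str = "monotone_ramp"
    coupling_baseline: str = "zero_baseline"
    driver_mode: str = "both"  # both | map_only | mcwd_only
    dt: float = 0.1
    t_max: float = 500.0
    residual_tol: float = 1e-8
    transition_threshold: float = 0.0
    check_every: int = 25

    def __post_init__(self) -> None:
        if abs(self.c_star - C_STAR) > 1e-12:
            raise ValueError("c_star is pinned to sqrt(4/27)")
        if self.map_form not in ("monotone_ramp", "literal_reciprocal"):
            raise ValueError(f"unknown map_form {self.map_form!r}")
        if self.coupling_baseline not in ("zero_baseline", "literal_half_x"):
            raise ValueError(f"unknown coupling_baseline {self.coupling_baseline!r}")
        if self.driver_mode not in ("both", "map_only", "mcwd_only"):
            raise ValueError(f"unknown driver_mode {self.driver_mode!r}")
        if self.t_max <= 0 or self.dt <= 0:
            raise ValueError("dt and t_max must be positive")

    def to_dict(self) -> dict:
        return {
            "c_star": self.c_star,
            "map_form": self.map_form,
            "coupling_baseline": self.coupling_baseline,
            "driver_mode": self.driver_mode,
            "dt": self.dt,
            "t_max": self.t_max,
            "residual_tol": self.residual_tol,
            "transition_threshold": self.transition_threshold,
        }


@dataclass
class ForcingComponents:
    """Per-cell dimensionless forcing components and their combination."""

    c_map: np.ndarray
    c_mcwd: np.ndarray
    c_crit: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.c_crit)


def c_map(
    map_value, mu, map_crit, form: str = "monotone_ramp", c_star: float = C_STAR
):
    """Forcing from mean annual precipitation.

    Zero at the adaptation mean, c* at the critical threshold, negative
    (stabilizing) when wetter than the mean.  The default ramp is linear
    in MAP; the literal reciprocal form shares the anchor points but
    diverges at MAP = mu and is non-monotone across it.
    """
    map_value = np.asarray(map_value, dtype=float)
    mu = np.asarray(mu, dtype=float)
    map_crit = np.asarray(map_crit, dtype=float)
    if np.any(mu <= map_crit):
        raise ValueError("need mu > map_crit (non-degenerate threshold)")
    if form == "monotone_ramp":
        return c_star * (mu - map_value) / (mu - map_crit)
    if form == "literal_reciprocal":
        with np.errstate(divide="ignore"):
            return c_star * (map_crit - mu) / (map_value - mu)
    raise ValueError(f"unknown form {form!r}")


def c_mcwd(mcwd_value, mu, mcwd_crit, c_star: float = C_STAR):
    """Forcing from drought intensity: linear, zero at mu, c* at the
    critical deficit."""
    mcwd_value = np.asarray(mcwd_value, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mcwd_crit = np.asarray(mcwd_crit, dtype=float)
    if np.any(mcwd_crit <= mu):
        raise ValueError("need mcwd_crit > mu (non-degenerate threshold)")
    return c_star * (mcwd_value - mu) / (mcwd_crit - mu)


def combine_components(c_a, c_b, c_star: float = C_STAR):
    """Combine two forcing components.

    For components at or below the critical value the combination is
    ``a + b - a*b/c_star`` -- algebraically identical to
    ``max + (1 - max/c_star) * min``, hence symmetric, equal to either
    component when the other is zero, and bounded by c_star whenever
    both components are (with equality iff the larger one is exactly
    c_star).  That form is only meaningful up to the threshold: past it
    the cross term would *reduce* the combination, so once the larger
    component exceeds c_star it dominates outright (continuous and
    monotone completion -- a driver beyond its critical value tips the
    cell regardless of the other).
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    hi = np.maximum(c_a, c_b)
    product_form = c_a + c_b - c_a * c_b / c_star
    return np.where(hi >= c_star, hi, product_form)


def forcing_components(
    map_windowed: np.ndarray,
    mcwd_windowed: np.ndarray,
    profile: AdaptationProfile,
    config: ModelConfig | None = None,
) -> ForcingComponents:
    """Per-cell forcing from windowed MAP/MCWD and a thresholded profile.

    Non-tippable cells (degenerate thresholds) get zero forcing; the
    integrator additionally clamps them to the forest state.
    """
    config = config or ModelConfig()
    if profile.map_crit is None or profile.mcwd_crit is None:
        raise ValueError("profile has no thresholds; call compute_thresholds")
    tippable = (
        profile.tippable
        if profile.tippable is not None
        else np.ones(profile.n_cells, dtype=bool)
    )
    cm = np.zeros(profile.n_cells)
    cw = np.zeros(profile.n_cells)
    t = tippable
    if t.any():
        cm[t] = c_map(
            np.asarray(map_windowed, dtype=float)[t],
            profile.mu_map[t],
            profile.map_crit[t],
            form=config.map_form,
            c_star=config.c_star,
        )
        cw[t] = c_mcwd(
            np.asarray(mcwd_windowed, dtype=float)[t],
            profile.mu_mcwd[t],
            profile.mcwd_crit[t],
            c_star=config.c_star,
        )
    if config.driver_mode == "map_only":
        cc = cm.copy()
        cw = np.zeros_like(cw)
    elif config.driver_mode == "mcwd_only":
        cc = cw.copy()
        cm = np.zeros_like(cm)
    else:
        cc = combine_components(cm, cw, config.c_star)
    return ForcingComponents(c_map=cm, c_mcwd=cw, c_crit=cc)


def coupling_matrix(
    effects: LinkEffects,
    profile: AdaptationProfile,
    config: ModelConfig | None = None,
) -> sp.csr_matrix:
    """Dimensionless couplings R_ki as a sparse (target, source) matrix.

    Per link, the MAP part measures the link's annual delivery against
    the target's adaptive MAP range and the MCWD part the link-induced
    deficit deepening against the adaptive MCWD range::

        R_ki,MAP  = c* * delta_MAP_ki  / (mu_MAP,i  - MAP_crit,i)
        R_ki,MCWD = c* * delta_MCWD_ki / (MCWD_crit,i - mu_MCWD,i)

    combined with the same capped form as the local components (the
    lead-component case split of the combination is algebraically
    irrelevant).  A link delivering the full adaptive range alone has
    R = c*: losing it is exactly tipping-equivalent.  Rows of
    non-tippable targets are zero.
    """
    config = config or ModelConfig()
    if profile.map_crit is None:
        raise ValueError("profile has no thresholds; call compute_thresholds")
    if np.any(effects.delta_map < 0) or np.any(effects.delta_mcwd < 0):
        raise ValueError("link effects must be non-negative")
    tgt = effects.target
    tippable = (
        profile.tippable
        if profile.tippable is not None
        else np.ones(profile.n_cells, dtype=bool)
    )
    range_map = profile.mu_map - profile.map_crit
    range_mcwd = profile.mcwd_crit - profile.mu_mcwd
    ok = tippable[tgt]
    r_map = np.zeros(effects.n_links)
    r_mcwd = np.zeros(effects.n_links)
    if config.map_form == "literal_reciprocal":
        # verbatim reciprocal: c* (MAP_crit - mu) / delta_MAP -- negative and
        # inversely proportional to link mass; comparison runs only
        with np.errstate(divide="ignore", invalid="ignore"):
            r_map[ok] = config.c_star * -range_map[tgt[ok]] / effects.delta_map[ok]
        r_map[ok & (effects.delta_map == 0)] = 0.0
    else:
        r_map[ok] = config.c_star * effects.delta_map[ok] / range_map[tgt[ok]]
    r_mcwd[ok] = config.c_star * effects.delta_mcwd[ok] / range_mcwd[tgt[ok]]
    if config.driver_mode == "map_only":
        r = r_map
    elif config.driver_mode == "mcwd_only":
        r = r_mcwd
    else:
        r = combine_components(r_map, r_mcwd, config.c_star)
    mat = sp.coo_matrix(
        (r, (tgt, effects.source)), shape=(effects.n_cells, effects.n_cells)
    )
    return mat.tocsr()


@dataclass
class SnapshotResult:
    """Steady state of one coupled snapshot run."""

    x_final: np.ndarray
    transitioned: np.ndarray
    forcing: ForcingComponents
    converged: bool
    reason: np.ndarray | None = None  # filled by attribution
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.x_final)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x_final": self.x_final,
                "transitioned": self.transitioned,
                "c_map": self.forcing.c_map,
                "c_mcwd": self.forcing.c_mcwd,
                "c_crit": self.forcing.c_crit,
            }
        )
        if self.reason is not None:
            df["reason"] = self.reason
        return df


def _activation(x, removed, baseline: str):
    """Per-source share of moisture withdrawn, as seen by targets.

    ``zero_baseline``: w(x) = (x+1)/2 clipped to [0,1] -- the withdrawn
    share interpolates between the forest (x=-1, nothing withdrawn) and
    the transitioned state (x=+1, all evapotranspiration gone) and
    saturates there, since the cubic's equilibria overshoot +/-1 under
    forcing but a cell cannot lose more than all of its moisture.  A
    cleared fraction rho composes as a = rho + (1-rho)*w(x) (clearing
    and tipping remove moisture multiplicatively).
    ``literal_half_x``: w(x) = x/2 verbatim, with the same composition
    toward w(+1) = 1/2.
    """
    if baseline == "zero_baseline":
        w = np.clip(0.5 * (x + 1.0), 0.0, 1.0)
        return removed + (1.0 - removed) * w
    w = 0.5 * x
    return removed * 0.5 + (1.0 - removed) * w


def classify_states(x_final: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """A cell has transitioned iff its steady state exceeds ``threshold``."""
    return np.asarray(x_final, dtype=float) > threshold


def integrate_network(
    forcing: ForcingComponents,
    coupling: sp.spmatrix,
    init: np.ndarray | None = None,
    config: ModelConfig | None = None,
    forced_tipped: np.ndarray | None = None,
    removed_fraction: np.ndarray | None = None,
    guard: np.ndarray | None = None,
) -> SnapshotResult:
    """Integrate the coupled cells to steady state (fixed-step RK4).

    ``forced_tipped`` cells (e.g. deforested beyond half their area) are
    held at +1; ``guard`` cells and non-tippable cells are clamped to
    the forest state -1; ``removed_fraction`` is the per-source share of
    evapotranspiration already withdrawn by land use.  Integration stops
    when the residual ||dx/dt||_inf falls below ``residual_tol`` or at
    ``t_max`` (the result is then flagged unconverged).
    """
    config = config or ModelConfig()
    n = forcing.n_cells
    coupling = sp.csr_matrix(coupling)
    if coupling.shape != (n, n):
        raise ValueError("coupling shape must be (n_cells, n_cells)")
    c = forcing.c_crit
    x = np.full(n, -1.0) if init is None else np.asarray(init, dtype=float).copy()
    forced = (
        np.zeros(n, dtype=bool) if forced_tipped is None
        else np.asarray(forced_tipped, dtype=bool)
    )
    clamp_forest = np.zeros(n, dtype=bool) if guard is None else np.asarray(
        guard, dtype=bool
    ).copy()
    removed = (
        np.zeros(n) if removed_fraction is None
        else np.asarray(removed_fraction, dtype=float)
    )
    free = ~(forced | clamp_forest)
    x[forced] = 1.0
    x[clamp_forest] = -1.0

    def rhs(state: np.ndarray) -> np.ndarray:
        a = _activation(state, removed, config.coupling_baseline)
        dx = -state**3 + state + c + coupling @ a
        dx[~free] = 0.0
        return dx

    dt = config.dt
    n_steps = int(np.ceil(config.t_max / dt))
    converged = False
    for step in range(n_steps):
        k1 = rhs(x)
        if step % config.check_every == 0:
            if np.max(np.abs(k1), initial=0.0) < config.residual_tol:
                converged = True
                break
        k2 = rhs(x + 0.5 * dt * k1)
        k3 = rhs(x + 0.5 * dt * k2)
        k4 = rhs(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not converged:
        converged = bool(np.max(np.abs(rhs(x)), initial=0.0) < config.residual_tol)

    transitioned = classify_states(x, config.transition_threshold)
    transitioned |= forced
    return SnapshotResult(
        x_final=x,
        transitioned=transitioned,
        forcing=forcing,
        converged=converged,
        meta={"config": config.to_dict()},
    )


def discrete_cascade(
    forcing: ForcingComponents | np.ndarray,
    coupling: sp.spmatrix,
    seed_tipped: np.ndarray | None = None,
    config: ModelConfig | None = None,
    removed_fraction: np.ndarray | None = None,
    guard: np.ndarray | None = None,
    return_history: bool = False,
):
    """Threshold-cascade oracle: fixed-point iteration on the tipped set.

    Starting from ``seed_tipped``, any cell whose effective forcing
    (local + couplings from tipped/cleared sources under the configured
    baseline) strictly exceeds c* is tipped; repeat until stable
    (terminates in <= N passes; monotone in the seed set and in the
    couplings).  With ``return_history``, also returns the effective
    forcing seen at each pass, for margin checks.
    """
    config = config or ModelConfig()
    c = forcing.c_crit if isinstance(forcing, ForcingComponents) else np.asarray(
        forcing, dtype=float
    )
    n = len(c)
    coupling = sp.csr_matrix(coupling)
    tipped = (
        np.zeros(n, dtype=bool) if seed_tipped is None
        else np.asarray(seed_tipped, dtype=bool).copy()
    )
    guarded = np.zeros(n, dtype=bool) if guard is None else np.asarray(
        guard, dtype=bool
    )
    removed = (
        np.zeros(n) if removed_fraction is None
        else np.asarray(removed_fraction, dtype=float)
    )
    history = []
    for _ in range(n + 1):
        state = np.where(tipped, 1.0, -1.0)
        eff = c + coupling @ _activation(state, removed, config.coupling_baseline)
        if return_history:
            history.append(eff.copy())
        new = tipped | ((eff > config.c_star) & ~guarded)
        if np.array_equal(new, tipped):
            break
        tipped = new
    return (tipped, history) if return_history else tipped


def equilibrium_roots(c: float) -> np.ndarray:
    """Real roots of -x^3 + x + c = 0, ascending (bifurcation oracle aid)."""
    roots = np.roots([-1.0, 0.0, 1.0, float(c)])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real)
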