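"""Fold-bifurcation cell dynamics, coupling matrix, cascade oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

from tipcascade.adaptation import AdaptationProfile, compute_thresholds
from tipcascade.dynamics import (
    C_STAR,
    ForcingComponents,
    ModelConfig,
    c_map,
    c_mcwd,
    classify_states,
    combine_components,
    coupling_matrix,
    discrete_cascade,
    equilibrium_roots,
    integrate_network,
)
from tipcascade.network import LinkEffects


def forcing_from(c_values):
    c = np.asarray(c_values, dtype=float)
    return ForcingComponents(c_map=c.copy(), c_mcwd=np.zeros_like(c), c_crit=c)


def bisect_root(c, lo=0.0, hi=3.0):
    """Positive real root of -x^3 + x + c by bisection (independent oracle)."""
    f = lambda x: -x**3 + x + c
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestForcingComponents:
    def test_map_anchor_points(self):
        assert c_map(2000.0, 2000.0, 1700.0) == pytest.approx(0.0)
        assert c_map(1700.0, 2000.0, 1700.0) == pytest.approx(C_STAR)
        assert c_map(1850.0, 2000.0, 1700.0) == pytest.approx(0.19245, abs=1e-5)

    def test_map_wetter_than_mean_is_stabilizing(self):
        assert c_map(2300.0, 2000.0, 1700.0) < 0

    def test_literal_reciprocal_shares_threshold_anchor(self):
        assert c_map(1700.0, 2000.0, 1700.0,
                     form="literal_reciprocal") == pytest.approx(C_STAR)
        # the printed reciprocal diverges at the adaptation mean
        assert not np.isfinite(
            c_map(2000.0, 2000.0, 1700.0, form="literal_reciprocal")
        )

    def test_mcwd_anchor_points(self):
        assert c_mcwd(150.0, 150.0, 250.0) == pytest.approx(0.0)
        assert c_mcwd(250.0, 150.0, 250.0) == pytest.approx(C_STAR)
        assert c_mcwd(200.0, 150.0, 250.0) == pytest.approx(0.19245, abs=1e-5)

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            c_map(1800.0, 2000.0, 2000.0)
        with pytest.raises(ValueError):
            c_mcwd(200.0, 150.0, 150.0)


class TestCombine:
    def test_zero_zero(self):
        assert combine_components(0.0, 0.0) == pytest.approx(0.0)

    def test_threshold_component_caps_exactly(self):
        assert combine_components(C_STAR, 0.1) == pytest.approx(C_STAR)

    def test_worked_example(self):
        assert combine_components(0.2, 0.1) == pytest.approx(0.24804, abs=1e-5)

    def test_symmetry(self, rng):
        a = rng.uniform(-0.2, 0.6, 50)
        b = rng.uniform(-0.2, 0.6, 50)
        np.testing.assert_allclose(
            combine_components(a, b), combine_components(b, a)
        )

    def test_cap_identity_on_grid(self):
        a, b = np.meshgrid(np.linspace(0, C_STAR, 60), np.linspace(0, C_STAR, 60))
        combined = combine_components(a, b)
        assert np.all(combined <= C_STAR + 1e-12)
        at_cap = np.isclose(combined, C_STAR, atol=1e-12)
        max_at_cstar = np.isclose(np.maximum(a, b), C_STAR, atol=1e-12)
        np.testing.assert_array_equal(at_cap, max_at_cstar)

    def test_beyond_threshold_component_dominates(self):
        assert combine_components(0.5, 0.2) == pytest.approx(0.5)
        assert combine_components(0.5, -0.3) == pytest.approx(0.5)


class TestCouplingMatrix:
    @pytest.fixture
    def profile(self):
        prof = AdaptationProfile(
            mu_map=np.array([2000.0, 2000.0]),
            delta_map=np.array([200.0, 200.0]),
            mu_mcwd=np.array([150.0, 150.0]),
            delta_mcwd=np.array([80.0, 80.0]),
        )
        return compute_thresholds(prof, np.ones(2))

    def test_full_range_link_is_tipping_equivalent(self, profile):
        eff = LinkEffects(
            source=np.array([0]), target=np.array([1]),
            delta_map=np.array([200.0]), delta_mcwd=np.array([0.0]),
            n_cells=2,
        )
        mat = coupling_matrix(eff, profile)
        assert mat[1, 0] == pytest.approx(C_STAR)

    def test_zero_effects_give_zero_coupling(self, profile):
        eff = LinkEffects(
            source=np.array([0]), target=np.array([1]),
            delta_map=np.array([0.0]), delta_mcwd=np.array([0.0]), n_cells=2,
        )
        assert coupling_matrix(eff, profile)[1, 0] == 0.0

    def test_both_subcomponents_at_threshold_cap(self, profile):
        eff = LinkEffects(
            source=np.array([0]), target=np.array([1]),
            delta_map=np.array([200.0]), delta_mcwd=np.array([80.0]),
            n_cells=2,
        )
        assert coupling_matrix(eff, profile)[1, 0] == pytest.approx(C_STAR)

    def test_negative_effects_rejected(self, profile):
        eff = LinkEffects(
            source=np.array([0]), target=np.array([1]),
            delta_map=np.array([-5.0]), delta_mcwd=np.array([0.0]), n_cells=2,
        )
        with pytest.raises(ValueError):
            coupling_matrix(eff, profile)


class TestIntegrate:
    def test_unforced_cell_stays_forest(self):
        res = integrate_network(forcing_from([0.0]), sp.csr_matrix((1, 1)))
        assert res.x_final[0] == pytest.approx(-1.0, abs=1e-6)
        assert not res.transitioned[0]

    def test_supercritical_cell_reaches_positive_root(self):
        res = integrate_network(forcing_from([0.5]), sp.csr_matrix((1, 1)))
        assert res.x_final[0] == pytest.approx(bisect_root(0.5), abs=1e-6)
        assert res.x_final[0] == pytest.approx(1.1915, abs=1e-4)
        assert res.transitioned[0]

    def test_two_cell_cascade_example(self):
        coupling = sp.csr_matrix(
            (np.array([0.20]), (np.array([1]), np.array([0]))), shape=(2, 2)
        )
        res = integrate_network(forcing_from([0.40, 0.25]), coupling)
        assert res.transitioned.tolist() == [True, True]
        tipped = discrete_cascade(forcing_from([0.40, 0.25]), coupling)
        np.testing.assert_array_equal(tipped, res.transitioned)

    def test_steady_state_satisfies_cubic_residual(self, rng):
        n = 12
        c = rng.uniform(-0.1, 0.3, n)
        mask = rng.random((n, n)) < 0.2
        np.fill_diagonal(mask, False)
        coupling = sp.csr_matrix(np.where(mask, rng.uniform(0, 0.1, (n, n)), 0))
        res = integrate_network(forcing_from(c), coupling)
        assert res.converged
        w = np.clip(0.5 * (res.x_final + 1.0), 0.0, 1.0)
        c_eff = c + coupling @ w
        residual = -res.x_final**3 + res.x_final + c_eff
        assert np.max(np.abs(residual)) < 1e-6

    def test_guarded_cell_clamped_to_forest(self):
        res = integrate_network(
            forcing_from([0.5]), sp.csr_matrix((1, 1)),
            guard=np.array([True]),
        )
        assert res.x_final[0] == -1.0 and not res.transitioned[0]

    def test_forced_tipped_cell_held_at_plus_one(self):
        res = integrate_network(
            forcing_from([0.0]), sp.csr_matrix((1, 1)),
            forced_tipped=np.array([True]),
        )
        assert res.x_final[0] == 1.0 and res.transitioned[0]


class TestDiscreteCascade:
    def test_three_cell_chain_tips_completely(self):
        coupling = sp.csr_matrix(
            (np.array([0.15, 0.15]), (np.array([1, 2]), np.array([0, 1]))),
            shape=(3, 3),
        )
        tipped = discrete_cascade(forcing_from([0.40, 0.30, 0.30]), coupling)
        assert tipped.tolist() == [True, True, True]

    def test_subcritical_forcings_and_empty_seed(self):
        tipped = discrete_cascade(forcing_from([0.3, 0.2]), sp.csr_matrix((2, 2)))
        assert not tipped.any()

    def test_no_links_stops_propagation(self):
        tipped = discrete_cascade(forcing_from([0.40, 0.30]), sp.csr_matrix((2, 2)))
        assert tipped.tolist() == [True, False]

    def test_monotone_in_seed_and_coupling(self, rng):
        n = 10
        c = rng.uniform(-0.1, 0.35, n)
        dense = np.where(rng.random((n, n)) < 0.3, rng.uniform(0, 0.2, (n, n)), 0)
        np.fill_diagonal(dense, 0.0)
        base = discrete_cascade(forcing_from(c), sp.csr_matrix(dense))
        seeded = discrete_cascade(
            forcing_from(c), sp.csr_matrix(dense),
            seed_tipped=np.eye(n, dtype=bool)[0],
        )
        assert np.all(base <= seeded)
        stronger = discrete_cascade(forcing_from(c), sp.csr_matrix(dense * 1.5))
        assert np.all(base <= stronger)


class TestBifurcation:
    def test_critical_forcing_is_sqrt_4_27(self):
        # discriminant-zero oracle: the forest root exists just below and
        # vanishes just above the critical forcing
        eps = 1e-6
        assert equilibrium_roots(C_STAR - eps).min() < 0
        assert equilibrium_roots(C_STAR + eps).min() > 0

    def test_squared_critical_value(self):
        assert C_STAR**2 == pytest.approx(4.0 / 27.0, rel=1e-15)

    def test_basin_membership_around_threshold(self):
        below = integrate_network(
            forcing_from([C_STAR - 0.02]), sp.csr_matrix((1, 1))
        )
        above = integrate_network(
            forcing_from([C_STAR + 0.02]), sp.csr_matrix((1, 1))
        )
        assert below.x_final[0] < 0 < above.x_final[0]


def test_classify_states_threshold():
    x = np.array([-1.0, 1.0, 1.1915, 0.0])
    np.testing.assert_array_equal(
        classify_states(x), [False, True, True, False]
    )


def test_config_rejects_unknown_modes():
    with pytest.raises(ValueError):
        ModelConfig(map_form="quadratic")
    with pytest.raises(ValueError):
        ModelConfig(driver_mode="both_and_more")
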