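"""Transition-hazard curves: neutral rates, forward iteration, the four-point
parametric approximation, and the per-interval dosage matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from introscan import (
    DemographicModel,
    SelectionModel,
    forward_transition_rates,
    four_point_fit,
    logistic_trajectory,
    neutral_rates,
    site_transition_matrices,
)
from introscan.simulate import Scenario, simulate_admixture
from introscan.transitions import (
    NeutralCurve,
    default_r_grid,
    hazards_at,
    lift_binomial,
)

DEM = DemographicModel(Ne=1e4, m=0.1, t=200)


def test_neutral_rate_printed_formula():
    """Direct evaluation of L = 2Ne(1-m)(1-e^{-t/2Ne})."""
    L10, L01 = neutral_rates(DemographicModel(Ne=1e5, m=0.17, t=430))
    assert L10 == pytest.approx(356.5, abs=0.1)
    assert L01 == pytest.approx(356.5 * 0.17 / 0.83, rel=1e-3)


def test_neutral_rate_limits():
    # t << 2Ne: L10 -> (1-m) t
    L10, _ = neutral_rates(DemographicModel(Ne=1e8, m=0.3, t=100))
    assert L10 == pytest.approx(0.7 * 100, rel=1e-5)
    # m -> 0: L01 -> 0, L10 -> 2Ne(1-e^{-t/2Ne})
    L10, L01 = neutral_rates(DemographicModel(Ne=1e4, m=1e-9, t=100))
    assert L01 == pytest.approx(0.0, abs=1e-5)
    assert L10 == pytest.approx(2e4 * -np.expm1(-100 / 2e4), rel=1e-6)


def test_selection_off_reduces_to_neutral_rates():
    """Both backends collapse onto (L10, L01) for s = 0 at every distance."""
    L10, L01 = neutral_rates(DEM)
    grid = default_r_grid(DEM)
    tab = forward_transition_rates(DEM, SelectionModel(s=0.0), grid)
    np.testing.assert_allclose(tab.f10_tab, L10, rtol=1e-3)
    np.testing.assert_allclose(tab.f01_tab, L01, rtol=1e-3)
    fp = four_point_fit(DEM, SelectionModel(s=0.0))
    r = np.linspace(0, 0.1, 50)
    np.testing.assert_allclose(fp.f10(r), L10, rtol=1e-2)
    np.testing.assert_allclose(fp.f01(r), L01, rtol=1e-2)


def test_monotone_approach_to_neutral_limits():
    grid = default_r_grid(DEM, span=40.0)
    tab = forward_transition_rates(DEM, SelectionModel(s=0.05), grid)
    slack = 1e-3 * tab.L10
    assert (np.diff(tab.f10_tab) >= -slack).all()
    assert (np.diff(tab.f01_tab) <= slack).all()
    assert tab.f10_tab[-1] == pytest.approx(tab.L10, rel=0.05)
    # the f01 tail sits slightly above L01: a sweep inflates donor frequency
    # even at loosely linked sites (complete LD in the pulse generation)
    assert tab.f01_tab[-1] == pytest.approx(tab.L01, rel=0.15)
    assert tab.f10_tab[0] < 0.5 * tab.L10


def test_stronger_selection_widens_the_dip():
    """The transition-rate dip around the focal site widens with s."""
    dem = DemographicModel(Ne=1e4, m=0.01, t=400)
    grid = default_r_grid(dem)

    def half_width(s):
        tab = forward_transition_rates(dem, SelectionModel(s=s), grid)
        below = tab.f10_tab < 0.5 * tab.L10
        return grid[below].max()

    assert half_width(0.1) > half_width(0.05)


def test_four_point_interpolates_its_anchors():
    fp = four_point_fit(DEM, SelectionModel(s=0.05))
    x = logistic_trajectory(DEM, SelectionModel(s=0.05))
    r = np.array([fp.r2 * 1e-4, fp.r1, fp.r2])
    f10, f01 = hazards_at(DEM, x, r)
    np.testing.assert_allclose(fp.f10(r), f10, rtol=1e-3)
    np.testing.assert_allclose(fp.f01(r), f01, rtol=1e-3)


def test_four_point_degenerate_anchors_give_constant_curve():
    fp = four_point_fit(DEM, SelectionModel(s=0.0))
    assert fp.k10 == 0.0 or fp.k10 < 1e-6 * fp.L10


@pytest.mark.parametrize("m,s,t", [(0.1, 0.01, 200), (0.1, 0.05, 100), (0.01, 0.05, 400)])
def test_four_point_tracks_forward_iteration(m, s, t):
    """Parametric and forward-iteration curves agree over [0, 5 r2]."""
    dem = DemographicModel(Ne=1e4, m=m, t=t)
    fp = four_point_fit(dem, SelectionModel(s=s))
    tab = forward_transition_rates(dem, SelectionModel(s=s), default_r_grid(dem))
    r = np.linspace(0, 5 * fp.r2, 200)
    assert np.abs(fp.f10(r) - tab.f10(r)).max() / fp.L10 < 0.07
    scale = max(tab.f01(np.array([0.0]))[0], fp.L01)
    assert np.abs(fp.f01(r) - tab.f01(r)).max() / scale < 0.07


def test_hazards_match_tract_simulation_oracle():
    """Pairwise ancestry statistics of forward-simulated chromosomes agree
    with the three-locus recursion around a selected site."""
    dem = DemographicModel(Ne=5000, m=0.1, t=100)
    s = 0.05
    r_probe = np.array([0.002, 0.004, 0.008, 0.016, 0.03])
    d = 0.004
    n11 = np.zeros(len(r_probe)); n1 = np.zeros(len(r_probe))
    n00 = np.zeros(len(r_probe)); n0 = np.zeros(len(r_probe))
    xts = []
    for seed in range(6):
        pop = simulate_admixture(dem, Scenario.single_sweep(pos_M=0.5, s=s), seed=50 + seed)
        idx = np.arange(10_000)
        for sign in (1, -1):
            A1 = pop.ancestry_at(idx, 0.5 + sign * r_probe)
            A2 = pop.ancestry_at(idx, 0.5 + sign * (r_probe + d))
            n1 += (A1 == 1).sum(0); n11 += ((A1 == 1) & (A2 == 1)).sum(0)
            n0 += (A1 == 0).sum(0); n00 += ((A1 == 0) & (A2 == 0)).sum(0)
        xts.append(pop.trajectory[:, 0])
    # condition the recursion on the realised mean trajectory, removing the
    # logistic-vs-drift discrepancy from the comparison
    x = np.mean(xts, axis=0)
    f10, f01 = hazards_at(dem, x, r_probe + d / 2)
    # theory-implied stay probabilities over the probe interval
    lam = f10 + f01
    p_stay1 = f01 / lam + f10 / lam * np.exp(-lam * d)
    p_stay0 = f10 / lam + f01 / lam * np.exp(-lam * d)
    np.testing.assert_allclose(n11 / n1, p_stay1, atol=0.04)
    np.testing.assert_allclose(n00 / n0, p_stay0, atol=0.05)


def test_interval_matrix_identity_at_zero_distance():
    curve = NeutralCurve.from_model(DEM)
    pos = np.array([0.2, 0.2, 0.25])
    T = site_transition_matrices(curve, pos, 0.2, ploidy=1)
    np.testing.assert_allclose(T[0], np.eye(2), atol=1e-12)


def test_neutral_chain_has_admixture_stationary_distribution():
    curve = NeutralCurve.from_model(DEM)
    T = site_transition_matrices(curve, np.array([0.0, 0.02]), 0.0, ploidy=1)[0]
    pi = np.array([1 - DEM.m, DEM.m])
    np.testing.assert_allclose(pi @ T, pi, atol=1e-12)


def test_diploid_lift_equals_two_chromosome_enumeration():
    """The dosage-chain lift is the marginalised product of two independent
    single-chromosome chains."""
    rng = np.random.default_rng(0)
    P2 = np.empty((5, 2, 2))
    for k in range(5):
        p01, p10 = rng.random(2) * 0.6
        P2[k] = [[1 - p01, p01], [p10, 1 - p10]]
    lifted = lift_binomial(P2, 2)
    for k in range(5):
        brute = np.zeros((3, 3))
        for a in (0, 1):
            for b in (0, 1):
                for a2 in (0, 1):
                    for b2 in (0, 1):
                        brute[a + b, a2 + b2] += P2[k, a, a2] * P2[k, b, b2]
        brute[1] /= 2  # two equally likely chromosome configurations for dosage 1
        np.testing.assert_allclose(lifted[k], brute, atol=1e-12)


def test_lifted_rows_are_stochastic_for_large_ploidy():
    curve = four_point_fit(DEM, SelectionModel(s=0.05))
    pos = np.linspace(0.4, 0.6, 30)
    T = site_transition_matrices(curve, pos, 0.5, ploidy=50)
    np.testing.assert_allclose(T.sum(axis=2), 1.0, atol=1e-9)
    assert (T >= 0).all()


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.floats(0.02, 0.5), st.floats(0.001, 0.12), st.integers(30, 500))
def test_curves_are_nonnegative_with_neutral_limit(m, s, t):
    dem = DemographicModel(Ne=1e4, m=m, t=t)
    fp = four_point_fit(dem, SelectionModel(s=s))
    r = np.linspace(0, 10 * fp.r2, 100)
    assert (fp.f10(r) >= 0).all() and (fp.f01(r) >= 0).all()
    assert fp.f10(np.array([1e3]))[0] == pytest.approx(fp.L10, rel=1e-6)
    assert fp.f01(np.array([1e3]))[0] == pytest.approx(fp.L01, rel=1e-6)
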