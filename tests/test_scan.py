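"""Scan operations: golden-section optimisation, likelihood ratios, peak
calling and the neutral-simulation threshold."""

import math

import numpy as np
import pandas as pd
import pytest

from introscan import (
    DemographicModel,
    ScanConfig,
    Scanner,
    Scenario,
    find_peaks,
    null_threshold,
    simulate_dataset,
)
from introscan.scan import ScanResult
from introscan.simulate import SelectedSite, flip_labels


def _result(lrs, positions=None, s_hats=None):
    n = len(lrs)
    positions = positions if positions is not None else np.arange(n) * 100_000 + 1
    s_hats = s_hats if s_hats is not None else np.full(n, 0.01)
    return ScanResult(mode="gss", rows=pd.DataFrame(
        dict(chrom="chr1", pos_bp=positions, site_index=np.arange(n),
             s_hat=s_hats, lr=lrs, flags="")))


class _StubScanner(Scanner):
    """Scanner with a closed-form likelihood surface, for optimizer tests."""

    def __init__(self, table, dem, config, surface):
        super().__init__(table, dem, config)
        self._surface = surface

    def _curve(self, s):
        self._last_s = s
        return self.neutral_curve

    def _loglik_selected(self, lo, hi, i, curve):
        return self._surface(self._last_s)


@pytest.fixture(scope="module")
def sweep_setup(small_dataset):
    table, truth, dem = small_dataset
    return table, truth, dem


def test_gss_recovers_known_unimodal_maximum(sweep_setup):
    table, _, dem = sweep_setup
    target = 0.03
    sc = _StubScanner(table, dem, ScanConfig(), lambda s: -(math.log(s) - math.log(target)) ** 2)
    s_hat, lr, flags = sc.golden_section_optimize(len(table) // 2)
    assert s_hat == pytest.approx(target, rel=0.02)
    assert "boundary_lo" not in flags and "boundary_hi" not in flags


def test_gss_boundary_maximum_is_flagged(sweep_setup):
    table, _, dem = sweep_setup
    sc = _StubScanner(table, dem, ScanConfig(), lambda s: math.log(s))
    s_hat, lr, flags = sc.golden_section_optimize(len(table) // 2)
    assert s_hat == pytest.approx(0.15, rel=0.03)
    assert "boundary_hi" in flags


def test_lr_vanishes_as_s_approaches_zero(sweep_setup):
    """The selection model converges to the neutral model as s -> 0."""
    table, _, dem = sweep_setup
    sc = Scanner(table, dem, ScanConfig(s_lo=1e-6))
    lr = sc.site_likelihood_ratio(len(table) // 2, 1e-6)
    assert abs(lr) < 0.05


def test_optimizer_dominates_grid(sweep_setup):
    """LR at the gss optimum >= LR at any post-hoc grid value of s."""
    table, truth, dem = sweep_setup
    sc = Scanner(table, dem, ScanConfig())
    i = int(np.argmin(np.abs(sc.pos_bp - truth["sel_pos_bp"][0])))
    s_hat, lr, _ = sc.golden_section_optimize(i)
    for s in (0.005, 0.02, 0.05, 0.12):
        assert lr >= sc.site_likelihood_ratio(i, s) - 1e-6


def test_stride_covers_expected_sites(sweep_setup):
    table, _, dem = sweep_setup
    n = len(table)
    res = Scanner(table, dem, ScanConfig(stride=n)).scan()
    assert len(res.rows) == 1
    fine = Scanner(table, dem, ScanConfig(stride=40)).scan()
    coarse = Scanner(table, dem, ScanConfig(stride=80)).scan()
    merged = fine.rows.merge(coarse.rows, on="site_index", suffixes=("_f", "_c"))
    np.testing.assert_allclose(merged["lr_f"], merged["lr_c"], atol=1e-9)


def test_grid_mode_shapes_and_consistency(sweep_setup):
    table, _, dem = sweep_setup
    grid = (0.01, 0.05, 0.1)
    cfg = ScanConfig(mode="grid", s_grid=grid, stride=60)
    res = Scanner(table, dem, cfg).scan()
    n_focal = len(range(0, len(table), 60))
    assert len(res.rows) == n_focal * len(grid)
    best = res.per_site_max()
    assert set(best.columns) >= {"s_hat", "lr"}


def test_find_peaks_empty_below_threshold():
    assert find_peaks(_result([1.0, 2.0, 3.0]), threshold=10, min_sep_cM=2) == []


def test_find_peaks_proximity_filtering():
    """Two super-threshold sites 1 cM apart with 2 cM separation: only the
    higher survives; at 3 cM apart both survive."""
    res = _result([20.0, 25.0], positions=np.array([1_000_000, 2_000_000]))
    peaks = find_peaks(res, threshold=15, min_sep_cM=2)
    assert len(peaks) == 1 and peaks[0].lr == 25.0
    res2 = _result([20.0, 25.0], positions=np.array([1_000_000, 4_000_000]))
    assert len(find_peaks(res2, threshold=15, min_sep_cM=2)) == 2


def test_find_peaks_plateau_leftmost_tiebreak():
    res = _result([20.0, 20.0, 20.0], positions=np.array([1_000_000, 1_500_000, 2_000_000]))
    peaks = find_peaks(res, threshold=15, min_sep_cM=2)
    assert peaks[0].pos_bp == 1_000_000


def test_null_threshold_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    scans = [_result(rng.random(30), positions=np.arange(30) * 400_000 + 1) for _ in range(12)]
    thr = null_threshold(scans, min_sep_cM=2.0, target_fd_per_genome=1.0)
    assert thr.threshold <= 1.0
    thr2 = null_threshold(scans, min_sep_cM=2.0, target_fd_per_genome=3.0)
    assert thr2.threshold <= thr.threshold
    assert thr.se >= 0.0


def test_null_threshold_refuses_few_replicates():
    scans = [_result([0.5, 0.2])] * 5
    with pytest.raises(ValueError, match=">= 10"):
        null_threshold(scans)


def test_label_flip_scan_localizes_negative_selection():
    """Negative selection on the donor ancestry, scanned after the label
    flip, peaks near the selected site."""
    dem = DemographicModel(Ne=4000, m=0.3, t=150)
    table, truth = simulate_dataset(dem, Scenario.single_sweep(pos_M=0.5, s=-0.05),
                                    n_diploids=25, n_sites=1200, seed=41)
    flipped, dem_f = flip_labels(table, dem)
    sc = Scanner(flipped, dem_f, ScanConfig(stride=12))
    best = sc.scan().best()
    assert abs(best["pos_bp"] - truth["sel_pos_bp"][0]) < 1.5e6
    assert best["lr"] > 10


def test_two_linked_selected_sites():
    """5 cM apart: two separable peaks; 0.1 cM apart: a single peak whose
    coefficient approaches the sum of the two."""
    dem = DemographicModel(Ne=5000, m=0.1, t=200)
    s_each = 0.025
    far = Scenario(selected_sites=(SelectedSite(0.45, s_each), SelectedSite(0.50, s_each)))
    table, truth = simulate_dataset(dem, far, n_diploids=25, n_sites=1500, seed=42)
    scanner = Scanner(table, dem, ScanConfig(stride=10))
    cM = dict(enumerate(scanner.table.pos_morgans() * 100))
    res = scanner.scan()
    peaks = find_peaks(res, threshold=15, min_sep_cM=2, pos_cM=cM)
    assert len(peaks) >= 2
    for pos in truth["sel_pos_bp"]:
        assert min(abs(p.pos_bp - pos) for p in peaks) < 1e6

    near = Scenario(selected_sites=(SelectedSite(0.4995, s_each), SelectedSite(0.5005, s_each)))
    table2, truth2 = simulate_dataset(dem, near, n_diploids=25, n_sites=1500, seed=43)
    scanner2 = Scanner(table2, dem, ScanConfig(stride=10))
    cM2 = dict(enumerate(scanner2.table.pos_morgans() * 100))
    res2 = scanner2.scan()
    best = res2.best()
    assert best["s_hat"] > 1.3 * s_each  # joint effect, near the additive sum
    peaks2 = find_peaks(res2, threshold=15, min_sep_cM=2, pos_cM=cM2)
    # the two sites are not separable: both are closest to the same peak
    nearest = [min(peaks2, key=lambda p: abs(p.pos_bp - pos)).pos_bp
               for pos in truth2["sel_pos_bp"]]
    assert nearest[0] == nearest[1]
    assert abs(best["pos_bp"] - truth2["sel_pos_bp"][0]) < 5e5


def test_scan_backends_agree_on_s_estimate(small_dataset):
    table, truth, dem = small_dataset
    i = len(table) // 2
    out = {}
    for backend in ("four_point", "forward"):
        sc = Scanner(table, dem, ScanConfig(backend=backend))
        out[backend] = sc.golden_section_optimize(i)[0]
    assert out["four_point"] == pytest.approx(out["forward"], rel=0.25)
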