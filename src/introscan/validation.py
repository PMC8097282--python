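"""Scaled-down reruns of the method's simulation validation experiments.

Each experiment simulates data with :mod:`introscan.simulate`, runs the scan,
and reports the headline accuracy measure.  Problem sizes are desk-scale:
populations of 10,000 diploids on a single 1-Morgan / 10-Mb chromosome with
2,000-10,000 variant sites, ten seeded replicates per experiment.  These
functions back both the validation test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .iolib import DemographicModel, SiteTable
from .scan import ScanConfig, Scanner
from .simulate import (
    Scenario,
    SelectedSite,
    flip_labels,
    pool_observations,
    simulate_dataset,
)

FAVORABLE_DEM = DemographicModel(Ne=10_000, m=0.1, t=200)
FAVORABLE_S = 0.05
FAVORABLE_SCENARIO = Scenario.single_sweep(pos_M=0.5, s=FAVORABLE_S)

DMI_DEM = DemographicModel(Ne=10_000, m=0.5, t=500)
DMI_S = 0.1
DMI_SCENARIO = Scenario(
    selected_sites=(SelectedSite(0.3, 0.0), SelectedSite(0.7, 0.0)),
    dmi=("dominant_sign", -DMI_S),
)


def favorable_datasets(n_replicates: int, seed: int) -> list[tuple[SiteTable, dict]]:
    """Simulate the favorable-regime replicates (m=0.1, s=0.05, t=200,
    25 diploids, depth 2, error 0.01)."""
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    return [
        simulate_dataset(FAVORABLE_DEM, FAVORABLE_SCENARIO, n_diploids=25,
                         n_sites=2000, seed=np.random.default_rng(c))
        for c in children
    ]


def scan_best(table: SiteTable, dem: DemographicModel, stride: int = 25,
              focal_indices=None, **config_kw):
    """Full (or restricted) gss scan; returns the top-likelihood-ratio row."""
    scanner = Scanner(table, dem, ScanConfig(stride=stride, **config_kw))
    return scanner.scan(focal_indices=focal_indices).best()


def parameter_recovery(datasets) -> float:
    """Mean relative error (%) of s_hat at the genome-wide top LR site."""
    errs = [
        abs(scan_best(table, FAVORABLE_DEM)["s_hat"] - FAVORABLE_S) / FAVORABLE_S
        for table, _ in datasets
    ]
    return 100.0 * float(np.mean(errs))


def _local_scan_error(table, truth, dem) -> float:
    scanner = Scanner(table, dem, ScanConfig())
    i0 = int(np.argmin(np.abs(scanner.pos_bp - truth["sel_pos_bp"][0])))
    idxs = np.arange(max(i0 - 20, 0), min(i0 + 21, scanner.n_sites()), 5)
    best = scanner.scan(focal_indices=idxs).best()
    return abs(best["s_hat"] - FAVORABLE_S) / FAVORABLE_S


def misspecification_robustness(datasets) -> float:
    """Worst-case mean relative error (%) of s_hat when m and t are each
    supplied 20% above/below truth, scanning the true focal region."""
    dem = FAVORABLE_DEM
    perturbed = [
        DemographicModel(dem.Ne, dem.m * 0.8, dem.t),
        DemographicModel(dem.Ne, dem.m * 1.2, dem.t),
        DemographicModel(dem.Ne, dem.m, dem.t * 0.8),
        DemographicModel(dem.Ne, dem.m, dem.t * 1.2),
    ]
    means = []
    for dm in perturbed:
        errs = [_local_scan_error(table, truth, dm) for table, truth in datasets]
        means.append(np.mean(errs))
    return 100.0 * float(max(means))


def pooled_recovery(datasets) -> float:
    """Mean relative error (%) of s_hat with all reads merged into one pooled
    50-chromosome observation column, scanning every 100th site."""
    errs = []
    for table, _ in datasets:
        pooled = pool_observations(table)
        best = scan_best(pooled, FAVORABLE_DEM, stride=100)
        errs.append(abs(best["s_hat"] - FAVORABLE_S) / FAVORABLE_S)
    return 100.0 * float(np.mean(errs))


def dmi_experiment(n_replicates: int, seed: int) -> tuple[float, float]:
    """Dominant-sign-epistasis DMI: 50% pulse, |s| = 0.1, loci 40 cM apart.

    Per replicate the winning (co-adapted) ancestry is read from the truth
    trajectory, the data are label-flipped accordingly so the scan sees it as
    positively selected, and each locus is scanned locally.  Returns the
    median peak-to-truth distance (kb) and the mean underestimation of |s|
    (%, relative to the simulated interaction strength).
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    dists, s_hats = [], []
    for c in children:
        table, truth = simulate_dataset(
            DMI_DEM, DMI_SCENARIO, n_diploids=25, n_sites=10_000,
            seed=np.random.default_rng(c),
        )
        win1 = truth["trajectory"][-1, 0] > 0.5
        tb, dem = (table, DMI_DEM) if win1 else flip_labels(table, DMI_DEM)
        scanner = Scanner(tb, dem, ScanConfig())
        for pos_true in truth["sel_pos_bp"]:
            i0 = int(np.argmin(np.abs(scanner.pos_bp - pos_true)))
            idxs = np.arange(max(i0 - 40, 0), min(i0 + 41, scanner.n_sites()), 2)
            best = scanner.scan(focal_indices=idxs).best()
            dists.append(abs(best["pos_bp"] - pos_true))
            s_hats.append(abs(best["s_hat"]))
    median_kb = float(np.median(dists)) / 1e3
    underest = 100.0 * float(np.mean([(DMI_S - s) / DMI_S for s in s_hats]))
    return median_kb, underest
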