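"""Forward Wright-Fisher simulator, panel synthesis and read simulation."""

import numpy as np
import pytest

from introscan import (
    DemographicModel,
    Scenario,
    SelectionModel,
    logistic_trajectory,
    neutral_rates,
    simulate_admixture,
    simulate_dataset,
)
from introscan.simulate import (
    SelectedSite,
    flip_labels,
    pool_observations,
    simulate_reads,
    synthesize_panels_and_genotypes,
)


def test_tract_tiling_invariant():
    dem = DemographicModel(Ne=500, m=0.3, t=60)
    pop = simulate_admixture(dem, Scenario.neutral(), seed=1)
    for i in range(0, pop.n_chromosomes, 97):
        tr = pop.tracts(i)
        assert tr[0][1] == 0.0 and tr[-1][2] == pytest.approx(pop.L_M)
        for (a1, _, e1), (a2, s2, _) in zip(tr, tr[1:]):
            assert e1 == s2 and a1 != a2


def test_neutral_donor_fraction_is_a_martingale():
    """Mean genome-wide donor fraction across replicates stays ~ m."""
    dem = DemographicModel(Ne=800, m=0.2, t=80)
    fracs = [simulate_admixture(dem, Scenario.neutral(), seed=s).donor_fraction()
             for s in range(6)]
    assert np.mean(fracs) == pytest.approx(0.2, abs=0.04)


def test_neutral_tract_length_matches_theory():
    """Mean interior donor tract length ~ 1/L10."""
    dem = DemographicModel(Ne=2000, m=0.2, t=100)
    pop = simulate_admixture(dem, Scenario.neutral(), seed=2)
    L10, _ = neutral_rates(dem)
    tl = pop.tract_lengths(1, chrom_idx=range(800))
    assert tl.mean() == pytest.approx(1 / L10, rel=0.15)


def test_sweep_trajectory_matches_logistic_within_drift():
    dem = DemographicModel(Ne=10_000, m=0.1, t=200)
    sel = SelectedSite(0.5, 0.05)
    pop = simulate_admixture(dem, Scenario(selected_sites=(sel,)), seed=3)
    x = logistic_trajectory(dem, SelectionModel(s=0.05))
    assert np.abs(pop.trajectory[:, 0] - x).max() < 0.06


def test_neutral_scenario_keeps_frequency_near_m():
    dem = DemographicModel(Ne=2000, m=0.2, t=100)
    pop = simulate_admixture(dem, Scenario.single_sweep(pos_M=0.5, s=0.0), seed=4)
    assert pop.trajectory[-1, 0] == pytest.approx(0.2, abs=0.06)


def test_conditioned_small_pulse_retains_allele():
    dem = DemographicModel(Ne=1000, m=0.002, t=100)
    for seed in range(3):
        pop = simulate_admixture(dem, Scenario.single_sweep(pos_M=0.5, s=0.05),
                                 seed=seed, condition_on_retention=True)
        assert pop.trajectory[-1, 0] > 0


def test_early_stop_at_high_frequency():
    dem = DemographicModel(Ne=2000, m=0.2, t=300)
    scen = Scenario(selected_sites=(SelectedSite(0.5, 0.1),), stop_at_freq=0.9)
    pop = simulate_admixture(dem, scen, seed=5)
    assert pop.gen_reached < 300
    assert pop.trajectory[pop.gen_reached, 0] >= 0.9
    assert pop.trajectory[-1, 0] == pop.trajectory[pop.gen_reached, 0]


def test_dominance_changes_fixation_speed():
    """A dominant allele escapes low frequency faster than a recessive one."""
    dem = DemographicModel(Ne=2000, m=0.05, t=150)
    end = {}
    for h in (0.0, 1.0):
        pop = simulate_admixture(
            dem, Scenario(selected_sites=(SelectedSite(0.5, 0.08, h=h),)), seed=6)
        end[h] = pop.trajectory[60, 0]
    assert end[1.0] > end[0.0]


def test_continuous_gene_flow_raises_donor_fraction():
    dem = DemographicModel(Ne=1000, m=0.01, t=60)
    scen = Scenario(migration_rate=0.01, migration_generations=20)
    pop = simulate_admixture(dem, scen, seed=7)
    # ~ m + 20 x 1% of migrant replacement, minus drift
    assert 0.1 < pop.donor_fraction() < 0.35


def test_panel_correlation_decreases_with_divergence():
    dem = DemographicModel(Ne=500, m=0.2, t=50)
    pop = simulate_admixture(dem, Scenario.neutral(), seed=8)
    cors = []
    for div in (0.05, 0.3, 0.7):
        df, _, _ = synthesize_panels_and_genotypes(pop, n_sites=2000, divergence=div,
                                                   seed=9)
        f0 = df["panel0_A"] / (df["panel0_A"] + df["panel0_a"])
        f1 = df["panel1_A"] / (df["panel1_A"] + df["panel1_a"])
        cors.append(np.corrcoef(f0, f1)[0, 1])
    assert cors[0] > cors[1] > cors[2]


def test_high_divergence_makes_ancestry_readable():
    dem = DemographicModel(Ne=500, m=0.3, t=50)
    pop = simulate_admixture(dem, Scenario.neutral(), seed=10)
    df, haps, anc = synthesize_panels_and_genotypes(pop, n_sites=1000, divergence=0.95,
                                                    n_sample_chrom=20, seed=11)
    f0 = (df["panel0_A"].to_numpy() + 1) / 52
    f1 = (df["panel1_A"].to_numpy() + 1) / 52
    informative = np.abs(f0 - f1) > 0.5
    call = (np.abs(haps - f1[None, :]) < np.abs(haps - f0[None, :]))
    acc = (call[:, informative] == (anc[:, informative] == 1)).mean()
    assert acc > 0.95


def test_read_simulation_edge_cases():
    haps = np.array([[1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.uint8)
    nA, na = simulate_reads(haps, (2,), depth_mean=0.0, seed=12)
    assert nA.sum() == 0 and na.sum() == 0
    homo = np.ones((2, 200), dtype=np.uint8)
    nA, na = simulate_reads(homo, (2,), depth_mean=3.0, error=0.0, seed=13)
    assert na.sum() == 0 and nA.sum() > 0
    many = np.zeros((2, 5000), dtype=np.uint8)
    nA, na = simulate_reads(many, (2,), depth_mean=2.0, seed=14)
    assert (nA + na).mean() == pytest.approx(2.0, rel=0.05)


def test_flip_labels_is_an_involution(small_dataset):
    table, _, dem = small_dataset
    flipped, dem_f = flip_labels(table, dem)
    assert dem_f.m == pytest.approx(1 - dem.m)
    back, dem_b = flip_labels(flipped, dem_f)
    assert dem_b.m == pytest.approx(dem.m)
    assert back.df.equals(table.df)


def test_pool_observations_conserves_reads(small_dataset):
    table, _, _ = small_dataset
    pooled = pool_observations(table)
    assert pooled.samples.pooled
    assert pooled.samples.ploidies == (sum(table.samples.ploidies),)
    tot_A = sum(table.obs(s)[0] for s in table.samples.ids)
    np.testing.assert_array_equal(pooled.obs(pooled.samples.ids[0])[0], tot_A)


def test_dmi_fixes_one_coadapted_pair():
    dem = DemographicModel(Ne=2000, m=0.5, t=300)
    scen = Scenario(selected_sites=(SelectedSite(0.3, 0.0), SelectedSite(0.7, 0.0)),
                    dmi=("dominant_sign", -0.1))
    pop = simulate_admixture(dem, scen, seed=15)
    fA, fB = pop.trajectory[-1]
    assert min(fA, 1 - fA) < 0.05 and min(fB, 1 - fB) < 0.05
    assert abs(fA - fB) < 0.1  # the winning alleles are co-adapted


def test_simulate_dataset_truth_record(small_dataset):
    table, truth, _ = small_dataset
    assert truth["sample_ancestry"].shape == (16, len(table))
    assert len(truth["sel_pos_bp"]) == 1
    assert 0 <= truth["site_donor_frequency"].min() <= truth["site_donor_frequency"].max() <= 1
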