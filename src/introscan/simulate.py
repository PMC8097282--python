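"""Forward Wright-Fisher admixture simulation with selection, reference-panel
synthesis and short-read simulation: the fixture generator used to validate
the scan end to end.

The simulator tracks exact ancestry tracts for every chromosome of a diploid
population through discrete generations (fitness-proportional parent
sampling, Poisson crossovers without interference).  Variant sites are then
laid down uniformly along the map, reference-panel and sample alleles are
drawn from Balding-Nichols-dispersed population frequencies (one divergence
knob standing in for the full two-population demography — the inference never
sees the demography, only panel counts), and reads are simulated with
Poisson depth and a uniform per-allele error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _wf
from .iolib import FIXED_COLUMNS, DemographicModel, SampleSet, SiteTable

__all__ = [
    "SelectedSite",
    "Scenario",
    "AdmixedPopulation",
    "simulate_admixture",
    "synthesize_panels_and_genotypes",
    "simulate_reads",
    "flip_labels",
    "pool_observations",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SelectedSite:
    """One selected locus: map position (Morgans), genic selection coefficient
    s (diploid fitness 1 + s * dosage), dominance h in {0, 0.5, 1} with 0.5
    additive, and the donor-population starting frequency of the allele."""

    pos_M: float
    s: float
    h: float = 0.5
    start_freq: float = 1.0

    def __post_init__(self):
        if not abs(self.s) < 1:
            raise ValueError("|s| must be < 1")


@dataclass(frozen=True)
class Scenario:
    """Admixture-plus-selection scenario for the simulator.

    ``dmi`` switches the fitness model to a two-locus Dobzhansky-Muller
    incompatibility: ``("dominant_sign", s)`` penalises any cross-population
    allele combination at the two selected sites by 1+s (s < 0);
    ``("one_directional", s)`` penalises only the A0+B1 combination.
    ``migration_rate``/``migration_generations`` add continuous gene flow
    after the initial pulse (migrants carry the selected allele at its donor
    starting frequency).
    """

    selected_sites: tuple[SelectedSite, ...] = ()
    dmi: tuple[str, float] | None = None
    migration_rate: float = 0.0
    migration_generations: int = 0
    stop_at_freq: float | None = None

    def __post_init__(self):
        if self.dmi is not None:
            mode, s = self.dmi
            if mode not in ("dominant_sign", "one_directional"):
                raise ValueError(f"unknown DMI mode {mode!r}")
            if len(self.selected_sites) != 2:
                raise ValueError("a DMI scenario needs exactly two loci")
            if s >= 0:
                raise ValueError("DMI interaction strength must be negative")

    @classmethod
    def single_sweep(cls, pos_M: float = 0.5, s: float = 0.05, **kw) -> "Scenario":
        return cls(selected_sites=(SelectedSite(pos_M, s, **kw),))

    @classmethod
    def neutral(cls) -> "Scenario":
        return cls(selected_sites=())


class AdmixedPopulation:
    """Simulated admixed population: exact ancestry tracts per chromosome,
    selected-site alleles, and the realised allele-frequency trajectory."""

    def __init__(self, junc, nj, start, allele, traj, dem, scenario, L_M, gen_reached):
        self._junc = junc
        self._nj = nj
        self._start = start
        self.alleles = allele
        self.trajectory = traj
        self.dem = dem
        self.scenario = scenario
        self.L_M = L_M
        self.gen_reached = gen_reached

    @property
    def n_chromosomes(self) -> int:
        return len(self._nj)

    def tracts(self, i: int) -> list[tuple[int, float, float]]:
        """Ancestry tracts (ancestry, start_M, end_M) tiling chromosome i."""
        junc = self._junc[i, : self._nj[i]]
        bounds = np.concatenate([[0.0], junc, [self.L_M]])
        anc = int(self._start[i])
        out = []
        for k in range(len(bounds) - 1):
            out.append(((anc + k) % 2, float(bounds[k]), float(bounds[k + 1])))
        return out

    def ancestry_at(self, chrom_idx: np.ndarray, pos_M: np.ndarray) -> np.ndarray:
        """Local ancestry matrix, shape (len(chrom_idx), len(pos_M))."""
        return _wf.ancestry_at_positions(
            self._junc, self._nj, self._start,
            np.asarray(chrom_idx, dtype=np.int64), np.asarray(pos_M, dtype=float),
        )

    def donor_fraction(self) -> float:
        """Genome-wide donor-ancestry fraction (tract-length weighted)."""
        total = 0.0
        for i in range(self.n_chromosomes):
            for anc, lo, hi in self.tracts(i):
                if anc == 1:
                    total += hi - lo
        return total / (self.n_chromosomes * self.L_M)

    def tract_lengths(self, ancestry: int, chrom_idx=None, interior_only: bool = True):
        """Tract lengths of one ancestry, optionally excluding end-censored tracts."""
        if chrom_idx is None:
            chrom_idx = range(self.n_chromosomes)
        out = []
        for i in chrom_idx:
            tr = self.tracts(i)
            for k, (anc, lo, hi) in enumerate(tr):
                if anc != ancestry:
                    continue
                if interior_only and (k == 0 or k == len(tr) - 1):
                    continue
                out.append(hi - lo)
        return np.asarray(out)


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed) % (2**31 - 1)


def simulate_admixture(
    dem: DemographicModel,
    scenario: Scenario,
    L_M: float = 1.0,
    seed: int | np.random.Generator = 0,
    condition_on_retention: bool = False,
    max_retries: int = 50,
) -> AdmixedPopulation:
    """Discrete-generation Wright-Fisher simulation of ``dem.Ne`` diploids for
    ``dem.t`` generations after a single admixture pulse of fraction ``m``.

    With ``condition_on_retention`` the run is restarted (fresh seed) when the
    first selected allele is lost, up to ``max_retries`` times — the device
    used for small-pulse scenarios.
    """
    n_ind = int(round(dem.Ne))
    t = int(round(dem.t))
    sites = scenario.selected_sites
    n_loci = max(len(sites), 1)
    loci_pos = np.array([s.pos_M for s in sites] or [L_M / 2.0])
    loci_s = np.array([s.s for s in sites] or [0.0])
    loci_h = np.array([s.h for s in sites] or [0.5])
    start_freq = np.array([s.start_freq for s in sites] or [1.0])
    if (loci_pos < 0).any() or (loci_pos > L_M).any():
        raise ValueError("selected-site positions must lie on the map")
    if scenario.dmi is None:
        mode, dmi_s = _wf.ADDITIVE, 0.0
    else:
        mode = _wf.DMI_DOMINANT if scenario.dmi[0] == "dominant_sign" else _wf.DMI_ONE_DIRECTIONAL
        dmi_s = float(scenario.dmi[1])
        loci_s = np.zeros(2)
    # expected ancestry switches per chromosome, used to size the tract buffer
    lam = 2.0 * dem.Ne * -np.expm1(-t / (2.0 * dem.Ne))
    cap = int(max(256, 3.0 * 2.0 * dem.m * (1 - dem.m) * lam * L_M + 64))
    base_seed = _seed_int(seed)
    for attempt in range(max_retries):
        run_seed = (base_seed + 7919 * attempt) % (2**31 - 1)
        junc, nj, start, allele, traj, gen_reached, err = _wf.simulate_wf_kernel(
            run_seed, n_ind, t, float(L_M), cap,
            loci_pos, loci_s, loci_h, start_freq, mode, dmi_s,
            float(scenario.migration_rate), int(scenario.migration_generations),
            float(scenario.stop_at_freq or 0.0), float(dem.m),
        )
        if err:
            raise RuntimeError(f"ancestry-junction buffer overflow (cap={cap})")
        if not condition_on_retention or traj[-1, 0] > 0:
            return AdmixedPopulation(junc, nj, start, allele, traj, dem, scenario, L_M, gen_reached)
    raise RuntimeError(
        f"selected allele lost in all {max_retries} conditioned attempts"
    )


def _sfs_frequencies(rng: np.random.Generator, n: int, lo=0.05, hi=0.95) -> np.ndarray:
    # neutral-SFS-like density ~ 1/x, truncated away from the boundaries
    u = rng.random(n)
    return lo * (hi / lo) ** u


def synthesize_panels_and_genotypes(
    pop: AdmixedPopulation,
    n_sites: int = 2000,
    divergence: float = 0.3,
    panel_size: int = 50,
    n_sample_chrom: int = 50,
    chrom_len_bp: int = 10_000_000,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
):
    """Lay down variant sites and draw panel counts plus sample haplotypes.

    Per site an ancestral frequency is drawn from a 1/x density and the two
    population frequencies are Balding-Nichols dispersed around it with the
    given ``divergence`` (an Fst-like scalar in (0, 1)).  Panel allele counts
    are binomial draws of ``panel_size`` haplotypes; each sampled chromosome's
    allele is drawn from the frequency of its local ancestry's population.

    Returns ``(site_df, haplotypes, sample_anc)``: the fixed count-table
    columns, the 0/1 A-allele haplotype matrix (n_sample_chrom, n_sites), and
    the true local-ancestry matrix of the sampled chromosomes.
    """
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must be in (0, 1)")
    if n_sites < 100:
        raise ValueError("need at least 100 sites")
    if panel_size < 10:
        raise ValueError("need at least 10 haplotypes per panel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_bp = np.sort(rng.choice(np.arange(1, chrom_len_bp + 1), size=n_sites, replace=False))
    pos_m = pos_bp / chrom_len_bp * pop.L_M
    anc_freq = _sfs_frequencies(rng, n_sites)
    c = (1.0 - divergence) / divergence
    p0 = rng.beta(anc_freq * c, (1.0 - anc_freq) * c)
    p1 = rng.beta(anc_freq * c, (1.0 - anc_freq) * c)
    p0 = np.clip(p0, 1e-6, 1.0 - 1e-6)
    p1 = np.clip(p1, 1e-6, 1.0 - 1e-6)
    panel0_A = rng.binomial(panel_size, p0)
    panel1_A = rng.binomial(panel_size, p1)
    chrom_idx = np.arange(n_sample_chrom)
    sample_anc = pop.ancestry_at(chrom_idx, pos_m)
    pfreq = np.where(sample_anc == 1, p1[None, :], p0[None, :])
    haplotypes = (rng.random(pfreq.shape) < pfreq).astype(np.uint8)
    dist = np.diff(pos_m, prepend=pos_m[0])
    dist[0] = 0.0
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos_bp,
            "panel0_A": panel0_A,
            "panel0_a": panel_size - panel0_A,
            "panel1_A": panel1_A,
            "panel1_a": panel_size - panel1_A,
            "dist": dist,
        }
    )
    return df, haplotypes, sample_anc


def simulate_reads(
    haplotypes: np.ndarray,
    ploidies: tuple[int, ...],
    depth_mean: float = 2.0,
    error: float = 0.01,
    pooled: bool = False,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-read counts (n_A, n_a) per sample per site.

    Chromosome rows of ``haplotypes`` are grouped into individuals of the
    declared ploidies (in order).  Depth is Poisson(``depth_mean``) per
    individual per site; each read reports the A allele with probability
    dosage/ploidy, flipped with the per-allele ``error`` rate.  ``pooled``
    merges every chromosome into a single observation column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_chrom, n_sites = haplotypes.shape
    if pooled:
        ploidies = (n_chrom,)
    if sum(ploidies) != n_chrom:
        raise ValueError("ploidies must partition the haplotype rows")
    nA = np.empty((n_sites, len(ploidies)), dtype=np.int64)
    na = np.empty_like(nA)
    row = 0
    for j, p in enumerate(ploidies):
        dosage = haplotypes[row: row + p].sum(axis=0)
        row += p
        depth = rng.poisson(depth_mean, size=n_sites)
        pA = dosage / p
        pA = pA * (1.0 - error) + (1.0 - pA) * error
        a = rng.binomial(depth, pA)
        nA[:, j] = a
        na[:, j] = depth - a
    return nA, na


def flip_labels(table: SiteTable, dem: DemographicModel) -> tuple[SiteTable, DemographicModel]:
    """Swap donor/recipient panel identities and replace m by 1 - m.

    Negative selection on the introgressed ancestry then appears as positive
    selection on the receiving ancestry; applying the flip twice is the
    identity.
    """
    df = table.df.copy()
    df[["panel0_A", "panel0_a", "panel1_A", "panel1_a"]] = df[
        ["panel1_A", "panel1_a", "panel0_A", "panel0_a"]
    ].to_numpy()
    return SiteTable(df, table.samples), dem.flipped()


def pool_observations(table: SiteTable) -> SiteTable:
    """Merge all samples' reads into a single pooled observation column."""
    df = table.df[FIXED_COLUMNS].copy()
    total_ploidy = sum(table.samples.ploidies)
    nA = np.zeros(len(df), dtype=np.int64)
    na = np.zeros(len(df), dtype=np.int64)
    for sid in table.samples.ids:
        a, b = table.obs(sid)
        nA += a
        na += b
    samples = SampleSet.pool(total_ploidy)
    df[f"{samples.ids[0]}_A"] = nA
    df[f"{samples.ids[0]}_a"] = na
    return SiteTable(df, samples)


def simulate_dataset(
    dem: DemographicModel,
    scenario: Scenario,
    n_diploids: int = 25,
    n_sites: int = 2000,
    L_M: float = 1.0,
    chrom_len_bp: int = 10_000_000,
    divergence: float = 0.3,
    panel_size: int = 50,
    depth_mean: float = 2.0,
    error: float = 0.01,
    seed: int | np.random.Generator = 0,
    condition_on_retention: bool = False,
) -> tuple[SiteTable, dict]:
    """One-call pipeline: simulate, synthesise sites and reads, and return a
    :class:`SiteTable` plus a truth record for assertions.

    The truth dict carries the realised allele-frequency trajectory, the
    selected sites' physical positions, the sampled chromosomes' true local
    ancestries and the simulated per-site donor-ancestry frequency.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = simulate_admixture(dem, scenario, L_M=L_M, seed=rng,
                             condition_on_retention=condition_on_retention)
    df, haps, sample_anc = synthesize_panels_and_genotypes(
        pop, n_sites=n_sites, divergence=divergence, panel_size=panel_size,
        n_sample_chrom=2 * n_diploids, chrom_len_bp=chrom_len_bp, seed=rng,
    )
    samples = SampleSet.diploid(n_diploids)
    nA, na = simulate_reads(haps, samples.ploidies, depth_mean=depth_mean,
                            error=error, seed=rng)
    for j, sid in enumerate(samples.ids):
        df[f"{sid}_A"] = nA[:, j]
        df[f"{sid}_a"] = na[:, j]
    table = SiteTable(df, samples)
    truth = {
        "trajectory": pop.trajectory,
        "sel_pos_bp": [int(round(s.pos_M / L_M * chrom_len_bp)) for s in scenario.selected_sites],
        "sample_ancestry": sample_anc,
        "site_donor_frequency": sample_anc.mean(axis=0),
        "population": pop,
    }
    return table, truth
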