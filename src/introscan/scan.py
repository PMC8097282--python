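"""Likelihood-ratio scan for adaptive introgression along a chromosome.

For each focal site the scan compares the windowed data likelihood under a
model with selection coefficient s at that site against the neutral one-pulse
model, using the distance-dependent transition hazards from
:mod:`introscan.transitions`.  s is optimised by golden-section search (or
evaluated on a grid), peaks are called greedily with a minimum genetic
separation, and significance is calibrated exclusively against neutral
simulations (linkage between sites makes analytic cutoffs unreliable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iolib import DemographicModel, SiteTable
from .trajectory import SelectionModel
from .transitions import (
    NeutralCurve,
    TransitionCurve,
    default_r_grid,
    forward_transition_rates,
    four_point_fit,
    site_transition_matrices,
)
from .hmm import (
    EmissionModel,
    HmmInstance,
    binomial_initial,
    emission_matrix,
    forward_loglik,
    genotype_given_dosage,
    panel_frequencies,
    posterior_population_frequency,
)

__all__ = [
    "ScanConfig",
    "ScanResult",
    "Peak",
    "Scanner",
    "scan_chromosome",
    "find_peaks",
    "null_threshold",
    "NullThreshold",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings.

    ``window_frac`` is the window half-width as a fraction of the physical
    chromosome length (the validation default, 10% per side); a fixed
    ``window_morgans`` half-width takes precedence when given.  ``stride``
    evaluates every stride-th site.  ``s_lo``/``s_hi`` bound the golden-section
    search; ``s_grid`` supplies explicit values in grid mode.
    """

    mode: str = "gss"
    s_lo: float = 0.001
    s_hi: float = 0.15
    s_grid: tuple[float, ...] = ()
    stride: int = 1
    window_frac: float = 0.1
    window_morgans: float | None = None
    backend: str = "four_point"
    lr_threshold: float = 15.0
    min_sep_cM: float = 2.0
    min_informative_sites: int = 10
    gss_rel_tol: float = 1e-2

    def __post_init__(self):
        if self.mode not in ("gss", "grid"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if not 0.0 < self.s_lo < self.s_hi < 1.0:
            raise ValueError("require 0 < s_lo < s_hi < 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 < self.window_frac <= 0.5:
            raise ValueError("window_frac must lie in (0, 0.5]")
        if self.backend not in ("four_point", "forward"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.mode == "grid" and not self.s_grid:
            raise ValueError("grid mode requires s_grid values")


@dataclass
class ScanResult:
    """Per-site scan output; ``rows`` is a DataFrame with columns
    (chrom, pos_bp, site_index, s or s_hat, lr, flags)."""

    mode: str
    rows: pd.DataFrame

    def records(self):
        return self.rows.to_dict("records")

    def per_site_max(self) -> pd.DataFrame:
        """Best LR per site (identity in gss mode; max over s in grid mode)."""
        if self.mode == "gss":
            return self.rows
        idx = self.rows.groupby("site_index")["lr"].idxmax()
        best = self.rows.loc[idx].rename(columns={"s": "s_hat"})
        return best.sort_values("site_index").reset_index(drop=True)

    def best(self) -> pd.Series:
        """Row with the genome-wide maximum likelihood ratio."""
        per_site = self.per_site_max()
        return per_site.loc[per_site["lr"].idxmax()]


@dataclass(frozen=True)
class Peak:
    chrom: str
    pos_bp: int
    pos_cM: float
    lr: float
    s_hat: float
    frequency: float | None = None


class Scanner:
    """Precomputed scan state for one chromosome of data.

    Sites with a zero-coverage reference panel are dropped on construction
    (``n_dropped`` records how many).  Emission matrices are computed once per
    sample and shared across focal sites and s values; transition curves
    depend only on (demography, s) and are cached across focal sites.
    """

    def __init__(
        self,
        table: SiteTable,
        dem: DemographicModel,
        config: ScanConfig | None = None,
        em: EmissionModel | None = None,
    ):
        if table.df["chrom"].nunique() != 1:
            raise ValueError("Scanner operates on a single chromosome; split the table first")
        self.config = config or ScanConfig()
        self.em = em or EmissionModel()
        self.table, self.n_dropped = table.drop_uncovered_panels()
        self.dem = dem
        self.pos_bp = self.table.pos_bp()
        self.pos_m = self.table.pos_morgans()
        self.chrom = str(self.table.df["chrom"].iloc[0])
        self.chrom_len_bp = float(self.pos_bp[-1] - self.pos_bp[0])
        self.neutral_curve = NeutralCurve.from_model(dem)
        # group samples by ploidy; emission tensors shape (S, n_group, K)
        self.groups: list[tuple[int, np.ndarray]] = []
        samples = self.table.samples
        f0, f1 = panel_frequencies(self.table, self.em)
        by_ploidy: dict[int, list[str]] = {}
        for sid, p in zip(samples.ids, samples.ploidies):
            by_ploidy.setdefault(p, []).append(sid)
        for ploidy, ids in sorted(by_ploidy.items()):
            G = genotype_given_dosage(f0, f1, ploidy)
            E = np.stack(
                [emission_matrix(self.table, sid, ploidy, self.em, _G=G) for sid in ids],
                axis=1,
            )
            self.groups.append((ploidy, E))
        self._curve_cache: dict[float, TransitionCurve] = {}
        self._null_ll_cache: dict[tuple[int, int], float] = {}

    # -- internals ---------------------------------------------------------

    def n_sites(self) -> int:
        return len(self.table)

    def window(self, i: int) -> tuple[int, int]:
        """Half-open site-index window around focal site i."""
        if self.config.window_morgans is not None:
            w = self.config.window_morgans
            lo = int(np.searchsorted(self.pos_m, self.pos_m[i] - w, side="left"))
            hi = int(np.searchsorted(self.pos_m, self.pos_m[i] + w, side="right"))
        else:
            w = self.config.window_frac * self.chrom_len_bp
            lo = int(np.searchsorted(self.pos_bp, self.pos_bp[i] - w, side="left"))
            hi = int(np.searchsorted(self.pos_bp, self.pos_bp[i] + w, side="right"))
        return lo, hi

    def _curve(self, s: float) -> TransitionCurve:
        curve = self._curve_cache.get(s)
        if curve is None:
            sel = SelectionModel(s=s)
            if self.config.backend == "four_point":
                curve = four_point_fit(self.dem, sel)
            else:
                curve = forward_transition_rates(self.dem, sel, default_r_grid(self.dem))
            if len(self._curve_cache) > 4096:
                self._curve_cache.clear()
            self._curve_cache[s] = curve
        return curve

    def _loglik_selected(self, lo: int, hi: int, i: int, curve: TransitionCurve) -> float:
        """Windowed log-likelihood under selection at site i.

        The dosage chain is anchored at the focal site, whose state
        distribution is binomial(ploidy, x_focal) with x_focal the
        selected-allele frequency at sampling, and run outward in both
        directions with the distance-dependent transition matrices.  The two
        branches are conditionally independent given the focal state.
        """
        total = 0.0
        pos = self.pos_m[lo:hi]
        f = i - lo
        for ploidy, E in self.groups:
            T = site_transition_matrices(curve, pos, self.pos_m[i], ploidy)
            Ew = E[lo:hi]
            ns = Ew.shape[1]
            ll = np.zeros(ns)
            # right branch: P(obs right of focal | focal state)
            right = np.ones((ns, ploidy + 1))
            for j in range(Ew.shape[0] - 2, f - 1, -1):
                right = (Ew[j + 1] * right) @ T[j].T
                c = right.sum(axis=1)
                ll += np.log(c)
                right /= c[:, None]
            # left branch: same per-interval matrices apply moving away leftward
            left = np.ones((ns, ploidy + 1))
            for k in range(lo + 1, i + 1):
                j = k - lo
                left = (Ew[j - 1] * left) @ T[j - 1].T
                c = left.sum(axis=1)
                ll += np.log(c)
                left /= c[:, None]
            init = binomial_initial(ploidy, curve.x_focal)
            joint = (init[None, :] * Ew[f] * left * right).sum(axis=1)
            ll += np.log(joint)
            total += float(ll.sum())
        return total

    def _null_loglik(self, lo: int, hi: int) -> float:
        key = (lo, hi)
        ll = self._null_ll_cache.get(key)
        if ll is None:
            ll = 0.0
            pos = self.pos_m[lo:hi]
            for ploidy, E in self.groups:
                T = site_transition_matrices(self.neutral_curve, pos, pos[0], ploidy)
                h = HmmInstance(
                    ploidy=ploidy,
                    emissions=E[lo:hi],
                    transitions=T,
                    initial=binomial_initial(ploidy, self.dem.m),
                )
                ll += forward_loglik(h)
            self._null_ll_cache[key] = ll
        return ll

    # -- public operations -------------------------------------------------

    def site_likelihood_ratio(self, i: int, s: float) -> float:
        """log L(window | selection s at site i) - log L(window | neutral)."""
        if not self.config.s_lo <= s <= self.config.s_hi:
            raise ValueError(f"s={s} outside configured bounds")
        lo, hi = self.window(i)
        if hi - lo < self.config.min_informative_sites:
            return float("nan")
        return self._loglik_selected(lo, hi, i, self._curve(s)) - self._null_loglik(lo, hi)

    def golden_section_optimize(self, i: int) -> tuple[float, float, str]:
        """Maximise LR(s) over [s_lo, s_hi] by golden-section search on log s.

        Returns (s_hat, lr, flags); deterministic, relative tolerance
        ``gss_rel_tol`` in s.
        """
        cfg = self.config
        lo, hi = self.window(i)
        if hi - lo < cfg.min_informative_sites:
            return float("nan"), float("nan"), "window_too_small"

        def f(u: float) -> float:
            return self._loglik_selected(lo, hi, i, self._curve(math.exp(u)))

        null_ll = self._null_loglik(lo, hi)
        a, b = math.log(cfg.s_lo), math.log(cfg.s_hi)
        tol = math.log1p(cfg.gss_rel_tol)
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc, fd = f(c), f(d)
        evals = {c: fc, d: fd}
        while b - a > tol:
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - _INVPHI * (b - a)
                fc = evals[c] = f(c)
            else:
                a, c, fc = c, d, fd
                d = a + _INVPHI * (b - a)
                fd = evals[d] = f(d)
            if not (np.isfinite(fc) and np.isfinite(fd)):
                break
        u_best, ll_best = max(evals.items(), key=lambda kv: kv[1])
        s_hat = math.exp(u_best)
        flags = []
        if s_hat <= cfg.s_lo * (1 + 2 * cfg.gss_rel_tol):
            flags.append("boundary_lo")
        if s_hat >= cfg.s_hi * (1 - 2 * cfg.gss_rel_tol):
            flags.append("boundary_hi")
        if self._curve(s_hat).fixation_regime:
            flags.append("fixation_regime")
        win_bp = (self.config.window_frac * self.chrom_len_bp
                  if self.config.window_morgans is None else None)
        if win_bp is not None and (
            self.pos_bp[i] - win_bp < self.pos_bp[0] or self.pos_bp[i] + win_bp > self.pos_bp[-1]
        ):
            flags.append("window_truncated")
        return s_hat, ll_best - null_ll, ";".join(flags)

    def scan(self, focal_indices: np.ndarray | None = None) -> ScanResult:
        """Evaluate every stride-th site (or an explicit index set)."""
        cfg = self.config
        if focal_indices is None:
            focal_indices = np.arange(0, self.n_sites(), cfg.stride)
        rows = []
        for i in focal_indices:
            i = int(i)
            if cfg.mode == "gss":
                s_hat, lr, flags = self.golden_section_optimize(i)
                rows.append(
                    dict(chrom=self.chrom, pos_bp=int(self.pos_bp[i]), site_index=i,
                         s_hat=s_hat, lr=lr, flags=flags)
                )
            else:
                lo, hi = self.window(i)
                small = hi - lo < cfg.min_informative_sites
                for s in cfg.s_grid:
                    lr = float("nan") if small else self.site_likelihood_ratio(i, s)
                    flags = "window_too_small" if small else ""
                    rows.append(
                        dict(chrom=self.chrom, pos_bp=int(self.pos_bp[i]), site_index=i,
                             s=s, lr=lr, flags=flags)
                    )
        return ScanResult(mode=cfg.mode, rows=pd.DataFrame(rows))

    def posterior_frequency(self) -> np.ndarray:
        """Posterior mean donor-ancestry frequency per site under the neutral
        model (the local-ancestry-inference view of the data)."""
        groups = []
        for ploidy, E in self.groups:
            T = site_transition_matrices(self.neutral_curve, self.pos_m, 0.0, ploidy)
            groups.append(
                HmmInstance(ploidy=ploidy, emissions=E, transitions=T,
                            initial=binomial_initial(ploidy, self.dem.m))
            )
        return posterior_population_frequency(groups)


def scan_chromosome(
    table: SiteTable,
    dem: DemographicModel,
    config: ScanConfig | None = None,
    em: EmissionModel | None = None,
    focal_indices: np.ndarray | None = None,
) -> ScanResult:
    """Convenience wrapper: build a :class:`Scanner` and run the scan."""
    return Scanner(table, dem, config, em).scan(focal_indices)


def find_peaks(
    result: ScanResult,
    threshold: float,
    min_sep_cM: float,
    pos_cM: dict[int, float] | None = None,
    frequencies: dict[int, float] | None = None,
) -> list[Peak]:
    """Greedy peak calling: descending LR, keep a site iff it clears the
    threshold and lies >= ``min_sep_cM`` from every accepted higher peak.
    Ties in LR are broken toward the leftmost position.

    ``pos_cM`` maps site_index to genetic position; when omitted, physical
    positions are used with 1 cM per Mb.
    """
    df = result.per_site_max().dropna(subset=["lr"])
    df = df.sort_values(["lr", "pos_bp"], ascending=[False, True], kind="mergesort")
    peaks: list[Peak] = []
    for rec in df.itertuples(index=False):
        if rec.lr < threshold:
            break
        cm = (pos_cM[rec.site_index] if pos_cM is not None else rec.pos_bp / 1e6)
        if all(abs(cm - p.pos_cM) >= min_sep_cM for p in peaks):
            freq = frequencies.get(rec.site_index) if frequencies else None
            peaks.append(
                Peak(chrom=rec.chrom, pos_bp=int(rec.pos_bp), pos_cM=float(cm),
                     lr=float(rec.lr), s_hat=float(rec.s_hat), frequency=freq)
            )
    return peaks


@dataclass(frozen=True)
class NullThreshold:
    threshold: float
    se: float
    n_replicates: int
    target_fd_per_genome: float


def null_threshold(
    neutral_scans: list[ScanResult],
    min_sep_cM: float = 2.0,
    target_fd_per_genome: float = 1.0,
    pos_cM_maps: list[dict[int, float]] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> NullThreshold:
    """Likelihood-ratio threshold yielding on average ``target_fd_per_genome``
    false discoveries per simulated neutral genome.

    Peaks are first reduced by the same minimum-separation rule used for real
    scans; the threshold is the smallest value such that the mean number of
    surviving peaks per replicate does not exceed the target.  A bootstrap
    standard error over replicates is reported.
    """
    R = len(neutral_scans)
    if R < 10:
        raise ValueError(
            f"need >= 10 neutral replicate scans for a stable threshold, got {R}; "
            "simulate more neutral genomes"
        )
    per_rep: list[np.ndarray] = []
    for k, res in enumerate(neutral_scans):
        pm = pos_cM_maps[k] if pos_cM_maps is not None else None
        pk = find_peaks(res, float("-inf"), min_sep_cM, pos_cM=pm)
        per_rep.append(np.array([p.lr for p in pk]))

    def _threshold(rep_lists: list[np.ndarray]) -> float:
        pool = np.sort(np.concatenate(rep_lists))[::-1]
        allowed = int(math.floor(target_fd_per_genome * len(rep_lists)))
        if len(pool) <= allowed:
            return 0.0
        if allowed == 0:
            return float(np.nextafter(pool[0], np.inf))
        return float(0.5 * (pool[allowed - 1] + pool[allowed]))

    thr = _threshold(per_rep)
    rng = np.random.default_rng(seed)
    boots = [
        _threshold([per_rep[j] for j in rng.integers(0, R, size=R)]) for _ in range(n_boot)
    ]
    return NullThreshold(
        threshold=thr, se=float(np.std(boots)), n_replicates=R,
        target_fd_per_genome=target_fd_per_genome,
    )
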