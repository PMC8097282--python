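"""Position-dependent ancestry-transition hazards around a selected site.

Under a one-pulse admixture model the local ancestry along a sampled
chromosome switches between donor (1) and recipient (0) tracts.  Far from any
selected site the switch hazards per Morgan are the neutral rates

    L10 = 2 Ne (1 - m) (1 - e^{-t / 2Ne}),      L01 = L10 m / (1 - m),

so that the stationary donor-ancestry frequency is m (detailed balance).
Selection at a focal site distorts both hazards in a distance-dependent way:
f10(r) is suppressed near the site (donor tracts carrying the selected allele
are long) and rises monotonically to L10, while f01(r) is elevated near the
site and decays to L01.

Two backends compute these curves:

* ``forward_transition_rates`` — iterate a three-locus hitchhiking recursion
  (selected site plus a closely spaced marker pair at distance r) over the t
  generations since admixture, and read off the conditional switch
  probability between the markers, marginalised over the selected-site
  state.  These pairwise conditionals are exactly the transition kernel the
  ancestry HMM needs: applied outward from the focal site they reproduce the
  hitchhiking-elevated marginal donor frequency at every distance.
* ``four_point_fit`` — the fast parametric approximation
  f10(r) = L - k e^{-alpha r^p} anchored at r = 0, r1 = r2/10 and r2 equal to
  the expected neutral tract length 2/L.

Per-generation recombination uses an exchange probability 1 - e^{-r w_g} with
a coalescence weight w_g = e^{-(t-1-g)/2Ne}, so that the neutral decay of the
focal-marker association is exactly e^{-r * 2Ne(1 - e^{-t/2Ne})} and both
backends reduce to (L10, L01) when s = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .iolib import DemographicModel
from .trajectory import SelectionModel, logistic_trajectory, FREQ_EPS

__all__ = [
    "neutral_rates",
    "TransitionCurve",
    "NeutralCurve",
    "TabulatedCurve",
    "FourPointCurve",
    "forward_transition_rates",
    "four_point_fit",
    "hazards_at",
    "site_transition_matrices",
    "lift_binomial",
]

#: trajectory endpoints above this are flagged as the fixation regime, where
#: the estimated s is known to be biased downward.
FIXATION_FREQ = 1.0 - 1e-6


def neutral_rates(dem: DemographicModel) -> tuple[float, float]:
    """Neutral ancestry-switch hazards (L10, L01) per Morgan."""
    L10 = 2.0 * dem.Ne * (1.0 - dem.m) * -np.expm1(-dem.t / (2.0 * dem.Ne))
    L01 = L10 * dem.m / (1.0 - dem.m)
    return float(L10), float(L01)


class TransitionCurve:
    """Direction-specific switch hazards as functions of distance r >= 0 (Morgans).

    ``x_focal`` is the marginal donor-ancestry frequency at the focal site
    (the selected-allele frequency at sampling; m under neutrality), used as
    the HMM's state distribution at the focal site.
    """

    L10: float
    L01: float
    fixation_regime: bool = False
    x_focal: float = 0.5

    def f10(self, r: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def f01(self, r: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class NeutralCurve(TransitionCurve):
    L10: float
    L01: float
    fixation_regime: bool = False
    x_focal: float = 0.5

    @classmethod
    def from_model(cls, dem: DemographicModel) -> "NeutralCurve":
        L10, L01 = neutral_rates(dem)
        return cls(L10, L01, x_focal=dem.m)

    def f10(self, r):
        return np.full_like(np.asarray(r, dtype=float), self.L10)

    def f01(self, r):
        return np.full_like(np.asarray(r, dtype=float), self.L01)


@dataclass
class TabulatedCurve(TransitionCurve):
    """Hazards tabulated on a distance grid; constant extrapolation to the
    neutral limits beyond the last grid point."""

    r_grid: np.ndarray
    f10_tab: np.ndarray
    f01_tab: np.ndarray
    L10: float
    L01: float
    fixation_regime: bool = False
    x_focal: float = 0.5

    def f10(self, r):
        return np.interp(np.asarray(r, dtype=float), self.r_grid, self.f10_tab,
                         right=self.L10)

    def f01(self, r):
        return np.interp(np.asarray(r, dtype=float), self.r_grid, self.f01_tab,
                         right=self.L01)


@dataclass
class FourPointCurve(TransitionCurve):
    """Parametric hazards f10(r) = L10 - k10 e^{-a10 r^p10} (f01 analogous,
    approaching L01 from above)."""

    L10: float
    L01: float
    k10: float
    alpha10: float
    p10: float
    k01: float
    alpha01: float
    p01: float
    r1: float = 0.0
    r2: float = 0.0
    fixation_regime: bool = False
    x_focal: float = 0.5

    def f10(self, r):
        r = np.asarray(r, dtype=float)
        if self.k10 == 0.0:
            return np.full_like(r, self.L10)
        with np.errstate(over="ignore"):
            out = self.L10 - self.k10 * np.exp(-self.alpha10 * np.power(r, self.p10))
        return np.clip(out, 0.0, None)

    def f01(self, r):
        r = np.asarray(r, dtype=float)
        if self.k01 == 0.0:
            return np.full_like(r, self.L01)
        with np.errstate(over="ignore"):
            out = self.L01 + self.k01 * np.exp(-self.alpha01 * np.power(r, self.p01))
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# forward iteration backend


def _coalescence_weights(dem: DemographicModel, t: int) -> np.ndarray:
    # weight of a junction formed in meiosis g -> g+1: the probability that the
    # flanking lineages have not coalesced by sampling time
    age = t - 1 - np.arange(t, dtype=float)
    return np.exp(-age / (2.0 * dem.Ne))


def conditional_probs(
    dem: DemographicModel, x_traj: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the two-locus recursion; returns (a, b) at sampling time.

    a(r) = P(marker donor | focal donor), b(r) = P(marker donor | focal
    recipient).  ``x_traj`` is the selected-allele trajectory of length t+1.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be >= 0")
    t = len(x_traj) - 1
    x = np.clip(x_traj, FREQ_EPS, 1.0 - FREQ_EPS)
    w = _coalescence_weights(dem, t)
    a = np.ones_like(r)
    b = np.zeros_like(r)
    for g in range(t):
        c = -np.expm1(-r * w[g])
        xn = x[g + 1]
        q = xn * a + (1.0 - xn) * b
        a = a + c * (q - a)
        b = b + c * (q - b)
    return a, b


def pair_joint(
    dem: DemographicModel,
    x_traj: np.ndarray,
    r_near: np.ndarray,
    r_far: np.ndarray,
) -> np.ndarray:
    """Joint ancestry distribution of a marker pair flanking one side of the
    selected site, marginalised over the selected-site state.

    Three loci are tracked in chromosome order (selected site, marker at
    ``r_near``, marker at ``r_far``): the 2x2x2 haplotype-frequency tensor z
    starts fully coupled (all-donor with probability m), selection reweights
    the selected-site axis so its marginal follows ``x_traj``, and
    recombination in the two gaps replaces the separated segment with a draw
    from a random population chromosome (with the coalescence weight of
    :func:`_coalescence_weights`).  Returns J with J[k, b, c] = P(marker at
    r_near = b, marker at r_far = c) for each distance pair k.
    """
    r_near = np.asarray(r_near, dtype=float)
    r_far = np.asarray(r_far, dtype=float)
    if (r_near < 0).any() or (r_far < r_near).any():
        raise ValueError("need 0 <= r_near <= r_far")
    t = len(x_traj) - 1
    x = np.clip(x_traj, FREQ_EPS, 1.0 - FREQ_EPS)
    w = _coalescence_weights(dem, t)
    n = len(r_near)
    z = np.zeros((n, 2, 2, 2))
    z[:, 1, 1, 1] = dem.m
    z[:, 0, 0, 0] = 1.0 - dem.m
    d1 = r_near
    d2 = r_far - r_near
    for g in range(t):
        # selection: force the selected-site marginal onto the trajectory
        xg = z[:, 1].sum(axis=(1, 2))
        z[:, 1] *= (x[g + 1] / xg)[:, None, None]
        z[:, 0] *= ((1.0 - x[g + 1]) / (1.0 - xg))[:, None, None]
        # recombination: crossovers in either gap splice in a random chromosome
        c1 = -np.expm1(-d1 * w[g])[:, None, None, None]
        c2 = -np.expm1(-d2 * w[g])[:, None, None, None]
        A = z.sum(axis=(2, 3))
        B = z.sum(axis=(1, 3))
        C = z.sum(axis=(1, 2))
        AB = z.sum(axis=3)
        BC = z.sum(axis=1)
        AC = z.sum(axis=2)
        z = (
            (1.0 - c1) * (1.0 - c2) * z
            + c1 * (1.0 - c2) * A[:, :, None, None] * BC[:, None, :, :]
            + (1.0 - c1) * c2 * AB[:, :, :, None] * C[:, None, None, :]
            + c1 * c2 * AC[:, :, None, :] * B[:, None, :, None]
        )
    return z.sum(axis=1)


def hazards_at(
    dem: DemographicModel,
    x_traj: np.ndarray,
    r_values: np.ndarray,
    rel_step: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Outward switch hazards (f10, f01) at given distances from the focal site.

    The hazard is the conditional probability per Morgan that ancestry
    switches between a marker at r and one slightly farther out, marginalised
    over the selected-site state — the quantity the HMM uses as its local
    transition rate away from the focal site.  Estimated from the three-locus
    recursion with a short probe interval.
    """
    r = np.asarray(r_values, dtype=float)
    L10, L01 = neutral_rates(dem)
    delta = np.maximum(rel_step * np.maximum(r, 2.0 / L10 / 100.0), 1e-12)
    J = pair_joint(dem, x_traj, r, r + delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        p10 = J[:, 1, 0] / np.maximum(J[:, 1].sum(axis=1), 1e-300)
        p01 = J[:, 0, 1] / np.maximum(J[:, 0].sum(axis=1), 1e-300)
        tau = np.clip(p10 + p01, 0.0, 1.0 - 1e-15)
        lam_d = -np.log1p(-tau)
        scale = np.where(tau > 1e-12, lam_d / np.where(tau > 0, tau, 1.0), 1.0)
        f10 = p10 * scale / delta
        f01 = p01 * scale / delta
    return np.clip(f10, 0.0, None), np.clip(f01, 0.0, None)


def forward_transition_rates(
    dem: DemographicModel,
    sel: SelectionModel,
    r_grid: np.ndarray,
    trajectory: np.ndarray | None = None,
) -> TabulatedCurve:
    """Tabulated transition-hazard curves on ``r_grid`` (sorted, >= 0 Morgans).

    ``trajectory`` defaults to the logistic approximation; pass a trajectory
    from :func:`introscan.trajectory.stochastic_trajectory` for tiny pulses.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if (np.diff(r_grid) < 0).any() or (r_grid < 0).any():
        raise ValueError("r_grid must be sorted and nonnegative")
    x = trajectory if trajectory is not None else logistic_trajectory(dem, sel)
    f10, f01 = hazards_at(dem, x, r_grid)
    L10, L01 = neutral_rates(dem)
    return TabulatedCurve(
        r_grid=r_grid, f10_tab=f10, f01_tab=f01, L10=L10, L01=L01,
        fixation_regime=bool(x[-1] > FIXATION_FREQ),
        x_focal=float(np.clip(x[-1], FREQ_EPS, 1.0 - FREQ_EPS)),
    )


def default_r_grid(dem: DemographicModel, span: float = 5.0, per_decade: int = 64) -> np.ndarray:
    """Log-spaced grid from ~0 out to ``span`` times the neutral tract length,
    dense enough for finite-difference hazard extraction near r = 0."""
    L10, _ = neutral_rates(dem)
    r2 = 2.0 / L10
    lo, hi = r2 * 1e-4, r2 * span
    n = max(int(np.ceil(per_decade * np.log10(hi / lo))), 2)
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


# ---------------------------------------------------------------------------
# four-point backend


def _fit_direction(L, f0, f1, f2, r1, r2, toward_limit_from_below):
    """Fit (k, alpha, p) for one direction from anchors at ~0, r1, r2."""
    if toward_limit_from_below:
        k = L - f0
        d1, d2 = L - f1, L - f2
    else:
        k = f0 - L
        d1, d2 = f1 - L, f2 - L
    if not np.isfinite(k) or k <= max(1e-10, 1e-9 * max(L, 1.0)):
        return 0.0, 0.0, 1.0  # degenerate: constant-L curve
    y1 = np.log(min(max(d1 / k, 1e-12), 1.0 - 1e-12))
    y2 = np.log(min(max(d2 / k, 1e-12), 1.0 - 1e-12))
    if y1 >= -1e-12 or y2 >= -1e-12 or abs(y1 - y2) < 1e-12:
        # anchors do not resolve a power law; fall back to a simple
        # exponential through the r2 anchor
        y = min(y1, y2, -1e-12)
        return float(k), float(-y / r2), 1.0
    p = np.log(y1 / y2) / np.log(r1 / r2)
    if not np.isfinite(p) or p <= 0:
        return float(k), float(-y2 / r2), 1.0
    alpha = -y1 / r1 ** p
    return float(k), float(alpha), float(p)


def four_point_fit(
    dem: DemographicModel,
    sel: SelectionModel,
    trajectory: np.ndarray | None = None,
) -> FourPointCurve:
    """Parametric transition curves from three numerically estimated anchors.

    The anchors are the forward-iteration hazards at r ~ 0, r1 = r2/10 and
    r2 = 2/L10 (the expected neutral tract length); the fourth point is the
    neutral limit L at infinity.  The fitted curve passes through the anchors
    exactly and extrapolates to L beyond them.
    """
    L10, L01 = neutral_rates(dem)
    r2 = 2.0 / L10
    r1 = r2 / 10.0
    r0 = r2 * 1e-4
    x = trajectory if trajectory is not None else logistic_trajectory(dem, sel)
    f10v, f01v = hazards_at(dem, x, np.array([r0, r1, r2]))
    k10, a10, p10 = _fit_direction(L10, f10v[0], f10v[1], f10v[2], r1, r2, True)
    k01, a01, p01 = _fit_direction(L01, f01v[0], f01v[1], f01v[2], r1, r2, False)
    return FourPointCurve(
        L10=L10, L01=L01, k10=k10, alpha10=a10, p10=p10,
        k01=k01, alpha01=a01, p01=p01, r1=r1, r2=r2,
        fixation_regime=bool(x[-1] > FIXATION_FREQ),
        x_focal=float(np.clip(x[-1], FREQ_EPS, 1.0 - FREQ_EPS)),
    )


# ---------------------------------------------------------------------------
# per-interval transition matrices


def _chromosome_matrices(curve: TransitionCurve, pos_m: np.ndarray, focal_m: float) -> np.ndarray:
    """Single-chromosome 2x2 transition matrices for each adjacent interval.

    Uses the exact two-state solution over an interval of length d with the
    trapezoidal mean of the endpoint hazards, so rows are stochastic without
    clamping; d = 0 yields the identity.
    """
    r = np.abs(pos_m - focal_m)
    f10 = curve.f10(r)
    f01 = curve.f01(r)
    f10m = 0.5 * (f10[:-1] + f10[1:])
    f01m = 0.5 * (f01[:-1] + f01[1:])
    d = np.diff(pos_m)
    lam = f10m + f01m
    lam_safe = np.where(lam > 0, lam, 1.0)
    decay = -np.expm1(-lam_safe * d)
    p10 = np.where(lam > 0, f10m / lam_safe * decay, 0.0)
    p01 = np.where(lam > 0, f01m / lam_safe * decay, 0.0)
    out = np.empty((len(d), 2, 2))
    out[:, 0, 0] = 1.0 - p01
    out[:, 0, 1] = p01
    out[:, 1, 0] = p10
    out[:, 1, 1] = 1.0 - p10
    return out


def lift_binomial(P2: np.ndarray, ploidy: int) -> np.ndarray:
    """Lift a stack of 2x2 single-chromosome matrices to the (ploidy+1)-state
    ancestry-dosage chain, assuming independent chromosomes.

    P[i -> j] = sum_k Binom(k; i, p11) Binom(j-k; n-i, p01): the surviving
    donor chromosomes and the newly switching recipient chromosomes add up.
    """
    n = ploidy
    if n == 1:
        return P2
    M = P2.shape[0]
    i = np.arange(n + 1)
    logC = gammaln(i[:, None] + 1) - gammaln(i[None, :] + 1) - gammaln(i[:, None] - i[None, :] + 1)
    logC = np.where(i[None, :] <= i[:, None], logC, -np.inf)

    def pmf(p):
        # pmf[m, i, k] = Binom(k; i, p[m]) for i = 0..n rows
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(p)[:, None, None]
            l1p = np.log1p(-p)[:, None, None]
            k = i[None, None, :]
            ii = i[None, :, None]
            out = logC[None] + np.where(k > 0, k * lp, 0.0) + np.where(ii - k > 0, (ii - k) * l1p, 0.0)
        return np.where(np.isfinite(out), np.exp(out), 0.0)

    A = pmf(P2[:, 1, 1])            # survivors among the i donor chromosomes
    B = pmf(P2[:, 0, 1])[:, ::-1]   # switchers among the n-i recipient ones; row i holds n-i trials
    nfft = 2 * (n + 1)
    Pf = np.fft.irfft(np.fft.rfft(A, nfft, axis=2) * np.fft.rfft(B, nfft, axis=2), nfft, axis=2)
    P = np.clip(Pf[:, :, : n + 1], 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def site_transition_matrices(
    curve: TransitionCurve,
    pos_m: np.ndarray,
    focal_m: float,
    ploidy: int,
) -> np.ndarray:
    """Per-interval (ploidy+1)-state transition matrices for ordered sites at
    cumulative map positions ``pos_m`` (Morgans), relative to a focal site."""
    P2 = _chromosome_matrices(curve, np.asarray(pos_m, dtype=float), focal_m)
    return lift_binomial(P2, ploidy)
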