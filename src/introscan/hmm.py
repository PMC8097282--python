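"""Emission models and forward/backward likelihood for the ancestry-dosage chain.

The hidden state at a site is the number of donor-ancestry chromosomes among
the ``ploidy`` chromosomes of a sample (dosage 0..ploidy).  Emissions are not
affected by selection: in pileup mode a chromosome of ancestry a carries the
A allele with the (pseudocount-regularised) frequency of reference panel a,
the sample genotype is the convolution of the two ancestry-conditional
binomials, and reads are drawn binomially with a per-read error rate; in
genotype mode the allele dosage is observed directly.  Samples are
independent chains, so the total log-likelihood is a sum over samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .iolib import SiteTable, SampleSet

__all__ = [
    "EmissionModel",
    "HmmInstance",
    "panel_frequencies",
    "emission_matrix",
    "emission_prob",
    "forward_loglik",
    "posterior_dosage",
]


@dataclass(frozen=True)
class EmissionModel:
    """Observation model shared by all samples.

    ``mode`` is ``"pileup"`` (read counts) or ``"genotype"`` (called allele
    dosages); ``error`` is the per-read allele error rate; panel allele
    frequencies are estimated with a +1/+2 pseudocount unless
    ``pseudocount=False``.
    """

    mode: str = "pileup"
    error: float = 0.01
    pseudocount: bool = True

    def __post_init__(self):
        if self.mode not in ("pileup", "genotype"):
            raise ValueError(f"unknown emission mode {self.mode!r}")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")


def panel_frequencies(table: SiteTable, em: EmissionModel) -> tuple[np.ndarray, np.ndarray]:
    """Estimated A-allele frequency per site for panel 0 and panel 1."""
    out = []
    for panel in (0, 1):
        cA, ca = table.panel_counts(panel)
        tot = cA + ca
        if em.pseudocount:
            out.append((cA + 1.0) / (tot + 2.0))
        else:
            if (tot == 0).any():
                raise ValueError("zero panel total with pseudocount disabled")
            out.append(np.clip(cA / tot, 1e-9, 1.0 - 1e-9))
    tot0 = np.add(*table.panel_counts(0))
    tot1 = np.add(*table.panel_counts(1))
    if ((tot0 == 0) & (tot1 == 0)).any():
        raise ValueError(
            "site with zero sampled alleles in both panels; drop such sites upstream"
        )
    return out[0], out[1]


def _binom_pmf_rows(p: np.ndarray, n: int) -> np.ndarray:
    """pmf[s, i, k] = Binom(k; i, p[s]) for i = 0..n, vectorised over sites."""
    i = np.arange(n + 1)
    logC = gammaln(i[:, None] + 1) - gammaln(i[None, :] + 1) - gammaln(i[:, None] - i[None, :] + 1)
    logC = np.where(i[None, :] <= i[:, None], logC, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(p)[:, None, None]
        l1p = np.log1p(-p)[:, None, None]
        k = i[None, None, :]
        ii = i[None, :, None]
        out = logC[None] + np.where(k > 0, k * lp, 0.0) + np.where(ii - k > 0, (ii - k) * l1p, 0.0)
    return np.where(np.isfinite(out), np.exp(out), 0.0)


def genotype_given_dosage(f0: np.ndarray, f1: np.ndarray, ploidy: int,
                          chunk: int = 512) -> np.ndarray:
    """G[s, z, g] = P(g A alleles | donor dosage z) at each site.

    The genotype is the sum of Binom(z, f1[s]) donor-derived and
    Binom(ploidy - z, f0[s]) recipient-derived A alleles.
    """
    n = ploidy
    S = len(f0)
    G = np.empty((S, n + 1, n + 1))
    nfft = 2 * (n + 1)
    for lo in range(0, S, chunk):
        sl = slice(lo, min(lo + chunk, S))
        A = _binom_pmf_rows(f1[sl], n)            # donor chromosomes: z trials
        B = _binom_pmf_rows(f0[sl], n)[:, ::-1]   # recipient: n - z trials
        conv = np.fft.irfft(np.fft.rfft(A, nfft, axis=2) * np.fft.rfft(B, nfft, axis=2),
                            nfft, axis=2)[:, :, : n + 1]
        G[sl] = np.clip(conv, 0.0, None)
    G /= G.sum(axis=2, keepdims=True)
    return G


def emission_matrix(
    table: SiteTable,
    sample_id: str,
    ploidy: int,
    em: EmissionModel,
    _G: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site emission vectors, shape (n_sites, ploidy + 1).

    ``_G`` lets callers share the genotype-given-dosage tensor between samples
    of equal ploidy (it does not depend on the observations).
    """
    f0, f1 = panel_frequencies(table, em)
    n = ploidy
    G = _G if _G is not None else genotype_given_dosage(f0, f1, n)
    nA, na = table.obs(sample_id)
    if em.mode == "genotype":
        if ((nA + na != n) & (nA + na != 0)).any():
            raise ValueError(f"genotype observations for {sample_id} must sum to the ploidy")
        # P(called dosage | z); zero-coverage rows are uninformative
        probs = G[np.arange(len(table)), :, np.minimum(nA, n)]
        return np.where((nA + na == 0)[:, None], 1.0, probs)
    d = nA + na
    g = np.arange(n + 1, dtype=float)
    phi = (g / n) * (1.0 - em.error) + (1.0 - g / n) * em.error   # read-level P(A) per genotype
    with np.errstate(divide="ignore"):
        lognA = np.where(phi > 0, np.log(phi), -np.inf)[None, :]
        logna = np.where(phi < 1, np.log1p(-phi), -np.inf)[None, :]
    logC = gammaln(d + 1) - gammaln(nA + 1) - gammaln(na + 1)
    with np.errstate(invalid="ignore"):
        lr = np.where(nA[:, None] > 0, nA[:, None] * lognA, 0.0) \
            + np.where(na[:, None] > 0, na[:, None] * logna, 0.0)
    read_lik = np.exp(lr + logC[:, None])         # (S, n+1) over genotypes g
    return np.einsum("szg,sg->sz", G, read_lik)


def emission_prob(table: SiteTable, site_index: int, sample_id: str, state: int,
                  ploidy: int, em: EmissionModel) -> float:
    """P(observation at one site | ancestry dosage ``state``)."""
    if state > ploidy:
        raise ValueError("state exceeds ploidy")
    E = emission_matrix(table, sample_id, ploidy, em)
    return float(E[site_index, state])


@dataclass
class HmmInstance:
    """One ploidy group of samples sharing transition matrices.

    ``emissions`` has shape (n_sites, n_samples, K); ``transitions`` has shape
    (n_sites - 1, K, K); ``initial`` is the binomial(ploidy, m) ancestry-dosage
    prior at the first site.
    """

    ploidy: int
    emissions: np.ndarray
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        K = self.ploidy + 1
        if self.emissions.shape[2] != K or self.initial.shape != (K,):
            raise ValueError("inconsistent state-space dimensions")
        if self.emissions.shape[0] != self.transitions.shape[0] + 1:
            raise ValueError("need one transition matrix per adjacent site pair")
        if not (np.isfinite(self.emissions).all() and (self.emissions >= 0).all()):
            raise ValueError("emissions must be finite and nonnegative")
        if abs(self.initial.sum() - 1.0) > 1e-8:
            raise ValueError("initial distribution must sum to 1")


def binomial_initial(ploidy: int, m: float) -> np.ndarray:
    z = np.arange(ploidy + 1)
    logC = gammaln(ploidy + 1) - gammaln(z + 1) - gammaln(ploidy - z + 1)
    return np.exp(logC + z * np.log(m) + (ploidy - z) * np.log1p(-m))


def forward_loglik(h: HmmInstance) -> float:
    """Total log P(observations | model), summed over the group's samples."""
    S, ns, K = h.emissions.shape
    alpha = h.initial[None, :] * h.emissions[0]
    ll = np.zeros(ns)
    c = alpha.sum(axis=1)
    if (c == 0).any():
        warnings.warn("all-zero emission vector at site 0; likelihood is -inf")
        return float("-inf")
    ll += np.log(c)
    alpha = alpha / c[:, None]
    for i in range(1, S):
        alpha = (alpha @ h.transitions[i - 1]) * h.emissions[i]
        c = alpha.sum(axis=1)
        if (c == 0).any():
            warnings.warn(f"all-zero emission vector at site {i}; likelihood is -inf")
            return float("-inf")
        ll += np.log(c)
        alpha = alpha / c[:, None]
    return float(ll.sum())


def posterior_dosage(h: HmmInstance) -> np.ndarray:
    """Forward-backward posterior mean donor dosage, shape (n_sites, n_samples)."""
    S, ns, K = h.emissions.shape
    alphas = np.empty((S, ns, K))
    alpha = h.initial[None, :] * h.emissions[0]
    alpha /= alpha.sum(axis=1, keepdims=True)
    alphas[0] = alpha
    for i in range(1, S):
        alpha = (alpha @ h.transitions[i - 1]) * h.emissions[i]
        norm = alpha.sum(axis=1, keepdims=True)
        if (norm == 0).any():
            raise ValueError(f"all-zero emission vector at site {i}")
        alpha /= norm
        alphas[i] = alpha
    beta = np.ones((ns, K))
    post = np.empty((S, ns, K))
    post[-1] = alphas[-1]
    for i in range(S - 2, -1, -1):
        beta = (beta * h.emissions[i + 1]) @ h.transitions[i].T
        beta /= beta.sum(axis=1, keepdims=True)
        p = alphas[i] * beta
        post[i] = p / p.sum(axis=1, keepdims=True)
    dosages = np.arange(K, dtype=float)
    return post @ dosages


def posterior_population_frequency(groups: list[HmmInstance]) -> np.ndarray:
    """Mean posterior donor frequency across all chromosomes, per site."""
    num = 0.0
    den = 0.0
    for h in groups:
        num = num + posterior_dosage(h).sum(axis=1)
        den += h.ploidy * h.emissions.shape[1]
    return num / den
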