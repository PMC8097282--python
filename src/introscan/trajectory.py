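"""Frequency trajectory of the selected donor allele from admixture to sampling.

The selection coefficient ``s`` throughout this package is genic (per allele
copy): a diploid carrying ``d`` copies of the selected allele has fitness
``1 + s*d``, so a heterozygote experiences half the selective strength of a
homozygote.  Under this model the deterministic per-generation recursion is

    x' = x (1 + s) / (1 + s x),

whose solution is the familiar logistic curve

    x_g = m e^{s g} / (1 - m + m e^{s g})

up to the usual continuous-growth approximation e^s ~ 1 + s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .iolib import DemographicModel

__all__ = ["SelectionModel", "logistic_trajectory", "stochastic_trajectory", "FREQ_EPS"]

#: trajectories are clipped to [FREQ_EPS, 1 - FREQ_EPS] before they enter the
#: transition-rate recursions, so rates stay finite near fixation/loss.
FREQ_EPS = 1e-9


@dataclass(frozen=True)
class SelectionModel:
    """Additive selection at a single focal site.

    ``s > 0`` means the donor allele is favoured; ``focal_pos`` is the
    physical position (bp) of the candidate selected site.
    """

    s: float
    focal_pos: int = 0

    def __post_init__(self):
        if not abs(self.s) < 1:
            raise ValueError("|s| must be < 1")


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, FREQ_EPS, 1.0 - FREQ_EPS)


def logistic_trajectory(dem: DemographicModel, sel: SelectionModel) -> np.ndarray:
    """Deterministic logistic trajectory x_0..x_t of the selected donor allele.

    Returns an array of length ``t + 1`` with ``x_0 = m`` exactly.  For
    ``s = 0`` the trajectory is constant at ``m``.
    """
    t = int(round(dem.t))
    g = np.arange(t + 1, dtype=float)
    m = dem.m
    # logit-space form of m e^{sg} / (1 - m + m e^{sg}) with per-generation
    # odds factor (1+s), the exact solution of x' = x(1+s)/(1+sx); stays
    # finite for large s*g
    logit = np.log(m) - np.log1p(-m) + g * np.log1p(sel.s)
    x = expit(logit)
    x[0] = m
    return x


def wf_deterministic_trajectory(dem: DemographicModel, sel: SelectionModel) -> np.ndarray:
    """Iterate the exact per-generation recursion x' = x(1+s)/(1+sx).

    Used as an oracle for the closed-form logistic; agreement is within 1%
    absolute for realistic (s, t).
    """
    t = int(round(dem.t))
    x = np.empty(t + 1)
    x[0] = dem.m
    for g in range(t):
        x[g + 1] = x[g] * (1.0 + sel.s) / (1.0 + sel.s * x[g])
    return x


def stochastic_trajectory(
    dem: DemographicModel,
    sel: SelectionModel,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    condition_on_survival: bool = True,
) -> np.ndarray:
    """Mean Wright-Fisher trajectory over binomially resampled replicates.

    Each replicate evolves 2*Ne allele copies with the deterministic update
    followed by binomial resampling.  With ``condition_on_survival`` only
    replicates in which the allele is not lost by generation ``t`` contribute
    to the mean — the intended use for small pulses (m <~ 0.01), where the
    conditional trajectory lies above the unconditional logistic one early on.

    Raises ``RuntimeError`` if every replicate loses the allele.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = int(round(dem.t))
    n_copies = int(round(2 * dem.Ne))
    x = np.full(n_reps, dem.m)
    traj = np.empty((t + 1, n_reps))
    traj[0] = x
    s = sel.s
    for g in range(t):
        p = x * (1.0 + s) / (1.0 + s * x)
        x = rng.binomial(n_copies, np.clip(p, 0.0, 1.0)) / n_copies
        traj[g + 1] = x
    if condition_on_survival:
        alive = traj[-1] > 0
        n_lost = int((~alive).sum())
        if not alive.any():
            raise RuntimeError(
                f"selected allele lost in all {n_lost} replicates; "
                "increase n_reps or Ne, or disable conditioning"
            )
        traj = traj[:, alive]
    out = traj.mean(axis=1)
    out[0] = dem.m
    return out
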