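"""Binomial presynaptic recruitment: linking the mean number of synapses
active per stimulus to the total available pool.

Under bulk stimulation only a random subset of the responsive terminals
releases on any given stimulus; the number active follows a binomial
distribution with mean N_active_bar = Pr * N_total, so the pool size is
recovered as N_total = N_active_bar / Pr.  The mean active count itself is
estimated by dividing the ensemble potency by the single-synapse potency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "RecruitmentEstimate",
    "binomial_active_pmf",
    "estimate_n_active",
    "estimate_n_total",
    "estimate_pool",
]


@dataclass(frozen=True)
class RecruitmentEstimate:
    n_active_bar: float
    pr: float
    n_total: int
    exact_quotient: float

    def __post_init__(self):
        if not 0.0 < self.pr <= 1.0:
            raise ParameterError("pr must lie in (0, 1]")
        if self.n_active_bar < 0 or self.n_total < self.n_active_bar - 1:
            raise ParameterError("n_total must be at least n_active_bar")


def binomial_active_pmf(n_active: int, n_total: int, pr: float) -> float:
    """P(exactly n_active of n_total synapses release), Binomial(n_total, pr)."""
    if not 0.0 <= pr <= 1.0:
        raise ParameterError("pr must lie in [0, 1]")
    if not 0 <= n_active <= n_total:
        raise ParameterError(f"n_active={n_active} outside support [0, {n_total}]")
    return float(sps.binom.pmf(n_active, n_total, pr))


def estimate_n_active(ensemble_potency: float, single_potency: float) -> int:
    """Mean active synapses per stimulus: ensemble potency divided by the
    single-synapse potency, rounded to the nearest integer."""
    if ensemble_potency <= 0 or single_potency <= 0:
        raise ParameterError("potencies must be positive")
    return int(np.rint(ensemble_potency / single_potency))


def estimate_n_total(n_active_bar: float, pr: float) -> int:
    """Total pool size N_total = N_active_bar / Pr, truncated toward zero to
    an integer count of synapses."""
    if not 0.0 < pr <= 1.0:
        raise ParameterError("pr must lie in (0, 1]")
    if n_active_bar < 0:
        raise ParameterError("n_active_bar must be non-negative")
    # tiny epsilon guards the truncation against floating representation of
    # exact quotients (e.g. 4.8 / 0.4)
    return int(np.floor(n_active_bar / pr + 1e-9))


def estimate_pool(
    ensemble_potency: float, single_potency: float, pr: float = 0.4
) -> RecruitmentEstimate:
    """Full recruitment estimate from the two potencies and Pr, keeping the
    unrounded quotient for transparency."""
    n_active = estimate_n_active(ensemble_potency, single_potency)
    quotient = n_active / pr
    return RecruitmentEstimate(n_active, pr, estimate_n_total(n_active, pr), quotient)
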