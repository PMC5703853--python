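"""Statistical primitives: one-/two-tailed paired t-tests and the
normal-approximation one-sample power / sample-size formula.

The paired t-test is evaluated on the differences y - x with n - 1 degrees
of freedom; 'left' means the alternative mean(y - x) < 0 (depression),
'right' mean(y - x) > 0 (potentiation).  The sample-size formula is the
standard one-sample normal approximation

    n = ceil( ((z_{1-a} + z_{1-b}) * sigma / delta)^2 )

with z_{1-a/2} in the two-sided case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import ndtri

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "TestResult",
    "PowerSpec",
    "paired_t_test",
    "one_sample_power_n",
    "normal_quantile",
]

_ALTERNATIVES = {"left": "less", "right": "greater", "two_sided": "two-sided"}


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    p_value: float
    tail: str
    df: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the sample-size formula: type-I rate alpha, type-II rate
    beta (power = 1 - beta), minimal detectable effect delta and measurement
    SD sigma, both in the units of the measurement."""

    delta: float
    sigma: float
    alpha: float = 0.05
    beta: float = 0.2
    tail: str = "one_sided"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.beta < 1.0:
            raise ParameterError("alpha and beta must lie in (0, 1)")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.tail not in ("one_sided", "two_sided"):
            raise ParameterError("tail must be 'one_sided' or 'two_sided'")


def paired_t_test(x, y, tail: str = "two_sided") -> TestResult:
    """Paired t-test of y against x with the requested tail."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tail not in _ALTERNATIVES:
        raise ParameterError(f"tail must be one of {tuple(_ALTERNATIVES)}")
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ParameterError("need at least 2 pairs")
    d = y - x
    if np.ptp(d) == 0.0:
        raise DegenerateDataError("paired differences have zero variance")
    res = sps.ttest_rel(y, x, alternative=_ALTERNATIVES[tail])
    return TestResult(float(res.statistic), float(res.pvalue), tail, x.size - 1)


def normal_quantile(p: float) -> float:
    """Inverse standard normal CDF."""
    if not 0.0 < p < 1.0:
        raise ParameterError("p must lie in (0, 1)")
    return float(ndtri(p))


def one_sample_power_n(spec: PowerSpec) -> int:
    """Smallest sample size giving power 1 - beta to detect a mean shift of
    delta at level alpha, by the normal-approximation formula."""
    if spec.delta == 0:
        raise ParameterError("delta = 0 would require an infinite sample size")
    if spec.tail == "one_sided":
        z_a = normal_quantile(1.0 - spec.alpha)
    else:
        z_a = normal_quantile(1.0 - spec.alpha / 2.0)
    z_b = normal_quantile(1.0 - spec.beta)
    n = ((z_a + z_b) * spec.sigma / abs(spec.delta)) ** 2
    return math.ceil(n)
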