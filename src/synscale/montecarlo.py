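"""Observation-scale Monte Carlo model of synapse-specific modulation.

The model works entirely on normalized synaptic efficacies (percent of
baseline).  Each synapse i has a baseline efficacy X_i ~ N(mu_b, sigma_b)
and a post-depolarization efficacy Y_i drawn from a two-component Gaussian
mixture: with probability ``fraction_regulated`` (0.36 by default) the
synapse is regulated (e.g. DSE-depressed or eSP-potentiated), otherwise it
is unregulated.  A simulated whole-cell ensemble experiment averages
``n_total`` (12 by default) independent X draws and, separately, 12
independent Y draws; a simulated field experiment further averages 100 such
cells laid out in concentric zones (proximal DSE, intermediate eSP, distal
unmodulated).  Replicate studies of n experiments are scored with a paired
t-test, the per-replicate p-values are aggregated (mean by default), and
n_0.05 is the smallest n at which the aggregate drops below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from ._rng import as_rng
from .stats import TestResult, paired_t_test

__all__ = [
    "EfficacyDistribution",
    "MixtureModel",
    "EnsembleConfig",
    "Zone",
    "FieldTopology",
    "SimulatedExperiment",
    "SampleSizeCurve",
    "DSE_BASELINE",
    "DSE_MIXTURE",
    "ESP_BASELINE",
    "ESP_MIXTURE",
    "draw_baseline",
    "draw_post",
    "simulate_experiment",
    "simulate_field_experiment",
    "run_study",
    "pvalue_curve",
    "field_pvalue_curve",
    "zone_fractions_from_radii",
    "zone_area_fractions",
    "hippocampal_field_topology",
    "sweep_n_total",
]


@dataclass(frozen=True)
class EfficacyDistribution:
    """Gaussian over normalized efficacy, in percent of baseline."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")

    @property
    def variance(self) -> float:
        return self.sigma**2


@dataclass(frozen=True)
class MixtureModel:
    """Bimodal regulated/unregulated mixture of post-ND efficacies."""

    regulated: EfficacyDistribution
    unregulated: EfficacyDistribution
    fraction_regulated: float = 0.36

    def __post_init__(self):
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ParameterError("fraction_regulated must lie in [0, 1]")

    @property
    def mean(self) -> float:
        f = self.fraction_regulated
        return f * self.regulated.mu + (1 - f) * self.unregulated.mu

    @property
    def variance(self) -> float:
        f = self.fraction_regulated
        second = f * (self.regulated.sigma**2 + self.regulated.mu**2) + (1 - f) * (
            self.unregulated.sigma**2 + self.unregulated.mu**2
        )
        return second - self.mean**2


# Printed single-synapse operating points (normalized efficacy, % of baseline).
DSE_BASELINE = EfficacyDistribution(100.0, 61.0)
DSE_MIXTURE = MixtureModel(
    regulated=EfficacyDistribution(52.0, 16.3),
    unregulated=EfficacyDistribution(116.0, 43.0),
)
ESP_BASELINE = EfficacyDistribution(100.0, 58.0)
ESP_MIXTURE = MixtureModel(
    regulated=EfficacyDistribution(130.0, 12.0),
    unregulated=EfficacyDistribution(89.0, 8.0),
)

_TAILS = ("left", "right", "two_sided")


@dataclass(frozen=True)
class EnsembleConfig:
    """Simulation settings shared by ensemble and field scenarios.

    ``membership`` selects how regulated synapses are assigned: independent
    Bernoulli(fraction) per synapse per experiment ('bernoulli', the
    default) or a fixed rounded count per experiment ('fixed', for
    sensitivity analysis).  ``aggregate`` selects how replicate p-values are
    collapsed into the p-vs-n curve.
    """

    n_total: int = 12
    tail: str = "two_sided"
    reps: int = 1000
    aggregate: str = "mean"
    membership: str = "bernoulli"
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_total < 1:
            raise ParameterError("n_total must be >= 1")
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")
        if self.tail not in _TAILS:
            raise ParameterError(f"tail must be one of {_TAILS}")
        if self.aggregate not in ("mean", "median"):
            raise ParameterError("aggregate must be 'mean' or 'median'")
        if self.membership not in ("bernoulli", "fixed"):
            raise ParameterError("membership must be 'bernoulli' or 'fixed'")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Zone:
    """One concentric zone of the field topology: cell count, the baseline
    efficacy distribution of its synapses, and the post-ND mixture (None for
    unmodulated zones, whose post draws come from the baseline)."""

    n_cells: int
    baseline: EfficacyDistribution
    mixture: MixtureModel | None = None

    def __post_init__(self):
        if self.n_cells < 0:
            raise ParameterError("n_cells must be non-negative")


@dataclass(frozen=True)
class FieldTopology:
    zones: tuple[Zone, ...]
    n_cells: int = 100

    def __post_init__(self):
        if sum(z.n_cells for z in self.zones) != self.n_cells:
            raise ParameterError(
                f"zone cell counts sum to {sum(z.n_cells for z in self.zones)}, "
                f"expected n_cells={self.n_cells}"
            )


@dataclass(frozen=True)
class SimulatedExperiment:
    """One simulated experiment: the baseline and post-ND ensemble (or
    field) values, each an arithmetic mean of the underlying draws."""

    baseline_value: float
    post_value: float


@dataclass(frozen=True)
class SampleSizeCurve:
    """Aggregated p-value per candidate sample size, and n_0.05: the
    smallest n whose aggregate p falls below alpha (None if never reached on
    the grid)."""

    n_values: np.ndarray
    aggregate_p: np.ndarray
    n005: int | None
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_values, "aggregate_p": self.aggregate_p})


def draw_baseline(n: int, dist: EfficacyDistribution, stream=None) -> np.ndarray:
    """n i.i.d. baseline efficacy draws from the Gaussian ``dist``."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return as_rng(stream).normal(dist.mu, dist.sigma, n)


def draw_post(
    n: int, mixture: MixtureModel, stream=None, membership: str = "bernoulli"
) -> tuple[np.ndarray, np.ndarray]:
    """n post-ND draws from the regulated/unregulated mixture.

    Returns (values, regulated_flags).  With ``membership='fixed'`` exactly
    round(fraction x n) draws come from the regulated component.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = as_rng(stream)
    if membership == "bernoulli":
        flags = rng.random(n) < mixture.fraction_regulated
    elif membership == "fixed":
        k = int(np.rint(mixture.fraction_regulated * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
    else:
        raise ParameterError("membership must be 'bernoulli' or 'fixed'")
    z = rng.standard_normal(n)
    values = np.where(
        flags,
        mixture.regulated.mu + mixture.regulated.sigma * z,
        mixture.unregulated.mu + mixture.unregulated.sigma * z,
    )
    return values, flags


def simulate_experiment(
    config: EnsembleConfig,
    baseline_dist: EfficacyDistribution,
    mixture: MixtureModel,
    stream=None,
) -> SimulatedExperiment:
    """One ensemble experiment: the means of ``n_total`` independent
    baseline draws and ``n_total`` independent mixture draws."""
    rng = as_rng(stream)
    x = draw_baseline(config.n_total, baseline_dist, rng)
    y, _ = draw_post(config.n_total, mixture, rng, config.membership)
    return SimulatedExperiment(float(x.mean()), float(y.mean()))


def simulate_field_experiment(
    topology: FieldTopology, config: EnsembleConfig, stream=None
) -> SimulatedExperiment:
    """One field experiment: baseline and post values are means over all
    cells of per-cell ensemble averages; modulated zones draw their post
    efficacies from their mixture, unmodulated zones from their baseline."""
    rng = as_rng(stream)
    base_cells: list[float] = []
    post_cells: list[float] = []
    for zone in topology.zones:
        for _ in range(zone.n_cells):
            base_cells.append(draw_baseline(config.n_total, zone.baseline, rng).mean())
            if zone.mixture is None:
                post_cells.append(draw_baseline(config.n_total, zone.baseline, rng).mean())
            else:
                y, _ = draw_post(config.n_total, zone.mixture, rng, config.membership)
                post_cells.append(y.mean())
    return SimulatedExperiment(float(np.mean(base_cells)), float(np.mean(post_cells)))


def run_study(
    n_experiments: int,
    config: EnsembleConfig,
    baseline_dist: EfficacyDistribution,
    mixture: MixtureModel,
    stream=None,
) -> TestResult:
    """Simulate one study of ``n_experiments`` ensemble experiments and test
    it with a paired t-test (post vs baseline) using ``config.tail``."""
    if n_experiments < 2:
        raise ParameterError("a study needs at least 2 experiments")
    rng = as_rng(stream)
    exps = [
        simulate_experiment(config, baseline_dist, mixture, rng)
        for _ in range(n_experiments)
    ]
    x = np.array([e.baseline_value for e in exps])
    y = np.array([e.post_value for e in exps])
    return paired_t_test(x, y, config.tail)


# ---------------------------------------------------------------------------
# vectorized replicate machinery (exactly the same sampling scheme as the
# scalar functions above, batched over replicates for speed)


def _mixture_values(shape, mixture: MixtureModel, rng, membership: str) -> np.ndarray:
    if membership == "bernoulli":
        flags = rng.random(shape) < mixture.fraction_regulated
    else:
        n_last = shape[-1]
        k = int(np.rint(mixture.fraction_regulated * n_last))
        flags = np.zeros(shape, dtype=bool)
        flags[..., :k] = True
        # permute the last axis independently per experiment
        perm = rng.permuted(np.broadcast_to(np.arange(n_last), shape), axis=-1)
        flags = np.take_along_axis(flags, perm, axis=-1)
    z = rng.standard_normal(shape)
    return np.where(
        flags,
        mixture.regulated.mu + mixture.regulated.sigma * z,
        mixture.unregulated.mu + mixture.unregulated.sigma * z,
    )


def _paired_t_pvalues(x: np.ndarray, y: np.ndarray, tail: str) -> np.ndarray:
    """Paired t-test p-values along the last axis of (replicate, pair) arrays."""
    d = y - x
    n = d.shape[-1]
    m = d.mean(axis=-1)
    s = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    df = n - 1
    if tail == "left":
        return sps.t.cdf(t, df)
    if tail == "right":
        return sps.t.sf(t, df)
    return 2.0 * sps.t.sf(np.abs(t), df)


def _ensemble_replicates(
    n_experiments: int,
    config: EnsembleConfig,
    baseline_dist: EfficacyDistribution,
    mixture: MixtureModel,
    rng,
) -> np.ndarray:
    shape = (config.reps, n_experiments, config.n_total)
    x = rng.normal(baseline_dist.mu, baseline_dist.sigma, shape).mean(axis=-1)
    y = _mixture_values(shape, mixture, rng, config.membership).mean(axis=-1)
    return _paired_t_pvalues(x, y, config.tail)


def _field_replicates(
    n_experiments: int, topology: FieldTopology, config: EnsembleConfig, rng
) -> np.ndarray:
    reps = config.reps
    nt = config.n_total
    x_sum = np.zeros((reps, n_experiments))
    y_sum = np.zeros((reps, n_experiments))
    for zone in topology.zones:
        if zone.n_cells == 0:
            continue
        shape = (reps, n_experiments, zone.n_cells * nt)
        x_sum += rng.normal(zone.baseline.mu, zone.baseline.sigma, shape).sum(axis=-1)
        if zone.mixture is None:
            y_sum += rng.normal(zone.baseline.mu, zone.baseline.sigma, shape).sum(axis=-1)
        else:
            y_sum += _mixture_values(shape, zone.mixture, rng, config.membership).sum(
                axis=-1
            )
    denom = topology.n_cells * nt
    return _paired_t_pvalues(x_sum / denom, y_sum / denom, config.tail)


def _curve(replicate_fn, config: EnsembleConfig, n_grid, stream, stop_when_significant):
    grid = [int(n) for n in n_grid]
    if not grid:
        raise ParameterError("n_grid must not be empty")
    if any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] < 2:
        raise ParameterError("n_grid must be strictly increasing with n >= 2")
    rng = as_rng(stream)
    agg = np.mean if config.aggregate == "mean" else np.median
    ns, ps = [], []
    n005 = None
    for n in grid:
        p = float(agg(replicate_fn(n, rng)))
        ns.append(n)
        ps.append(p)
        if n005 is None and p < config.alpha:
            n005 = n
            if stop_when_significant:
                break
    return SampleSizeCurve(np.array(ns), np.array(ps), n005, config.alpha)


def pvalue_curve(
    config: EnsembleConfig,
    baseline_dist: EfficacyDistribution,
    mixture: MixtureModel,
    n_grid: Iterable[int] = range(2, 501),
    stream=None,
    stop_when_significant: bool = False,
) -> SampleSizeCurve:
    """Aggregate p-value vs sample size for the ensemble scenario.

    For each n on the grid, ``config.reps`` replicate studies of n
    experiments are simulated and tested; their p-values are aggregated
    (mean by default).  ``stop_when_significant`` truncates the scan at the
    first crossing, which leaves n_0.05 unchanged.
    """
    return _curve(
        lambda n, rng: _ensemble_replicates(n, config, baseline_dist, mixture, rng),
        config,
        n_grid,
        stream,
        stop_when_significant,
    )


def field_pvalue_curve(
    topology: FieldTopology,
    config: EnsembleConfig,
    n_grid: Iterable[int] = range(2, 501),
    stream=None,
    stop_when_significant: bool = False,
) -> SampleSizeCurve:
    """Aggregate p-value vs sample size for a field (population) scenario."""
    return _curve(
        lambda n, rng: _field_replicates(n, topology, config, rng),
        config,
        n_grid,
        stream,
        stop_when_significant,
    )


# ---------------------------------------------------------------------------
# field geometry


def zone_area_fractions(radii: Sequence[float]) -> np.ndarray:
    """Exact annulus area fractions of concentric zones, as percentages."""
    r = np.asarray(radii, dtype=float)
    if r.size < 1 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ParameterError("radii must be positive and strictly increasing")
    outer = r[-1] ** 2
    inner = np.concatenate([[0.0], r[:-1] ** 2])
    return 100.0 * (r**2 - inner) / outer


def zone_fractions_from_radii(radii: Sequence[float]) -> tuple[int, ...]:
    """Integer zone percentages: each annulus area fraction rounded to the
    nearest percent, the outermost zone absorbing the rounding remainder so
    the total is exactly 100."""
    exact = zone_area_fractions(radii)
    rounded = [int(np.rint(f)) for f in exact[:-1]]
    return tuple(rounded + [100 - sum(rounded)])


def hippocampal_field_topology(
    include_dse: bool = True,
    include_esp: bool = True,
    radii: Sequence[float] = (60.0, 120.0, 180.0),
    n_cells: int = 100,
) -> FieldTopology:
    """The standard 180-um-disc topology: proximal cells (<=60 um) carry the
    DSE mixture, intermediate cells (60-120 um) the eSP mixture, distal
    cells are unmodulated.  Cell counts are the integer zone percentages of
    ``n_cells`` (11/33/56 of 100), fixed deterministically.

    Zone baselines follow the experiment that characterized each zone:
    the proximal (depolarized-neuron) zone uses the DSE baseline
    (100 +/- 61%), the intermediate and distal (heteroneuron) zones the eSP
    baseline (100 +/- 58%).
    """
    fractions = zone_fractions_from_radii(radii)
    counts = [int(np.rint(f * n_cells / 100)) for f in fractions[:-1]]
    counts.append(n_cells - sum(counts))
    zones = (
        Zone(counts[0], DSE_BASELINE, DSE_MIXTURE if include_dse else None),
        Zone(counts[1], ESP_BASELINE, ESP_MIXTURE if include_esp else None),
        Zone(counts[2], ESP_BASELINE, None),
    )
    return FieldTopology(zones, n_cells)


def sweep_n_total(
    n_totals: Iterable[int],
    config: EnsembleConfig,
    baseline_dist: EfficacyDistribution | None = None,
    mixture: MixtureModel | None = None,
    topology: FieldTopology | None = None,
    n_grid: Iterable[int] = range(2, 501),
    stream=None,
) -> pd.DataFrame:
    """n_0.05 as a function of the number of synapses per ensemble.

    Pass (baseline_dist, mixture) for an ensemble scenario or ``topology``
    for a field scenario; in the field case every zone keeps its own
    distributions and only ``n_total`` changes.  Returns a DataFrame with
    columns n_total and n005 (NaN when significance is never reached on the
    grid).
    """
    totals = [int(v) for v in n_totals]
    if any(v < 1 or v > 64 for v in totals):
        raise ParameterError("n_total values must lie in [1, 64]")
    if (topology is None) == (baseline_dist is None or mixture is None):
        raise ParameterError(
            "provide either (baseline_dist, mixture) or topology, not both"
        )
    rng = as_rng(stream)
    grid = list(n_grid)
    rows = []
    for nt in totals:
        cfg = EnsembleConfig(
            nt, config.tail, config.reps, config.aggregate, config.membership, config.alpha
        )
        if topology is None:
            curve = pvalue_curve(cfg, baseline_dist, mixture, grid, rng, True)
        else:
            curve = field_pvalue_curve(topology, cfg, grid, rng, True)
        rows.append({"n_total": nt, "n005": np.nan if curve.n005 is None else curve.n005})
    return pd.DataFrame(rows)
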