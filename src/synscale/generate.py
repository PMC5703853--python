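"""Synthetic minimal-stimulation, bulk and field recordings.

This module emulates the experimental protocol used to probe CA3-CA1
transmission: stimuli delivered at 0.33 Hz, a 3-minute baseline window, a
simulated neuronal depolarization (ND) at the end of the baseline, and a
2-minute post-ND window.  A single synapse responds to each stimulus with a
Bernoulli release (probability Pr), success amplitudes drawn from a Gaussian
around the synaptic potency, and additive Gaussian electrode noise.  Bulk
(ensemble) recordings sum several synapses linearly, as CA1 pyramidal
neurons do; field recordings average many such cells.

Ground truth (which stimuli actually released) is carried alongside the
amplitudes so downstream analysis can be validated without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from ._rng import as_rng, as_seed_sequence

__all__ = [
    "SynapseSpec",
    "StimulusProtocol",
    "ModulationSpec",
    "EpscTrain",
    "FieldLayout",
    "generate_single_synapse_train",
    "generate_bulk_train",
    "generate_field_series",
]


@dataclass(frozen=True)
class SynapseSpec:
    """Generative parameters of one synapse.

    Parameters
    ----------
    pr
        Probability of neurotransmitter release per stimulus, in [0, 1].
    potency_mean
        Synaptic potency: mean peak amplitude of successful responses (pA).
    potency_sd
        Trial-to-trial SD of success amplitudes (pA).
    noise_sd
        SD of the additive recording noise applied to every stimulus (pA).
    """

    pr: float
    potency_mean: float = 9.0
    potency_sd: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.pr <= 1.0:
            raise ParameterError(f"pr must lie in [0, 1], got {self.pr}")
        if self.potency_mean <= 0:
            raise ParameterError("potency_mean must be positive")
        if self.potency_sd < 0 or self.noise_sd < 0:
            raise ParameterError("standard deviations must be non-negative")


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation schedule: ``floor(duration x rate)`` stimuli per window,
    the first at the start of each window; ND occurs at the end of the
    baseline window."""

    rate: float = 0.33
    baseline_duration: float = 180.0
    post_duration: float = 120.0

    def __post_init__(self):
        if self.rate <= 0 or self.baseline_duration <= 0 or self.post_duration <= 0:
            raise ParameterError("rate and durations must be positive")

    @property
    def nd_time(self) -> float:
        return self.baseline_duration

    @property
    def n_baseline(self) -> int:
        return math.floor(self.baseline_duration * self.rate)

    @property
    def n_post(self) -> int:
        return math.floor(self.post_duration * self.rate)

    def stimulus_times(self) -> np.ndarray:
        base = np.arange(self.n_baseline) / self.rate
        post = self.nd_time + np.arange(self.n_post) / self.rate
        return np.concatenate([base, post])


@dataclass(frozen=True)
class ModulationSpec:
    """Step change applied to a synapse's parameters from ND onwards.

    DSE reduces Pr (``pr_factor < 1``); eSP increases efficacy, chiefly
    through Pr.  ``kind='none'`` forces both factors to 1.
    """

    kind: str = "none"
    pr_factor: float = 1.0
    potency_factor: float = 1.0

    def __post_init__(self):
        if self.kind not in ("dse", "esp", "none"):
            raise ParameterError(f"unknown modulation kind {self.kind!r}")
        if self.pr_factor < 0 or self.potency_factor < 0:
            raise ParameterError("modulation factors must be non-negative")
        if self.kind == "none" and (self.pr_factor != 1.0 or self.potency_factor != 1.0):
            raise ParameterError("kind='none' requires both factors equal to 1")

    @classmethod
    def none(cls) -> "ModulationSpec":
        return cls()

    @classmethod
    def dse(cls, pr_factor: float = 0.52, potency_factor: float = 1.0) -> "ModulationSpec":
        return cls("dse", pr_factor, potency_factor)

    @classmethod
    def esp(cls, pr_factor: float = 1.0, potency_factor: float = 1.3) -> "ModulationSpec":
        return cls("esp", pr_factor, potency_factor)


@dataclass(frozen=True)
class EpscTrain:
    """A stimulus-locked amplitude series with ground-truth release flags."""

    stim_times: np.ndarray
    amplitudes: np.ndarray
    truth_success: np.ndarray
    nd_time: float

    def __post_init__(self):
        object.__setattr__(self, "stim_times", np.asarray(self.stim_times, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "truth_success", np.asarray(self.truth_success, dtype=bool))
        if not (len(self.stim_times) == len(self.amplitudes) == len(self.truth_success)):
            raise ParameterError("per-stimulus sequences must have equal length")
        if np.any(np.diff(self.stim_times) <= 0):
            raise ParameterError("stim_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.stim_times)

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.stim_times < self.nd_time

    @property
    def post_mask(self) -> np.ndarray:
        return self.stim_times >= self.nd_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stim_time_s": self.stim_times,
                "amplitude_pA": self.amplitudes,
                "truth_success": self.truth_success,
                "window": np.where(self.baseline_mask, "baseline", "post"),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpscTrain":
        df = pd.read_csv(path)
        post = df["window"] == "post"
        if post.any():
            nd_time = float(df.loc[post, "stim_time_s"].min())
        else:
            nd_time = float(df["stim_time_s"].max()) + 1.0
        return cls(
            df["stim_time_s"].to_numpy(),
            df["amplitude_pA"].to_numpy(),
            df["truth_success"].to_numpy(dtype=bool),
            nd_time,
        )


def _synapse_responses(
    spec: SynapseSpec,
    mod: ModulationSpec,
    times: np.ndarray,
    nd_time: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free responses of one synapse: (amplitudes, success flags)."""
    post = times >= nd_time
    pr_eff = np.where(post, spec.pr * mod.pr_factor, spec.pr)
    if np.any(pr_eff > 1.0):
        raise ParameterError(
            f"effective release probability {spec.pr * mod.pr_factor:.3f} exceeds 1"
        )
    success = rng.random(times.size) < pr_eff
    mean = np.where(post, spec.potency_mean * mod.potency_factor, spec.potency_mean)
    draws = rng.normal(mean, spec.potency_sd)
    return np.where(success, draws, 0.0), success


def generate_single_synapse_train(
    spec: SynapseSpec,
    protocol: StimulusProtocol = StimulusProtocol(),
    mod: ModulationSpec = ModulationSpec(),
    seed=None,
) -> EpscTrain:
    """Simulate a minimal-stimulation recording of a single synapse.

    Successes are Bernoulli(Pr) per stimulus (Pr scaled by ``mod.pr_factor``
    after ND), success amplitudes Gaussian around the (possibly scaled)
    potency, failures 0 pA; Gaussian recording noise is added to every
    stimulus.
    """
    ss = as_seed_sequence(seed)
    syn_ss, noise_ss = ss.spawn(2)
    times = protocol.stimulus_times()
    amp, success = _synapse_responses(spec, mod, times, protocol.nd_time, as_rng(syn_ss))
    noise = as_rng(noise_ss).normal(0.0, spec.noise_sd, times.size)
    return EpscTrain(times, amp + noise, success, protocol.nd_time)


def generate_bulk_train(
    specs: Sequence[SynapseSpec],
    regulated_flags: Sequence[bool],
    protocol: StimulusProtocol = StimulusProtocol(),
    mod: ModulationSpec = ModulationSpec(),
    seed=None,
    noise_sd: float | None = None,
) -> EpscTrain:
    """Simulate a bulk-stimulation (synapse ensemble) recording.

    Each synapse responds independently per stimulus; the recorded amplitude
    is the linear sum of the individual responses plus one shared electrode
    noise term (noise lives at the electrode, not per synapse).  Modulation
    is applied only to synapses whose ``regulated_flags`` entry is True.
    ``truth_success`` marks stimuli at which at least one synapse released.

    With a single synapse this reproduces ``generate_single_synapse_train``
    exactly under the same seed.
    """
    specs = list(specs)
    flags = list(regulated_flags)
    if not specs:
        raise ParameterError("need at least one synapse")
    if len(flags) != len(specs):
        raise ParameterError("one regulated flag per synapse is required")
    ss = as_seed_sequence(seed)
    *syn_seeds, noise_ss = ss.spawn(len(specs) + 1)
    times = protocol.stimulus_times()
    total = np.zeros(times.size)
    released = np.zeros(times.size, dtype=bool)
    none = ModulationSpec.none()
    for spec, flag, child in zip(specs, flags, syn_seeds):
        amp, success = _synapse_responses(
            spec, mod if flag else none, times, protocol.nd_time, as_rng(child)
        )
        total += amp
        released |= success
    sd = specs[0].noise_sd if noise_sd is None else noise_sd
    total += as_rng(noise_ss).normal(0.0, sd, times.size)
    return EpscTrain(times, total, released, protocol.nd_time)


@dataclass(frozen=True)
class FieldLayout:
    """Cell layout for a simulated field (population) recording.

    ``zone_counts`` gives the number of cells per concentric zone and must
    sum to ``n_cells``; ``zone_mods`` assigns each zone's modulation, applied
    after ND to a random ``fraction_regulated`` subset of each cell's
    synapses.  All synapses share ``synapse_spec``.
    """

    zone_counts: tuple[int, ...]
    zone_mods: tuple[ModulationSpec, ...]
    synapse_spec: SynapseSpec = SynapseSpec(pr=0.4)
    n_synapses: int = 12
    n_cells: int = 100
    fraction_regulated: float = 0.36

    def __post_init__(self):
        if len(self.zone_counts) != len(self.zone_mods):
            raise ParameterError("one modulation per zone is required")
        if sum(self.zone_counts) != self.n_cells:
            raise ParameterError(
                f"zone cell counts {self.zone_counts} do not sum to n_cells={self.n_cells}"
            )
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ParameterError("fraction_regulated must lie in [0, 1]")


def generate_field_series(
    layout: FieldLayout,
    protocol: StimulusProtocol = StimulusProtocol(),
    seed=None,
) -> EpscTrain:
    """Simulate a field recording: per stimulus, the mean over cells of that
    cell's bulk-train amplitude.  Deterministic under a fixed seed."""
    ss = as_seed_sequence(seed)
    flag_ss, *cell_seeds = ss.spawn(layout.n_cells + 1)
    flag_rng = as_rng(flag_ss)
    times = protocol.stimulus_times()
    total = np.zeros(times.size)
    released = np.zeros(times.size, dtype=bool)
    specs = [layout.synapse_spec] * layout.n_synapses
    i = 0
    for count, mod in zip(layout.zone_counts, layout.zone_mods):
        for _ in range(count):
            if mod.kind == "none":
                flags = np.zeros(layout.n_synapses, dtype=bool)
            else:
                flags = flag_rng.random(layout.n_synapses) < layout.fraction_regulated
            train = generate_bulk_train(specs, flags, protocol, mod, cell_seeds[i])
            total += train.amplitudes
            released |= train.truth_success
            i += 1
    return EpscTrain(times, total / layout.n_cells, released, protocol.nd_time)
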