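"""Synaptic-parameter extraction and the 2-SD modulation classifier.

Given a stimulus-locked EPSC train, this module computes the three quantal
parameters used throughout the analysis

* Pr        - probability of release: successes / total stimuli,
* potency   - mean peak amplitude of the successes (pA),
* efficacy  - Pr x potency (pA), i.e. the mean response including failures,

bins them into 1-minute bins to expose the time course, and classifies a
synapse as depressed / potentiated / unchanged depending on whether the
post-ND efficacy falls more than two standard deviations below or above the
baseline-bin efficacies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .generate import EpscTrain

__all__ = [
    "SynapticParams",
    "BinnedSeries",
    "ModulationCall",
    "detect_successes",
    "compute_params",
    "bin_series",
    "classify_modulation",
    "normalize_to_baseline",
]


@dataclass(frozen=True)
class SynapticParams:
    pr: float
    potency: float
    efficacy: float
    window_label: str
    n_stimuli: int

    def __post_init__(self):
        if not 0.0 <= self.pr <= 1.0:
            raise ParameterError(f"pr must lie in [0, 1], got {self.pr}")


@dataclass(frozen=True)
class BinnedSeries:
    """Per-bin synaptic parameters; bins tile the recording without overlap."""

    bin_starts: np.ndarray
    params: tuple[SynapticParams, ...]
    bin_width: float = 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_s": np.asarray(self.bin_starts, dtype=float),
                "window": [p.window_label for p in self.params],
                "n_stimuli": [p.n_stimuli for p in self.params],
                "pr": [p.pr for p in self.params],
                "potency_pA": [p.potency for p in self.params],
                "efficacy_pA": [p.efficacy for p in self.params],
            }
        )


@dataclass(frozen=True)
class ModulationCall:
    label: str
    baseline_mean: float
    baseline_sd: float
    post_mean: float


def detect_successes(train: EpscTrain, noise_sd: float, k: float = 3.0) -> np.ndarray:
    """Amplitude-threshold success detection: success iff amplitude exceeds
    ``k x noise_sd``.  Ignores the ground-truth flags."""
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    return train.amplitudes > k * noise_sd


def compute_params(
    train: EpscTrain, success_flags: np.ndarray, window: str
) -> SynapticParams:
    """Pr / potency / efficacy over one window ('baseline' or 'post').

    A window with zero successes reports potency 0 (and hence efficacy 0) so
    that the product identity efficacy = Pr x potency always holds.
    """
    if window == "baseline":
        mask = train.baseline_mask
    elif window == "post":
        mask = train.post_mask
    else:
        raise ParameterError(f"window must be 'baseline' or 'post', got {window!r}")
    flags = np.asarray(success_flags, dtype=bool)
    if flags.shape != train.amplitudes.shape:
        raise ParameterError("success_flags must match the train length")
    n = int(mask.sum())
    if n == 0:
        raise ParameterError(f"no stimuli in the {window} window")
    succ = mask & flags
    pr = succ.sum() / n
    potency = float(train.amplitudes[succ].mean()) if succ.any() else 0.0
    return SynapticParams(pr, potency, pr * potency, window, n)


def bin_series(
    train: EpscTrain, success_flags: np.ndarray, bin_width: float = 60.0
) -> BinnedSeries:
    """Group the train into fixed-width bins (default 1 min) and compute the
    synaptic parameters per bin.  Empty bins report zero stimuli."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    flags = np.asarray(success_flags, dtype=bool)
    n_bins = int(np.floor(train.stim_times.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    params = []
    starts = []
    for lo in edges[:-1]:
        hi = lo + bin_width
        mask = (train.stim_times >= lo) & (train.stim_times < hi)
        label = "baseline" if lo < train.nd_time else "post"
        n = int(mask.sum())
        if n == 0:
            params.append(SynapticParams(0.0, 0.0, 0.0, label, 0))
        else:
            succ = mask & flags
            pr = succ.sum() / n
            potency = float(train.amplitudes[succ].mean()) if succ.any() else 0.0
            params.append(SynapticParams(pr, potency, pr * potency, label, n))
        starts.append(lo)
    return BinnedSeries(np.asarray(starts), tuple(params), bin_width)


def classify_modulation(binned: BinnedSeries) -> ModulationCall:
    """Apply the 2-SD rule.

    The baseline mean and SD are taken across the baseline-bin efficacies
    (the time course is presented in 1-min bins, so the bin is the sampling
    unit).  The post value is the efficacy pooled over the whole post
    window, reconstructed exactly from the per-bin parameters by weighting
    Pr with stimulus counts and potency with success counts.
    """
    base = [p for p in binned.params if p.window_label == "baseline" and p.n_stimuli > 0]
    post = [p for p in binned.params if p.window_label == "post" and p.n_stimuli > 0]
    if len(base) < 2:
        raise ParameterError("need at least 2 non-empty baseline bins to estimate the SD")
    if not post:
        raise ParameterError("no non-empty post bins")
    base_eff = np.array([p.efficacy for p in base])
    baseline_mean = float(base_eff.mean())
    baseline_sd = float(base_eff.std(ddof=1))

    n_stim = np.array([p.n_stimuli for p in post], dtype=float)
    n_succ = np.array([p.pr * p.n_stimuli for p in post])
    pooled_pr = n_succ.sum() / n_stim.sum()
    pooled_potency = (
        float(np.dot([p.potency for p in post], n_succ) / n_succ.sum())
        if n_succ.sum() > 0
        else 0.0
    )
    post_mean = pooled_pr * pooled_potency

    if post_mean < baseline_mean - 2.0 * baseline_sd:
        label = "depressed"
    elif post_mean > baseline_mean + 2.0 * baseline_sd:
        label = "potentiated"
    else:
        label = "unchanged"
    return ModulationCall(label, baseline_mean, baseline_sd, post_mean)


def normalize_to_baseline(
    params_baseline: SynapticParams, params_post: SynapticParams
) -> float:
    """Relative synaptic efficacy: post as percent of baseline (baseline = 100)."""
    if params_baseline.efficacy <= 0:
        raise ParameterError("baseline efficacy must be positive to normalize")
    return 100.0 * params_post.efficacy / params_baseline.efficacy


def params_table(train: EpscTrain, success_flags: np.ndarray) -> pd.DataFrame:
    """Window-level summary table (one row per window) plus the 2-SD label."""
    base = compute_params(train, success_flags, "baseline")
    post = compute_params(train, success_flags, "post")
    call = classify_modulation(bin_series(train, success_flags))
    return pd.DataFrame(
        {
            "window": ["baseline", "post"],
            "pr": [base.pr, post.pr],
            "potency_pA": [base.potency, post.potency],
            "efficacy_pA": [base.efficacy, post.efficacy],
            "label": [call.label, call.label],
        }
    )
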