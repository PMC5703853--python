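"""Named simulation scenarios, JSON configuration, and artifact output.

The registry pins the printed single-synapse parameter sets:

* ``dse_ensemble``   baseline 100 +/- 61 %, regulated 52 +/- 16.3 %,
  unregulated 116 +/- 43 %, left-tailed test, 1000 replicates
* ``esp_ensemble``   baseline 100 +/- 58 %, regulated 130 +/- 12 %,
  unregulated 89 +/- 8 %, right-tailed test, 1000 replicates
* ``field_full`` / ``field_dse_only`` / ``field_esp_only``   100-cell disc
  topologies (11 / 33 / 56 cells), two-tailed test, 100 replicates

``run_scenario`` executes the matching Monte Carlo pipeline and writes a
p-vs-n CSV plus a JSON summary that records the full parameter set and seed,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .montecarlo import (
    DSE_BASELINE,
    DSE_MIXTURE,
    ESP_BASELINE,
    ESP_MIXTURE,
    EfficacyDistribution,
    EnsembleConfig,
    FieldTopology,
    MixtureModel,
    SampleSizeCurve,
    field_pvalue_curve,
    hippocampal_field_topology,
    pvalue_curve,
)

log = logging.getLogger("synscale")

__all__ = ["ScenarioConfig", "SCENARIO_NAMES", "load_config", "run_scenario"]

SCENARIO_NAMES = (
    "dse_ensemble",
    "esp_ensemble",
    "field_full",
    "field_dse_only",
    "field_esp_only",
    "custom",
)


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "custom"
    baseline: EfficacyDistribution = EfficacyDistribution(100.0, 61.0)
    mixture: MixtureModel = DSE_MIXTURE
    topology: FieldTopology | None = None
    n_total: int = 12
    tail: str = "two_sided"
    reps: int = 1000
    aggregate: str = "mean"
    membership: str = "bernoulli"
    alpha: float = 0.05
    n_grid: tuple[int, int] = (2, 500)
    master_seed: int = 0
    full_curve: bool = False

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            self.n_total, self.tail, self.reps, self.aggregate, self.membership, self.alpha
        )


def _named_scenario(name: str, **overrides) -> ScenarioConfig:
    if name == "dse_ensemble":
        base = dict(baseline=DSE_BASELINE, mixture=DSE_MIXTURE, tail="left", reps=1000)
    elif name == "esp_ensemble":
        base = dict(baseline=ESP_BASELINE, mixture=ESP_MIXTURE, tail="right", reps=1000)
    elif name == "field_full":
        base = dict(topology=hippocampal_field_topology(True, True), tail="two_sided", reps=100)
    elif name == "field_dse_only":
        base = dict(topology=hippocampal_field_topology(True, False), tail="two_sided", reps=100)
    elif name == "field_esp_only":
        base = dict(topology=hippocampal_field_topology(False, True), tail="two_sided", reps=100)
    elif name == "custom":
        base = {}
    else:
        raise ParameterError(f"unknown scenario name {name!r}; choose from {SCENARIO_NAMES}")
    base.update(overrides)
    return ScenarioConfig(name=name, **base)


_DIST_KEYS = {"mu", "sigma"}
_TOP_KEYS = {
    "name",
    "seed",
    "n_total",
    "reps",
    "tail",
    "aggregate",
    "membership",
    "alpha",
    "n_grid",
    "baseline",
    "regulated",
    "unregulated",
    "fraction_regulated",
    "full_curve",
}


def _dist(obj, key) -> EfficacyDistribution:
    if not isinstance(obj, dict) or set(obj) - _DIST_KEYS or _DIST_KEYS - set(obj):
        raise ParameterError(f"'{key}' must be an object with keys mu and sigma")
    return EfficacyDistribution(float(obj["mu"]), float(obj["sigma"]))


def load_config(path) -> ScenarioConfig:
    """Read and validate a JSON scenario configuration.

    Unknown keys are rejected by name; omitted keys fall back to the named
    scenario's defaults (or the custom defaults: n_total 12, 1000 replicates,
    alpha 0.05, grid 2..500).
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError("config must be a JSON object")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    name = raw.get("name", "custom")
    overrides: dict = {}
    for key in ("n_total", "reps"):
        if key in raw:
            overrides[key] = int(raw[key])
    for key in ("tail", "aggregate", "membership"):
        if key in raw:
            overrides[key] = str(raw[key])
    if "alpha" in raw:
        overrides["alpha"] = float(raw["alpha"])
    if "seed" in raw:
        overrides["master_seed"] = int(raw["seed"])
    if "full_curve" in raw:
        overrides["full_curve"] = bool(raw["full_curve"])
    if "n_grid" in raw:
        lo, hi = (int(v) for v in raw["n_grid"])
        if not 2 <= lo < hi:
            raise ParameterError("n_grid must be [lo, hi] with 2 <= lo < hi")
        overrides["n_grid"] = (lo, hi)
    mixture_keys = {"baseline", "regulated", "unregulated", "fraction_regulated"} & set(raw)
    if mixture_keys:
        if name.startswith("field"):
            raise ParameterError(
                "field scenarios fix their per-zone distributions; "
                f"cannot override {sorted(mixture_keys)}"
            )
        defaults = _named_scenario(name)
        baseline = _dist(raw["baseline"], "baseline") if "baseline" in raw else defaults.baseline
        mix = defaults.mixture
        regulated = _dist(raw["regulated"], "regulated") if "regulated" in raw else mix.regulated
        unregulated = (
            _dist(raw["unregulated"], "unregulated") if "unregulated" in raw else mix.unregulated
        )
        fraction = float(raw.get("fraction_regulated", mix.fraction_regulated))
        overrides["baseline"] = baseline
        overrides["mixture"] = MixtureModel(regulated, unregulated, fraction)
    cfg = _named_scenario(name, **overrides)
    # EnsembleConfig construction revalidates tail/aggregate/membership/alpha
    cfg.ensemble_config()
    return cfg


def _params_record(cfg: ScenarioConfig) -> dict:
    rec = {
        "n_total": cfg.n_total,
        "tail": cfg.tail,
        "reps": cfg.reps,
        "aggregate": cfg.aggregate,
        "membership": cfg.membership,
        "alpha": cfg.alpha,
    }
    if cfg.topology is None:
        rec["baseline"] = dataclasses.asdict(cfg.baseline)
        rec["mixture"] = dataclasses.asdict(cfg.mixture)
    else:
        rec["topology"] = [
            {
                "n_cells": z.n_cells,
                "baseline": dataclasses.asdict(z.baseline),
                "mixture": None if z.mixture is None else dataclasses.asdict(z.mixture),
            }
            for z in cfg.topology.zones
        ]
    return rec


def run_scenario(cfg: ScenarioConfig, out_dir=None) -> dict:
    """Run a scenario's p-vs-n scan; optionally write CSV + JSON artifacts.

    Returns the summary record (scenario, n005, n_grid, reps, seed, params).
    """
    grid = range(cfg.n_grid[0], cfg.n_grid[1] + 1)
    stream = np.random.default_rng(cfg.master_seed)
    econf = cfg.ensemble_config()
    log.info("running scenario %s (seed=%d, reps=%d)", cfg.name, cfg.master_seed, cfg.reps)
    if cfg.topology is None:
        curve: SampleSizeCurve = pvalue_curve(
            econf, cfg.baseline, cfg.mixture, grid, stream, not cfg.full_curve
        )
    else:
        curve = field_pvalue_curve(cfg.topology, econf, grid, stream, not cfg.full_curve)
    summary = {
        "scenario": cfg.name,
        "n005": curve.n005,
        "n_grid": list(cfg.n_grid),
        "reps": cfg.reps,
        "seed": cfg.master_seed,
        "params": _params_record(cfg),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve_path = out / f"{cfg.name}_pvalue_curve.csv"
        curve.to_frame().to_csv(curve_path, index=False)
        (out / f"{cfg.name}_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        log.info("wrote %s", curve_path)
    return summary
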