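"""Run configuration: YAML schema, validation and the pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, InvalidArgumentError
from .model import PriorSpec, fit_mcmc
from .projection import Scenario, run_scenario, summarize_run
from .synth import TrendSpec, make_default_truth, simulate_incidence, write_fixture

log = logging.getLogger("envenom")

_LATTICE_KEYS = {"n_rows", "n_cols", "cell_size"}
_MODEL_KEYS = {"family", "sd_fixed", "sd_c", "tau_shape", "tau_rate", "n_chains", "n_iter"}
_SCENARIO_KEYS = {
    "ssp_id", "rcp_id", "rcm_id", "warming_per_decade", "rain_multiplier_per_decade",
    "demand_end_shares", "population_growth",
}
_TOP_KEYS = {"seed", "out_dir", "lattice", "model", "scenarios", "stages"}
_STAGES = ("synth", "fit", "project", "summarize")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs"
    lattice: dict = field(default_factory=lambda: {"n_rows": 20, "n_cols": 20, "cell_size": 1.0})
    model: dict = field(default_factory=lambda: {"family": "poisson", "n_chains": 3, "n_iter": 4000})
    scenarios: list = field(default_factory=list)
    stages: list = field(default_factory=lambda: list(_STAGES))

    def priors(self) -> PriorSpec:
        kw = {k: self.model[k] for k in ("family", "sd_fixed", "sd_c", "tau_shape", "tau_rate")
              if k in self.model}
        return PriorSpec(**kw)

    def scenario_objects(self) -> list[Scenario]:
        out = []
        for s in self.scenarios:
            trend = TrendSpec(
                s.get("warming_per_decade", 0.0), s.get("rain_multiplier_per_decade", 1.0)
            )
            kw = {
                "ssp_id": s["ssp_id"], "rcp_id": s["rcp_id"], "rcm_id": s["rcm_id"],
                "trend": trend,
            }
            if "demand_end_shares" in s:
                kw["demand_end_shares"] = tuple(s["demand_end_shares"])
            if "population_growth" in s:
                kw["population_growth"] = tuple(s["population_growth"])
            out.append(Scenario(**kw))
        return out


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {unknown}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    if "lattice" in raw:
        _reject_unknown(raw["lattice"], _LATTICE_KEYS, "lattice")
    if "model" in raw:
        _reject_unknown(raw["model"], _MODEL_KEYS, "model")
    for i, s in enumerate(raw.get("scenarios", [])):
        _reject_unknown(s, _SCENARIO_KEYS, f"scenarios[{i}]")
    stages = raw.get("stages", list(_STAGES))
    bad = [s for s in stages if s not in _STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs")),
        lattice={**RunConfig().lattice, **raw.get("lattice", {})},
        model={**RunConfig().model, **raw.get("model", {})},
        scenarios=list(raw.get("scenarios", [])),
        stages=list(stages),
    )
    cfg.scenario_objects()  # validate pairings early
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute synth -> fit -> project -> summarize as toggled.

    Writes a JSON manifest with per-stage timing, seeds and output
    checksums; a stage failure is recorded in the manifest before the
    exception propagates.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    manifest_path = out / "manifest.json"

    def _record(stage: str, status: str, t0: float) -> None:
        manifest["stages"][stage] = {"status": status, "seconds": round(time.time() - t0, 3)}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    truth = None
    result = None
    try:
        if "synth" in config.stages:
            t0 = time.time()
            log.info("stage synth: generating landscapes")
            truth = make_default_truth(
                seed=config.seed,
                n_rows=config.lattice["n_rows"],
                n_cols=config.lattice["n_cols"],
            )
            write_fixture(truth, out / "fixture")
            _record("synth", "ok", t0)
        if "fit" in config.stages:
            t0 = time.time()
            if truth is None:
                raise InvalidArgumentError("fit requested without a synth stage or fixture")
            log.info("stage fit: MCMC over %d iterations", config.model["n_iter"])
            obs = simulate_incidence(truth, int(truth.population.years[0]), seed=config.seed)
            result = fit_mcmc(
                obs, truth.species, truth.landcover, truth.h2010_layer(),
                priors=config.priors(),
                n_chains=int(config.model["n_chains"]),
                n_iter=int(config.model["n_iter"]),
                seed=config.seed,
            )
            result.summary.to_csv(out / "posterior_summary.csv")
            result.save(out / "chains")
            manifest["files"]["posterior_summary.csv"] = _checksum(out / "posterior_summary.csv")
            manifest["files"]["chains/chains.csv"] = _checksum(out / "chains" / "chains.csv")
            _record("fit", "ok", t0)
        if "project" in config.stages:
            t0 = time.time()
            if truth is None:
                raise InvalidArgumentError("project requested without synth")
            params = truth.params  # projections hold fitted params constant
            for scenario in config.scenario_objects():
                log.info("stage project: scenario %s", scenario.name)
                run = run_scenario(scenario, params, truth)
                np.save(out / f"incidence_{scenario.name}.npy", run.incidence)
                if "summarize" in config.stages:
                    summary = summarize_run(run)
                    summary.national.to_csv(out / f"national_{scenario.name}.csv", index=False)
                    summary.transitions.to_csv(
                        out / f"transitions_{scenario.name}.csv", index=False
                    )
                    manifest["files"][f"national_{scenario.name}.csv"] = _checksum(
                        out / f"national_{scenario.name}.csv"
                    )
            _record("project", "ok", t0)
            if "summarize" in config.stages:
                _record("summarize", "ok", t0)
    except Exception as exc:  # noqa: BLE001 - record failure point, then re-raise
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
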