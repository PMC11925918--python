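"""End-to-end orchestration: synthetic data -> weights -> index -> forecast.

The single entry point :func:`run_pipeline` chains every stage on a
synthetic multi-year scenario:

1. generate the study region and the 13-indicator stacks for each year;
2. normalise, pool the years, check sampling adequacy, fit the PCA weights;
3. build H, S, E and the HHR surface per year, classify with Jenks breaks
   frozen on the baseline year (or a fixed grading standard);
4. account areas, transitions and dominance subzones;
5. hindcast the last observed year from the two earlier ones and score it
   with Cohen's kappa, sweep the CA iteration count for robustness, then
   forecast one period beyond the last year.

A manifest JSON records the seed, a config hash and every stage summary, so
two runs with the same config are byte-identical apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import camarkov, indicators, risk_index, synthetic_data, validation
from .grid_io import Grid, write_raster
from .risk_index import RISK_LEVELS

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("heatrisk")

_SCHEMA_VERSION = 1

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(synthetic_data.SyntheticScenario)}
_TOP_KEYS = {"schema_version", "seed", "out_dir", "scenario", "weights", "breaks",
             "simulation", "robustness_iterations", "write_rasters"}
_WEIGHTS_KEYS = {"b_formula", "retention", "sample_cap"}
_BREAKS_KEYS = {"mode", "values", "sample_cap"}
_SIM_KEYS = {"iterations", "filter_size"}


@dataclass
class PipelineConfig:
    """Validated configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "heatrisk_out"
    scenario: dict[str, Any] = field(default_factory=dict)
    weights: dict[str, Any] = field(default_factory=dict)
    breaks: dict[str, Any] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)
    robustness_iterations: tuple[int, ...] = ()
    write_rasters: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        version = raw.get("schema_version", _SCHEMA_VERSION)
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version}")
        for section, allowed in (("scenario", _SCENARIO_KEYS), ("weights", _WEIGHTS_KEYS),
                                 ("breaks", _BREAKS_KEYS), ("simulation", _SIM_KEYS)):
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "heatrisk_out")),
            scenario=dict(raw.get("scenario", {})),
            weights=dict(raw.get("weights", {})),
            breaks=dict(raw.get("breaks", {})),
            simulation=dict(raw.get("simulation", {})),
            robustness_iterations=tuple(raw.get("robustness_iterations", ())),
            write_rasters=bool(raw.get("write_rasters", True)),
        )


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a YAML mapping")
    return PipelineConfig.from_dict(raw)


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # output location does not affect results
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _thin_sorted(values: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic even thinning of sorted values down to <= cap points."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size <= cap:
        return v
    idx = np.linspace(0, v.size - 1, cap).round().astype(int)
    return v[idx]


def build_scenario(config: PipelineConfig) -> synthetic_data.SyntheticScenario:
    params = dict(config.scenario)
    params.setdefault("seed", config.seed)
    if "shape" in params:
        params["shape"] = tuple(params["shape"])
    if "years" in params:
        params["years"] = tuple(params["years"])
    return synthetic_data.SyntheticScenario(**params)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full chain and return (and write) the manifest."""
    t_start = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    scenario = build_scenario(config)
    manifest: dict[str, Any] = {
        "schema_version": _SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "years": list(scenario.years),
        "stages": {},
    }

    def stage(name: str, payload: dict[str, Any]) -> None:
        manifest["stages"][name] = payload
        logger.info("stage %-12s %s", name, json.dumps(payload, default=str)[:200])

    # 1. synthetic data ---------------------------------------------------
    region = synthetic_data.make_study_region(scenario)
    stacks = {}
    truths = {}
    for year in scenario.years:
        stacks[year], truths[year] = synthetic_data.gen_indicator_stack(scenario, region, year)
    stage("simulate", {
        "shape": list(scenario.shape),
        "n_valid_cells": int((~region.urbanization.nodata_mask).sum()),
        "landform_shares": {
            name: float((region.landform.values[~region.landform.nodata_mask] == code).mean())
            for name, code in synthetic_data.LANDFORM_CODES.items()
        },
    })

    # 2. weights ----------------------------------------------------------
    norm_stacks = {year: indicators.normalize_stack(stacks[year]) for year in scenario.years}
    cap = int(config.weights.get("sample_cap", 50_000))
    sv_ex_idx = [i for i, s in enumerate(stacks[scenario.years[0]].specs)
                 if s.category != "hazard"]
    obs = indicators.sample_observations(list(stacks.values()), cap=cap)
    adequacy = indicators.kmo(obs[:, sv_ex_idx])
    weights = indicators.pca_weights(
        obs, stacks[scenario.years[0]].specs,
        retention=config.weights.get("retention", "eigenvalue_gt_1"),
        b_formula=config.weights.get("b_formula", "abs_over_sqrt"),
    )
    stage("weights", {
        "kmo": adequacy.kmo,
        "bartlett_chi2": adequacy.bartlett_chi2,
        "bartlett_df": adequacy.bartlett_df,
        "bartlett_p": adequacy.bartlett_p,
        "n_retained": weights.n_retained,
        "cumulative_variance_retained": float(weights.cumulative[weights.n_retained - 1]),
        "weights": weights.weights,
    })

    # 3. risk surfaces and classification ---------------------------------
    risk_maps = {}
    for year in scenario.years:
        ns = norm_stacks[year]
        h = ns["lst"]
        s = indicators.composite_score(ns, weights, "social_vulnerability")
        e = indicators.composite_score(ns, weights, "exposure")
        risk_maps[year] = risk_index.compute_hhr(h, s, e, year=year)

    mode = config.breaks.get("mode", "jenks")
    if mode == "jenks":
        baseline = risk_maps[scenario.years[0]].hhr.unmasked_values()
        sample = _thin_sorted(baseline, int(config.breaks.get("sample_cap", 4000)))
        thresholds = risk_index.jenks_breaks(sample, len(RISK_LEVELS))
    elif mode == "fixed":
        values = config.breaks.get("values") or risk_index.REFERENCE_BREAKS
        thresholds = tuple(float(v) for v in values)
    else:
        raise ValueError(f"unknown breaks mode {mode!r}")

    class_maps = {year: risk_index.classify(risk_maps[year], thresholds)
                  for year in scenario.years}
    proportions = {year: risk_index.area_proportions(class_maps[year])
                   for year in scenario.years}
    transitions = {}
    for y0, y1 in zip(scenario.years[:-1], scenario.years[1:]):
        acc = risk_index.transition_accounting(class_maps[y0], class_maps[y1])
        transitions[f"{y0}->{y1}"] = acc.counts.tolist()
    dominance = {year: risk_index.dominant_factor_subzones(risk_maps[year],
                                                           class_maps[year]).proportions
                 for year in scenario.years}
    stage("assess", {
        "thresholds": list(thresholds),
        "proportions": {str(y): p for y, p in proportions.items()},
        "transitions": transitions,
        "dominance": {str(y): d for y, d in dominance.items()},
    })

    # 4. hindcast validation and forecast ---------------------------------
    y0, y1, y2 = scenario.years[0], scenario.years[1], scenario.years[-1]
    sim_cfg = camarkov.SimulationConfig(
        iterations=int(config.simulation.get("iterations", 10)),
        filter_size=int(config.simulation.get("filter_size", 5)),
        seed=config.seed,
    )
    hindcast = camarkov.predict_pipeline(class_maps[y0], class_maps[y1], sim_cfg)
    report = validation.kappa(hindcast, class_maps[y2])
    robustness = {}
    if config.robustness_iterations:
        table = validation.robustness_sweep(class_maps[y0], class_maps[y1], class_maps[y2],
                                            config.robustness_iterations, sim_cfg)
        robustness = {int(r.iterations): float(r.kappa) for r in table.itertuples()}
    forecast = camarkov.predict_pipeline(class_maps[y1], class_maps[y2], sim_cfg)
    forecast_props = risk_index.area_proportions(forecast)
    stage("predict", {
        "hindcast_kappa": report.kappa,
        "hindcast_p": report.p_value,
        "robustness_kappa": robustness,
        "forecast_proportions": forecast_props,
    })

    # 5. artefacts ---------------------------------------------------------
    if config.write_rasters:
        for year in scenario.years:
            write_raster(risk_maps[year].hhr, os.path.join(config.out_dir, f"hhr_{year}.tif"))
            write_raster(class_maps[year].classes,
                         os.path.join(config.out_dir, f"classes_{year}.tif"))
        write_raster(forecast.classes, os.path.join(config.out_dir, "forecast_classes.tif"))

    manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
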