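"""YAML configuration for the pipeline stages.

The file has up to three sections — ``simulate``, ``score``, ``analyze``
— and every default stated by the scoring/simulation modules can be
overridden.  Unknown keys raise, so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import DEFAULT_TWEEDIE_POWER
from .model import FieldOfView
from .synthetic import CohortParams, NetworkParams


@dataclass(frozen=True)
class ScoreConfig:
    tie_break: str = "lower"            # quadrant-mode ties: lower|higher
    empty_quadrant: str = "skip"        # MFI empty quadrants: skip|zero
    de_backer_small_only: bool = True
    max_clips_per_time_point: int = 3


@dataclass(frozen=True)
class AnalyzeConfig:
    tweedie_power: float = DEFAULT_TWEEDIE_POWER
    interaction_threshold: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    simulate: CohortParams = field(default_factory=CohortParams)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)


def _build(cls, payload: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise KeyError(f"unknown {where} config keys: {sorted(unknown)}")
    return payload


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config; a missing path gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"simulate", "score", "analyze"}
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")

    sim_raw = dict(raw.get("simulate", {}))
    if "fov" in sim_raw:
        sim_raw["fov"] = FieldOfView(**sim_raw["fov"])
    if "network" in sim_raw:
        net = _build(NetworkParams, dict(sim_raw["network"]), "simulate.network")
        for key in ("flow_score_probs", "vessel_length_um", "diameter_um"):
            if key in net:
                net[key] = tuple(net[key])
        sim_raw["network"] = NetworkParams(**net)
    for key in ("arm_probs", "clips_per_time_probs"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    if "pass_rate_by_time" in sim_raw:
        sim_raw["pass_rate_by_time"] = {
            int(k): float(v) for k, v in sim_raw["pass_rate_by_time"].items()
        }
    simulate = CohortParams(**_build(CohortParams, sim_raw, "simulate"))
    score = ScoreConfig(**_build(ScoreConfig, dict(raw.get("score", {})),
                                 "score"))
    analyze = AnalyzeConfig(**_build(AnalyzeConfig,
                                     dict(raw.get("analyze", {})), "analyze"))
    return PipelineConfig(simulate=simulate, score=score, analyze=analyze)


__all__ = ["ScoreConfig", "AnalyzeConfig", "PipelineConfig", "load_config"]
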