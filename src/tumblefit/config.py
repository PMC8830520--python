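"""YAML configuration mirroring every package default.

A config file is a mapping with optional sections ``scenario``,
``filter``, ``policy``, ``optimizer``, ``termination`` and ``metrics``;
each key inside a section overrides the corresponding dataclass default.
Missing sections mean "all defaults".
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dynamics import EquationParams, FlowCondition, OblateGeometry
from .learner import OptimizerConfig, TerminationConfig
from .preprocess import FilterConfig
from .sampler import SamplingPolicy
from .synthetic import ScenarioSpec

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    """Typed view of one configuration file."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        self.raw = raw
        self.filter = FilterConfig(**raw.get("filter", {}))
        pol = dict(raw.get("policy", {}))
        for key in ("region_counts", "region_bounds"):
            if key in pol:
                pol[key] = tuple(pol[key])
        self.policy = SamplingPolicy(**pol)
        self.optimizer = OptimizerConfig(**raw.get("optimizer", {}))
        self.termination = TerminationConfig(**raw.get("termination", {}))
        self.stride = raw.get("stride", 0.25)
        self.metrics = dict(raw.get("metrics", {}))
        self.scenario = self._build_scenario(dict(raw.get("scenario", {})))

    @staticmethod
    def _build_scenario(sc: dict) -> ScenarioSpec:
        kwargs = {}
        flow = sc.pop("flow", {})
        if flow:
            kwargs["flow"] = FlowCondition(**flow)
        geom = sc.pop("geometry", {})
        if geom:
            kwargs["geometry"] = OblateGeometry(**geom)
        for key in ("true_params", "drift_rate"):
            block = sc.pop(key, {})
            if block:
                kwargs[key] = EquationParams(**block)
        kwargs.update(sc)
        return ScenarioSpec(**kwargs)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; a missing path gives the all-defaults config."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    return RunConfig(yaml.safe_load(text) or {})
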