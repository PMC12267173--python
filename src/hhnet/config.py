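"""Experiment configuration: YAML in, validated dataclasses out.

An empty file (or ``ExperimentConfig()``) is the full default experiment:
the reference parameter set (canonical HH membrane, g = 0.1 coupling,
-52 mV threshold, 1 ms chemical delay), the 100-neuron ring and hub
small-world topologies, the 60 sin(0.1 pi t) + 30 stimulus with and without
sigma = 20 Gaussian interference, 300 ms of RK4 at dt = 0.01 ms.  Unknown
keys are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .neuron import HHParams
from .simulation import SimConfig
from .stimulus import StimulusSpec
from .synapses import ConfigurationError, SynapseSpec

__all__ = ["ExperimentConfig", "TopologySpec", "parse_config", "ConfigurationError"]

log = logging.getLogger("hhnet")

#: Potassium conductance as printed in the source parameter table; it
#: suppresses firing entirely (see HHParams) and triggers a warning.
_SUSPECT_G_K = 360.0


@dataclass(frozen=True)
class TopologySpec:
    """Which graph to build: ring, hub small-world ('nw-hub') or probabilistic NW."""

    kind: str = "ring"
    n: int = 100
    hub: int = 1
    n_shortcuts: int = 24
    shortcut_targets: list[int] | None = None
    p: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ring", "nw-hub", "nw-p"):
            raise ConfigurationError(f"unknown topology kind {self.kind!r}")
        if self.n < 2:
            raise ConfigurationError(f"need at least 2 neurons, got {self.n}")

    def build(self, directed: bool):
        from . import topology

        if self.kind == "ring":
            return topology.build_ring(self.n, directed=directed)
        if self.kind == "nw-hub":
            return topology.build_nw_hub(
                self.n, hub=self.hub, k=self.n_shortcuts,
                directed=directed, targets=self.shortcut_targets,
            )
        return topology.build_nw_random(self.n, self.p, seed=self.seed, directed=directed)


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in section {where!r}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad value in section {where!r}: {exc}") from exc


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun the full comparative experiment."""

    hh: HHParams = field(default_factory=HHParams)
    synapse: SynapseSpec = field(default_factory=lambda: SynapseSpec(kind="RS"))
    topology: TopologySpec = field(default_factory=TopologySpec)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    pairs: list[list[int]] = field(
        default_factory=lambda: [[1, 25], [15, 30], [20, 35], [5, 45]]
    )
    burn_in_ms: float = 0.0
    noise_seeds: list[int] = field(default_factory=lambda: list(range(10)))
    out_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(_serializable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _serializable(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["synapse"]["kind"] = cfg.synapse.kind.value
    d["stimulus"]["waveform"] = cfg.stimulus.waveform.value
    return d


_SECTIONS = {
    "hh": HHParams,
    "synapse": SynapseSpec,
    "topology": TopologySpec,
    "stimulus": StimulusSpec,
    "sim": SimConfig,
}


def parse_config(source: str | Path | dict | None) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file path or a dict.

    Missing sections and keys fall back to the experiment defaults; unknown
    keys raise :class:`ConfigurationError`.  A potassium conductance of
    360 mS/cm^2 (the value printed in the source parameter table) is
    accepted but logged as firing-suppressing.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("top-level config must be a mapping")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, name)
    for name in ("pairs", "burn_in_ms", "noise_seeds", "out_dir"):
        if name in data:
            kwargs[name] = data.pop(name)
    if data:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(data)}")
    cfg = ExperimentConfig(**kwargs)
    if cfg.hh.g_k >= _SUSPECT_G_K:
        log.warning(
            "g_k=%.0f mS/cm^2 accepted, but a potassium conductance this large "
            "suppresses action-potential firing entirely", cfg.hh.g_k,
        )
    return cfg
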