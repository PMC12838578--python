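"""Run configuration: one YAML file mapped onto the library dataclasses.

The defaults reproduce the package's standard desk-scale study: a synthetic
cohort at 256 Hz with 22 channels, 0.5-40 Hz causal filtering, 2-s windows
at 1 Hz, the default student architecture, multi-teacher distillation, and
k-of-n alarm post-processing with SPH/SOP scoring.  Every stochastic
component derives its seed from the single top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alarms import AlarmPolicy
from .distill import LossWeights
from .metrics import EvalProtocol
from .pipeline import TrainBudget, demo_synth_config, demo_windowing
from .preprocess import FilterSpec, WindowingSpec
from .student import StudentConfig
from .synthetic import SynthConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 4
    mode: str = "multi"     # {multi, single_pred, single_det, none}
    synth: SynthConfig = field(default_factory=lambda: demo_synth_config(0))
    filter: FilterSpec = field(default_factory=FilterSpec)
    windowing: WindowingSpec = field(default_factory=demo_windowing)
    model: StudentConfig = field(default_factory=StudentConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    budget: TrainBudget = field(default_factory=TrainBudget)
    policy: AlarmPolicy = field(default_factory=lambda: AlarmPolicy(refractory=300.0))
    protocol: EvalProtocol = field(default_factory=lambda: EvalProtocol(sph=60.0, sop=300.0))


_SECTIONS = {
    "synth": SynthConfig,
    "filter": FilterSpec,
    "windowing": WindowingSpec,
    "model": StudentConfig,
    "weights": LossWeights,
    "budget": TrainBudget,
    "policy": AlarmPolicy,
    "protocol": EvalProtocol,
}

_TUPLE_FIELDS = {"seizure_schedule", "background_alpha_hz", "mbconv_out",
                 "notch_bands", "band"}


def _coerce(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name in _TUPLE_FIELDS and isinstance(v, list):
                v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
            kwargs[f.name] = v
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus dotted-key overrides
    (e.g. ``--set windowing.sop=600``)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    for item in overrides or []:
        key, _, value = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not of the form key=value")
        node = raw
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(value)

    cfg = RunConfig()
    for name, value in raw.items():
        if name in _SECTIONS:
            base = dataclasses.asdict(getattr(cfg, name))
            base.update(value or {})
            setattr(cfg, name, _coerce(_SECTIONS[name], base))
        elif name in ("seed", "n_subjects", "mode"):
            setattr(cfg, name, value)
        else:
            raise KeyError(f"unknown config section {name!r}")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration (for provenance)."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
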