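"""Declarative pipeline configuration.

A single YAML file drives the whole pipeline; unknown keys are rejected so a
typo cannot silently fall back to a default.  The master seed recorded here
(or overridden on the command line) is the only source of randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .bold_sim import ClinicalSimParams, SimParams
from .learning_analysis import AnalysisConfig
from .paradigm import DEFAULT_TR_S, N_DISCARD_OFFLINE, N_DISCARD_ONLINE

__all__ = ["ParadigmConfig", "StatsConfig", "PipelineConfig"]


@dataclass(frozen=True)
class ParadigmConfig:
    n_sessions: int = 8
    tr_s: float = DEFAULT_TR_S
    up_first: bool = False
    n_discard_online: int = N_DISCARD_ONLINE
    n_discard_offline: int = N_DISCARD_OFFLINE


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    gg_correction: bool = True
    response_frac: float = 0.5
    remission_cutoff: float = 10.0


@dataclass(frozen=True)
class PipelineConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    sim: SimParams = field(default_factory=SimParams)
    clinical_sim: ClinicalSimParams = field(default_factory=ClinicalSimParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_subjects: int = 6
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.sim, seed=seed)
        clin = dataclasses.replace(self.clinical_sim, seed=seed + 1)
        return dataclasses.replace(self, seed=seed, sim=sim, clinical_sim=clin)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short provenance hash of the canonical config serialization."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sections = {
            "paradigm": ParadigmConfig,
            "sim": SimParams,
            "clinical_sim": ClinicalSimParams,
            "analysis": AnalysisConfig,
            "stats": StatsConfig,
        }
        scalars = {"n_subjects", "seed"}
        unknown = set(raw) - set(sections) - scalars
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, typ in sections.items():
            sub = raw.get(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            allowed = {f.name for f in dataclasses.fields(typ)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
            kwargs[name] = typ(**sub)
        for key in scalars:
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)
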