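"""Run configuration: a flat, human-writable YAML mapping.

Every key is optional; omitted keys take the model defaults.  Unknown keys
are rejected rather than ignored, so typos cannot silently change a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ConfigurationError, DrugCondition, ModelParams

__all__ = ["RunConfig", "load_config", "dump_config"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_RUN_KEYS = {
    "drug_direction", "drug_dose", "probability", "probabilities",
    "etas", "n_acq", "n_acqs", "doses", "n_seeds", "seeds", "seed",
    "tolerance", "out_dir", "verbose",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one command invocation."""

    params: ModelParams = field(default_factory=ModelParams)
    condition: DrugCondition = field(default_factory=DrugCondition)
    probability: float = 0.5
    probabilities: tuple = (0.25, 0.5, 0.75, 1.0)
    etas: tuple = (0.91, 0.93, 0.95, 0.97, 0.99)
    n_acq: int = 30
    n_acqs: tuple = (10, 30, 100)
    doses: tuple = (0.0, 0.05, 0.1)
    n_seeds: int = 20
    seeds: tuple | None = None
    seed: int = 0
    tolerance: float = 0.5
    out_dir: str = "out"
    verbose: bool = False

    @property
    def seed_list(self) -> list:
        if self.seeds is not None:
            return [int(s) for s in self.seeds]
        return [self.seed + i for i in range(self.n_seeds)]

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update({
            "drug_direction": self.condition.direction,
            "drug_dose": self.condition.dose,
            "probability": self.probability,
            "probabilities": list(self.probabilities),
            "etas": list(self.etas),
            "n_acq": self.n_acq,
            "n_acqs": list(self.n_acqs),
            "doses": list(self.doses),
            "n_seeds": self.n_seeds,
            "seeds": list(self.seeds) if self.seeds is not None else None,
            "seed": self.seed,
            "tolerance": self.tolerance,
            "out_dir": self.out_dir,
            "verbose": self.verbose,
        })
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _config_from_mapping(doc: dict) -> RunConfig:
    unknown = set(doc) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    try:
        params = ModelParams(**{k: doc[k] for k in _PARAM_KEYS if k in doc})
        condition = DrugCondition(
            direction=doc.get("drug_direction", "none"),
            dose=float(doc.get("drug_dose", 0.0)))
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc
    kwargs: dict = {"params": params, "condition": condition}
    for key in ("probability", "n_acq", "n_seeds", "seed", "tolerance",
                "out_dir", "verbose"):
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("probabilities", "etas", "n_acqs", "doses", "seeds"):
        if key in doc and doc[key] is not None:
            kwargs[key] = tuple(doc[key])
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    doc = yaml.safe_load(p.read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config must be a flat key-value mapping")
    return _config_from_mapping(doc)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
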