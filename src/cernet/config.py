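"""Pipeline configuration: thresholds, modes, input paths, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import DEFAULT_CONDITIONS, DEFAULT_TISSUES
from .errors import ConfigurationError
from .simulate import SimulationConfig


@dataclass
class Thresholds:
    """Every printed decision threshold of the screen, as a default."""

    scc_threshold: float = -0.7
    pcc_threshold: float = 0.9
    sponge_alpha: float = 0.05
    fc_threshold: float = 2.0
    de_alpha: float = 0.05
    mrna_fdr: float = 0.05
    pseudocount: float = 1.0

    def validate(self) -> None:
        if not -1.0 <= self.scc_threshold <= 1.0:
            raise ConfigurationError("scc_threshold must lie in [-1, 1]")
        if not -1.0 <= self.pcc_threshold <= 1.0:
            raise ConfigurationError("pcc_threshold must lie in [-1, 1]")
        for name in ("sponge_alpha", "de_alpha", "mrna_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.fc_threshold < 1.0:
            raise ConfigurationError("fc_threshold must be >= 1")
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")


@dataclass
class InputPaths:
    """Paths to externally supplied inputs (all TSV)."""

    counts: dict[str, dict[str, str]] = field(default_factory=dict)  # class -> tissue -> path
    metadata: str = ""
    interactions: str = ""


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``simulate`` (generate inputs) or ``inputs`` (read
    them) must be set.
    """

    seed: int = 0
    outdir: str = "cernet_out"
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    replicates: int = 3
    simulate: SimulationConfig | None = None
    inputs: InputPaths | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    universe_mode: str = "interactions_de"
    correlation_pooling: str = "pooled"
    sponge_bh: bool = False

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of 'simulate' or 'inputs' must be set")
        if self.universe_mode not in ("interactions_de", "interactions_all", "profiled"):
            raise ConfigurationError(f"unknown universe_mode {self.universe_mode!r}")
        if self.correlation_pooling not in ("pooled", "within_condition"):
            raise ConfigurationError(
                f"unknown correlation_pooling {self.correlation_pooling!r}"
            )
        self.thresholds.validate()
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        _reject_unknown(d, {f for f in cls.__dataclass_fields__})
        if "thresholds" in d and d["thresholds"] is not None:
            _reject_unknown(d["thresholds"], set(Thresholds.__dataclass_fields__))
            d["thresholds"] = Thresholds(**d["thresholds"])
        if d.get("simulate") is not None:
            _reject_unknown(d["simulate"], set(SimulationConfig.__dataclass_fields__))
            d["simulate"] = SimulationConfig(**d["simulate"])
        if d.get("inputs") is not None:
            _reject_unknown(d["inputs"], set(InputPaths.__dataclass_fields__))
            d["inputs"] = InputPaths(**d["inputs"])
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _reject_unknown(d: dict, allowed: set[str]) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
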