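"""Configuration objects for the simulator and the end-to-end pipeline.

All randomness in a run flows from a single integer seed.  Stages derive
independent substreams with :func:`substream_seed`, so each stage is
reproducible in isolation and the whole run is byte-identical on re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["SimulationConfig", "RunConfig", "ConfigError", "substream_seed"]

#: canonical stage order used to derive per-stage random substreams
STAGES = ("references", "counts", "reads", "gmt")


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def substream_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive the named stage's independent seed sequence from the run seed."""
    if stage not in STAGES:
        raise ConfigError(f"unknown random substream {stage!r}")
    return np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic hybrid transcriptome.

    Defaults describe a horse x donkey-like design at desk scale: two
    parental transcript sets diverged by point substitutions, two cell
    conditions (fibroblast-like and iPSC-like) with replicated samples,
    a differentially expressed gene subset and an allelically biased
    gene subset.
    """

    n_genes: int = 200
    transcript_length_range: tuple[int, int] = (500, 1500)
    divergence_rate: float = 0.01
    n_conditions: int = 2
    n_replicates_per_condition: int = 3
    baseline_mean_log2: float = 8.0
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    bias_fraction: float = 0.2
    biased_allelic_ratio: float = 0.8
    nb_dispersion: float = 0.2
    read_length: int = 100
    reads_per_sample: int = 50_000
    error_rate: float = 0.0
    seed: int = 0
    condition_names: tuple[str, ...] = ("fibroblast", "iPSC")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be a positive integer")
        lo, hi = self.transcript_length_range
        if lo < 1 or hi < lo:
            raise ConfigError("transcript_length_range must be a (low, high) pair of positive integers with low <= high")
        for name in ("divergence_rate", "de_fraction", "bias_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.biased_allelic_ratio < 1.0:
            raise ConfigError("biased_allelic_ratio must lie in the open interval (0, 1)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_conditions < 1:
            raise ConfigError("n_conditions must be >= 1")
        if len(self.condition_names) < self.n_conditions:
            raise ConfigError("condition_names must name every condition")
        if self.n_replicates_per_condition < 1:
            raise ConfigError("n_replicates_per_condition must be a positive integer")
        if self.read_length < 1:
            raise ConfigError("read_length must be a positive integer")
        if self.read_length > lo:
            raise ConfigError("read_length must not exceed the transcript_length_range lower bound")
        if self.reads_per_sample < 0:
            raise ConfigError("reads_per_sample must be >= 0")
        if self.de_log2fc <= 0:
            raise ConfigError("de_log2fc must be positive")

    @property
    def sample_ids(self) -> list[str]:
        """Ordered sample identifiers, `<condition>_<replicate>`."""
        return [
            f"{self.condition_names[c]}_{r + 1}"
            for c in range(self.n_conditions)
            for r in range(self.n_replicates_per_condition)
        ]

    @property
    def sample_conditions(self) -> list[str]:
        return [
            self.condition_names[c]
            for c in range(self.n_conditions)
            for _ in range(self.n_replicates_per_condition)
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transcript_length_range"] = list(self.transcript_length_range)
        d["condition_names"] = list(self.condition_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "transcript_length_range" in d:
            d["transcript_length_range"] = tuple(d["transcript_length_range"])
        if "condition_names" in d:
            d["condition_names"] = tuple(d["condition_names"])
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration.

    In synthetic mode (the default) ``simulation`` generates all inputs;
    in real mode ``ref1/ref2/homologs/reads`` point at existing files.
    """

    outdir: str = "hybridase_run"
    seed: int = 0
    log2fc_threshold: float = 1.0
    alpha: float = 0.05
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ref1: str | None = None
    ref2: str | None = None
    homologs: str | None = None
    reads: dict[str, str] | None = None  # sample_id -> fastq path (real mode)
    conditions: dict[str, str] | None = None  # sample_id -> condition (real mode)

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ConfigError("log2fc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if self.real_mode:
            for name in ("ref1", "ref2", "homologs", "reads", "conditions"):
                if getattr(self, name) is None:
                    raise ConfigError(f"real mode requires {name}")

    @property
    def real_mode(self) -> bool:
        return any(x is not None for x in (self.ref1, self.ref2, self.homologs, self.reads))

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "log2fc_threshold": self.log2fc_threshold,
            "alpha": self.alpha,
            "simulation": self.simulation.to_dict(),
            "ref1": self.ref1,
            "ref2": self.ref2,
            "homologs": self.homologs,
            "reads": self.reads,
            "conditions": self.conditions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)
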