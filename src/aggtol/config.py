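"""Flat sectioned key=value configuration for the pipeline.

Every analysis threshold is a named key defaulting to the value used in the
comparative study: similarity 60%, gaps 20%, protein-length cap 10,000 AA,
|z| > 2 classification, ±1 mutational hotspot thresholds, and a 5-protein
minimum for enrichment terms.
"""
from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class PredictorConfig:
    kind: str = "surrogate"  # surrogate | file
    scale_name: str = "kyte_doolittle"
    window: int = 5
    theta: float = 2.0
    score_dir: str = ""
    score_dialect: str = "simple"


@dataclass
class QCConfig:
    min_similarity: float = 60.0
    max_gaps: float = 20.0
    max_length: int = 10_000


@dataclass
class MutagenesisConfig:
    denominator: str = "distinct"  # distinct | events
    genetic_code: int = 1


@dataclass
class ClassifyConfig:
    z_threshold: float = 2.0


@dataclass
class ProfileConfig:
    detrimental_threshold: float = 1.0
    beneficial_threshold: float = -1.0


@dataclass
class EnrichmentConfig:
    min_proteins: int = 5
    fdr: float = 0.05


@dataclass
class PipelineConfig:
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    mutagenesis: MutagenesisConfig = field(default_factory=MutagenesisConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.predictor.kind not in {"surrogate", "file"}:
            raise ValueError(f"predictor.kind must be surrogate or file, got {self.predictor.kind!r}")
        if self.predictor.kind == "file" and not self.predictor.score_dir:
            raise ValueError("predictor.kind=file requires predictor.score_dir")
        if self.predictor.window < 1 or self.predictor.window % 2 == 0:
            raise ValueError("predictor.window must be an odd integer >= 1")
        if self.mutagenesis.denominator not in {"distinct", "events"}:
            raise ValueError("mutagenesis.denominator must be distinct or events")
        if self.classify.z_threshold <= 0:
            raise ValueError("classify.z_threshold must be positive")
        if not self.profiles.beneficial_threshold < self.profiles.detrimental_threshold:
            raise ValueError("beneficial threshold must be below detrimental threshold")
        if self.enrichment.min_proteins < 0:
            raise ValueError("enrichment.min_proteins must be non-negative")

    def snapshot(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "predictor": PredictorConfig,
    "qc": QCConfig,
    "mutagenesis": MutagenesisConfig,
    "classify": ClassifyConfig,
    "profiles": ProfileConfig,
    "enrichment": EnrichmentConfig,
}


def load_config(path=None) -> PipelineConfig:
    """Read an INI-style config; absent keys keep their defaults."""
    config = PipelineConfig()
    if path is None:
        return config
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    for section, cls in _SECTIONS.items():
        if not parser.has_section(section):
            continue
        target = getattr(config, section)
        for key, raw in parser.items(section):
            if not hasattr(target, key):
                raise ValueError(f"unknown config key [{section}] {key}")
            current = getattr(target, key)
            if isinstance(current, bool):
                value: object = raw.strip().lower() in {"1", "true", "yes"}
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(target, key, value)
    if parser.has_section("run") and parser.has_option("run", "seed"):
        config.seed = parser.getint("run", "seed")
    config.validate()
    return config


def write_config(config: PipelineConfig, path) -> None:
    parser = configparser.ConfigParser()
    for section in _SECTIONS:
        parser[section] = {
            k: str(v) for k, v in asdict(getattr(config, section)).items()
        }
    parser["run"] = {"seed": str(config.seed)}
    with open(path, "w") as fh:
        parser.write(fh)
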