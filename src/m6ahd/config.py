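"""Run configuration schema, run manifest and logging setup.

One YAML file configures a run; unknown keys are rejected and every
default is filled in explicitly so the effective configuration can be
echoed back verbatim. All randomness in a run flows from the single
top-level ``seed`` through documented per-stage derivations recorded in
the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .encoders import SCHEMES

__all__ = ["SimSection", "StagesSection", "Config", "RunManifest",
           "load_config", "dump_config", "setup_logging"]


def setup_logging(level=logging.INFO) -> logging.Logger:
    logger = logging.getLogger("m6ahd")
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)
    return logger


class SimSection(BaseModel):
    """Synthetic-bundle parameters (see simulate.SimConfig)."""

    model_config = ConfigDict(extra="forbid")

    n_transcripts: int = 250
    transcript_length: int = 2000
    gc_content: float = 0.5
    motif: str = "RRACH"
    site_rate: int = 10
    base_methyl_rate: float = 0.5
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    peak_halfwidth: int = 50
    n_conditions: int = 5
    signal_bias: float = 0.85
    signal_halfwidth: int = 8


class StagesSection(BaseModel):
    """Optional model-selection stages for run-all (each adds many fits)."""

    model_config = ConfigDict(extra="forbid")

    scan_windows: bool = False
    search_features: bool = False
    compare_algorithms: bool = False
    tune_rf: bool = False


class Config(BaseModel):
    """Validated run configuration with explicit defaults."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    window_length: int = 41
    n_per_class: int = 1000
    train_frac: float = 0.8
    negative_mode: Literal["definitional", "unmethylated"] = "definitional"
    center_check: bool = True
    schemes: list = Field(default_factory=lambda: list(SCHEMES))
    psednc_lambda: int = 3
    psednc_w: float = 0.05
    algorithm: Literal["RF", "SVM", "GLM", "GBT"] = "RF"
    ntree: int = 500
    mtry: Optional[int] = None
    threshold: float = 0.5
    window_lengths: list = Field(default_factory=lambda: [21, 31, 41, 51, 61, 71, 81])
    ntree_grid: list = Field(default_factory=lambda: list(range(200, 1401, 100)))
    mtry_grid: list = Field(default_factory=lambda: list(range(50, 101)))
    sim: SimSection = Field(default_factory=SimSection)
    stages: StagesSection = Field(default_factory=StagesSection)

    @field_validator("window_length")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("window_length must be odd")
        return v

    @field_validator("window_lengths")
    @classmethod
    def _all_odd(cls, v):
        if any(x % 2 == 0 for x in v):
            raise ValueError("window_lengths must all be odd")
        return v

    @field_validator("train_frac")
    @classmethod
    def _frac(cls, v):
        if not (0 < v < 1):
            raise ValueError("train_frac must be in (0, 1)")
        return v

    @field_validator("schemes")
    @classmethod
    def _schemes(cls, v):
        unknown = set(v) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")
        if not v:
            raise ValueError("schemes must be nonempty")
        return v


def load_config(path) -> Config:
    """Load and validate a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return Config(**(data or {}))


def dump_config(cfg: Config, path=None) -> str:
    """Serialize the effective configuration (all defaults resolved)."""
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(cfg: Config) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class RunManifest(BaseModel):
    """Machine-readable record of one run."""

    tool_version: str = ""
    config_hash: str = ""
    seeds: dict = Field(default_factory=dict)
    input_checksums: dict = Field(default_factory=dict)
    chosen_settings: dict = Field(default_factory=dict)
    stages_completed: list = Field(default_factory=list)
    failed_stage: Optional[str] = None
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, cfg: Config) -> "RunManifest":
        return cls(
            tool_version=__version__,
            config_hash=config_hash(cfg),
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def finish(self) -> "RunManifest":
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
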