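"""Serializable run configuration shared by the CLI commands."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantify import SegmentationConfig


@dataclass
class StatsOptions:
    test_variant: str = "student"  # or "welch"
    dunnett: str = "auto"  # "auto" | "never"
    seed: int = 0


@dataclass
class IOOptions:
    channel_map: dict = field(default_factory=lambda: {"dapi": 0, "actin": 1})
    roi_dialect: str = "json"  # preferred dialect when writing


@dataclass
class RunConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    io: IOOptions = field(default_factory=IOOptions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "segmentation" in data:
            cfg.segmentation = SegmentationConfig(**data["segmentation"])
        if "stats" in data:
            cfg.stats = StatsOptions(**data["stats"])
        if "io" in data:
            cfg.io = IOOptions(**data["io"])
        cfg.segmentation.validate()
        return cfg
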