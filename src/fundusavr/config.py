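"""Pipeline configuration: the fixed constants of the measurement protocol
plus the knobs the protocol leaves open, loadable from a YAML file."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import SchemaError

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All result-affecting settings; every value is echoed into output metadata.

    Defaults encode the measurement protocol: 16 fps capture, 25 trace points
    on either side of the seed, the 15 mmHg regression split, the 20 mmHg
    pathology boundary and the 0.8015 A/V cut-off.
    """

    fps: int = 16
    q_min: float = 50.0                 # quality gate on the 0-100 score
    is_fundus_threshold: float = 0.5
    n_side: int = 25
    step_px: float = 2.0
    profile_halfwidth_px: float = 12.0
    min_ok_points: int = 13             # >= 25% of the 51 sampling locations
    epoch_seconds: float = 60.0
    cutoff: float = 0.8015
    icp_split: float = 15.0
    boundary: float = 20.0
    seed: int = 0
    n_bootstrap: int = 2000

    def validate(self) -> None:
        checks = [
            ("fps", self.fps >= 1),
            ("q_min", 0.0 <= self.q_min <= 100.0),
            ("is_fundus_threshold", 0.0 <= self.is_fundus_threshold <= 1.0),
            ("n_side", self.n_side >= 1),
            ("step_px", self.step_px > 0),
            ("profile_halfwidth_px", self.profile_halfwidth_px >= 2),
            ("min_ok_points", self.min_ok_points >= 1),
            ("epoch_seconds", self.epoch_seconds > 0),
            ("cutoff", self.cutoff > 0),
            ("boundary", self.boundary > self.icp_split),
            ("n_bootstrap", self.n_bootstrap >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise SchemaError(f"config field {name!r} is out of range "
                                  f"(value {getattr(self, name)!r})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys are rejected, not ignored.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise SchemaError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg
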