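"""Run configuration: a small validated key-value file with CLI overrides."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Effective pipeline parameters.

    Thresholds mirror the signal-feature defaults; ``icc_form`` and
    ``loa_multiplier`` control the agreement analysis; ``seed`` feeds the
    simulator.  Unknown keys in a config file are rejected rather than
    silently ignored.
    """

    target_hz: float = 30.0
    theta_sit_deg: float = 45.0
    s_move_g: float = 0.1
    theta_lying_deg: float = 65.0
    sd_max_g: float = 0.5
    icc_form: str = "single"
    loa_multiplier: float = 1.96
    min_paired_nights: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.icc_form not in ("single", "average"):
            raise ValueError(f"icc_form must be single or average, got {self.icc_form!r}")
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be positive")
        if self.target_hz <= 0:
            raise ValueError("target_hz must be positive")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML key-value config file, applying keyword overrides on top."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
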