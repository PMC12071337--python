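"""Pipeline configuration: one document holding every tunable.

Loaded from YAML or JSON; unknown keys are rejected with a message naming
the field, and invalid values raise :class:`ConfigError` naming the field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    dt: float = 5e-5
    noise_mv: float = 0.3
    noise_pa: float = 2.0
    n_scale: float = 1.0
    # piezo protocol used for cohort generation (20 steps cover all groups'
    # displacement thresholds; the acquisition default is 10)
    n_steps: int = 20
    step_um: float = 1.5
    hold_ms: float = 300.0
    inter_step_s: float = 10.0
    # classifier cutoffs
    db_cut_ms: float = 4.0
    ahp80_slow_ms: float = 20.0
    ahp80_fast_ms: float = 5.0
    ahp_small_mv: float = 5.0
    # statistics
    posthoc: str = "tukey"
    # immunohistochemistry simulation
    ihc_cells_per_section: int = 400
    ihc_sections: int = 9
    ihc_replicates: int = 3

    def validate(self) -> "PipelineConfig":
        checks = {
            "dt": self.dt > 0,
            "noise_mv": self.noise_mv >= 0,
            "noise_pa": self.noise_pa >= 0,
            "n_scale": self.n_scale >= 0,
            "n_steps": self.n_steps >= 1,
            "step_um": self.step_um > 0,
            "hold_ms": self.hold_ms > 0,
            "posthoc": self.posthoc in ("tukey", "bonferroni"),
            "ihc_cells_per_section": self.ihc_cells_per_section > 0,
            "ihc_sections": self.ihc_sections > 0,
            "ihc_replicates": self.ihc_replicates > 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigError(
                f"invalid config field(s): {', '.join(bad)} "
                f"(values: {[getattr(self, k) for k in bad]})"
            )
        return self

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls().__dict__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full configuration, for output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
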