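"""Run configuration: one YAML file drives the whole pipeline.

Every stochastic stage derives its seed deterministically from the master
seed, so a config file fully determines every artifact a run produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "derive_seed", "ConfigError"]


class ConfigError(ValueError):
    """A named validation error for a bad or missing config section."""


_SECTIONS = ("stimulus", "periphery", "cohort", "analysis", "stats")


def _default_sections() -> dict:
    return {
        "stimulus": {
            "n_tones": 20,
            "f_lo_hz": 200.0,
            "f_hi_hz": 8000.0,
            "per_tone_level_db": 60.0,
            "band_lo_hz": 4.0,
            "band_hi_hz": 24.0,
            "trial_duration_s": 4.0,
            "isi_lo_s": 1.2,
            "isi_hi_s": 1.3,
            "trials_per_condition": 240,
            "audio_rate_hz": 48000.0,
            "conditions": [6, 12, 18],
        },
        "periphery": {"bandwidth_erb": 1.0, "order": 4, "n_validate_trials": 3},
        "cohort": {
            "n_td": 26,
            "n_asd": 21,
            "trials_per_condition": 60,
            "sample_rate_hz": 1000.0,
            "epoch_window_s": [-0.5, 1.0],
        },
        "analysis": {"window_s": 0.2, "nw": 2.0, "n_tapers": 3},
        "stats": {"n_repeats": 50, "test_fraction": 0.10, "svm_c": 1.0},
    }


@dataclass
class RunConfig:
    """Structured configuration with stage sections and a master seed."""

    sections: dict = field(default_factory=_default_sections)
    master_seed: int = 0
    out_dir: str = "runs/run0"
    desk_scale: bool = True

    def __post_init__(self):
        missing = [s for s in _SECTIONS if s not in self.sections]
        if missing:
            raise ConfigError(f"missing config section(s): {', '.join(missing)}")
        if not self.desk_scale:
            self.sections["cohort"]["trials_per_condition"] = 240

    def __getitem__(self, section: str) -> dict:
        try:
            return self.sections[section]
        except KeyError:
            raise ConfigError(f"missing config section: {section}") from None

    def stage_seed(self, stage: str, extra: int = 0) -> int:
        return derive_seed(self.master_seed, stage, extra)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "master_seed": self.master_seed,
            "out_dir": self.out_dir,
            "desk_scale": self.desk_scale,
            "sections": self.sections,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "sections" not in raw:
            raise ConfigError("config file must contain a 'sections' mapping")
        return cls(
            sections=raw["sections"],
            master_seed=int(raw.get("master_seed", 0)),
            out_dir=str(raw.get("out_dir", "runs/run0")),
            desk_scale=bool(raw.get("desk_scale", True)),
        )


def derive_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed below 2**31, stable across sessions."""
    tag = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
    ss = np.random.SeedSequence([int(master_seed), tag % (2**31 - 1), int(extra)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
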