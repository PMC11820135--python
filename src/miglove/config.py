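"""YAML run configuration shared by the CLI subcommands.

A run config nests one block per pipeline stage (synthetic, preprocessing,
model, controller, evaluation) plus a global seed and output directory; the
effective config is written next to a run's outputs so every run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs",
    "synthetic": {
        "effect_size": 0.5,
        "noise_scale": 5.0,
        "rest_alpha_gain": 1.0,
        "fs": 125.0,
        "montage": None,
        "n_subjects": 1,
        "phase_duration_s": 16.0,
        "n_trials_per_session": 6,
        "n_sessions": 3,
        "format": "csv",
    },
    "preprocessing": {
        "band_low": 0.5,
        "band_high": 45.0,
        "notch_freq": 60.0,
        "filter_order": 4,
        "notch_q": 30.0,
        "trim_s": 3.0,
        "epoch_length_s": 1.0,
        "overlap_s": 0.75,
        "split_group": "trial",
        "test_fraction": 0.25,
    },
    "model": {
        "gamma": 2.0,
        "learning_rate": 1e-3,
        "batch_size": 32,
        "max_epochs": 100,
        "patience": 10,
        "symmetric_blocks": False,
    },
    "controller": {
        "P_max": 50.0,
        "P_min": 0.0,
        "delta_P": 5.0,
        "gain": 2.0,
        "leak_rate": 0.05,
        "sensor_noise_sd": 0.0,
        "rest_behavior": "hold",
    },
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    synthetic: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    controller: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _merge(base: dict, override: dict, context: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        where = f"{context}.{key}" if context else key
        if key not in base:
            raise KeyError(f"unknown config key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise KeyError(f"config key {where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config on top of the defaults; unknown keys are errors."""
    merged = dict(_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise KeyError(f"{path}: top level must be a mapping")
        merged = _merge(merged, user)
    if overrides:
        merged = _merge(merged, overrides)
    return RunConfig(
        seed=int(merged["seed"]),
        out_dir=str(merged["out_dir"]),
        synthetic=merged["synthetic"],
        preprocessing=merged["preprocessing"],
        model=merged["model"],
        controller=merged["controller"],
    )
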