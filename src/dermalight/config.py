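"""Run configuration: defaults, YAML config files, and run logs.

Precedence is defaults < config file < command-line flags.  Every run that
writes artifacts also writes ``run_config.yaml`` recording the fully
resolved configuration and the package version, so a run can be reproduced
bit-for-bit from its own log (deterministic stages only need the seed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "n_fish": 3,
    "cells_per_fish_per_type": 20,
    "grid_lo_nm": 400.0,
    "grid_hi_nm": 700.0,
    "grid_step_nm": 0.3,
    "reference_mean_counts": 20000.0,
    "noise_cv": 0.03,
    "noise_model": "gaussian",
    "jitter_sigma": 0.1,
    "anchor_lambda_max_nm": 415.0,
    "smooth_window_nm": 5.0,
    "min_slope": 0.2,
    "mixing_mode": "areal",
    "dispersion_steps": 11,
}


def load_config_file(path: Union[str, Path, None]) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw


def resolve(
    file_config: Mapping[str, Any],
    flag_overrides: Mapping[str, Any],
) -> dict[str, Any]:
    """Merge defaults < file < flags; flags set to None are 'not given'."""
    merged = dict(DEFAULTS)
    merged.update(file_config)
    merged.update({k: v for k, v in flag_overrides.items() if v is not None})
    return merged


def write_run_log(
    out_dir: Union[str, Path],
    subcommand: str,
    config: Mapping[str, Any],
) -> None:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "dermalight",
        "version": __version__,
        "subcommand": subcommand,
        "config": dict(config),
    }
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
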