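"""Pipeline configuration: YAML in, resolved YAML back out.

A configuration is a nested mapping mirroring the stage parameters.
Unknown sections or keys are rejected (typos should fail loudly), and
every CLI run writes the fully resolved configuration next to its
outputs so results are reproducible from the persisted file alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "smrloop_out",
    "channels": {
        "center": "C3",
        "neighbors": ["F3", "P3", "T7", "Cz"],
    },
    "replay": {
        "band": [3.0, 70.0],
        "filter_order": 3,
        "notch": 50.0,
        "buffer_s": 5.0,
        "window_s": 1.0,
        "tick_s": 0.1,
        "smoothing": 10,
        "n_frames": 20,
        "smr_mode": "foi",
    },
    "spectral": {
        "fit_range": [2.0, 40.0],
        "max_peaks": 6,
        "min_peak_height": 0.05,
        "peak_threshold": 2.0,
        "bandwidth_bounds": [0.5, 8.0],
        "welch_segment_s": 2.0,
    },
    "sep": {
        "highpass": 3.0,
        "lowpass": 500.0,
        "latencies_ms": {"N9": 9.0, "N13": 13.0, "N20": 20.0},
        "search_ms": 3.0,
    },
    "behavior": {
        "bounds_lower": [0.0, 0.0, 0.0],
        "bounds_upper": [1.5, 10.0, 1.0],
        "b_starts": [0.1, 0.5, 1.0, 2.0],
    },
    "stats": {
        "threshold_p": 1.0e-4,
        "n_permutations": 1000,
        "alpha": 0.05,
    },
    "simulate": {
        "eeg_trials": 20,
        "erd_depth": 0.3,
        "iaf": 10.0,
        "sep_stimuli": 1000,
        "behavior_b": 0.8,
        "n_per_group": 10,
    },
}


def _check_keys(user: dict, ref: dict, prefix: str = "") -> None:
    for key, value in user.items():
        if key not in ref:
            raise KeyError(f"unknown configuration key {prefix + str(key)!r}")
        if isinstance(ref[key], dict) and isinstance(value, dict):
            _check_keys(value, ref[key], prefix=f"{prefix}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over defaults; unknown keys raise."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("configuration must be a mapping")
    _check_keys(user, DEFAULTS)
    return _merge(DEFAULTS, user)


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
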