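"""Pipeline configuration: schema, defaults, YAML round-trip, hashing.

The configuration is a nested mapping mirroring the pipeline stages.  It is
validated strictly — unknown keys are rejected — and the effective (fully
defaulted) configuration plus its hash are echoed into every output artifact
so reruns are reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml


class ConfigError(Exception):
    """The configuration is malformed or holds unknown keys."""


def default_config() -> dict:
    """The bundled default pipeline configuration: a small three-layer
    transverse phantom imaged at 0°/±45°."""
    return {
        "seed": 0,
        "tilts_deg": [0.0, 45.0, -45.0],
        "synth": {
            "grid": [64, 64],
            "detector": [128, 128],
            "recip_pixel_inv_A": 0.005,
            "step_nm": 100.0,
            "geometry": "annular",
            "lumen_radius_px": 10.0,
            "layer_thickness_px": 6.5,
            "layers": [
                {"in_plane_deg": 33.0, "out_of_plane_deg": 56.0},
                {"in_plane_deg": 47.0, "out_of_plane_deg": -61.0},
                {"in_plane_deg": 27.0, "out_of_plane_deg": 60.0},
            ],
            "noise": {
                "azimuth_sigma_deg": 0.0,
                "background_level": 2.0,
                "peak_snr": 30.0,
            },
        },
        "ring": {
            "radius_inv_A": 0.258,
            "detector_box_inv_A": 0.04,
            "n_detectors": 360,
            "quality_threshold": 0.05,
        },
        "align": {
            "refine": False,
            "correlation_floor": 0.2,
        },
        "reconstruct": {
            "tol": 1.0e-10,
            "max_iter": 1000,
            "eigen_gap_tol": 0.05,
        },
        "analysis": {
            "positive_theta_is": "left",
            "label_erosion_px": 1,
        },
        "viz": {
            "hue_offset_deg": 0.0,
            "lightness_positive_y": 0.65,
            "lightness_negative_y": 0.35,
            "glyph_stride": 2,
        },
    }


def _merge_validate(defaults, given, path=""):
    if not isinstance(given, dict):
        raise ConfigError(f"section '{path or '<root>'}' must be a mapping")
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key '{path}{key}'")
        if isinstance(defaults[key], dict):
            out[key] = _merge_validate(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML config, merged over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        # layer lists replace wholesale rather than merging per-entry
        cfg = _merge_validate(cfg, user)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
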