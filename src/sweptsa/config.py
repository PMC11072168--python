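"""YAML experiment configuration.

Config files use clinical units (mm, µs, degrees, MHz are spelled out as Hz)
and are converted to the SI quantities the library uses.  Any omitted block
falls back to the package defaults, which mirror the simulation study.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .acquisition import ArraySpec, make_sequence, make_trajectory

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash", "build_spec", "build_sequence", "build_trajectory"]

DEFAULT_CONFIG: dict = {
    "array": {
        "n_elements": 64,
        "pitch_mm": 0.3,
        "f0_hz": 3.0e6,
        "bandwidth": 0.8,
        "c_mps": 1540.0,
    },
    "sequence": {
        "mode": "left_right",
        "frame_rate_hz": 500.0,
        "spacing_us": 260.0,
        "subaperture": 11,
        "f_number": -0.75,
    },
    "trajectory": {"extent_mm": 50.0, "duration_s": 1.0, "profile": "constant"},
    "phantom": {
        "lateral_mm": [-13.0, 63.0],
        "depth_mm": [13.0, 27.0],
        "density_per_cell": 15.0,
        "lesions": [],
        "points": [],
        "seed": 0,
    },
    "estimation": {
        "method": "channel",
        "kernel_depth_mm": 20.0,
        "kernel_axial_mm": 10.0,
        "kernel_lateral_mm": 10.0,
        "search_mm": 2.5,
        "max_shift_elements": 10,
        "max_lag_frames": 10,
        "subsample": "iterative",
    },
    "beamforming": {
        "taper": 0.25,
        "resample_mm": 0.5,
        "f_number_rx": 1.5,
        "n_reference_angles": 91,
    },
    "metrics": {"dynamic_range_db": 50.0, "gcnr_bins": 256},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the defaults (None = pure defaults)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def build_spec(cfg: dict) -> ArraySpec:
    a = cfg["array"]
    return ArraySpec(
        n_elements=int(a["n_elements"]),
        pitch=a["pitch_mm"] * 1e-3,
        center_frequency=float(a["f0_hz"]),
        fractional_bandwidth=float(a["bandwidth"]),
        sound_speed=float(a["c_mps"]),
    )


def build_sequence(cfg: dict):
    s = cfg["sequence"]
    return make_sequence(
        s["mode"],
        spec=build_spec(cfg),
        frame_rate=float(s["frame_rate_hz"]),
        spacing=s["spacing_us"] * 1e-6,
        subaperture_size=int(s["subaperture"]),
        f_number=float(s["f_number"]),
    )


def build_trajectory(cfg: dict):
    t = cfg["trajectory"]
    s = cfg["sequence"]
    return make_trajectory(
        t["extent_mm"] * 1e-3,
        float(t["duration_s"]),
        float(s["frame_rate_hz"]),
        profile=t.get("profile", "constant"),
    )
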