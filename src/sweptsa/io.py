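"""HDF5 / CSV interchange.

Channel-data layout: one group per frame at ``/frames/<i>`` holding an
``rf`` dataset (float32, samples × elements) with attributes ``fs``, ``t0``,
``event_kind``, ``angle``, ``vs_position`` (diverging only), ``true_pose_mm``
and ``frame_index``; array and sequence metadata live under ``/meta``.
Trajectory estimates are stored both as CSV and under ``/trajectory``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquisition import ArraySpec, TransmitEvent
from .beamform import BeamformedImage, ImageGrid
from .simulate import ChannelFrame

__all__ = [
    "save_frames",
    "load_frames",
    "save_trajectory_csv",
    "load_trajectory_csv",
    "save_image",
    "load_image",
    "write_manifest",
]

_SPEC_ATTRS = ("n_elements", "pitch", "center_frequency", "fractional_bandwidth", "sound_speed")


def save_frames(path, frames: list[ChannelFrame], attrs: dict | None = None) -> None:
    if not frames:
        raise ValueError("no frames to save")
    spec = frames[0].spec
    with h5py.File(path, "w") as h5:
        meta = h5.create_group("meta")
        for name in _SPEC_ATTRS:
            meta.attrs[name] = getattr(spec, name)
        for key, val in (attrs or {}).items():
            meta.attrs[key] = val
        grp = h5.create_group("frames")
        for i, f in enumerate(frames):
            g = grp.create_group(str(i))
            g.create_dataset("rf", data=f.rf.astype(np.float32))
            g.attrs["fs"] = f.fs
            g.attrs["t0"] = f.t0
            g.attrs["event_kind"] = f.event.kind
            g.attrs["angle"] = f.event.angle
            g.attrs["t_offset"] = f.event.t_offset
            if f.event.virtual_source is not None:
                g.attrs["vs_position"] = np.asarray(f.event.virtual_source)
            g.attrs["true_pose_mm"] = f.pose * 1e3
            g.attrs["frame_index"] = f.frame_index


def load_frames(path) -> list[ChannelFrame]:
    frames = []
    with h5py.File(path, "r") as h5:
        meta = dict(h5["meta"].attrs)
        spec = ArraySpec(
            n_elements=int(meta["n_elements"]),
            pitch=float(meta["pitch"]),
            center_frequency=float(meta["center_frequency"]),
            fractional_bandwidth=float(meta["fractional_bandwidth"]),
            sound_speed=float(meta["sound_speed"]),
        )
        grp = h5["frames"]
        for key in sorted(grp, key=int):
            g = grp[key]
            kind = g.attrs["event_kind"]
            if isinstance(kind, bytes):
                kind = kind.decode()
            vs = g.attrs.get("vs_position")
            event = TransmitEvent(
                kind=kind,
                angle=float(g.attrs.get("angle", 0.0)),
                virtual_source=tuple(vs) if vs is not None else None,
                t_offset=float(g.attrs.get("t_offset", 0.0)),
            )
            frames.append(
                ChannelFrame(
                    rf=g["rf"][()],
                    fs=float(g.attrs["fs"]),
                    t0=float(g.attrs["t0"]),
                    event=event,
                    pose=float(g.attrs["true_pose_mm"]) * 1e-3,
                    frame_index=int(g.attrs["frame_index"]),
                    spec=spec,
                )
            )
    return frames


def save_trajectory_csv(path, frame_indices, times, positions, mean_peak_corr=None) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.asarray(frame_indices, dtype=int),
            "time_s": np.asarray(times, dtype=float),
            "x_hat_mm": np.asarray(positions, dtype=float) * 1e3,
        }
    )
    if mean_peak_corr is not None:
        df["mean_peak_corr"] = np.asarray(mean_peak_corr, dtype=float)
    df.to_csv(path, index=False)


def append_trajectory_h5(path, frame_indices, times, positions, mean_peak_corr=None) -> None:
    """Write (or replace) the /trajectory group of an existing channel-data file."""
    with h5py.File(path, "a") as h5:
        if "trajectory" in h5:
            del h5["trajectory"]
        grp = h5.create_group("trajectory")
        grp.create_dataset("frame_index", data=np.asarray(frame_indices, dtype=int))
        grp.create_dataset("time_s", data=np.asarray(times, dtype=float))
        grp.create_dataset("x_hat_m", data=np.asarray(positions, dtype=float))
        if mean_peak_corr is not None:
            grp.create_dataset("mean_peak_corr", data=np.asarray(mean_peak_corr, dtype=float))


def load_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["x_hat_m"] = df["x_hat_mm"] * 1e-3
    return df


def save_image(path, image: BeamformedImage) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("pixels_real", data=image.pixels.real)
        h5.create_dataset("pixels_imag", data=image.pixels.imag)
        h5.create_dataset("grid/x", data=image.grid.x)
        h5.create_dataset("grid/z", data=image.grid.z)
        h5.attrs["provenance"] = json.dumps(image.provenance, default=str)


def load_image(path) -> BeamformedImage:
    with h5py.File(path, "r") as h5:
        grid = ImageGrid(x=h5["grid/x"][()], z=h5["grid/z"][()])
        pixels = h5["pixels_real"][()] + 1j * h5["pixels_imag"][()]
        provenance = json.loads(h5.attrs.get("provenance", "{}"))
    return BeamformedImage(grid=grid, pixels=pixels, provenance=provenance)


def write_manifest(path, config_hash: str, outputs: dict, timings: dict) -> None:
    missing = [str(p) for p in outputs.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"declared outputs missing: {missing}")
    from . import __version__

    manifest = {
        "config_hash": config_hash,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "timings_s": timings,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
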