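"""Readers and writers for the pipeline's on-disk formats.

Waveforms: 2-column CSV (time_s, flow_mL_per_s).  Velocity fields:
HDF5 with /x /y /t /vx /vy /mask and mandatory units attributes.
Images: multi-page grayscale TIFF plus a plain-text key=value sidecar
carrying pixel size and frame rate.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .types import FlowWaveform, ParticleImageSequence, VelocityField2D

__all__ = [
    "write_waveform_csv",
    "read_waveform_csv",
    "write_field_h5",
    "read_field_h5",
    "write_images_tiff",
    "read_images_tiff",
]

PathLike = Union[str, Path]


def write_waveform_csv(waveform: FlowWaveform, path: PathLike) -> None:
    pd.DataFrame(
        {"time_s": waveform.time, "flow_mL_per_s": waveform.flow_rate}
    ).to_csv(path, index=False)


def read_waveform_csv(path: PathLike) -> FlowWaveform:
    """Read a waveform CSV; rejects missing columns and non-monotone time."""
    df = pd.read_csv(path)
    required = {"time_s", "flow_mL_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)} (header line 1)")
    extra = set(df.columns) - required
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {sorted(extra)}",
                      stacklevel=2)
    t = df["time_s"].to_numpy(dtype=float)
    q = df["flow_mL_per_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: header line plus 1-based data row of the offending sample
        raise ValueError(f"{path}: time not strictly increasing at line {bad[0] + 3}")
    return FlowWaveform(time=t, flow_rate=q, period=float(t[-1] - t[0]))


def write_field_h5(field: VelocityField2D, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=field.x)
        f.create_dataset("y", data=field.y)
        f.create_dataset("t", data=field.t)
        f.create_dataset("vx", data=field.vx)
        f.create_dataset("vy", data=field.vy)
        f.create_dataset("mask", data=field.mask)
        f.attrs["units"] = "cm/s"
        f.attrs["length_units"] = "mm"
        f.attrs["spacing_mm"] = field.spacing
        f.attrs["frame_rate"] = field.frame_rate
        for key, val in field.attrs.items():
            if isinstance(val, (int, float, str, np.integer, np.floating)):
                f.attrs[f"meta_{key}"] = val


def read_field_h5(path: PathLike) -> VelocityField2D:
    """Read a velocity field; a missing units attribute is a hard error
    (it is the only guard against cm/s vs mm/s mix-ups)."""
    with h5py.File(path, "r") as f:
        if "units" not in f.attrs:
            raise ValueError(f"{path}: missing mandatory 'units' attribute")
        x = f["x"][()]
        y = f["y"][()]
        t = f["t"][()]
        vx = f["vx"][()]
        vy = f["vy"][()]
        expected = (t.size, y.size, x.size)
        if vx.shape != expected or vy.shape != expected:
            raise ValueError(
                f"{path}: structural error, vx/vy shape {vx.shape} does not "
                f"match axes {expected}"
            )
        if "mask" in f:
            mask = f["mask"][()].astype(bool)
        else:
            warnings.warn(f"{path}: missing /mask, defaulting to all-true",
                          stacklevel=2)
            mask = np.ones((y.size, x.size), dtype=bool)
        attrs = {k[5:]: v for k, v in f.attrs.items() if k.startswith("meta_")}
    return VelocityField2D(x=x, y=y, t=t, vx=vx, vy=vy, mask=mask, attrs=attrs)


def write_images_tiff(images: ParticleImageSequence, path: PathLike) -> None:
    """Write frames as multi-page grayscale TIFF + key=value sidecar."""
    path = Path(path)
    dtype = np.uint8 if images.bit_depth == 8 else np.uint16
    data = np.clip(np.round(images.frames), 0, images.max_intensity).astype(dtype)
    tifffile.imwrite(path, data)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(
        f"pixel_size_mm={images.pixel_size!r}\n"
        f"frame_rate_fps={images.frame_rate!r}\n"
        f"bit_depth={images.bit_depth}\n"
        f"origin_x_mm={images.origin[0]!r}\n"
        f"origin_y_mm={images.origin[1]!r}\n"
    )


def read_images_tiff(path: PathLike) -> ParticleImageSequence:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".meta")
    if not sidecar.exists():
        raise ValueError(f"{path}: missing sidecar {sidecar.name} "
                         "(pixel size and frame rate are mandatory)")
    meta = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    return ParticleImageSequence(
        frames=frames,
        pixel_size=float(meta["pixel_size_mm"]),
        frame_rate=float(meta["frame_rate_fps"]),
        bit_depth=int(meta.get("bit_depth", 8)),
        origin=(float(meta.get("origin_x_mm", 0.0)),
                float(meta.get("origin_y_mm", 0.0))),
    )
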