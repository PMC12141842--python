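"""File I/O: images and stacks, force-trace CSV, field/profile export.

Formats follow the pipeline conventions: 8/16-bit TIFF or PNG images,
multi-page TIFF or numbered PNG frames plus a CSV manifest
(frame, time_h) for stacks, and force traces as CSV with a
``# channel=deflection_um|force_mN`` header comment above columns
``time_s, plate_displacement_mm, signal``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
import yaml

from pellikit.pivcore import Image, DisplacementField
from pellikit.mechanics import ForceTrace
from pellikit.kinetics import ImageStack

__all__ = [
    "read_image", "write_image", "read_stack", "write_stack",
    "read_force_trace", "write_force_trace", "write_field", "read_field",
    "write_profile", "load_config",
]


def read_image(path, pixel_size: float | None = None) -> Image:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        from pellikit.pivcore import to_grayscale
        return Image(to_grayscale(arr).pixels, pixel_size=pixel_size)
    return Image(arr, pixel_size=pixel_size)


def write_image(path, image: Image) -> None:
    path = Path(path)
    arr = np.clip(image.pixels, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_stack(directory, stack: ImageStack, fmt: str = "tiff") -> Path:
    """Write a stack as multi-page TIFF or numbered PNGs + manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame({
        "frame": np.arange(stack.n_frames), "time_h": stack.times})
    if fmt == "tiff":
        tifffile.imwrite(directory / "stack.tif",
                         np.clip(stack.frames, 0, 255).astype(np.uint8))
    elif fmt == "png":
        for k in range(stack.n_frames):
            iio.imwrite(directory / f"frame_{k:04d}.png",
                        np.clip(stack.frames[k], 0, 255).astype(np.uint8))
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    manifest["pixel_size_mm"] = stack.pixel_size
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory


def read_stack(directory) -> ImageStack:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    pixel_size = float(manifest["pixel_size_mm"].iloc[0])
    tif = directory / "stack.tif"
    if tif.exists():
        frames = tifffile.imread(tif).astype(float)
    else:
        frames = np.array([
            iio.imread(directory / f"frame_{int(k):04d}.png").astype(float)
            for k in manifest["frame"]])
    return ImageStack(frames, manifest["time_h"].to_numpy(float), pixel_size)


def write_force_trace(path, trace: ForceTrace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# channel={trace.channel}\n")
        fh.write("time_s,plate_displacement_mm,signal\n")
        for t, d, s in zip(trace.time, trace.plate_displacement,
                           trace.raw_signal):
            fh.write(f"{t:.6g},{d:.9g},{s:.9g}\n")


def read_force_trace(path) -> ForceTrace:
    path = Path(path)
    channel = "force_mN"
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if token.startswith("channel="):
                channel = token.split("=", 1)[1]
        df = pd.read_csv(path, comment="#",
                         names=["time_s", "plate_displacement_mm", "signal"],
                         skiprows=2)
    else:
        df = pd.read_csv(path)
    return ForceTrace(time=df["time_s"].to_numpy(float),
                      plate_displacement=df["plate_displacement_mm"]
                      .to_numpy(float),
                      raw_signal=df["signal"].to_numpy(float),
                      channel=channel)


def write_field(path, field: DisplacementField) -> None:
    df = pd.DataFrame({
        "x_px": field.grid_x.ravel(), "y_px": field.grid_y.ravel(),
        "u_px": field.u.ravel(), "v_px": field.v.ravel(),
        "valid": field.valid.ravel().astype(int),
        "peak_quality": field.peak_quality.ravel(),
        "status": field.status.ravel()})
    df.to_csv(path, index=False)


def read_field(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile(path_csv, path_json, profile, results=None) -> None:
    """Export a profile (+ optional fit) as CSV and JSON."""
    data = {"x_rel": profile.x_rel, "u_rel": profile.u_rel}
    if results is not None:
        data["u_fit"] = results.piecewise.predict(profile.x_rel)
        data["residual"] = profile.u_rel - data["u_fit"]
    pd.DataFrame(data).to_csv(path_csv, index=False)
    if results is not None:
        payload = {
            "nodes": [list(n) for n in results.piecewise.nodes.nodes],
            "sse": results.piecewise.sse,
            "n_segments": results.piecewise.n_segments,
            "affine": {"slope": results.affine.slope,
                       "intercept": results.affine.intercept,
                       "r_squared": results.affine.r_squared},
            "regions": [{"interval": list(r.interval),
                         "elongation_fraction": r.elongation_fraction,
                         "label": r.label} for r in results.regions],
        }
        Path(path_json).write_text(json.dumps(payload, indent=2))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
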