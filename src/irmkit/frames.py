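"""Multichannel IRM image containers and TIFF stack input/output.

An :class:`IRMFrame` holds one time point: a float image per illumination
wavelength, the lateral pixel size, and a timestamp. Stacks are written as
plain multipage TIFF (pages ordered frame-major, then channel) with the
wavelengths, pixel size and timestamps stored both in the TIFF image
description and in a JSON sidecar next to the file, so the stack survives
tools that strip TIFF metadata.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["IRMFrame", "write_stack", "read_stack"]


@dataclass
class IRMFrame:
    """Per-wavelength intensity images sharing one geometry.

    data has shape (n_channels, height, width); ``wavelengths`` gives the
    vacuum wavelength (nm) of each channel; ``pixel_size`` is in μm/pixel;
    ``timestamp`` in seconds.
    """

    data: np.ndarray
    wavelengths: tuple[float, ...]
    pixel_size: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"data must be (channels, H, W), got shape {self.data.shape}")
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if len(self.wavelengths) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[0]} channels"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, wavelength: float) -> np.ndarray:
        """Image of the channel whose wavelength is closest to ``wavelength``."""
        idx = int(np.argmin([abs(w - wavelength) for w in self.wavelengths]))
        if abs(self.wavelengths[idx] - wavelength) > 1.0:
            raise KeyError(f"no channel at {wavelength} nm (have {self.wavelengths})")
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "IRMFrame":
        return IRMFrame(data, self.wavelengths, self.pixel_size, self.timestamp)


def _sidecar_path(path: str) -> str:
    return str(path) + ".json"


def write_stack(frames: list[IRMFrame], path: str) -> None:
    """Write frames to a multipage TIFF, frame-major then channel.

    Metadata (wavelengths nm, pixel size μm, timestamps s) goes into the TIFF
    image description and a ``<path>.json`` sidecar.
    """
    if not frames:
        raise ValueError("no frames to write")
    wavelengths = frames[0].wavelengths
    pixel_size = frames[0].pixel_size
    shape = frames[0].shape
    for f in frames:
        if f.wavelengths != wavelengths or f.shape != shape or f.pixel_size != pixel_size:
            raise ValueError("all frames in a stack must share wavelengths, shape and pixel size")
    meta = {
        "wavelengths_nm": list(wavelengths),
        "pixel_size_um": pixel_size,
        "timestamps_s": [f.timestamp for f in frames],
        "n_frames": len(frames),
        "n_channels": len(wavelengths),
    }
    pages = np.stack([f.data for f in frames]).reshape(-1, *shape).astype(np.float32)
    tifffile.imwrite(path, pages, description=json.dumps(meta))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_stack(path: str) -> list[IRMFrame]:
    """Read a TIFF stack written by :func:`write_stack` (or a bare TIFF with
    a JSON sidecar declaring the metadata).

    Raises a ``ValueError`` naming the sidecar fix when wavelength metadata
    is missing, and when channel shapes are inconsistent.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description or ""
    meta = None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = None
    if not isinstance(meta, dict) or "wavelengths_nm" not in meta:
        sidecar = _sidecar_path(path)
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                meta = json.load(fh)
        else:
            raise ValueError(
                f"{path} carries no wavelength metadata; write a sidecar "
                f"{sidecar} with keys 'wavelengths_nm', 'pixel_size_um' and "
                f"optionally 'timestamps_s'"
            )
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    n_chan = len(wavelengths)
    if len(pages) % n_chan != 0:
        raise ValueError(
            f"{len(pages)} TIFF pages are not a multiple of {n_chan} channels"
        )
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in stack: {sorted(shapes)}")
    n_frames = len(pages) // n_chan
    times = meta.get("timestamps_s") or [float(i) for i in range(n_frames)]
    if len(times) != n_frames:
        raise ValueError(f"{len(times)} timestamps for {n_frames} frames")
    frames = []
    for i in range(n_frames):
        data = np.stack(pages[i * n_chan:(i + 1) * n_chan]).astype(float)
        frames.append(IRMFrame(data, wavelengths, pixel_size, float(times[i])))
    frames.sort(key=lambda f: f.timestamp)
    return frames
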