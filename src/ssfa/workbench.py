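"""Shared I/O, resizing, seeding and run-manifest plumbing.

Conventions used across the package: coordinates are (row, col), 0-based,
top-left origin; masks travel as 0/255 8-bit grayscale PNG with a >127
foreground threshold on read; FA maps travel as 3-channel 32-bit float TIFF
in fixed (TS1, TS2, DS) channel order; images are 8-bit grayscale PNG (or
TIFF) mapped to [0, 1] floats.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _resize


def read_image(path) -> np.ndarray:
    """Grayscale image as float32 in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: expected a grayscale image, got shape {arr.shape}; "
            "convert to single-channel first")
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        return (arr / 65535.0).astype(np.float32)
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def write_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {image.shape}")
    if image.dtype.kind == "f":
        if image.min() < 0.0 or image.max() > 1.0:
            raise ValueError("float image values must lie in [0, 1]")
        image = np.round(image * 255.0).astype(np.uint8)
    iio.imwrite(path, image)


def read_mask(path) -> np.ndarray:
    """Binary mask from a grayscale PNG/TIFF: pixels > 127 are foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: RGB masks are not supported; convert to grayscale")
    return arr > 127


def write_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got {mask.shape}")
    iio.imwrite(path, (mask.astype(bool) * np.uint8(255)))


def write_fa_map(fa: np.ndarray, path) -> None:
    """FA map as 3-channel float32 TIFF, channels (TS1, TS2, DS)."""
    fa = np.asarray(fa, dtype=np.float32)
    if fa.ndim != 3 or fa.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) FA map, got {fa.shape}")
    if fa.min() < 0.0 or fa.max() > 1.0:
        raise ValueError("FA map values must lie in [0, 1]")
    tifffile.imwrite(path, fa, photometric="minisblack", planarconfig="separate")


def read_fa_map(path) -> np.ndarray:
    fa = tifffile.imread(path)
    if fa.ndim != 3 or fa.shape[0] != 3:
        raise ValueError(f"{path}: expected a (3, H, W) FA map, got {fa.shape}")
    return fa.astype(np.float32)


def resize_to(arr: np.ndarray, size: int, kind: str = "image") -> np.ndarray:
    """Resize to (size, size): bilinear for images, nearest for masks/FA maps.

    Resizing only ever feeds the network; metrics are computed at the
    original resolution by the callers.
    """
    if size <= 0:
        raise ValueError("target size must be positive")
    arr = np.asarray(arr)
    if kind == "image":
        if arr.shape == (size, size):
            return arr
        return _resize(arr, (size, size), order=1, anti_aliasing=False,
                       preserve_range=True).astype(np.float32)
    if kind == "mask":
        if arr.shape == (size, size):
            return arr.astype(bool)
        out = _resize(arr.astype(np.uint8), (size, size), order=0,
                      anti_aliasing=False, preserve_range=True)
        return out.astype(bool)
    if kind == "fa":
        if arr.shape[1:] == (size, size):
            return arr
        return np.stack([_resize(ch, (size, size), order=0,
                                 anti_aliasing=False, preserve_range=True)
                         for ch in arr]).astype(np.float32)
    raise ValueError(f"unknown kind {kind!r}")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one integer seed."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(int(seed)).spawn(n)]


class RunManifest:
    """Append-only provenance record for CLI runs (JSON file per run dir)."""

    def __init__(self, path):
        self.path = Path(path)
        self.records = []
        if self.path.exists():
            self.records = json.loads(self.path.read_text())

    def record(self, command: str, config: dict, inputs: list, outputs: list) -> None:
        self.records.append({
            "command": command,
            "config": config,
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.records, indent=2))
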