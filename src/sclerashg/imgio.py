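"""Grayscale TIFF reading/writing and the in-memory image container.

Micrographs are single-plane integer grayscale TIFFs. Acquisitions are
nominally 12-bit inside a 16-bit container; 8-bit inputs are accepted and
their bit depth recorded. Multi-channel or floating-point TIFFs are refused.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ImageReadError, InvalidParameterError, UnsupportedImageError


@dataclass(frozen=True)
class Image16:
    """2-D grid of non-negative integer intensities.

    bit_depth is the nominal payload depth (8, 12 or 16); all pixel values
    must fit in it. pixel_size_um defaults to 1.0 when calibration metadata
    is absent — the waviness statistic is dimensionless, so this only scales
    reported lengths.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidParameterError("pixels must be a non-empty 2-D array")
        if arr.dtype.kind not in "ui":
            raise InvalidParameterError("pixels must have an integer dtype")
        if self.bit_depth not in (8, 12, 16):
            raise InvalidParameterError("bit_depth must be 8, 12 or 16")
        if arr.size and int(arr.min()) < 0:
            raise InvalidParameterError("pixel values must be non-negative")
        if arr.size and int(arr.max()) > (1 << self.bit_depth) - 1:
            raise InvalidParameterError(
                f"pixel values exceed {self.bit_depth}-bit range"
            )
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImageMetadata:
    """Provenance of one pipeline image: which animal, which eye, which dose."""

    rabbit_id: str
    arm: str  # "treated" | "control"
    condition: str
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ("treated", "control"):
            raise InvalidParameterError("arm must be 'treated' or 'control'")
        if not self.condition:
            raise InvalidParameterError("condition must be present")


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype.itemsize == 1:
        return 8
    return 12 if int(arr.max(initial=0)) <= 4095 else 16


def read_image(path: str | Path, pixel_size_um: float = 1.0) -> Image16:
    """Losslessly load a single-plane grayscale TIFF.

    Raises UnsupportedImageError for multi-channel or float data and
    ImageReadError for missing/corrupt files.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except (ValueError, OSError, tifffile.TiffFileError) as exc:
        raise ImageReadError(f"could not read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ImageReadError(f"{path}: empty or truncated TIFF")
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: expected a single-plane grayscale image, got shape {arr.shape}"
        )
    if arr.dtype.kind not in "ui":
        raise UnsupportedImageError(f"{path}: float TIFFs are not supported")
    if arr.dtype.itemsize > 2:
        raise UnsupportedImageError(f"{path}: >16-bit containers are not supported")
    if arr.dtype.kind == "i":
        if arr.min(initial=0) < 0:
            raise UnsupportedImageError(f"{path}: negative pixel values")
        arr = arr.astype(np.uint16)
    return Image16(arr, bit_depth=_infer_bit_depth(arr), pixel_size_um=pixel_size_um)


def write_image(img: Image16, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF whose read-back is pixel-identical."""
    path = Path(path)
    data = img.pixels.astype(np.uint8 if img.bit_depth == 8 else np.uint16)
    try:
        tifffile.imwrite(path, data, photometric="minisblack")
    except OSError as exc:
        raise ImageReadError(f"could not write TIFF {path}: {exc}") from exc


def write_metadata(meta: ImageMetadata, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(meta), indent=1))


def read_metadata(path: str | Path) -> ImageMetadata:
    return ImageMetadata(**json.loads(Path(path).read_text()))
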