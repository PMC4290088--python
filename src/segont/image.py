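"""Raster image container.

Images are held as float arrays normalized to [0, 1], either grayscale
(H, W) or RGB (H, W, 3).  All pixel coordinates throughout the package are
0-based (row, col).  The bytes of the file an image was loaded from are kept
alongside the decoded array so archives can store the original verbatim.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import SegontError

ALLOWED_FORMATS = ("JPEG", "PNG", "GIF", "BMP")


@dataclass(frozen=True)
class ImageGrid:
    """A decoded raster: the pixel lattice every mask and seed refers to.

    Parameters
    ----------
    values
        Float array of shape (H, W) for grayscale or (H, W, 3) for RGB,
        all entries in [0, 1].
    source_format
        One of JPEG, PNG, GIF, BMP.
    """

    values: np.ndarray
    source_format: str = "PNG"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim not in (2, 3) or (v.ndim == 3 and v.shape[2] != 3):
            raise SegontError(f"image must be (H, W) or (H, W, 3), got {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise SegontError("image must have height >= 1 and width >= 1")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise SegontError("image values must lie in [0, 1]")
        if self.source_format not in ALLOWED_FORMATS:
            raise SegontError(
                f"unsupported format {self.source_format!r}; "
                f"allowed: {', '.join(ALLOWED_FORMATS)}"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def channels(self) -> int:
        return 1 if self.values.ndim == 2 else 3

    def pixel(self, row: int, col: int) -> np.ndarray:
        """Intensity vector at (row, col): length 1 (gray) or 3 (RGB)."""
        return np.atleast_1d(self.values[row, col])

    def flat_values(self) -> np.ndarray:
        """All pixels as an (H*W, channels) array, row-major."""
        return self.values.reshape(self.height * self.width, -1)


def decode_image(data: bytes) -> ImageGrid:
    """Decode raw JPEG/PNG/GIF/BMP bytes into an :class:`ImageGrid`."""
    with Image.open(io.BytesIO(data)) as im:
        fmt = im.format or "PNG"
        if fmt not in ALLOWED_FORMATS:
            raise SegontError(f"unsupported image format {fmt!r}")
        if im.mode in ("L", "I;16", "I", "F", "1"):
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        else:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return ImageGrid(arr, source_format=fmt)


def load_image(path: str | Path) -> tuple[ImageGrid, bytes]:
    """Load an image file; return the decoded grid and the original bytes."""
    data = Path(path).read_bytes()
    return decode_image(data), data


def encode_png(image: ImageGrid) -> bytes:
    """Deterministically encode an in-memory grid as PNG bytes.

    Used when a document is built from a synthetic array rather than a file,
    so the "original image" entry of an archive still has well-defined bytes.
    """
    arr = np.round(image.values * 255.0).astype(np.uint8)
    im = Image.fromarray(arr, mode="L" if image.channels == 1 else "RGB")
    buf = io.BytesIO()
    im.save(buf, format="PNG", optimize=False)
    return buf.getvalue()
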