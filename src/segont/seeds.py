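"""Seed scribbles: per-pixel hard-constraint labels.

A :class:`SeedSet` mirrors the red/blue mark-up workflow: red strokes declare
foreground, blue strokes declare background, everything else is unlabeled.
Seeds accumulate monotonically; relabeling a pixel with the opposite class is
an error, and the caller must clear first (the session module exposes that).

Scribbles can be supplied three ways:
  * explicit (row, col, label) points,
  * polyline strokes rasterized with Bresenham's line algorithm,
  * a label-mask image where red pixels mean foreground and blue background.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skimage.draw import line as _bresenham

from .errors import MissingSeedClassError, SeedConflictError, ShapeMismatchError
from .image import ImageGrid

UNLABELED = 0
FOREGROUND = 1
BACKGROUND = 2

_LABEL_NAMES = {UNLABELED: "unlabeled", FOREGROUND: "foreground", BACKGROUND: "background"}


_LABEL_ALIASES = {
    "foreground": FOREGROUND, "fg": FOREGROUND, "f": FOREGROUND,
    "background": BACKGROUND, "bg": BACKGROUND, "b": BACKGROUND,
    "unlabeled": UNLABELED,
}


def _as_label(label: int | str) -> int:
    if isinstance(label, str):
        try:
            return _LABEL_ALIASES[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown seed label {label!r}")
    if label not in _LABEL_NAMES:
        raise ValueError(f"unknown seed label {label!r}")
    return int(label)


class SeedSet:
    """Per-pixel labels in {FOREGROUND, BACKGROUND, UNLABELED} on an image lattice."""

    def __init__(self, shape: tuple[int, int], labels: np.ndarray | None = None):
        if labels is None:
            labels = np.zeros(shape, dtype=np.uint8)
        labels = np.asarray(labels, dtype=np.uint8)
        if labels.shape != tuple(shape):
            raise ShapeMismatchError(
                f"seed labels shape {labels.shape} != lattice shape {tuple(shape)}"
            )
        if labels.max(initial=0) > BACKGROUND:
            raise ValueError("seed labels must be in {0, 1, 2}")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "SeedSet":
        return SeedSet(self.shape, self.labels.copy())

    # -- construction -----------------------------------------------------

    @classmethod
    def from_points(
        cls, shape: tuple[int, int], points: Iterable[tuple[int, int, int | str]]
    ) -> "SeedSet":
        """Build from (row, col, label) triples; label may be 'fg'/'bg' text."""
        s = cls(shape)
        for row, col, label in points:
            s.add_point(row, col, label)
        return s

    @classmethod
    def from_strokes(
        cls,
        shape: tuple[int, int],
        strokes: Iterable[tuple[Sequence[tuple[int, int]], int | str]],
    ) -> "SeedSet":
        """Build from polyline strokes: ((r, c) vertex list, label) pairs."""
        s = cls(shape)
        for vertices, label in strokes:
            s.add_stroke(vertices, label)
        return s

    @classmethod
    def from_label_image(cls, image: ImageGrid) -> "SeedSet":
        """Interpret an RGB image as mark-up: red=foreground, blue=background.

        A pixel counts as red when its R channel dominates (R > 0.5, G and B
        below 0.25), symmetrically for blue; anything else is unlabeled.
        """
        if image.channels != 3:
            raise ValueError("label-mask image must be RGB")
        v = image.values
        red = (v[..., 0] > 0.5) & (v[..., 1] < 0.25) & (v[..., 2] < 0.25)
        blue = (v[..., 2] > 0.5) & (v[..., 0] < 0.25) & (v[..., 1] < 0.25)
        labels = np.zeros(image.shape, dtype=np.uint8)
        labels[red] = FOREGROUND
        labels[blue] = BACKGROUND
        return cls(image.shape, labels)

    # -- mutation ----------------------------------------------------------

    def add_point(self, row: int, col: int, label: int | str) -> None:
        code = _as_label(label)
        h, w = self.shape
        if not (0 <= row < h and 0 <= col < w):
            raise IndexError(f"seed point ({row}, {col}) outside {h}x{w} image")
        current = self.labels[row, col]
        if current != UNLABELED and current != code:
            raise SeedConflictError((row, col))
        self.labels[row, col] = code

    def add_stroke(self, vertices: Sequence[tuple[int, int]], label: int | str) -> None:
        """Rasterize a polyline through the given (row, col) vertices."""
        if len(vertices) == 0:
            return
        if len(vertices) == 1:
            self.add_point(vertices[0][0], vertices[0][1], label)
            return
        for (r0, c0), (r1, c1) in zip(vertices[:-1], vertices[1:]):
            rr, cc = _bresenham(int(r0), int(c0), int(r1), int(c1))
            for r, c in zip(rr.tolist(), cc.tolist()):
                self.add_point(r, c, label)

    def clear(self) -> None:
        self.labels[:] = UNLABELED

    # -- queries -----------------------------------------------------------

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def has_both_classes(self) -> bool:
        return self.count(FOREGROUND) >= 1 and self.count(BACKGROUND) >= 1

    def require_both_classes(self) -> None:
        for code in (FOREGROUND, BACKGROUND):
            if self.count(code) == 0:
                raise MissingSeedClassError(_LABEL_NAMES[code])

    def merged_with(self, other: "SeedSet") -> "SeedSet":
        """Union of two seed sets; a pixel labeled oppositely in the two is an error."""
        if other.shape != self.shape:
            raise ShapeMismatchError(
                f"cannot merge seeds of shape {other.shape} into {self.shape}"
            )
        a, b = self.labels, other.labels
        conflict = (a != UNLABELED) & (b != UNLABELED) & (a != b)
        if conflict.any():
            r, c = np.argwhere(conflict)[0]
            raise SeedConflictError((int(r), int(c)))
        return SeedSet(self.shape, np.where(b != UNLABELED, b, a))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SeedSet) and np.array_equal(self.labels, other.labels)
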