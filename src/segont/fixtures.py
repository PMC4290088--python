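"""Deterministic synthetic test scenes with known ground truth.

Real botanical photographs contain curvilinear, asymmetric, overlapping
structures; these generators emulate that geometry with three organic shape
families — ellipses, lobed blobs (ellipses with a sinusoidal radius
perturbation) and curvilinear bands (thickened polylines) — rendered over a
uniform background with Gaussian pixel noise.  Ground truth region ids are
recorded before noise, so segmentation output can be scored against a known
answer (Jaccard overlap).

Everything is a pure function of its integer seed: the same seed and specs
always produce the identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import SegontError
from .image import ImageGrid
from .seeds import BACKGROUND, FOREGROUND, SeedSet


@dataclass(frozen=True)
class RegionSpec:
    """Geometry + mean color of one synthetic region.

    kind
        "ellipse", "lobed" (blob with ``lobes`` sinusoidal lobes of relative
        amplitude ``lobe_amplitude``) or "band" (polyline through ``points``
        thickened to ``thickness`` pixels).
    color
        Mean intensity, scalar for grayscale scenes or an RGB triple.
    center / axes / rotation
        Ellipse and lobed-blob placement, in pixel units and radians.
    """

    kind: str
    color: float | tuple[float, float, float]
    center: tuple[float, float] | None = None
    axes: tuple[float, float] | None = None
    rotation: float = 0.0
    lobes: int = 0
    lobe_amplitude: float = 0.0
    points: tuple[tuple[float, float], ...] = ()
    thickness: float = 0.0


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene: noisy image + per-pixel ground-truth region id.

    Region ids follow spec order (1-based); id 0 is the background.  Later
    specs win contested pixels.
    """

    image: ImageGrid
    ground_truth: np.ndarray
    region_specs: tuple[RegionSpec, ...]
    seed: int

    def region_mask(self, region_id: int) -> np.ndarray:
        return (self.ground_truth == region_id).astype(np.uint8)


def _region_membership(spec: RegionSpec, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    if spec.kind in ("ellipse", "lobed"):
        if spec.center is None or spec.axes is None:
            raise SegontError(f"{spec.kind} region needs center and axes")
        a, b = spec.axes
        if a <= 0 or b <= 0:
            raise SegontError("zero-area region: axes must be positive")
        reach = max(a, b) * (1.0 + abs(spec.lobe_amplitude))
        cr, ccol = spec.center
        if not (reach <= cr <= h - 1 - reach and reach <= ccol <= w - 1 - reach):
            raise SegontError("region does not fit inside the canvas")
        dr, dc = rr - cr, cc - ccol
        cos, sin = np.cos(spec.rotation), np.sin(spec.rotation)
        u = cos * dr + sin * dc
        v = -sin * dr + cos * dc
        if spec.kind == "ellipse":
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # lobed blob: sinusoidal perturbation of the elliptical radius
        theta = np.arctan2(v, u)
        scale = 1.0 + spec.lobe_amplitude * np.cos(spec.lobes * theta)
        return (u / a) ** 2 + (v / b) ** 2 <= scale**2
    if spec.kind == "band":
        if len(spec.points) < 2 or spec.thickness <= 0:
            raise SegontError("band region needs >= 2 points and thickness > 0")
        half = spec.thickness / 2.0
        pts = np.asarray(spec.points, dtype=float)
        if (pts - half < 0).any() or ((pts[:, 0] + half) > h - 1).any() or (
            (pts[:, 1] + half) > w - 1
        ).any():
            raise SegontError("region does not fit inside the canvas")
        p = np.stack([rr.ravel(), cc.ravel()], axis=1)
        dmin = np.full(p.shape[0], np.inf)
        for a_pt, b_pt in zip(pts[:-1], pts[1:]):
            ab = b_pt - a_pt
            denom = float(ab @ ab)
            if denom == 0:
                raise SegontError("zero-length band segment")
            t = np.clip((p - a_pt) @ ab / denom, 0.0, 1.0)
            proj = a_pt + t[:, None] * ab
            dmin = np.minimum(dmin, np.linalg.norm(p - proj, axis=1))
        return (dmin <= half).reshape(h, w)
    raise SegontError(f"unknown region kind {spec.kind!r}")


def make_scene(
    specs: Sequence[RegionSpec],
    size: tuple[int, int],
    noise_sd: float,
    seed: int,
    background: float | tuple[float, float, float] = 0.05,
) -> SyntheticScene:
    """Render regions over a uniform background and add clipped Gaussian noise.

    Ground truth is recorded before noise; contested pixels go to the later
    spec.  A zero-area or out-of-canvas spec raises.
    """
    if noise_sd < 0:
        raise SegontError("noise_sd must be >= 0")
    h, w = size
    rgb = any(np.ndim(s.color) == 1 for s in specs) or np.ndim(background) == 1
    clean = np.zeros((h, w, 3) if rgb else (h, w), dtype=np.float64)
    clean[...] = background
    truth = np.zeros((h, w), dtype=np.int32)
    for i, spec in enumerate(specs, start=1):
        member = _region_membership(spec, (h, w))
        if not member.any():
            raise SegontError(f"region {i} rasterizes to zero pixels")
        truth[member] = i
        clean[member] = spec.color
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, clean.shape), 0.0, 1.0)
    return SyntheticScene(
        image=ImageGrid(noisy),
        ground_truth=truth,
        region_specs=tuple(specs),
        seed=seed,
    )


def make_scribbles(
    scene: SyntheticScene,
    target_region: int,
    n_fg: int,
    n_bg: int,
    seed: int,
) -> SeedSet:
    """Sample label-correct seed points for one target region.

    Foreground points are drawn inside the eroded target region (so they sit
    safely away from the true boundary, as a human scribble would);
    background points outside its dilation.  Both draws are deterministic in
    the seed.
    """
    if n_fg < 1 or n_bg < 1:
        raise SegontError("n_fg and n_bg must be >= 1")
    target = scene.ground_truth == target_region
    if not target.any():
        raise SegontError(f"target region {target_region} is empty")
    eroded = ndimage.binary_erosion(target, iterations=2)
    if not eroded.any():
        raise SegontError(f"region {target_region} too small to erode")
    outside = ~ndimage.binary_dilation(target, iterations=2)
    if not outside.any():
        raise SegontError("no background left outside the dilated region")
    rng = np.random.default_rng(seed)
    seeds = SeedSet(scene.image.shape)
    for pool, n, label in ((eroded, n_fg, FOREGROUND), (outside, n_bg, BACKGROUND)):
        coords = np.argwhere(pool)
        idx = rng.choice(len(coords), size=min(n, len(coords)), replace=False)
        for r, c in coords[idx]:
            seeds.labels[r, c] = label
    return seeds


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap score |A ∩ B| / |A ∪ B| between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# Canned study conditions
# ---------------------------------------------------------------------------

#: Default contrast between region and background in the high-contrast
#: recovery conditions, and the pixel-noise standard deviation used there.
HIGH_CONTRAST_GAP = 0.8
HIGH_CONTRAST_NOISE_SD = 0.02


def high_contrast_scene(seed: int, size: tuple[int, int] = (64, 64)) -> SyntheticScene:
    """One randomly placed lobed blob at the canonical high-contrast settings.

    Background intensity 0.05, region 0.85 (gap 0.8), noise sd 0.02; the
    blob's center, axes, rotation and lobe count vary with the seed.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    axes = (float(rng.uniform(0.16, 0.24) * h), float(rng.uniform(0.14, 0.22) * w))
    reach = max(axes) * 1.25 + 1
    spec = RegionSpec(
        kind="lobed",
        color=0.05 + HIGH_CONTRAST_GAP,
        center=(
            float(rng.uniform(reach, h - 1 - reach)),
            float(rng.uniform(reach, w - 1 - reach)),
        ),
        axes=axes,
        rotation=float(rng.uniform(0, np.pi)),
        lobes=int(rng.integers(3, 6)),
        lobe_amplitude=float(rng.uniform(0.08, 0.2)),
    )
    return make_scene(
        [spec], size, noise_sd=HIGH_CONTRAST_NOISE_SD,
        seed=int(rng.integers(0, 2**31)), background=0.05,
    )


def five_region_scene(seed: int, size: tuple[int, int] = (72, 72)) -> SyntheticScene:
    """Five well-separated high-contrast regions on one canvas.

    Emulates a flower photograph with five distinct organs so a scripted
    annotation pass can form and label five segments.
    """
    h, w = size
    colors = (0.9, 0.7, 0.85, 0.6, 0.75)
    centers = ((14, 14), (14, 54), (36, 36), (58, 14), (58, 54))
    rng = np.random.default_rng(seed)
    specs = [
        RegionSpec(
            kind="ellipse",
            color=colors[i],
            center=(float(centers[i][0]), float(centers[i][1])),
            axes=(float(rng.uniform(7, 9)), float(rng.uniform(6, 8))),
            rotation=float(rng.uniform(0, np.pi)),
        )
        for i in range(5)
    ]
    return make_scene(
        specs, size, noise_sd=HIGH_CONTRAST_NOISE_SD,
        seed=int(rng.integers(0, 2**31)), background=0.05,
    )
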