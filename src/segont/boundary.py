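"""Exact boundary polygons for binary masks.

A formed segment stores its outline as closed polygons whose filled
rasterization reproduces the mask pixel-for-pixel, holes included.  To make
that exact, vertices live on the *pixel-corner* grid: corner (r, c) is the
top-left corner of pixel (r, c), and pixel (r, c) covers the half-open square
[r, r+1) x [c, c+1).  The outline is the set of unit "crack" edges between a
foreground pixel and a background pixel (or the image border), linked into
closed loops.

Loops are directed so the foreground lies to the right of the direction of
travel; at corner vertices where two loops touch diagonally, the tracer takes
the sharpest right turn, which keeps the touching loops separate.  Collinear
runs are merged, so polygon edges are axis-aligned segments of integer
length.  Filling uses even-odd parity of the vertical edges along each pixel
row, which is exact for these rectilinear polygons.
"""

from __future__ import annotations

import numpy as np

from .errors import SegontError

# Directed crack edges around a foreground pixel (r, c), corner to corner:
#   top    (r, c)     -> (r, c+1)   heading east,  background above
#   right  (r, c+1)   -> (r+1, c+1) heading south, background to the east
#   bottom (r+1, c+1) -> (r+1, c)   heading west,  background below
#   left   (r+1, c)   -> (r, c)     heading north, background to the west


def _right(d: tuple[int, int]) -> tuple[int, int]:
    return (d[1], -d[0])


def _left(d: tuple[int, int]) -> tuple[int, int]:
    return (-d[1], d[0])


def trace_boundaries(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """Trace a binary mask into closed boundary polygons (outer + holes).

    Returns a list of polygons; each polygon is a list of (row, col) corner
    vertices without the closing repeat of the first vertex.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise SegontError("mask must be 2-D")
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    fg = padded[1:-1, 1:-1]
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a: tuple[int, int], b: tuple[int, int]) -> None:
        edges.setdefault(a, []).append(b)

    rs, cs = np.nonzero(fg)
    for r, c in zip(rs.tolist(), cs.tolist()):
        if not padded[r, c + 1]:  # background above
            add((r, c), (r, c + 1))
        if not padded[r + 1, c + 2]:  # background east
            add((r, c + 1), (r + 1, c + 1))
        if not padded[r + 2, c + 1]:  # background below
            add((r + 1, c + 1), (r + 1, c))
        if not padded[r + 1, c]:  # background west
            add((r + 1, c), (r, c))
    for starts in edges.values():
        starts.sort()

    polygons: list[list[tuple[int, int]]] = []
    for start in sorted(edges):
        while edges[start]:
            loop = [start]
            prev, cur = start, edges[start].pop(0)
            while cur != start:
                loop.append(cur)
                d = (cur[0] - prev[0], cur[1] - prev[1])
                outs = edges.get(cur, [])
                nxt = None
                for cand_d in (_right(d), d, _left(d)):
                    cand = (cur[0] + cand_d[0], cur[1] + cand_d[1])
                    if cand in outs:
                        nxt = cand
                        break
                if nxt is None:  # pragma: no cover - tracing invariant
                    raise SegontError(f"boundary tracing stuck at corner {cur}")
                outs.remove(nxt)
                prev, cur = cur, nxt
            polygons.append(_merge_collinear(loop))
    return polygons


def _merge_collinear(loop: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    n = len(loop)
    for i, v in enumerate(loop):
        a, b = loop[i - 1], loop[(i + 1) % n]
        d_in = (v[0] - a[0], v[1] - a[1])
        d_out = (b[0] - v[0], b[1] - v[1])
        if (d_in[0] == 0) != (d_out[0] == 0):  # direction changes at v
            out.append(v)
    return out


def fill_polygons(
    polygons: list[list[tuple[int, int]]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize rectilinear corner-grid polygons back into a binary mask.

    A pixel is foreground when an even-odd ray cast along its row crosses an
    odd number of vertical polygon edges at columns <= its own.  For polygons
    produced by :func:`trace_boundaries` this inverts the tracing exactly.
    """
    h, w = shape
    toggles = np.zeros((h, w + 1), dtype=np.int64)
    for poly in polygons:
        n = len(poly)
        for i in range(n):
            (r0, c0), (r1, c1) = poly[i], poly[(i + 1) % n]
            if c0 != c1 and r0 != r1:
                raise SegontError("polygon edges must be axis-aligned")
            if c0 == c1 and r0 != r1:  # vertical edge
                lo, hi = sorted((r0, r1))
                toggles[lo:hi, c0] += 1
    return (np.cumsum(toggles, axis=1)[:, :w] % 2).astype(np.uint8)
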