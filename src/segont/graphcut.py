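"""Seeded binary segmentation by interactive graph cuts.

The energy follows the classic seeded min-cut formulation: each pixel p gets a
regional cost R_p(label) = -ln of the seed-histogram probability of its
intensity under that label, and each neighboring pair (p, q) pays a boundary
cost w_pq = exp(-||I_p - I_q||^2 / (2 sigma^2)) / dist(p, q) when labeled
differently.  The total energy

    E(A) = lambda * sum_p R_p(A_p) + sum_{(p,q) in N} w_pq * [A_p != A_q]

is minimized exactly by a minimum s-t cut on a pixel graph: n-links carry the
boundary weights, t-links to the source (foreground) and sink (background)
terminals carry the regional costs, and seeded pixels are pinned to their
terminal by a t-link of capacity K = 1 + max_p sum_q w_pq, which no minimum
cut can afford to sever.

The max-flow problem is solved with networkx's shortest-augmenting-path
algorithm on integer capacities: floats are scaled by 2^44 and rounded, so
the arithmetic is exact (no floating-point residual dust can corrupt the
cut partition) and the quantization error per edge is ~3e-14 — far below
any energy difference the tests resolve.  The graph is built in a fixed
order, so the solver is deterministic and identical inputs always yield
identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import SegontError, ShapeMismatchError
from .image import ImageGrid
from .seeds import BACKGROUND, FOREGROUND, SeedSet

#: Fixed-point scale for edge capacities.  Capacities stay well below 2^9,
#: so scaled values stay below 2^53 and round exactly through float64.
CAPACITY_SCALE = 2**44


@dataclass(frozen=True)
class EnergyParams:
    """Tunable weights of the segmentation energy.

    Parameters
    ----------
    lambda_regional
        Nonnegative weight of the regional (histogram) term.  0 makes the
        cut purely contrast-driven.
    sigma
        Contrast scale of the boundary term, in [0, 1] intensity units.
        Differences well below sigma are cheap to cut through; differences
        well above it are nearly free to separate.
    hist_bins
        Bins per channel for the seed histograms (joint-binned over channels
        for RGB).
    neighborhood
        4 or 8 pixel connectivity.
    epsilon_prob
        Floor probability mixed into every histogram cell so regional costs
        stay finite.
    """

    lambda_regional: float = 1.0
    sigma: float = 0.1
    hist_bins: int = 16
    neighborhood: int = 8
    epsilon_prob: float = 1e-4

    def __post_init__(self):
        if self.lambda_regional < 0:
            raise SegontError("lambda_regional must be >= 0")
        if self.sigma <= 0:
            raise SegontError("sigma must be > 0")
        if self.hist_bins < 2:
            raise SegontError("hist_bins must be >= 2")
        if self.neighborhood not in (4, 8):
            raise SegontError("neighborhood must be 4 or 8")
        if not (0 < self.epsilon_prob <= 0.1):
            raise SegontError("epsilon_prob must be in (0, 0.1]")

    def n_cells(self, channels: int) -> int:
        return self.hist_bins**channels

    def for_image(self, image: ImageGrid) -> "EnergyParams":
        """Validate the histogram floor against this image's cell count."""
        if self.epsilon_prob * self.n_cells(image.channels) >= 1.0:
            raise SegontError(
                "epsilon_prob * hist_bins^channels must be < 1 "
                f"(got {self.epsilon_prob} * {self.n_cells(image.channels)})"
            )
        return self


# Defaults: 8 bins per channel joint-binned for RGB, 16 for grayscale.
def default_params(image: ImageGrid) -> EnergyParams:
    bins = 16 if image.channels == 1 else 8
    return EnergyParams(hist_bins=bins)


def estimate_sigma(image: ImageGrid, neighborhood: int = 8) -> float:
    """Contrast scale heuristic: sqrt of the mean squared neighbor difference."""
    p_idx, q_idx, _ = _neighbor_pairs(image.height, image.width, neighborhood)
    flat = image.flat_values()
    d2 = np.sum((flat[p_idx] - flat[q_idx]) ** 2, axis=1)
    return float(max(np.sqrt(d2.mean()), 1e-6))


# ---------------------------------------------------------------------------
# Regional term: seed histograms
# ---------------------------------------------------------------------------


def histogram_bin_index(image: ImageGrid, params: EnergyParams) -> np.ndarray:
    """Flat joint-bin index of every pixel, shape (H, W)."""
    b = params.hist_bins
    v = np.atleast_3d(image.values)
    idx = np.minimum((v * b).astype(np.int64), b - 1)
    flat = np.zeros(image.shape, dtype=np.int64)
    for ch in range(v.shape[2]):
        flat = flat * b + idx[..., ch]
    return flat


def build_seed_histograms(
    image: ImageGrid, seeds: SeedSet, params: EnergyParams
) -> tuple[np.ndarray, np.ndarray]:
    """Foreground and background intensity histograms from the seeded pixels.

    Each histogram is a probability distribution over the joint intensity
    bins, floored by mixing with the uniform distribution at total weight
    ``epsilon_prob * n_cells`` so that every cell is >= epsilon_prob while
    the whole histogram still sums to 1.
    """
    _check_shapes(image, seeds)
    seeds.require_both_classes()
    params.for_image(image)
    n = params.n_cells(image.channels)
    bins = histogram_bin_index(image, params)
    out = []
    for code in (FOREGROUND, BACKGROUND):
        sel = bins[seeds.labels == code]
        counts = np.bincount(sel, minlength=n).astype(np.float64)
        emp = counts / counts.sum()
        alpha = params.epsilon_prob * n
        out.append((1.0 - alpha) * emp + alpha / n)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Boundary term
# ---------------------------------------------------------------------------


def boundary_weight(p_value, q_value, dist: float, params: EnergyParams):
    """Contrast-sensitive n-link weight exp(-||dI||^2 / (2 sigma^2)) / dist.

    Equal neighbors at unit distance get weight 1; the weight decays with the
    squared intensity difference and with pixel distance.
    """
    if np.any(np.asarray(dist) <= 0):
        raise SegontError("pixel distance must be > 0")
    d2 = np.sum((np.atleast_1d(np.asarray(p_value, dtype=np.float64))
                 - np.atleast_1d(np.asarray(q_value, dtype=np.float64))) ** 2, axis=-1)
    w = np.exp(-d2 / (2.0 * params.sigma**2)) / dist
    return float(w) if np.isscalar(d2) or w.ndim == 0 else w


def _neighbor_pairs(h: int, w: int, neighborhood: int):
    """Unordered neighboring pixel pairs as flat indices, plus distances."""
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        s2 = float(np.sqrt(2.0))
        offsets += [(1, 1, s2), (1, -1, s2)]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ps, qs, ds = [], [], []
    for dr, dc, dist in offsets:
        valid = (rr + dr >= 0) & (rr + dr < h) & (cc + dc >= 0) & (cc + dc < w)
        p = rr[valid] * w + cc[valid]
        q = (rr[valid] + dr) * w + (cc[valid] + dc)
        ps.append(p)
        qs.append(q)
        ds.append(np.full(p.size, dist))
    return np.concatenate(ps), np.concatenate(qs), np.concatenate(ds)


# ---------------------------------------------------------------------------
# Energy and the cut
# ---------------------------------------------------------------------------


def regional_costs(
    image: ImageGrid, params: EnergyParams, fg_hist: np.ndarray, bg_hist: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel -ln histogram probability under each label, shape (H, W)."""
    bins = histogram_bin_index(image, params)
    return -np.log(fg_hist[bins]), -np.log(bg_hist[bins])


def segmentation_energy(
    image: ImageGrid,
    mask: np.ndarray,
    params: EnergyParams,
    fg_hist: np.ndarray,
    bg_hist: np.ndarray,
) -> float:
    """Evaluate E(A) for an arbitrary binary labeling (1 = foreground)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ShapeMismatchError("mask shape != image shape")
    r_fg, r_bg = regional_costs(image, params, fg_hist, bg_hist)
    regional = np.where(mask, r_fg, r_bg).sum()
    p_idx, q_idx, dist = _neighbor_pairs(image.height, image.width, params.neighborhood)
    flat = image.flat_values()
    d2 = np.sum((flat[p_idx] - flat[q_idx]) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * params.sigma**2)) / dist
    m = mask.ravel()
    boundary = w[m[p_idx] != m[q_idx]].sum()
    return float(params.lambda_regional * regional + boundary)


def _check_shapes(image: ImageGrid, seeds: SeedSet) -> None:
    if seeds.shape != image.shape:
        raise ShapeMismatchError(
            f"seed shape {seeds.shape} != image shape {image.shape}"
        )


def _build_capacities(image: ImageGrid, seeds: SeedSet, params: EnergyParams):
    """Edge lists (u, v, capacity) for the s-t graph.

    Node numbering: pixels 0..N-1 row-major, source N, sink N+1.  n-links are
    symmetric (both directions carry the boundary weight); t-links carry the
    regional costs, except at seeded pixels where the seed's terminal edge
    gets capacity K = 1 + max_p sum_q w_pq and the opposite edge 0.
    """
    h, w = image.shape
    n = h * w
    source, sink = n, n + 1

    p_idx, q_idx, dist = _neighbor_pairs(h, w, params.neighborhood)
    flat = image.flat_values()
    d2 = np.sum((flat[p_idx] - flat[q_idx]) ** 2, axis=1)
    w_n = np.round(
        np.exp(-d2 / (2.0 * params.sigma**2)) / dist * CAPACITY_SCALE
    ).astype(np.int64)

    # K must strictly dominate the n-link capacity at any single node, in the
    # same integer units, so no minimum cut can sever a seed's t-link.
    node_sum = np.zeros(n, dtype=np.int64)
    np.add.at(node_sum, p_idx, w_n)
    np.add.at(node_sum, q_idx, w_n)
    k_cap = 1 + int(node_sum.max(initial=0))

    fg_hist, bg_hist = build_seed_histograms(image, seeds, params)
    r_fg, r_bg = regional_costs(image, params, fg_hist, bg_hist)
    lam = params.lambda_regional
    src_cap = np.round(lam * r_bg.ravel() * CAPACITY_SCALE).astype(np.int64)
    snk_cap = np.round(lam * r_fg.ravel() * CAPACITY_SCALE).astype(np.int64)

    labels = seeds.labels.ravel()
    src_cap[labels == FOREGROUND] = k_cap
    snk_cap[labels == FOREGROUND] = 0
    src_cap[labels == BACKGROUND] = 0
    snk_cap[labels == BACKGROUND] = k_cap

    pixels = np.arange(n, dtype=np.int64)
    u = np.concatenate([p_idx, q_idx, np.full(n, source, dtype=np.int64), pixels])
    v = np.concatenate([q_idx, p_idx, pixels, np.full(n, sink, dtype=np.int64)])
    cap = np.concatenate([w_n, w_n, src_cap, snk_cap])
    return u, v, cap, (fg_hist, bg_hist)


def _solve_mincut(n_pixels: int, u: np.ndarray, v: np.ndarray, cap: np.ndarray):
    """Min-cut side assignment: True for pixels on the source (foreground) side."""
    source, sink = n_pixels, n_pixels + 1
    graph = nx.DiGraph()
    graph.add_nodes_from(range(n_pixels + 2))
    graph.add_weighted_edges_from(
        zip(u.tolist(), v.tolist(), cap.tolist()), weight="capacity"
    )
    _, (source_side, _) = nx.minimum_cut(
        graph, source, sink, flow_func=nx.algorithms.flow.shortest_augmenting_path
    )
    fg = np.zeros(n_pixels, dtype=bool)
    fg[[i for i in source_side if i < n_pixels]] = True
    return fg


def segment(image: ImageGrid, seeds: SeedSet, params: EnergyParams | None = None) -> np.ndarray:
    """Run the seeded min-cut and return the foreground mask (H, W) uint8.

    Every foreground-seeded pixel is 1 and every background-seeded pixel is 0
    in the result; among labelings satisfying those hard constraints the
    returned mask minimizes the segmentation energy.
    """
    if params is None:
        params = default_params(image)
    _check_shapes(image, seeds)
    seeds.require_both_classes()
    params.for_image(image)
    u, v, cap, _ = _build_capacities(image, seeds, params)
    fg_side = _solve_mincut(image.height * image.width, u, v, cap)
    mask = fg_side.reshape(image.shape).astype(np.uint8)
    labels = seeds.labels
    if (mask[labels == FOREGROUND] == 0).any() or (mask[labels == BACKGROUND] == 1).any():
        raise SegontError("hard constraint violated by min-cut")  # pragma: no cover
    return mask


def refine(
    image: ImageGrid,
    seeds: SeedSet,
    new_scribbles: SeedSet,
    params: EnergyParams | None = None,
) -> np.ndarray:
    """Re-segment with additional scribbles merged into the existing seeds.

    Conflicting relabels (a pixel foreground in one set and background in the
    other) raise; clear the seeds explicitly to start over.
    """
    merged = seeds.merged_with(new_scribbles)
    return segment(image, merged, params)
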