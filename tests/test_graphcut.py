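"""Unit and property tests for the seeded min-cut segmentation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segont import (
    EnergyParams,
    ImageGrid,
    MissingSeedClassError,
    SeedConflictError,
    SegontError,
    SeedSet,
    ShapeMismatchError,
    boundary_weight,
    build_seed_histograms,
    estimate_sigma,
    refine,
    segment,
    segmentation_energy,
)
from segont.graphcut import _build_capacities, _solve_mincut
from segont.seeds import BACKGROUND, FOREGROUND


def brute_force_minimum(image, seeds, params):
    """Exhaustive minimum energy over all labelings respecting the seeds."""
    fg_hist, bg_hist = build_seed_histograms(image, seeds, params)
    labels = seeds.labels.ravel()
    free = np.flatnonzero(labels == 0)
    base = labels == FOREGROUND
    best = np.inf
    for bits in itertools.product((0, 1), repeat=len(free)):
        m = base.copy()
        m[free] = bits
        best = min(
            best,
            segmentation_energy(image, m.reshape(image.shape), params, fg_hist, bg_hist),
        )
    return best


def random_instance(rng, max_side=4):
    h, w = int(rng.integers(2, max_side + 1)), int(rng.integers(2, max_side + 1))
    image = ImageGrid(rng.random((h, w)))
    labels = np.zeros(h * w, np.uint8)
    order = rng.permutation(h * w)
    labels[order[0]] = FOREGROUND
    labels[order[1]] = BACKGROUND
    for i in order[2 : 2 + rng.integers(0, 3)]:
        labels[i] = rng.integers(1, 3)
    seeds = SeedSet((h, w), labels.reshape(h, w))
    params = EnergyParams(
        lambda_regional=float(rng.uniform(0, 3)),
        sigma=float(rng.uniform(0.05, 0.5)),
        hist_bins=int(rng.integers(2, 9)),
        neighborhood=int(rng.choice([4, 8])),
        epsilon_prob=float(rng.uniform(1e-5, 1e-2)),
    )
    return image, seeds, params


class TestBoundaryWeight:
    def test_zero_contrast_unit_distance(self):
        params = EnergyParams(sigma=0.1)
        assert boundary_weight(0.4, 0.4, 1.0, params) == pytest.approx(1.0, abs=1e-12)

    def test_contrast_of_sigma_sqrt2(self):
        params = EnergyParams(sigma=0.1)
        delta = 0.1 * np.sqrt(2.0)
        w = boundary_weight(0.3, 0.3 + delta, 1.0, params)
        assert w == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_diagonal_neighbor_identical_values(self):
        params = EnergyParams(sigma=0.1)
        w = boundary_weight((0.2, 0.5, 0.9), (0.2, 0.5, 0.9), np.sqrt(2.0), params)
        assert w == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_strictly_decreasing_in_contrast(self):
        params = EnergyParams(sigma=0.2)
        ws = [boundary_weight(0.0, d, 1.0, params) for d in (0.0, 0.1, 0.2, 0.4, 0.8)]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(SegontError):
            boundary_weight(0.1, 0.2, 0.0, EnergyParams())


class TestSeedHistograms:
    def test_point_mass_histograms(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 1.0
        image = ImageGrid(img)
        labels = np.zeros((4, 4), np.uint8)
        labels[:, 0] = FOREGROUND
        labels[:, 3] = BACKGROUND
        params = EnergyParams(hist_bins=8, epsilon_prob=1e-4)
        fg, bg = build_seed_histograms(image, SeedSet((4, 4), labels), params)
        floor = 1e-4
        assert fg[0] == pytest.approx(1 - 7 * floor)
        assert bg[7] == pytest.approx(1 - 7 * floor)
        assert np.allclose(fg[1:], floor) and np.allclose(bg[:7], floor)
        assert fg.sum() == pytest.approx(1.0) and bg.sum() == pytest.approx(1.0)

    def test_single_sample_two_bins(self):
        image = ImageGrid(np.full((2, 2), 0.5))
        labels = np.array([[1, 0], [0, 2]], np.uint8)
        params = EnergyParams(hist_bins=2, epsilon_prob=0.01)
        fg, _ = build_seed_histograms(image, SeedSet((2, 2), labels), params)
        assert fg[0] == pytest.approx(0.01)
        assert fg[1] == pytest.approx(0.99)

    def test_histograms_approach_true_distribution(self):
        # oracle: bin the same known samples directly and compare in total variation
        rng = np.random.default_rng(11)
        n = 500
        fg_samples = np.clip(rng.normal(0.3, 0.05, n), 0, 1)
        bg_samples = np.clip(rng.normal(0.7, 0.05, n), 0, 1)
        values = np.concatenate([fg_samples, bg_samples]).reshape(40, 25)
        image = ImageGrid(values)
        labels = np.concatenate(
            [np.full(n, FOREGROUND, np.uint8), np.full(n, BACKGROUND, np.uint8)]
        ).reshape(40, 25)
        params = EnergyParams(hist_bins=8, epsilon_prob=1e-4)
        fg, bg = build_seed_histograms(image, SeedSet((40, 25), labels), params)
        bins = np.minimum((np.concatenate([fg_samples, bg_samples]) * 8).astype(int), 7)
        oracle_fg = np.bincount(bins[:n], minlength=8) / n
        oracle_bg = np.bincount(bins[n:], minlength=8) / n
        assert 0.5 * np.abs(fg - oracle_fg).sum() <= 0.1
        assert 0.5 * np.abs(bg - oracle_bg).sum() <= 0.1

    def test_missing_class_names_the_class(self):
        image = ImageGrid(np.zeros((3, 3)))
        labels = np.zeros((3, 3), np.uint8)
        labels[0, 0] = FOREGROUND
        with pytest.raises(MissingSeedClassError, match="background"):
            build_seed_histograms(image, SeedSet((3, 3), labels), EnergyParams())


class TestSegment:
    def test_two_region_image_cut_at_contrast_edge(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        image = ImageGrid(img)
        seeds = SeedSet.from_points((6, 8), [(3, 1, "fg"), (3, 6, "bg")])
        mask = segment(image, seeds, EnergyParams(sigma=0.1))
        expected = np.zeros((6, 8), np.uint8)
        expected[:, :4] = 1
        assert np.array_equal(mask, expected)

    def test_cheapest_cut_around_lone_background_seed(self):
        image = ImageGrid(np.full((3, 3), 0.5))
        labels = np.full((3, 3), FOREGROUND, np.uint8)
        labels[1, 1] = BACKGROUND
        seeds = SeedSet((3, 3), labels)
        params = EnergyParams(lambda_regional=0.0, hist_bins=4)
        mask = segment(image, seeds, params)
        fg, bg = build_seed_histograms(image, seeds, params)
        energy = segmentation_energy(image, mask, params, fg, bg)
        assert energy == pytest.approx(brute_force_minimum(image, seeds, params), abs=1e-8)

    @pytest.mark.parametrize("trial", range(25))
    def test_energy_matches_bruteforce(self, trial):
        rng = np.random.default_rng(200 + trial)
        image, seeds, params = random_instance(rng)
        mask = segment(image, seeds, params)
        fg, bg = build_seed_histograms(image, seeds, params)
        energy = segmentation_energy(image, mask, params, fg, bg)
        assert energy == pytest.approx(brute_force_minimum(image, seeds, params), abs=1e-8)
        assert (mask[seeds.labels == FOREGROUND] == 1).all()
        assert (mask[seeds.labels == BACKGROUND] == 0).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_hard_constraints_and_determinism(self, seed):
        rng = np.random.default_rng(seed)
        image, seeds, params = random_instance(rng, max_side=5)
        mask1 = segment(image, seeds, params)
        mask2 = segment(image, seeds, params)
        assert np.array_equal(mask1, mask2)
        assert (mask1[seeds.labels == FOREGROUND] == 1).all()
        assert (mask1[seeds.labels == BACKGROUND] == 0).all()

    def test_shape_mismatch_rejected(self):
        image = ImageGrid(np.zeros((3, 3)))
        seeds = SeedSet.from_points((4, 4), [(0, 0, "fg"), (1, 1, "bg")])
        with pytest.raises(ShapeMismatchError):
            segment(image, seeds)

    def test_missing_seed_class_rejected(self):
        image = ImageGrid(np.zeros((3, 3)))
        seeds = SeedSet.from_points((3, 3), [(0, 0, "fg")])
        with pytest.raises(MissingSeedClassError):
            segment(image, seeds)

    def test_scale_invariance_of_capacities(self):
        rng = np.random.default_rng(77)
        image, seeds, params = random_instance(rng, max_side=4)
        u, v, cap, _ = _build_capacities(image, seeds, params)
        n = image.height * image.width
        base = _solve_mincut(n, u, v, cap)
        scaled = _solve_mincut(n, u, v, cap * 3)
        assert np.array_equal(base, scaled)


class TestRefine:
    def _setup(self, seed=5):
        rng = np.random.default_rng(seed)
        image = ImageGrid(rng.random((3, 4)))
        seeds = SeedSet.from_points((3, 4), [(0, 0, "fg"), (2, 3, "bg")])
        return image, seeds, EnergyParams(hist_bins=4)

    def test_empty_refinement_is_identity(self):
        image, seeds, params = self._setup()
        base = segment(image, seeds, params)
        refined = refine(image, seeds, SeedSet(image.shape), params)
        assert np.array_equal(base, refined)

    def test_background_scribble_excludes_pixels(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        image = ImageGrid(img)
        seeds = SeedSet.from_points((6, 8), [(3, 1, "fg"), (3, 6, "bg")])
        new = SeedSet.from_strokes((6, 8), [([(0, 2), (5, 2)], "bg")])
        mask = refine(image, seeds, new, EnergyParams(sigma=0.1))
        assert (mask[:, 2] == 0).all()

    def test_refinement_energy_matches_bruteforce_of_merged_problem(self):
        image, seeds, params = self._setup(9)
        new = SeedSet.from_points(image.shape, [(1, 2, "bg")])
        mask = refine(image, seeds, new, params)
        merged = seeds.merged_with(new)
        fg, bg = build_seed_histograms(image, merged, params)
        energy = segmentation_energy(image, mask, params, fg, bg)
        assert energy == pytest.approx(brute_force_minimum(image, merged, params), abs=1e-8)

    def test_conflicting_relabel_identifies_pixel(self):
        image, seeds, params = self._setup()
        new = SeedSet.from_points(image.shape, [(0, 0, "bg")])
        with pytest.raises(SeedConflictError) as excinfo:
            refine(image, seeds, new, params)
        assert excinfo.value.pixel == (0, 0)


class TestLocality:
    def test_markup_in_one_half_never_flips_the_other(self):
        # two high-contrast halves, lambda=0: scribbles have a local effect
        rng = np.random.default_rng(31)
        h, w = 16, 16
        img = np.clip(
            np.where(np.arange(w) < w // 2, 0.05, 0.9) + rng.normal(0, 0.02, (h, w)),
            0,
            1,
        )
        image = ImageGrid(img)
        params = EnergyParams(lambda_regional=0.0, sigma=0.1)
        seeds = SeedSet.from_points((h, w), [(h // 2, 2, "fg"), (h // 2, w - 2, "bg")])
        base = segment(image, seeds, params)
        right = np.s_[:, w // 2 :]
        extra = SeedSet.from_strokes((h, w), [([(2, 1), (2, 5)], "bg")])
        refined = refine(image, seeds, extra, params)
        assert np.array_equal(refined[right], base[right])


def test_estimate_sigma_on_uniform_image_is_floor():
    assert estimate_sigma(ImageGrid(np.full((5, 5), 0.3))) == pytest.approx(1e-6)


def test_estimate_sigma_reflects_contrast():
    img = np.zeros((4, 4))
    img[:, 2:] = 1.0
    est = estimate_sigma(ImageGrid(img), neighborhood=4)
    # 4 of the 24 four-neighbor pairs straddle the step edge
    assert est == pytest.approx(np.sqrt(4 / 24), rel=1e-6)
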