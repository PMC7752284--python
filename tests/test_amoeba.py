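import itertools

import numpy as np
import pytest
from scipy import ndimage

from amoebact import _kernels
from amoebact._kernels import NBINS
from amoebact.amoeba import (DegenerateWindowError, KernelMask, ShapingConfig,
                             ThresholdSet, amoeba_mean_filter,
                             bin_of_interest_mask, central_connected_component,
                             classical_amoeba_kernel, multilevel_otsu,
                             rbs_kernel, select_n_classes)
from amoebact.phantoms import piecewise_test_image
from amoebact.pilots import WindowSpec


def exhaustive_otsu_objective(values, n_classes):
    """Brute-force maximum of sum S_k^2/C_k over all cut placements of the
    64-bin quantized histogram (independent of the DP implementation)."""
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    span = vmax - vmin
    bins = np.minimum((values - vmin) / span * NBINS, NBINS - 1).astype(int)
    cnt = np.bincount(bins, minlength=NBINS)
    s1 = np.bincount(bins, weights=values, minlength=NBINS)
    ccum = np.concatenate([[0], np.cumsum(cnt)])
    scum = np.concatenate([[0.0], np.cumsum(s1)])

    def score(i, j):  # class spanning bins i..j inclusive
        c = ccum[j + 1] - ccum[i]
        return (scum[j + 1] - scum[i]) ** 2 / c if c else 0.0

    best = -np.inf
    for cuts in itertools.combinations(range(NBINS - 1), n_classes - 1):
        edges = [-1, *cuts, NBINS - 1]
        best = max(best, sum(score(a + 1, b)
                             for a, b in zip(edges, edges[1:])))
    return best


def threshold_objective(values, thresholds):
    """sum S_k^2/C_k achieved by a concrete threshold set on the raw values."""
    values = np.asarray(values, dtype=float).ravel()
    idx = np.searchsorted(np.asarray(thresholds.levels), values, side="left")
    total = 0.0
    for k in range(thresholds.n_classes):
        sel = values[idx == k]
        if sel.size:
            total += sel.sum() ** 2 / sel.size
    return total


class TestMultilevelOtsu:
    def test_two_separated_clusters(self):
        ts = multilevel_otsu([0.0] * 4 + [1.0] * 4, 2)
        assert len(ts.levels) == 1
        assert 0.0 < ts.levels[0] < 1.0

    def test_two_cluster_window_threshold_in_gap(self):
        values = np.array([1, 1, 2, 2, 8, 8, 9, 9]) / 9.0
        ts = multilevel_otsu(values, 2)
        assert 2 / 9 < ts.levels[0] < 8 / 9

    def test_three_level_window_thresholds_between_levels(self):
        # a 9x9 window spanning all three plateaus of a three-level image
        window = np.repeat([[0.0] * 3 + [0.5] * 3 + [1.0] * 3], 9, axis=0)
        ts = multilevel_otsu(window, 3)
        t1, t2 = ts.levels
        assert 0.0 < t1 < 0.5 < t2 < 1.0

    @pytest.mark.parametrize("n_classes", [2, 3])
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_search(self, seed, n_classes):
        values = np.random.default_rng(seed).random(81)
        ts = multilevel_otsu(values, n_classes)
        achieved = threshold_objective(values, ts)
        best = exhaustive_otsu_objective(values, n_classes)
        assert achieved == pytest.approx(best, abs=1e-9)

    def test_degenerate_window_error(self):
        with pytest.raises(DegenerateWindowError):
            multilevel_otsu([0.5, 0.5, 0.5], 2)

    def test_single_class_has_no_levels(self):
        assert multilevel_otsu([0.1, 0.9], 1).levels == ()


class TestSelectNClasses:
    def test_constant_window_is_flat(self):
        assert select_n_classes(np.full(81, 0.4)) == 1

    def test_span_below_tolerance_is_flat(self, rng):
        assert select_n_classes(0.5 + 0.001 * rng.random(81),
                                tolerance=0.02) == 1

    def test_clean_two_level_window(self):
        values = np.array([0.1] * 40 + [0.9] * 41)
        assert select_n_classes(values) == 2

    def test_clean_three_level_window(self):
        values = np.array([0.05] * 27 + [0.5] * 27 + [0.95] * 27)
        assert select_n_classes(values) == 3


class TestBinOfInterest:
    def test_single_bin_is_all_true(self, rng):
        w = rng.random((5, 5))
        mask = bin_of_interest_mask(w, ThresholdSet((), 1), (2, 2))
        assert mask.all()

    def test_center_on_threshold_goes_to_lower_bin(self):
        w = np.array([[0.2, 0.5, 0.8]])
        mask = bin_of_interest_mask(w, ThresholdSet((0.5,), 2), (0, 1))
        assert mask.tolist() == [[True, True, False]]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_elementwise_interval_oracle(self, seed):
        r = np.random.default_rng(seed)
        w = r.random((7, 7))
        levels = tuple(sorted(r.random(3)))
        ts = ThresholdSet(levels, 4)
        center = (3, 3)
        mask = bin_of_interest_mask(w, ts, center)
        edges = [-np.inf, *levels, np.inf]
        v = w[center]
        k = next(i for i in range(4) if edges[i] < v <= edges[i + 1])
        expect = (w > edges[k]) & (w <= edges[k + 1])
        assert np.array_equal(mask, expect)


def recursive_flood_fill(mask, center, connectivity=8):
    out = np.zeros_like(mask, dtype=bool)

    def visit(r, c):
        out[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                if connectivity == 4 and dr != 0 and dc != 0:
                    continue
                rr, cc = r + dr, c + dc
                if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                        and mask[rr, cc] and not out[rr, cc]):
                    visit(rr, cc)

    visit(*center)
    return out


class TestCentralConnectedComponent:
    def test_all_true_preserved(self):
        mask = np.ones((5, 5), dtype=bool)
        assert central_connected_component(mask, (2, 2)).mask.all()

    def test_disconnected_blob_removed(self):
        mask = np.ones((3, 5), dtype=bool)
        mask[:, 2] = False
        out = central_connected_component(mask, (1, 0)).mask
        assert out[:, :2].all() and not out[:, 2:].any()

    def test_center_false_raises(self):
        mask = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            central_connected_component(mask, (1, 1))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_all_512_three_by_three_masks_match_flood_fill(self, connectivity):
        # exhaustive over every 3x3 binary mask with a true center
        for bits in range(512):
            mask = np.array([(bits >> k) & 1 for k in range(9)],
                            dtype=bool).reshape(3, 3)
            mask[1, 1] = True
            got = central_connected_component(mask, (1, 1), connectivity).mask
            want = recursive_flood_fill(mask, (1, 1), connectivity)
            assert np.array_equal(got, want), f"mask {bits:09b}"

    @pytest.mark.parametrize("seed", range(5))
    def test_random_masks_match_flood_fill(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((9, 9)) < 0.5
        mask[4, 4] = True
        got = central_connected_component(mask, (4, 4), 8).mask
        assert np.array_equal(got, recursive_flood_fill(mask, (4, 4), 8))


class TestRBSKernel:
    def test_constant_window_keeps_full_square(self):
        k = rbs_kernel(np.full((9, 9), 0.5), ShapingConfig())
        assert k.mask.all()

    def test_straight_edge_yields_half_window(self):
        w = np.full((9, 9), 0.2)
        w[:, 5:] = 0.8  # center column 4 on the dark side
        k = rbs_kernel(w, ShapingConfig())
        assert np.array_equal(k.mask, w == 0.2)

    def test_isolated_center_yields_singleton(self):
        w = np.full((9, 9), 0.1)
        w[4, 4] = 0.9
        k = rbs_kernel(w, ShapingConfig())
        assert k.size == 1 and k.mask[4, 4]

    @pytest.mark.parametrize("seed", range(8))
    def test_invariants_under_fuzzing(self, seed):
        r = np.random.default_rng(seed)
        w = r.random((9, 9))
        cfg = ShapingConfig(max_classes=int(r.integers(2, 5)),
                            connectivity=int(r.choice([4, 8])))
        k = rbs_kernel(w, cfg)
        assert k.mask[4, 4]
        assert 1 <= k.size <= 81
        assert k.is_connected(cfg.connectivity)
        # kernel is a subset of the bin-of-interest mask
        n = select_n_classes(w, cfg.max_classes, cfg.uniformity_tolerance)
        if n > 1:
            bin_mask = bin_of_interest_mask(
                w, multilevel_otsu(w, n), (4, 4))
            assert not np.any(k.mask & ~bin_mask)


class TestClassicalKernel:
    def test_lambda_zero_is_hop_count_ball(self, rng):
        w = rng.random((9, 9))
        cfg = ShapingConfig(method="classical", lam=0.0, radius=3.0)
        k = classical_amoeba_kernel(w, cfg)
        yy, xx = np.mgrid[0:9, 0:9]
        cheb = np.maximum(np.abs(yy - 4), np.abs(xx - 4))
        assert np.array_equal(k.mask, cheb <= 3)

    def test_constant_window_ball_for_any_lambda(self):
        w = np.full((7, 7), 0.3)
        k1 = classical_amoeba_kernel(w, ShapingConfig(method="classical",
                                                      lam=0.0, radius=2.0))
        k2 = classical_amoeba_kernel(w, ShapingConfig(method="classical",
                                                      lam=50.0, radius=2.0))
        assert np.array_equal(k1.mask, k2.mask)

    def test_high_contrast_wall_blocks_kernel(self):
        w = np.zeros((5, 5))
        w[:, 3] = 1.0  # crossing costs 1 + 10 > radius
        cfg = ShapingConfig(method="classical", lam=10.0, radius=4.0)
        k = classical_amoeba_kernel(w, cfg)
        assert k.mask[:, :3].all() and not k.mask[:, 3:].any()

    def test_four_connectivity_ball_is_diamond(self):
        w = np.full((9, 9), 0.5)
        cfg = ShapingConfig(method="classical", lam=0.0, radius=3.0,
                            connectivity=4)
        k = classical_amoeba_kernel(w, cfg)
        yy, xx = np.mgrid[0:9, 0:9]
        manhattan = np.abs(yy - 4) + np.abs(xx - 4)
        assert np.array_equal(k.mask, manhattan <= 3)


class TestAmoebaMeanFilter:
    def test_identity_on_piecewise_image(self):
        img = piecewise_test_image(144, [0.0, 0.5, 1.0])
        out = amoeba_mean_filter(img, img, ShapingConfig())
        assert np.array_equal(out, img)

    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.25)
        for method in ("rbs", "classical"):
            out = amoeba_mean_filter(img, img, ShapingConfig(method=method))
            assert np.array_equal(out, img)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            amoeba_mean_filter(rng.random((10, 10)), rng.random((10, 12)))

    def test_output_range_within_input_range(self, rng):
        img = 0.2 + 0.6 * rng.random((32, 32))
        pilot = rng.random((32, 32))
        for method in ("rbs", "classical"):
            out = amoeba_mean_filter(img, pilot, ShapingConfig(method=method))
            assert out.min() >= img.min() - 1e-12
            assert out.max() <= img.max() + 1e-12

    def test_smooths_pure_noise(self, rng):
        img = 0.5 + 0.1 * rng.standard_normal((64, 64))
        for method in ("rbs", "classical"):
            out = amoeba_mean_filter(img, img, ShapingConfig(method=method))
            assert out.var() < img.var()

    def test_step_edge_preserved_unlike_box_filter(self):
        step = piecewise_test_image(40, [0.25, 0.75], layout="bands")
        out = amoeba_mean_filter(step, step, ShapingConfig())
        assert np.array_equal(out, step)
        box = ndimage.uniform_filter(step, 9, mode="nearest")
        assert not np.array_equal(box, step)

    @pytest.mark.parametrize("method", ["rbs", "classical"])
    def test_matches_per_window_composition_oracle(self, method,
                                                   smooth_random_image):
        # the fast whole-image loop must agree with composing the single
        # window operations by hand, including truncated border windows
        img = smooth_random_image
        pilot = np.sqrt(img)  # any deterministic companion field
        cfg = ShapingConfig(method=method, window=WindowSpec(5, 5),
                            max_classes=3)
        out = amoeba_mean_filter(img, pilot, cfg)
        H, W = img.shape
        kern = rbs_kernel if method == "rbs" else classical_amoeba_kernel
        for r in range(H):
            for c in range(W):
                r0, r1 = max(0, r - 2), min(H, r + 3)
                c0, c1 = max(0, c - 2), min(W, c + 3)
                k = kern(pilot[r0:r1, c0:c1], cfg, center=(r - r0, c - c0))
                expect = img[r0:r1, c0:c1][k.mask].mean()
                assert out[r, c] == pytest.approx(expect, abs=1e-12), (r, c)


def test_otsu_dp_table_matches_exhaustive_on_histograms(rng):
    # DP optimum equals brute force for every class count on random histograms
    for _ in range(3):
        cnt = rng.integers(0, 5, NBINS).astype(np.int64)
        cnt[rng.integers(0, NBINS)] += 10
        s1 = cnt * rng.random(NBINS)
        f = np.empty((4, NBINS))
        arg = np.empty((4, NBINS), dtype=np.int64)
        _kernels.otsu_dp(cnt, s1, 4, f, arg)
        ccum = np.concatenate([[0], np.cumsum(cnt)])
        scum = np.concatenate([[0.0], np.cumsum(s1)])

        def score(i, j):
            c = ccum[j + 1] - ccum[i]
            return (scum[j + 1] - scum[i]) ** 2 / c if c else 0.0

        for n in (2, 3, 4):
            best = max(sum(score(a + 1, b) for a, b in
                           zip([-1, *cuts, NBINS - 1][:-1],
                               [*cuts, NBINS - 1]))
                       for cuts in itertools.combinations(range(NBINS - 1),
                                                          n - 1))
            assert f[n - 1, NBINS - 1] == pytest.approx(best, rel=1e-12)


def test_kernel_mask_requires_center():
    with pytest.raises(ValueError):
        KernelMask(np.zeros((3, 3), dtype=bool), (1, 1))


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (9, 9),
                      elements=st.floats(0.0, 1.0, allow_nan=False)),
           st.integers(2, 4), st.sampled_from([4, 8]))
    def test_kernel_invariants_hold_for_arbitrary_windows(w, max_classes,
                                                          connectivity):
        cfg = ShapingConfig(max_classes=max_classes,
                            connectivity=connectivity)
        for kern in (rbs_kernel, classical_amoeba_kernel):
            k = kern(w, cfg)
            assert k.mask[4, 4]
            assert 1 <= k.size <= 81
            assert k.is_connected(connectivity)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
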