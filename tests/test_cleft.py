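"""Cleft segmentation stages: binarization, curve fit, shortest path,
trimap, GMM energies, GrabCut, and the full composition."""
import math

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import bellman_ford

from synrec import (SegmentationConfig, binarize_adaptive, curve_endpoints,
                    fit_quadratic, grabcut, init_trimap, jaccard, morph_clean,
                    segment_cleft, shortest_cleft_path)
from synrec.cleft import (TRIMAP_BG, TRIMAP_FG, TRIMAP_UNKNOWN, ClassGMM,
                          DegenerateMaskError, GrabCutModel, component_energies,
                          data_term, path_cost, pixel_step_cost)

# ---------------------------------------------------------------------------
# binarization + morphology


def test_binarize_constant_patch_empty():
    patch = np.full((40, 40), 128, dtype=np.uint8)
    assert binarize_adaptive(patch).sum() == 0


def test_binarize_dark_ribbon_matches_global_threshold_oracle():
    patch = np.full((60, 60), 200, dtype=np.uint8)
    patch[28:32, 5:55] = 40
    mask = binarize_adaptive(patch, block_size=51, offset=10)
    oracle = patch < 120  # midpoint global threshold
    # the adaptive result must contain the ribbon and nothing bright
    assert (mask.astype(bool) & ~oracle).sum() == 0
    assert (oracle & ~mask.astype(bool)).sum() == 0


def test_binarize_darkness_convention():
    """Bright ribbon on dark background is NOT foreground: clefts are dark."""
    patch = np.full((60, 60), 40, dtype=np.uint8)
    patch[28:32, 5:55] = 200
    mask = binarize_adaptive(patch)
    assert mask[29, 30] == 0


def test_morph_removes_isolated_pixel_keeps_ribbon():
    mask = np.zeros((30, 40), dtype=np.uint8)
    mask[5, 5] = 1                      # speckle
    mask[10:14, 5:25] = 1               # 20x4 ribbon
    out = morph_clean(mask)
    assert out[5, 5] == 0
    area_in = 20 * 4
    assert out.sum() >= 0.7 * area_in


def test_morph_empty_stays_empty():
    assert morph_clean(np.zeros((10, 10), dtype=np.uint8)).sum() == 0


# ---------------------------------------------------------------------------
# quadratic fit + endpoints


def test_fit_recovers_exact_parabola():
    mask = np.zeros((60, 70), dtype=np.uint8)
    xs = np.arange(5, 65)
    ys = np.round(0.01 * xs**2 - 0.5 * xs + 30).astype(int)
    mask[ys, xs] = 1
    curve = fit_quadratic(mask, rng_seed=0)
    # rounding to the pixel grid leaves a sub-pixel residual
    fitted = curve(xs.astype(float))
    assert np.abs(fitted - (0.01 * xs**2 - 0.5 * xs + 30)).max() < 1.0


def test_fit_exact_on_grid_points():
    """Pixels lying exactly on an integer-valued parabola are interpolated
    to machine precision."""
    mask = np.zeros((80, 40), dtype=np.uint8)
    # y = x^2/10 - 2x + 30 is integer-valued at x = 0, 10, 20, 30
    xs = np.array([0, 10, 20, 30])
    ys = (xs**2) // 10 - 2 * xs + 30
    mask[ys, xs] = 1
    curve = fit_quadratic(mask, rng_seed=1)
    assert curve.a == pytest.approx(0.1, abs=1e-6)
    assert curve.b == pytest.approx(-2.0, abs=1e-6)
    assert curve.c == pytest.approx(30.0, abs=1e-6)


def test_fit_horizontal_line():
    mask = np.zeros((20, 50), dtype=np.uint8)
    mask[7, 5:45] = 1
    curve = fit_quadratic(mask, rng_seed=0)
    assert curve.a == pytest.approx(0.0, abs=1e-9)
    assert curve.b == pytest.approx(0.0, abs=1e-9)
    assert curve.c == pytest.approx(7.0, abs=1e-9)


def test_fit_matches_normal_equations_oracle(rng):
    """Least-squares coefficients equal the independent normal-equations
    solution computed from the same sampled points."""
    mask = (rng.uniform(size=(30, 40)) > 0.8).astype(np.uint8)
    curve = fit_quadratic(mask, rng_seed=7)
    xs, ys = curve.points[:, 0], curve.points[:, 1]
    s = {k: np.sum(xs**k) for k in range(5)}
    A = np.array([[s[4], s[3], s[2]], [s[3], s[2], s[1]], [s[2], s[1], s[0]]])
    b = np.array([np.sum(ys * xs**2), np.sum(ys * xs), np.sum(ys)])
    a_, b_, c_ = np.linalg.solve(A, b)
    assert curve.a == pytest.approx(a_, rel=1e-6, abs=1e-6)
    assert curve.b == pytest.approx(b_, rel=1e-6, abs=1e-6)
    assert curve.c == pytest.approx(c_, rel=1e-6, abs=1e-6)


def test_fit_sample_size_rule(rng):
    mask = (rng.uniform(size=(40, 40)) > 0.5).astype(np.uint8)
    w = int(mask.sum())
    curve = fit_quadratic(mask, rng_seed=0)
    assert curve.m == max(3, round(w / 3))


def test_fit_deterministic_under_seed(rng):
    mask = (rng.uniform(size=(30, 30)) > 0.7).astype(np.uint8)
    c1 = fit_quadratic(mask, rng_seed=42)
    c2 = fit_quadratic(mask, rng_seed=42)
    assert (c1.a, c1.b, c1.c) == (c2.a, c2.b, c2.c)
    assert np.array_equal(c1.points, c2.points)


def test_fit_needs_three_pixels():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[2, 2] = mask[3, 3] = 1
    with pytest.raises(DegenerateMaskError):
        fit_quadratic(mask)


def test_endpoints_straight_ribbon():
    mask = np.zeros((20, 50), dtype=np.uint8)
    mask[10, 5:41] = 1
    curve = fit_quadratic(mask, rng_seed=0)
    p1, pn = curve_endpoints(curve, mask)
    assert p1 == (10, 5)
    assert pn == (10, 40)


def test_endpoints_curved_ribbon_at_extreme_x():
    """Endpoints sit at the extreme-x arm tips, matching an exhaustive
    extreme-point search."""
    mask = np.zeros((60, 60), dtype=np.uint8)
    xs = np.arange(10, 50)
    ys = np.round(0.05 * (xs - 30) ** 2 + 20).astype(int)
    mask[ys, xs] = 1
    curve = fit_quadratic(mask, rng_seed=0)
    p1, pn = curve_endpoints(curve, mask)
    rows, cols = np.nonzero(mask)
    assert p1[1] == cols.min()
    assert pn[1] == cols.max()
    assert mask[p1] == 1 and mask[pn] == 1


def test_endpoints_vertical_fallback():
    mask = np.zeros((30, 10), dtype=np.uint8)
    mask[5:25, 4] = 1
    curve = fit_quadratic(mask, rng_seed=0)
    p1, pn = curve_endpoints(curve, mask)
    assert p1 == (5, 4)
    assert pn == (24, 4)


# ---------------------------------------------------------------------------
# shortest path


def bellman_ford_cost(patch, p1, pn, eps=0.01):
    """Independent oracle: Bellman-Ford on the same directed pixel graph."""
    w = pixel_step_cost(patch, eps)
    h, wd = w.shape
    rows_i, cols_i, data = [], [], []
    for r in range(h):
        for c in range(wd):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < wd:
                        step = math.sqrt(2) if dr and dc else 1.0
                        rows_i.append(r * wd + c)
                        cols_i.append(nr * wd + nc)
                        data.append(w[nr, nc] * step)
    g = coo_matrix((data, (rows_i, cols_i)), shape=(h * wd, h * wd))
    dist = bellman_ford(g, indices=p1[0] * wd + p1[1])
    return dist[pn[0] * wd + pn[1]]


def test_uniform_patch_gives_straight_chain():
    patch = np.full((15, 15), 100, dtype=np.uint8)
    path = shortest_cleft_path(patch, (7, 2), (7, 12))
    assert path[0] == (7, 2) and path[-1] == (7, 12)
    # 10 straight steps at cost (1.0 + eps) each
    assert path_cost(patch, path) == pytest.approx(10 * 1.01)
    assert len(path) == 11


def test_path_follows_dark_channel():
    """On an S-shaped dark channel, every path pixel is a channel pixel."""
    patch = np.full((40, 40), 220, dtype=np.uint8)
    channel = np.zeros((40, 40), dtype=bool)
    cols = np.arange(3, 37)
    rows = np.round(20 + 12 * np.sin((cols - 3) / 33 * 2 * np.pi)).astype(int)
    for r, c in zip(rows, cols):
        channel[r - 1:r + 2, c] = True
    patch[channel] = 20
    p1 = (rows[0], 3)
    pn = (rows[-1], 36)
    path = shortest_cleft_path(patch, p1, pn)
    assert all(channel[r, c] for r, c in path)


def test_dijkstra_cost_equals_bellman_ford(rng):
    for _ in range(10):
        patch = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        p1 = (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
        pn = (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
        if p1 == pn:
            continue
        path = shortest_cleft_path(patch, p1, pn)
        assert path_cost(patch, path) == pytest.approx(
            bellman_ford_cost(patch, p1, pn), abs=1e-9
        )


def test_path_is_simple_with_8_connected_steps(rng):
    patch = rng.integers(0, 256, size=(25, 25), dtype=np.uint8)
    path = shortest_cleft_path(patch, (0, 0), (24, 24))
    assert len(set(path)) == len(path)
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        assert max(abs(r0 - r1), abs(c0 - c1)) == 1


# ---------------------------------------------------------------------------
# trimap


def make_path_patch():
    patch = np.full((40, 50), 180, dtype=np.uint8)
    path = [(20, c) for c in range(10, 40)]
    return patch, path


def test_trimap_partitions_patch():
    patch, path = make_path_patch()
    tri = init_trimap(patch.shape, (5, 5, 45, 35), path, rng_seed=0)
    assert set(np.unique(tri)) <= {TRIMAP_BG, TRIMAP_FG, TRIMAP_UNKNOWN}
    assert tri.size == patch.size


def test_trimap_outside_box_is_background():
    patch, path = make_path_patch()
    tri = init_trimap(patch.shape, (5, 5, 45, 35), path, rng_seed=0)
    assert (tri[:5, :] == TRIMAP_BG).all()
    assert (tri[35:, :] == TRIMAP_BG).all()
    assert (tri[:, :5] == TRIMAP_BG).all()
    assert (tri[:, 45:] == TRIMAP_BG).all()


def test_trimap_path_is_foreground_and_bg_respects_standoff():
    from scipy import ndimage

    patch, path = make_path_patch()
    tri = init_trimap(patch.shape, (5, 5, 45, 35), path, rng_seed=0, d_bg=8.0)
    for r, c in path:
        assert tri[r, c] == TRIMAP_FG
    path_mask = np.zeros(patch.shape, dtype=bool)
    for r, c in path:
        path_mask[r, c] = True
    dist = ndimage.distance_transform_edt(~path_mask)
    inside = np.zeros(patch.shape, dtype=bool)
    inside[5:35, 5:45] = True
    assert not ((tri == TRIMAP_BG) & inside & (dist <= 8.0)).any()


def test_trimap_empty_path_rejected():
    with pytest.raises(ValueError):
        init_trimap((10, 10), (0, 0, 10, 10), [], rng_seed=0)


# ---------------------------------------------------------------------------
# GMM energies / data term


def unit_model(mean=0.0, weight=1.0):
    return ClassGMM(weights=np.array([weight]), means=np.array([[mean]]),
                    covs=np.array([[[1.0]]]))


def test_single_component_energy_at_mean():
    """G at the mean of a unit-variance 1-D Gaussian with weight 1 is
    0.5 log(2 pi)."""
    e = component_energies(np.array([[0.0]]), unit_model())
    assert e[0, 0] == pytest.approx(0.5 * math.log(2 * math.pi))


def test_half_weight_adds_log_two():
    e1 = component_energies(np.array([[0.3]]), unit_model())
    e2 = component_energies(np.array([[0.3]]), unit_model(weight=0.5))
    assert e2[0, 0] - e1[0, 0] == pytest.approx(math.log(2))


def test_zero_weight_component_is_infinite():
    model = ClassGMM(weights=np.array([0.0, 1.0]),
                     means=np.array([[0.0], [1.0]]),
                     covs=np.array([[[1.0]], [[1.0]]]))
    e = component_energies(np.array([[0.0]]), model)
    assert np.isinf(e[0, 0]) and np.isfinite(e[0, 1])


def test_argmin_assignment_matches_exhaustive_search(rng):
    model = ClassGMM(
        weights=np.array([0.2, 0.5, 0.3]),
        means=rng.normal(size=(3, 1)),
        covs=np.array([np.eye(1) * v for v in (0.5, 1.0, 2.0)]),
    )
    vals = rng.normal(size=(50, 1))
    e = component_energies(vals, model)
    best = np.argmin(e, axis=1)
    for i in range(len(vals)):
        exhaustive = min(range(3), key=lambda k: e[i, k])
        assert best[i] == exhaustive


def test_data_term_sums_per_pixel_energies(rng):
    fg = unit_model(mean=0.0)
    bg = unit_model(mean=5.0)
    model = GrabCutModel(fg=fg, bg=bg)
    vals = rng.normal(size=(20, 1))
    labels = (rng.uniform(size=20) > 0.5).astype(int)
    comps = np.zeros(20, dtype=int)
    d = data_term(vals, labels, comps, model)
    e_fg = component_energies(vals, fg)[:, 0]
    e_bg = component_energies(vals, bg)[:, 0]
    expected = np.where(labels == 1, e_fg, e_bg).sum()
    assert d == pytest.approx(expected)


# ---------------------------------------------------------------------------
# GrabCut


def two_region_image(rng):
    img = rng.normal(180, 5, (50, 50))
    img[15:35, 10:40] = rng.normal(60, 5, (20, 30))
    tri = np.full((50, 50), TRIMAP_UNKNOWN, dtype=np.uint8)
    tri[25, 15:35] = TRIMAP_FG
    tri[3, 3:47] = TRIMAP_BG
    tri[47, 3:47] = TRIMAP_BG
    truth = np.zeros((50, 50), dtype=bool)
    truth[15:35, 10:40] = True
    return img, tri, truth


def test_grabcut_matches_threshold_oracle(rng):
    """Two well-separated Gaussian regions: the result agrees with the
    midpoint-threshold oracle on >= 99% of unknown pixels."""
    img, tri, truth = two_region_image(rng)
    mask, _ = grabcut(img, tri, n_components=5, n_iters=10)
    oracle = img < 120
    unknown = tri == TRIMAP_UNKNOWN
    agreement = (mask.astype(bool) == oracle)[unknown].mean()
    assert agreement >= 0.99


def test_grabcut_energy_trace_non_increasing(rng):
    img, tri, _ = two_region_image(rng)
    _, trace = grabcut(img, tri, n_components=5, n_iters=10)
    assert len(trace) == 10
    for a, b in zip(trace[:-1], trace[1:]):
        assert b <= a + 1e-6 * max(1.0, abs(a))


def test_grabcut_seeds_never_flip(rng):
    img, tri, _ = two_region_image(rng)
    mask, _ = grabcut(img, tri)
    assert mask[tri == TRIMAP_FG].all()
    assert not mask[tri == TRIMAP_BG].any()


def test_grabcut_requires_both_seed_classes():
    img = np.zeros((10, 10))
    tri = np.full((10, 10), TRIMAP_UNKNOWN, dtype=np.uint8)
    with pytest.raises(ValueError):
        grabcut(img, tri)


# ---------------------------------------------------------------------------
# full composition


def test_segment_cleft_recovers_synthetic_cleft(small_synth):
    cfg, stack, truth = small_synth
    b = truth.boxes[0]
    pad = 10
    y1, y2 = max(0, b.y1 - pad), b.y2 + pad
    x1, x2 = max(0, b.x1 - pad), b.x2 + pad
    patch = stack[b.section][y1:y2, x1:x2]
    gt = truth.masks[b.section][y1:y2, x1:x2]
    mask = segment_cleft(patch, rng_seed=0,
                         box=(b.x1 - x1, b.y1 - y1, b.x2 - x1, b.y2 - y1))
    assert jaccard(mask, gt) >= 0.6


def test_segment_cleft_blank_patch_is_empty():
    patch = np.full((60, 60), 150, dtype=np.uint8)
    mask = segment_cleft(patch, rng_seed=0)
    assert mask.shape == patch.shape
    assert mask.sum() == 0


def test_segment_boxes_assembles_label_stack(small_synth):
    from synrec import segment_boxes
    from synrec.config import preset

    cfg, stack, truth = small_synth
    pipeline_cfg = preset("synthetic")
    labels = segment_boxes(stack, truth.boxes[:3], pipeline_cfg, seed=0)
    assert labels.data.shape == stack.data.shape
    assert set(np.unique(labels.data)) <= {0, 1}
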