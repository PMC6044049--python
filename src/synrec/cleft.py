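"""Synaptic-cleft segmentation inside a detection box.

The cleft is the dark, narrow, ribbon-like gap between the presynaptic and
postsynaptic membranes.  Segmentation proceeds in stages:

1. adaptive binarization of dark pixels, then a morphological opening, to
   roughly locate the cleft;
2. a quadratic curve ``y = a x^2 + b x + c`` fit to randomly sampled
   foreground pixels — cleft shapes are well approximated by parabolas;
3. endpoints taken at the two ends of the fitted curve, joined by a
   Dijkstra shortest path over an intensity-weighted 8-connected pixel
   grid, so the path hugs the dark cleft;
4. GrabCut: iterative Gibbs-energy minimization with per-class
   full-covariance Gaussian mixture models and an exact graph min-cut,
   seeded with the path pixels as sure-foreground and sampled
   path-distant pixels as sure-background.

All pixel coordinates in this module are ``(row, col)``; curve algebra uses
``x = col`` and ``y = row``.
"""
from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label as cc_label
from sklearn.cluster import KMeans

logger = logging.getLogger("synrec")

# trimap labels
TRIMAP_BG = 0  #: sure background (T_B)
TRIMAP_FG = 1  #: sure synapse (T_S)
TRIMAP_UNKNOWN = 2  #: undecided (T_U)

_SQRT2 = math.sqrt(2.0)
_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateMaskError(ValueError):
    """Too few foreground pixels to fit a curve (< 3)."""


@dataclass
class SegmentationConfig:
    """Tunable parameters of the cleft-segmentation stage.

    Intensity units refer to the 8-bit scale.  ``grabcut_iters`` and
    ``gmm_components`` are the iteration budget T_G and per-class GMM size
    K (defaults 10 and 5).
    """

    block_size: int = 51        # adaptive-threshold neighbourhood (odd px)
    offset: float = 10.0        # darker than local mean by this much
    morph_iters: int = 1        # opening iterations
    path_eps: float = 0.01      # additive step cost so bright paths stay finite
    d_bg: float = 8.0           # background samples keep this distance from the path
    bg_fraction: float = 0.1    # background seed count = fraction * box area
    grabcut_iters: int = 10     # T_G
    gmm_components: int = 5     # K
    gamma: float = 50.0         # smoothness weight
    pad: int = 10               # context pixels around the box when cropping


# ---------------------------------------------------------------------------
# stage 1: binarization + morphology


def binarize_adaptive(
    patch: np.ndarray, block_size: int = 51, offset: float = 10.0
) -> np.ndarray:
    """Mark pixels darker than their local mean minus ``offset`` as foreground.

    The cleft is dark, so foreground is ``patch < local_mean - offset``
    computed over a ``block_size`` neighbourhood.
    """
    img = np.asarray(patch, dtype=float)
    if img.size == 0:
        raise ValueError("empty patch")
    block = min(block_size, img.shape[0] | 1, img.shape[1] | 1)
    if block % 2 == 0:
        block -= 1
    block = max(block, 3)
    loc = threshold_local(img, block, method="mean", offset=offset)
    return (img < loc).astype(np.uint8)


def morph_clean(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological opening (erode then dilate, elliptical 3x3 element).

    Removes single-pixel speckle while preserving ribbon-scale components
    up to boundary effects.
    """
    out = np.asarray(mask).astype(bool)
    selem = ndimage.generate_binary_structure(2, 1)  # elliptical/cross 3x3
    out = ndimage.binary_erosion(out, selem, iterations=iterations)
    out = ndimage.binary_dilation(out, selem, iterations=iterations)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# stage 2: quadratic curve fit


@dataclass
class QuadraticCurve:
    """``y = a x^2 + b x + c`` in patch coordinates plus the sampled points."""

    a: float
    b: float
    c: float
    m: int
    points: np.ndarray = field(repr=False)  # (m, 2) sampled (x, y)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.square(x) + self.b * np.asarray(x, dtype=float) + self.c


def fit_quadratic(mask: np.ndarray, rng_seed: int = 0) -> QuadraticCurve:
    """Least-squares parabola through randomly sampled foreground pixels.

    ``m = max(3, round(W / 3))`` points (W = foreground pixel count) are
    drawn uniformly without replacement; the fit minimizes
    ``sum (y_i - a x_i^2 - b x_i - c)^2``.  Deterministic given
    ``rng_seed``.
    """
    rows, cols = np.nonzero(np.asarray(mask))
    w = rows.size
    if w < 3:
        raise DegenerateMaskError(f"need >= 3 foreground pixels to fit, got {w}")
    m = max(3, round(w / 3))
    rng = np.random.default_rng(rng_seed)
    sel = rng.choice(w, size=min(m, w), replace=False)
    xs = cols[sel].astype(float)
    ys = rows[sel].astype(float)
    if np.unique(xs).size < 3:
        # vertical ribbon: a parabola in x is ill-posed; report the flat
        # curve through the mean and let endpoint selection fall back
        return QuadraticCurve(0.0, 0.0, float(ys.mean()), m=int(sel.size),
                              points=np.column_stack([xs, ys]))
    design = np.column_stack([xs**2, xs, np.ones_like(xs)])
    coeffs, *_ = np.linalg.lstsq(design, ys, rcond=None)
    return QuadraticCurve(float(coeffs[0]), float(coeffs[1]), float(coeffs[2]),
                          m=int(sel.size), points=np.column_stack([xs, ys]))


def curve_endpoints(
    curve: QuadraticCurve, mask: np.ndarray
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pick the path endpoints from the two ends of the fitted curve.

    ``p_1`` is the foreground pixel nearest the curve evaluated at the
    minimum foreground x, ``p_n`` nearest the curve at the maximum x.  If
    all foreground sits in one column (vertical cleft), endpoints fall back
    to the min-/max-row foreground pixels.  Returned as (row, col).
    """
    rows, cols = np.nonzero(np.asarray(mask))
    if rows.size < 2:
        raise DegenerateMaskError("need >= 2 foreground pixels for endpoints")

    def nearest(target_x: float, target_y: float) -> tuple[int, int]:
        d2 = (cols - target_x) ** 2 + (rows - target_y) ** 2
        i = int(np.argmin(d2))
        return int(rows[i]), int(cols[i])

    xmin, xmax = int(cols.min()), int(cols.max())
    if xmin == xmax:
        i1 = int(np.argmin(rows))
        i2 = int(np.argmax(rows))
        p1 = (int(rows[i1]), int(cols[i1]))
        pn = (int(rows[i2]), int(cols[i2]))
    else:
        p1 = nearest(xmin, float(curve(xmin)))
        pn = nearest(xmax, float(curve(xmax)))
    if p1 == pn:
        # tiny masks: force distinct extremes
        order = np.lexsort((rows, cols))
        p1 = (int(rows[order[0]]), int(cols[order[0]]))
        pn = (int(rows[order[-1]]), int(cols[order[-1]]))
    return p1, pn


# ---------------------------------------------------------------------------
# stage 3: shortest path


def pixel_step_cost(patch: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Per-pixel entry cost ``w(q) = intensity(q)/max + eps``."""
    img = np.asarray(patch, dtype=float)
    mx = img.max()
    base = img / mx if mx > 0 else np.zeros_like(img)
    return base + eps


def shortest_cleft_path(
    patch: np.ndarray,
    p1: tuple[int, int],
    pn: tuple[int, int],
    eps: float = 0.01,
) -> list[tuple[int, int]]:
    """Dijkstra shortest path between two pixels on the 8-connected grid.

    Stepping onto pixel ``q`` costs ``w(q) = intensity(q)/max + eps``
    (diagonal steps scaled by sqrt(2)), so dark cleft pixels are cheap and
    the minimum-cost path traces the cleft.  The returned path is simple
    and consecutive pixels are 8-neighbors.
    """
    w = pixel_step_cost(patch, eps)
    h, wd = w.shape
    for p in (p1, pn):
        if not (0 <= p[0] < h and 0 <= p[1] < wd):
            raise ValueError(f"endpoint {p} outside patch of shape {(h, wd)}")
    dist = np.full((h, wd), np.inf)
    pred = np.full((h, wd, 2), -1, dtype=np.int32)
    dist[p1] = 0.0
    heap: list[tuple[float, int, int]] = [(0.0, p1[0], p1[1])]
    while heap:
        d, r, c = heapq.heappop(heap)
        if (r, c) == pn:
            break
        if d > dist[r, c]:
            continue
        for dr, dc in _NEIGHBORS8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < wd):
                continue
            step = _SQRT2 if dr and dc else 1.0
            nd = d + w[nr, nc] * step
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                pred[nr, nc] = (r, c)
                heapq.heappush(heap, (nd, nr, nc))
    path = [pn]
    while path[-1] != p1:
        r, c = path[-1]
        pr, pc = pred[r, c]
        if pr < 0:
            raise RuntimeError("shortest path search failed to reach the start")
        path.append((int(pr), int(pc)))
    path.reverse()
    return path


def path_cost(patch: np.ndarray, path: list[tuple[int, int]], eps: float = 0.01) -> float:
    """Cost of a concrete path under the same weighting as the search."""
    w = pixel_step_cost(patch, eps)
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        step = _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
        total += w[r1, c1] * step
    return total


# ---------------------------------------------------------------------------
# stage 4: trimap + GrabCut


def init_trimap(
    patch_shape: tuple[int, int],
    box: tuple[int, int, int, int],
    path: list[tuple[int, int]],
    rng_seed: int = 0,
    n_bg: int | None = None,
    d_bg: float = 8.0,
) -> np.ndarray:
    """Seed the GrabCut trimap from the shortest path.

    The path pixels (their own skeleton) become sure-foreground T_S; pixels
    outside the detection ``box`` (half-open ``(x1, y1, x2, y2)`` in patch
    coordinates) plus ``n_bg`` randomly sampled in-box pixels farther than
    ``d_bg`` from the path become sure-background T_B; the rest is unknown
    T_U.  ``n_bg`` defaults to 10% of the box area.  Deterministic given
    ``rng_seed``.
    """
    if not path:
        raise ValueError("cannot seed a trimap from an empty path")
    h, w = patch_shape
    x1, y1, x2, y2 = box
    trimap = np.full((h, w), TRIMAP_BG, dtype=np.uint8)
    trimap[y1:y2, x1:x2] = TRIMAP_UNKNOWN

    path_mask = np.zeros((h, w), dtype=bool)
    rr = [p[0] for p in path]
    cc = [p[1] for p in path]
    path_mask[rr, cc] = True
    trimap[path_mask] = TRIMAP_FG

    if n_bg is None:
        n_bg = int(round(0.1 * (x2 - x1) * (y2 - y1)))
    dist_to_path = ndimage.distance_transform_edt(~path_mask)
    inside = np.zeros((h, w), dtype=bool)
    inside[y1:y2, x1:x2] = True
    d = float(d_bg)
    cand = inside & ~path_mask & (dist_to_path > d)
    while not cand.any() and d > 1:
        d /= 2.0  # tiny boxes: relax the stand-off so some background exists
        cand = inside & ~path_mask & (dist_to_path > d)
    cand_idx = np.flatnonzero(cand)
    if n_bg > 0 and cand_idx.size:
        rng = np.random.default_rng(rng_seed)
        chosen = rng.choice(cand_idx, size=min(n_bg, cand_idx.size), replace=False)
        trimap.ravel()[chosen] = TRIMAP_BG
    return trimap


@dataclass
class ClassGMM:
    """One class's K-component full-covariance Gaussian mixture.

    With single-channel EM patches the features are 1-D and the full
    covariances degenerate to scalar variances; the code path is written
    for general D.  Components with zero weight are inactive and carry
    infinite energy.
    """

    weights: np.ndarray  # (K,)
    means: np.ndarray    # (K, D)
    covs: np.ndarray     # (K, D, D)

    @property
    def n_components(self) -> int:
        return self.weights.size


@dataclass
class GrabCutModel:
    """The pair of per-class mixtures (synapse, background)."""

    fg: ClassGMM
    bg: ClassGMM


def component_energies(values: np.ndarray, model: ClassGMM) -> np.ndarray:
    """Energy ``G_k(n) = -log p(alpha_n | k) - log pi_k`` for every component.

    Returns an ``(N, K)`` array; zero-weight components get ``+inf`` so they
    are never selected by the assignment step.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    if vals.shape[0] == 1 and vals.shape[1] != 1 and model.means.shape[1] == 1:
        vals = vals.T
    n, d = vals.shape
    k = model.n_components
    out = np.full((n, k), np.inf)
    for j in range(k):
        if model.weights[j] <= 0:
            continue
        cov = model.covs[j]
        sign, logdet = np.linalg.slogdet(cov)
        inv = np.linalg.inv(cov)
        diff = vals - model.means[j]
        mahal = np.einsum("ni,ij,nj->n", diff, inv, diff)
        out[:, j] = (
            0.5 * (d * math.log(2 * math.pi) + logdet + mahal)
            - math.log(model.weights[j])
        )
    return out


def data_term(
    values: np.ndarray,
    labels: np.ndarray,
    comps: np.ndarray,
    model: GrabCutModel,
) -> float:
    """Gibbs data term ``D = sum_n G(beta_n, k_n, theta, alpha_n)``.

    ``labels`` are per-pixel classes (1 = synapse), ``comps`` the per-pixel
    component assignments within the pixel's class.
    """
    e_fg = component_energies(values, model.fg)
    e_bg = component_energies(values, model.bg)
    n = np.arange(labels.size)
    per_pixel = np.where(labels.astype(bool), e_fg[n, comps], e_bg[n, comps])
    return float(per_pixel.sum())


def _fit_class(
    values: np.ndarray, assignments: np.ndarray, k: int, reg: float = 1e-6
) -> ClassGMM:
    """Closed-form per-component refit (ML) given component assignments."""
    vals = values.reshape(len(values), -1).astype(float)
    d = vals.shape[1]
    weights = np.zeros(k)
    means = np.zeros((k, d))
    covs = np.tile(np.eye(d), (k, 1, 1))
    total = len(vals)
    for j in range(k):
        sel = assignments == j
        nj = int(sel.sum())
        if nj == 0:
            continue
        weights[j] = nj / total
        means[j] = vals[sel].mean(axis=0)
        diff = vals[sel] - means[j]
        covs[j] = diff.T @ diff / nj + reg * np.eye(d)
    return ClassGMM(weights=weights, means=means, covs=covs)


def _init_class(values: np.ndarray, k: int, seed: int) -> ClassGMM:
    vals = values.reshape(len(values), -1).astype(float)
    k_eff = int(min(k, np.unique(vals, axis=0).shape[0], len(vals)))
    if k_eff <= 1:
        assignments = np.zeros(len(vals), dtype=int)
    else:
        km = KMeans(n_clusters=k_eff, n_init=2, random_state=seed)
        assignments = km.fit_predict(vals)
    return _fit_class(vals, assignments, k)


def _smoothness_structure(patch: np.ndarray, gamma: float):
    """Precompute 8-neighbour pair indices and contrast-sensitive weights.

    Weight of pair (m, n): ``gamma * dist(m,n)^-1 * exp(-beta (a_m - a_n)^2)``
    with ``beta = 1 / (2 <(a_m - a_n)^2>)`` averaged over adjacent pairs.
    """
    img = np.asarray(patch, dtype=float)
    h, w = img.shape
    idx = np.arange(h * w).reshape(h, w)
    pa, pb, dist = [], [], []
    for dr, dc, step in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)):
        if dc >= 0:
            a = idx[: h - dr or None, : w - dc or None]
            b = idx[dr:, dc:]
        else:
            a = idx[: h - dr, -dc:]
            b = idx[dr:, :dc]
        pa.append(a.ravel())
        pb.append(b.ravel())
        dist.append(np.full(a.size, step))
    pa = np.concatenate(pa)
    pb = np.concatenate(pb)
    dist = np.concatenate(dist)
    flat = img.ravel()
    diff2 = (flat[pa] - flat[pb]) ** 2
    mean_diff2 = diff2.mean() if diff2.size else 0.0
    beta = 1.0 / (2.0 * mean_diff2) if mean_diff2 > 0 else 0.0
    weights = gamma / dist * np.exp(-beta * diff2)
    return pa, pb, weights


_HARD = 1e12  # terminal capacity enforcing seed constraints


def grabcut(
    patch: np.ndarray,
    trimap: np.ndarray,
    n_components: int = 5,
    n_iters: int = 10,
    gamma: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[float]]:
    """Iterative Gibbs-energy minimization (GrabCut) on a grayscale patch.

    Each iteration (i) assigns every pixel its best mixture component
    within its current class, (ii) refits both K-component GMMs in closed
    form, and (iii) minimizes the energy over the labeling exactly by an
    s-t min-cut on the 8-connected grid with contrast-sensitive pairwise
    weights.  Sure-foreground and sure-background seeds are hard
    constraints.  Returns the final binary mask and the energy after every
    iteration (non-increasing by construction of the coordinate descent).
    """
    img = np.asarray(patch, dtype=float)
    tri = np.asarray(trimap)
    if img.shape != tri.shape:
        raise ValueError("patch and trimap shapes differ")
    fg_seed = (tri == TRIMAP_FG).ravel()
    bg_seed = (tri == TRIMAP_BG).ravel()
    if not fg_seed.any() or not bg_seed.any():
        raise ValueError("GrabCut needs nonempty foreground and background seeds")
    values = img.ravel()
    n = values.size

    pa, pb, pw = _smoothness_structure(img, gamma)

    # static graph: pixels 0..n-1, source n, sink n+1; only capacities change
    src, sink = n, n + 1
    edges = (
        [(int(a), int(b)) for a, b in zip(pa, pb)]
        + [(src, i) for i in range(n)]
        + [(i, sink) for i in range(n)]
    )
    graph = igraph.Graph(n + 2, edges, directed=False)

    # unknown pixels start as background; the foreground model is fit from
    # the path seeds, the background model from everything else
    labels = fg_seed.copy()
    fg_model = _init_class(values[labels], n_components, seed)
    bg_model = _init_class(values[~labels], n_components, seed)

    trace: list[float] = []
    for _ in range(n_iters):
        e_fg = component_energies(values, fg_model)
        e_bg = component_energies(values, bg_model)
        k_fg = np.argmin(e_fg, axis=1)
        k_bg = np.argmin(e_bg, axis=1)

        if labels.any():
            fg_model = _fit_class(values[labels], k_fg[labels], n_components)
        else:
            fg_model = _fit_class(values[fg_seed], k_fg[fg_seed], n_components)
        if (~labels).any():
            bg_model = _fit_class(values[~labels], k_bg[~labels], n_components)
        else:
            bg_model = _fit_class(values[bg_seed], k_bg[bg_seed], n_components)

        e_fg = component_energies(values, fg_model).min(axis=1)
        e_bg = component_energies(values, bg_model).min(axis=1)

        cap_src = e_bg.copy()   # cut when the pixel ends up background
        cap_sink = e_fg.copy()  # cut when the pixel ends up foreground
        cap_src[fg_seed] = _HARD
        cap_sink[fg_seed] = 0.0
        cap_sink[bg_seed] = _HARD
        cap_src[bg_seed] = 0.0

        caps = np.concatenate([pw, cap_src, cap_sink])
        cut = graph.st_mincut(src, sink, capacity=caps.tolist())
        part0, _part1 = cut.partition
        side = np.zeros(n + 2, dtype=bool)
        side[np.asarray(part0, dtype=int)] = True
        labels = side[:n] if side[src] else ~side[:n]
        labels = labels.copy()
        labels[fg_seed] = True
        labels[bg_seed] = False

        energy = (
            float(e_fg[labels].sum() + e_bg[~labels].sum())
            + float(pw[labels[pa] != labels[pb]].sum())
        )
        trace.append(energy)

    return labels.reshape(img.shape).astype(np.uint8), trace


# ---------------------------------------------------------------------------
# full composition


def segment_cleft(
    patch: np.ndarray,
    rng_seed: int = 0,
    config: SegmentationConfig | None = None,
    box: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Segment the synaptic cleft in one detection patch.

    Runs the full binarize -> morphology -> curve fit -> shortest path ->
    trimap -> GrabCut composition and keeps only the output components
    touched by the foreground seed path.  When the morphological mask is
    degenerate (< 3 foreground pixels) it is returned directly.  Always
    returns a mask (possibly empty) of the patch shape.
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(patch)
    mask = morph_clean(
        binarize_adaptive(img, cfg.block_size, cfg.offset), cfg.morph_iters
    )
    if int(mask.sum()) < 3:
        logger.info("segment: degenerate mask (%d px), morphological fallback",
                    int(mask.sum()))
        return mask
    curve = fit_quadratic(mask, rng_seed)
    p1, pn = curve_endpoints(curve, mask)
    path = shortest_cleft_path(img, p1, pn, eps=cfg.path_eps)
    if box is None:
        box = (0, 0, img.shape[1], img.shape[0])
    trimap = init_trimap(img.shape, box, path, rng_seed, d_bg=cfg.d_bg,
                         n_bg=int(round(cfg.bg_fraction * (box[2] - box[0]) * (box[3] - box[1]))))
    out, _trace = grabcut(img, trimap, cfg.gmm_components, cfg.grabcut_iters,
                          cfg.gamma, seed=rng_seed)

    # keep only components the seed path touches
    lab = cc_label(out > 0, connectivity=2)
    keep = np.unique([lab[r, c] for r, c in path])
    keep = keep[keep > 0]
    filtered = np.isin(lab, keep).astype(np.uint8)
    return filtered
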