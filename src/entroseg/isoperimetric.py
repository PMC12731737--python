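"""Pixel-graph machinery validating the max-min threshold criterion.

The image is a 4-connected undirected graph on its pixels with normalized
edge weights

    w_ij = exp(-beta (I_i - I_j)^2) / sum_over_edges exp(-beta (I_m - I_n)^2),

intensities rescaled to [0, 1] first so beta is image-depth independent.
A threshold t induces the partition S_t = {pixels <= t}; its cut, volumes
and isoperimetric ratio h(S_t) = cut / min(vol S, vol S-bar) are computed
per t.  Because the weights sum to 1 the cut never exceeds 1, which bounds
the entropy-substituted ratio cut / min(S_A, S_r_B) by 1 / min(S_A, S_r_B)
— the inequality behind using argmax_t min(S_A(t), S_r_B(t)) as the
threshold criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .criteria import _masi_transform, _shannon_curves
from .image import GrayImage, compute_histogram

__all__ = ["PixelGraph", "PartitionStats", "MaxMinBoundReport",
           "build_pixel_graph", "partition_stats", "check_maxmin_bound"]


@dataclass(frozen=True)
class PixelGraph:
    shape: tuple[int, int]
    edges_u: np.ndarray  # flat pixel index of one endpoint per edge
    edges_v: np.ndarray
    weights: np.ndarray
    degrees: np.ndarray  # flat, per pixel
    beta: float


@dataclass(frozen=True)
class PartitionStats:
    t: int
    cut: float
    vol_s: float
    vol_s_complement: float
    ratio: float | None  # None when a side is empty


@dataclass(frozen=True)
class MaxMinBoundReport:
    r: float
    t_values: np.ndarray
    min_entropy: np.ndarray       # min(S_A, S_r_B) per t (NaN if invalid)
    cut: np.ndarray
    entropy_ratio: np.ndarray     # cut / min-entropy
    bound: np.ndarray             # 1 / min-entropy
    bound_holds: np.ndarray       # entropy_ratio <= bound at valid t
    t_argmax_minentropy: int
    t_min_entropy_ratio: int


def build_pixel_graph(img: GrayImage, beta: float = 10.0) -> PixelGraph:
    """4-connectivity graph with normalized Gaussian-of-contrast weights."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    n, m = img.shape
    if n * m < 2:
        raise ValueError("graph needs at least two pixels")
    intens = img.pixels.astype(float) / img.max_level
    idx = np.arange(n * m).reshape(n, m)

    us, vs = [], []
    if m > 1:
        us.append(idx[:, :-1].ravel())
        vs.append(idx[:, 1:].ravel())
    if n > 1:
        us.append(idx[:-1, :].ravel())
        vs.append(idx[1:, :].ravel())
    u = np.concatenate(us)
    v = np.concatenate(vs)

    flat = intens.ravel()
    raw = np.exp(-beta * (flat[u] - flat[v]) ** 2)
    w = raw / raw.sum()

    deg = np.zeros(n * m)
    np.add.at(deg, u, w)
    np.add.at(deg, v, w)
    return PixelGraph(shape=(n, m), edges_u=u, edges_v=v, weights=w,
                      degrees=deg, beta=beta)


def partition_stats(g: PixelGraph, img: GrayImage, t: int) -> PartitionStats:
    """Cut, volumes and isoperimetric ratio of the partition S_t = {I <= t}."""
    if g.shape != img.shape:
        raise ValueError("graph and image shapes differ")
    in_s = (img.pixels.ravel() <= t)
    boundary = in_s[g.edges_u] != in_s[g.edges_v]
    cut = float(g.weights[boundary].sum())
    vol_s = float(g.degrees[in_s].sum())
    vol_sc = float(g.degrees[~in_s].sum())
    smaller = min(vol_s, vol_sc)
    ratio = cut / smaller if smaller > 0 else None
    return PartitionStats(t=t, cut=cut, vol_s=vol_s,
                          vol_s_complement=vol_sc, ratio=ratio)


def check_maxmin_bound(g: PixelGraph, img: GrayImage, r: float,
                       form: int = 1) -> MaxMinBoundReport:
    """Per-threshold check of the normalized-cut bound.

    For every valid t it verifies cut(S_t) / min(S_A, S_r_B) <= 1 /
    min(S_A, S_r_B) (equivalent to cut <= 1, guaranteed by weight
    normalization) and reports both the t maximizing the min-entropy (the
    max-min criterion's pick) and the t minimizing the entropy ratio.
    """
    h = compute_histogram(img)
    s_a, s_b, nonempty = _shannon_curves(h)
    if form == 1:
        m_b, ok_m = _masi_transform(s_b, r)
        minent = np.minimum(s_a, m_b)
    else:
        m_a, ok_m = _masi_transform(s_a, r)
        minent = np.minimum(m_a, s_b)
    valid = nonempty & ok_m

    ts = np.arange(h.max_level)
    cut = np.full(ts.shape, np.nan)
    for t in ts[valid]:
        cut[t] = partition_stats(g, img, int(t)).cut
    # ratio and bound are only meaningful where the min-entropy is positive
    defined = valid & (minent > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, cut / minent, np.nan)
        bound = np.where(defined, 1.0 / minent, np.nan)
    holds = np.zeros(ts.shape, dtype=bool)
    holds[valid] = (cut[valid] <= 1.0 + 1e-12)
    holds[defined] &= ratio[defined] <= bound[defined] + 1e-12

    minent_masked = np.where(valid, minent, -np.inf)
    t_star = int(np.argmax(minent_masked))
    ratio_masked = np.where(defined, ratio, np.inf)
    t_ratio = int(np.argmin(ratio_masked)) if defined.any() else -1
    return MaxMinBoundReport(
        r=r, t_values=ts, min_entropy=np.where(valid, minent, np.nan),
        cut=cut, entropy_ratio=ratio, bound=bound, bound_holds=holds,
        t_argmax_minentropy=t_star, t_min_entropy_ratio=t_ratio,
    )
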