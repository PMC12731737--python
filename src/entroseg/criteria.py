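"""Exhaustive bi-level threshold selection under five entropy criteria.

Criteria
--------
``shannon``      Kapur: maximize S(A) + S(B).
``tsallis``      Albuquerque: maximize S_q(A) + S_q(B) + (1-q) S_q(A) S_q(B).
``masi``         Nie et al.: maximize S_r(A) + S_r(B).
``linou``        Lin & Ou max-min: form 1 maximizes min(S(A), S_q(B)),
                 form 2 maximizes min(S_q(A), S(B)).
``maxmin_masi``  The Masi/Shannon max-min: form 1 maximizes min(S(A), S_r(B)),
                 form 2 maximizes min(S_r(A), S(B)).

Candidate thresholds are t in {0 .. L-1} with both classes non-empty; level
t itself belongs to the background class A.  Masi-invalid candidates are
excluded from the argmax but kept (flagged) in the exported objective trace.
Ties break to the smallest maximizing t.

Class entropies for all t are computed at once from cumulative sums:
with P_A(t) = sum_{i<=t} p_i and C(t) = sum_{i<=t} p_i ln p_i,

    S_A(t) = ln P_A(t) - C(t) / P_A(t)

and analogously for B; Tsallis uses cumulative sums of p_i^q, Masi is the
pointwise transform ln(1 + (1-r) S) / (1-r) of the Shannon curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .entropy import NEAR_ONE_TOL
from .image import BinaryMask, GrayImage, Histogram, binarize, compute_histogram
from .metrics import misclassification_error

__all__ = [
    "ThresholdResult",
    "GridSearchResult",
    "NoValidThresholdError",
    "kapur_threshold",
    "tsallis_threshold",
    "masi_threshold",
    "linou_threshold",
    "proposed_threshold",
    "threshold_by_method",
    "grid_search_param",
]


class NoValidThresholdError(ValueError):
    """No candidate t is valid (degenerate histogram or Masi domain empty)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of an exhaustive criterion search.

    ``objective_trace[t]`` holds the objective at every candidate t (NaN
    where invalid), ``valid[t]`` the validity flag, and ``ties`` every t
    attaining the maximum; ``t_opt`` is the smallest of them.
    """

    t_opt: int
    method: str
    param: float | None
    form: int | None
    objective_trace: np.ndarray
    valid: np.ndarray
    ties: tuple[int, ...]

    @property
    def objective_at_opt(self) -> float:
        return float(self.objective_trace[self.t_opt])


@dataclass(frozen=True)
class GridSearchResult:
    best_param: float
    grid: tuple[float, ...]
    score_per_param: tuple[float, ...]


def _class_masses(h: Histogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(nonempty, P_A, P_B) over candidates t = 0..L-1.

    Emptiness is decided on exact integer counts, not float mass.
    """
    ca = np.cumsum(h.counts)[:-1]
    nonempty = (ca > 0) & (ca < h.total_pixels)
    p_a = ca / h.total_pixels
    p_b = 1.0 - p_a
    return nonempty, p_a, p_b


def _shannon_curves(h: Histogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shannon class entropies S_A(t), S_B(t) for all t, plus validity."""
    nonempty, p_a, p_b = _class_masses(h)
    p = h.probs
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    c = np.cumsum(plogp)[:-1]
    total = plogp.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        s_a = np.where(nonempty, np.log(np.where(p_a > 0, p_a, 1.0)) - c / p_a, np.nan)
        s_b = np.where(nonempty, np.log(np.where(p_b > 0, p_b, 1.0)) - (total - c) / p_b, np.nan)
    return s_a, s_b, nonempty


def _tsallis_curves(h: Histogram, q: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if abs(q - 1.0) < NEAR_ONE_TOL:
        return _shannon_curves(h)
    nonempty, p_a, p_b = _class_masses(h)
    p = h.probs
    pq = np.where(p > 0, np.power(np.where(p > 0, p, 1.0), q), 0.0)
    cq = np.cumsum(pq)[:-1]
    total = pq.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        s_a = np.where(nonempty, (cq / np.power(p_a, q) - 1.0) / (1.0 - q), np.nan)
        s_b = np.where(nonempty, ((total - cq) / np.power(p_b, q) - 1.0) / (1.0 - q), np.nan)
    return s_a, s_b, nonempty


def _masi_transform(s: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Masi curve from a Shannon curve; returns (values, domain-validity)."""
    if abs(r - 1.0) < NEAR_ONE_TOL:
        return s, np.isfinite(s)
    arg = 1.0 + (1.0 - r) * s
    ok = np.isfinite(arg) & (arg > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ok, np.log(np.where(ok, arg, 1.0)) / (1.0 - r), np.nan)
    return out, ok


def _argmax_result(objective: np.ndarray, valid: np.ndarray, method: str,
                   param: float | None, form: int | None) -> ThresholdResult:
    objective = np.where(valid, objective, np.nan)
    if not valid.any():
        raise NoValidThresholdError(
            f"no valid threshold candidate for method={method}, param={param}"
        )
    best = np.nanmax(objective)
    ties = tuple(int(t) for t in np.flatnonzero(valid & (objective == best)))
    return ThresholdResult(
        t_opt=ties[0], method=method, param=param, form=form,
        objective_trace=objective, valid=valid, ties=ties,
    )


def kapur_threshold(h: Histogram) -> ThresholdResult:
    """Maximize the summed Shannon entropy of the two classes."""
    s_a, s_b, ok = _shannon_curves(h)
    return _argmax_result(s_a + s_b, ok, "shannon", None, None)


def tsallis_threshold(h: Histogram, q: float) -> ThresholdResult:
    """Maximize the pseudo-additive two-class Tsallis objective."""
    s_a, s_b, ok = _tsallis_curves(h, q)
    if abs(q - 1.0) < NEAR_ONE_TOL:
        obj = s_a + s_b
    else:
        obj = s_a + s_b + (1.0 - q) * s_a * s_b
    return _argmax_result(obj, ok, "tsallis", q, None)


def masi_threshold(h: Histogram, r: float) -> ThresholdResult:
    """Maximize S_r(A) + S_r(B); Masi-invalid candidates are excluded."""
    s_a, s_b, ok = _shannon_curves(h)
    m_a, ok_a = _masi_transform(s_a, r)
    m_b, ok_b = _masi_transform(s_b, r)
    valid = ok & ok_a & ok_b
    return _argmax_result(m_a + m_b, valid, "masi", r, None)


def linou_threshold(h: Histogram, q: float, form: int = 1) -> ThresholdResult:
    """Lin & Ou max-min of Shannon and Tsallis class entropies.

    Form 1: maximize min(S(A), S_q(B)); form 2: maximize min(S_q(A), S(B)).
    """
    if form not in (1, 2):
        raise ValueError("form must be 1 or 2")
    s_a, s_b, ok = _shannon_curves(h)
    t_a, t_b, _ = _tsallis_curves(h, q)
    obj = np.minimum(s_a, t_b) if form == 1 else np.minimum(t_a, s_b)
    return _argmax_result(obj, ok, "linou", q, form)


def proposed_threshold(h: Histogram, r: float, form: int = 1) -> ThresholdResult:
    """Masi/Shannon max-min criterion.

    Form 1: maximize min(S(A), S_r(B)) -- Shannon on the background, Masi on
    the object.  Form 2 interleaves: maximize min(S_r(A), S(B)).  Candidates
    where the Masi term leaves its domain are invalid.
    """
    if form not in (1, 2):
        raise ValueError("form must be 1 or 2")
    s_a, s_b, ok = _shannon_curves(h)
    if form == 1:
        m_b, ok_m = _masi_transform(s_b, r)
        obj = np.minimum(s_a, m_b)
    else:
        m_a, ok_m = _masi_transform(s_a, r)
        obj = np.minimum(m_a, s_b)
    return _argmax_result(obj, ok & ok_m, "maxmin_masi", r, form)


def threshold_by_method(h: Histogram, method: str, param: float | None = None,
                        form: int = 1) -> ThresholdResult:
    """Dispatch a criterion by name (CLI / grid-search entry point)."""
    if method == "shannon":
        return kapur_threshold(h)
    if param is None:
        raise ValueError(f"method {method!r} requires an entropic parameter")
    if method == "tsallis":
        return tsallis_threshold(h, param)
    if method == "masi":
        return masi_threshold(h, param)
    if method == "linou":
        return linou_threshold(h, param, form)
    if method == "maxmin_masi":
        return proposed_threshold(h, param, form)
    raise ValueError(f"unknown method {method!r}")


def grid_search_param(
    img: GrayImage,
    gt: BinaryMask,
    method: str,
    grid: Sequence[float],
    form: int = 1,
    invert: bool = False,
    refine: bool = False,
) -> GridSearchResult:
    """Pick the entropic parameter on a grid by minimizing ME against gt.

    Parameters with no valid threshold are skipped (NaN score); ties break
    to the smaller parameter.  ``refine=True`` adds one bisection pass
    sampling the midpoints between the best coarse cell and its neighbours.
    """
    if gt.shape != img.shape:
        raise ValueError("ground-truth shape does not match image")
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty parameter grid")
    h = compute_histogram(img)

    def score(param: float) -> float:
        try:
            res = threshold_by_method(h, method, param, form)
        except NoValidThresholdError:
            return np.nan
        me, _ = misclassification_error(gt, binarize(img, res.t_opt, invert))
        return me

    scores = [score(g) for g in grid]
    if np.all(np.isnan(scores)):
        raise NoValidThresholdError("no grid value admits a valid threshold")

    order = sorted(range(len(grid)), key=lambda i: (np.nan_to_num(scores[i], nan=np.inf), grid[i]))
    best_i = order[0]

    if refine:
        extra = []
        for j in (best_i - 1, best_i + 1):
            if 0 <= j < len(grid):
                extra.append((grid[best_i] + grid[j]) / 2.0)
        for g in extra:
            s = score(g)
            grid.append(g)
            scores.append(s)
        order = sorted(range(len(grid)), key=lambda i: (np.nan_to_num(scores[i], nan=np.inf), grid[i]))
        best_i = order[0]

    return GridSearchResult(
        best_param=grid[best_i],
        grid=tuple(grid),
        score_per_param=tuple(scores),
    )
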