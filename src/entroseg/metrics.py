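"""Segmentation accuracy and quality measures.

With ground truth: misclassification error (ME), Jaccard similarity (JS, in
percent), relative foreground area error (RAE) and the weighted F-measure.
Without ground truth: the uniformity measure (UM), a score <= 1 built from
intra-region squared intensity deviations.

Empty-set conventions (none of which arise on well-posed inputs) are the
continuity limits: JS with both foregrounds empty is 100, RAE with both
empty is 0, F with an empty predicted foreground is 0 (flagged via P=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import BinaryMask, GrayImage

__all__ = [
    "MetricsReport",
    "misclassification_error",
    "jaccard",
    "relative_area_error",
    "f_measure",
    "uniformity",
    "compute_report",
]


@dataclass(frozen=True)
class MetricsReport:
    me: float | None = None
    misclassified_pixels: int | None = None
    js: float | None = None
    rae: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_alpha: float | None = None
    alpha: float = 0.5
    um: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_shapes(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def misclassification_error(gt: BinaryMask, pred: BinaryMask) -> tuple[float, int]:
    """ME = 1 - (|B_GT & B_T| + |F_GT & F_T|) / total pixels.

    0 for a perfect segmentation, 1 for a totally inverted one.  Returns
    (ME, number of misclassified pixels).
    """
    _check_shapes(gt, pred)
    agree = int((gt.labels == pred.labels).sum())
    total = gt.labels.size
    wrong = total - agree
    return wrong / total, wrong


def jaccard(gt: BinaryMask, pred: BinaryMask) -> float:
    """Jaccard similarity of the foregrounds, in percent (100 = perfect)."""
    _check_shapes(gt, pred)
    inter = int((gt.foreground & pred.foreground).sum())
    union = int((gt.foreground | pred.foreground).sum())
    if union == 0:
        return 100.0
    return 100.0 * inter / union


def relative_area_error(gt: BinaryMask, pred: BinaryMask) -> float:
    """RAE = ||F_GT| - |F_T|| / max(|F_GT|, |F_T|); 0 when areas agree."""
    _check_shapes(gt, pred)
    a = int(gt.foreground.sum())
    b = int(pred.foreground.sum())
    m = max(a, b)
    if m == 0:
        return 0.0
    return abs(a - b) / m


def f_measure(gt: BinaryMask, pred: BinaryMask, alpha: float = 0.5
              ) -> tuple[float, float, float]:
    """Precision, recall and the weighted harmonic mean

    F_alpha = (1 + alpha) P R / (alpha P + R), alpha defaulting to 0.5.
    An empty predicted foreground yields P = 0 and F = 0.
    """
    _check_shapes(gt, pred)
    inter = int((gt.foreground & pred.foreground).sum())
    n_pred = int(pred.foreground.sum())
    n_gt = int(gt.foreground.sum())
    p = inter / n_pred if n_pred else 0.0
    r = inter / n_gt if n_gt else 0.0
    denom = alpha * p + r
    f = (1 + alpha) * p * r / denom if denom > 0 else 0.0
    return p, r, f


def uniformity(img: GrayImage, pred: BinaryMask,
               literal_variance: bool = False) -> float:
    """Uniformity measure  UM = 1 - 2 (s1 + s2) / (N M (Imax - Imin)^2).

    ``s_i`` is the sum of squared deviations from the mean intensity of
    region i (the reading under which N*M normalizes the score into a
    bounded range); ``literal_variance=True`` divides each s_i by the
    region size instead.  A constant image (Imax = Imin) scores 1; an empty
    region contributes 0.  Higher UM means lower intra-region variance.
    """
    if img.shape != pred.shape:
        raise ValueError("image and mask shapes differ")
    px = img.pixels.astype(float)
    i_max, i_min = px.max(), px.min()
    if i_max == i_min:
        return 1.0

    def dev(region: np.ndarray) -> float:
        vals = px[region]
        if vals.size == 0:
            return 0.0
        s = float(((vals - vals.mean()) ** 2).sum())
        return s / vals.size if literal_variance else s

    s1 = dev(pred.background)
    s2 = dev(pred.foreground)
    return 1.0 - 2.0 * (s1 + s2) / (px.size * (i_max - i_min) ** 2)


def compute_report(gt: BinaryMask | None, pred: BinaryMask,
                   img: GrayImage | None = None,
                   alpha: float = 0.5,
                   literal_variance: bool = False) -> MetricsReport:
    """All metrics at once; gt-free reports carry only UM."""
    um = uniformity(img, pred, literal_variance) if img is not None else None
    if gt is None:
        return MetricsReport(um=um, alpha=alpha)
    me, wrong = misclassification_error(gt, pred)
    p, r, f = f_measure(gt, pred, alpha)
    return MetricsReport(
        me=me, misclassified_pixels=wrong,
        js=jaccard(gt, pred),
        rae=relative_area_error(gt, pred),
        precision=p, recall=r, f_alpha=f, alpha=alpha,
        um=um,
    )
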