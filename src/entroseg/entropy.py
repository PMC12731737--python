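"""Shannon, Tsallis and Masi entropies on discrete probability sequences.

All entropies use the natural logarithm (nats).  Tsallis and Masi carry an
entropic parameter (``q`` and ``r``) measuring nonextensivity; both recover
Shannon in the limit -> 1, and values within ``NEAR_ONE_TOL`` of 1 are
routed to the Shannon formula to avoid 1/(1-r) cancellation blow-up.

Masi entropy, S_r = ln(1 + (1-r) S) / (1-r) with S the Shannon entropy, is
only defined where the logarithm argument is positive.  Invalidity is data,
not an exception (:class:`EntropyValue.valid`), so threshold searches can
silently skip invalid (t, r) candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import ClassSplit

__all__ = [
    "EntropyValue",
    "NEAR_ONE_TOL",
    "shannon",
    "tsallis",
    "masi",
    "combined_shannon",
    "combined_tsallis",
    "combined_masi",
]

#: |q - 1| or |r - 1| below this routes to the Shannon limit.
NEAR_ONE_TOL = 1e-6


@dataclass(frozen=True)
class EntropyValue:
    """An entropy with a validity flag (Masi can fall outside its domain)."""

    value: float
    valid: bool = True

    def __float__(self) -> float:
        return self.value


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D probability sequence")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return p


def _shannon_value(p: np.ndarray) -> float:
    # 0 * ln 0 := 0 -- zero-probability entries are dropped.
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon(p) -> EntropyValue:
    """Shannon entropy  S = -sum p_i ln p_i.  Always valid."""
    return EntropyValue(_shannon_value(_check_probs(p)))


def tsallis(p, q: float) -> EntropyValue:
    """Tsallis entropy  S_q = (sum p_i^q - 1) / (1 - q).

    Nonextensive for q != 1; pseudo-additive over independent subsystems.
    Near q = 1 the Shannon limit is returned.  Always valid.
    """
    p = _check_probs(p)
    if abs(q - 1.0) < NEAR_ONE_TOL:
        return EntropyValue(_shannon_value(p))
    nz = p[p > 0]  # 0^q is ill-defined for q <= 0
    return EntropyValue(float((np.power(nz, q).sum() - 1.0) / (1.0 - q)))


def masi(p, r: float) -> EntropyValue:
    """Masi entropy  S_r = ln(1 - (1-r) sum p_i ln p_i) / (1-r).

    Combines Tsallis nonextensivity with Renyi-style additivity.  Defined
    only where the ln argument ``1 + (1-r) S_shannon`` is positive; outside
    that domain an ``EntropyValue`` with ``valid=False`` is returned.
    """
    p = _check_probs(p)
    if r <= 0:
        raise ValueError("Masi parameter r must be positive")
    s = _shannon_value(p)
    if abs(r - 1.0) < NEAR_ONE_TOL:
        return EntropyValue(s)
    arg = 1.0 + (1.0 - r) * s
    if arg <= 0:
        return EntropyValue(math.nan, valid=False)
    return EntropyValue(math.log(arg) / (1.0 - r))


def combined_shannon(split: ClassSplit) -> float:
    """Kapur objective: S(A) + S(B) on the normalized class distributions."""
    return shannon(split.dist_a).value + shannon(split.dist_b).value


def combined_tsallis(split: ClassSplit, q: float) -> float:
    """Two-class Tsallis objective with the pseudo-additive cross term:

    S_q(A) + S_q(B) + (1 - q) S_q(A) S_q(B).
    """
    sa = tsallis(split.dist_a, q).value
    sb = tsallis(split.dist_b, q).value
    if abs(q - 1.0) < NEAR_ONE_TOL:
        return sa + sb
    return sa + sb + (1.0 - q) * sa * sb

def combined_masi(split: ClassSplit, r: float) -> EntropyValue:
    """Two-class Masi objective S_r(A) + S_r(B); invalid if either term is."""
    sa = masi(split.dist_a, r)
    sb = masi(split.dist_b, r)
    if not (sa.valid and sb.valid):
        return EntropyValue(math.nan, valid=False)
    return EntropyValue(sa.value + sb.value)
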