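"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes objectives from first principles, in extended
precision (long double), with explicit loops over thresholds and explicit
class-distribution normalization.  Nothing imports the package's criterion
code paths.
"""

import numpy as np

LD = np.longdouble


def ld(x):
    return np.asarray(x, dtype=LD)


def bf_shannon(p) -> LD:
    p = ld(p)
    nz = p[p > 0]
    return -(nz * np.log(nz)).sum()


def bf_tsallis(p, q: float) -> LD:
    p = ld(p)
    nz = p[p > 0]
    q = LD(q)
    return (np.power(nz, q).sum() - 1) / (1 - q)


def bf_masi(p, r: float):
    """Returns (value, valid)."""
    s = bf_shannon(p)
    r = LD(r)
    arg = 1 + (1 - r) * s
    if arg <= 0:
        return np.nan, False
    return np.log(arg) / (1 - r), True


def bf_split(probs, t):
    """(dist_a, dist_b) or None if a class is empty."""
    probs = ld(probs)
    pa = probs[: t + 1].sum()
    pb = probs[t + 1:].sum()
    if pa <= 0 or pb <= 0:
        return None
    return probs[: t + 1] / pa, probs[t + 1:] / pb


def bf_objective(probs, t, method, param=None, form=1):
    """Objective value at threshold t, or None if invalid there."""
    split = bf_split(probs, t)
    if split is None:
        return None
    da, db = split
    if method == "shannon":
        return bf_shannon(da) + bf_shannon(db)
    if method == "tsallis":
        q = LD(param)
        sa, sb = bf_tsallis(da, q), bf_tsallis(db, q)
        return sa + sb + (1 - q) * sa * sb
    if method == "masi":
        ma, ok_a = bf_masi(da, param)
        mb, ok_b = bf_masi(db, param)
        if not (ok_a and ok_b):
            return None
        return ma + mb
    if method == "linou":
        if form == 1:
            return min(bf_shannon(da), bf_tsallis(db, param))
        return min(bf_tsallis(da, param), bf_shannon(db))
    if method == "maxmin_masi":
        if form == 1:
            mb, ok = bf_masi(db, param)
            if not ok:
                return None
            return min(bf_shannon(da), mb)
        ma, ok = bf_masi(da, param)
        if not ok:
            return None
        return min(ma, bf_shannon(db))
    raise ValueError(method)


def bf_threshold(probs, method, param=None, form=1):
    """Smallest argmax t over all valid candidates, or None if none valid."""
    best_t, best_v = None, None
    for t in range(len(probs) - 1):
        v = bf_objective(probs, t, method, param, form)
        if v is None:
            continue
        if best_v is None or v > best_v:
            best_t, best_v = t, v
    return best_t


def random_histogram_counts(rng, n_levels, max_count=30):
    """Random integer counts with at least two occupied levels."""
    while True:
        counts = rng.integers(0, max_count + 1, size=n_levels)
        if (counts > 0).sum() >= 2:
            return counts
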