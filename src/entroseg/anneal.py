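"""Simulated-annealing search for the Masi entropic parameter r.

The annealer wraps a threshold criterion: at each step it perturbs the
current parameter, r_j = r_hat + U(-d, d), re-solves the exhaustive
threshold search, scores the resulting binarization, and accepts or rejects
the move Metropolis-style under a geometric cooling schedule
T <- T * cooling.  Two guidance modes:

* ground truth available -- minimize the misclassification error (ME);
  early exit as soon as ME <= e_ref (default 0).
* no ground truth -- maximize the uniformity measure (UM); early exit as
  soon as UM >= um_ref (default 1).

Two variants share the shell:

* ``proposed`` -- the Masi/Shannon max-min criterion.  Form 1 runs first;
  if it terminates without meeting the reference score the whole schedule
  is repeated with the interleaved form 2 objective and the better of the
  two results is returned.
* ``masi_only`` -- the inner selection is the plain Masi-sum criterion
  (ablation variant).

Worsening ME moves are accepted with probability exp(-dE/T); worsening UM
moves with exp(dUM/T) (dUM < 0).  By default a candidate is compared with
the score of the currently accepted parameter; ``strict_paper=True``
compares with the previous candidate's score even if it was rejected.
The best (score, r, t) seen anywhere is tracked and returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .criteria import (NoValidThresholdError, ThresholdResult, masi_threshold,
                       proposed_threshold)
from .image import BinaryMask, GrayImage, binarize, compute_histogram
from .metrics import misclassification_error, uniformity

__all__ = ["SAConfig", "SAResult", "TraceRecord",
           "run_algorithm1", "run_algorithm_a1"]


@dataclass(frozen=True)
class SAConfig:
    """Annealer inputs.  Defaults are the reference parameterization:
    r_init 1.5, half-width d 0.1, T 100 -> 1e-3 at cooling 0.99,
    Markov chain length 20, at most 100 temperature levels, reference
    error 0 and reference uniformity 1.
    """

    r_init: float = 1.5
    d: float = 0.1
    t_initial: float = 100.0
    t_min: float = 1e-3
    cooling: float = 0.99
    markov_length: int = 20
    max_iter: int = 100
    e_ref: float = 0.0
    um_ref: float = 1.0
    fix_par: int = 1
    seed: int = 0
    variant: str = "proposed"
    strict_paper: bool = False
    invert: bool = False

    def __post_init__(self) -> None:
        if not (self.t_initial > self.t_min > 0):
            raise ValueError("need t_initial > t_min > 0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")
        if self.markov_length < 1 or self.max_iter < 1:
            raise ValueError("markov_length and max_iter must be >= 1")
        if self.d <= 0:
            raise ValueError("perturbation half-width d must be positive")
        if self.variant not in ("proposed", "masi_only"):
            raise ValueError("variant must be 'proposed' or 'masi_only'")
        if self.fix_par not in (0, 1):
            raise ValueError("fix_par must be 0 or 1")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    r: float
    score: float
    accepted: bool
    temperature: float
    valid: bool = True


@dataclass(frozen=True)
class SAResult:
    t_opt: int
    r_hat: float
    best_score: float
    score_trace: tuple[TraceRecord, ...]
    termination: str
    form_used: int
    mode: str  # "me" or "um"
    seed: int

    def best_so_far(self) -> list[float]:
        """Running best score over valid evaluations (ME: min, UM: max)."""
        out, best = [], None
        better = min if self.mode == "me" else max
        for rec in self.score_trace:
            if not rec.valid:
                continue
            best = rec.score if best is None else better(best, rec.score)
            out.append(best)
        return out


def _select(h, r: float, form: int, variant: str) -> ThresholdResult:
    if variant == "masi_only":
        return masi_threshold(h, r)
    return proposed_threshold(h, r, form)


def _run_phase(img: GrayImage, cfg: SAConfig, gt: BinaryMask | None,
               form: int, rng: np.random.Generator):
    """One full annealing schedule for one objective form.

    Returns (best_t, best_r, best_score, trace, termination).
    """
    h = compute_histogram(img)
    mode = "me" if gt is not None else "um"
    minimize = mode == "me"

    def score_of(res: ThresholdResult) -> float:
        mask = binarize(img, res.t_opt, invert=cfg.invert)
        if gt is not None:
            return misclassification_error(gt, mask)[0]
        return uniformity(img, mask)

    trace: list[TraceRecord] = []
    best: tuple[int, float, float] | None = None
    s_hat: float | None = None
    try:
        res0 = _select(h, cfg.r_init, form, cfg.variant)
    except NoValidThresholdError:
        # the initial candidate is itself invalid: reject it and let the
        # annealing walk search for a valid parameter (fix_par=0 cannot)
        if cfg.fix_par == 0:
            raise
        trace.append(TraceRecord(0, cfg.r_init, math.nan, False,
                                 cfg.t_initial, valid=False))
    else:
        s0 = score_of(res0)
        trace.append(TraceRecord(0, cfg.r_init, s0, True, cfg.t_initial))
        best = (res0.t_opt, cfg.r_init, s0)
        if cfg.fix_par == 0:
            return (*best, tuple(trace), "fix_par_bypass")
        if minimize and s0 <= cfg.e_ref:
            return (*best, tuple(trace), "reached_E_ref")
        if not minimize and s0 >= cfg.um_ref:
            return (*best, tuple(trace), "reached_UM_ref")
        s_hat = s0

    r_hat = cfg.r_init
    prev_candidate_score = s_hat
    temp = cfg.t_initial
    i = 0
    while temp > cfg.t_min and i < cfg.max_iter:
        for _j in range(1, cfg.markov_length):
            # resample until r > 0 (Masi domain); bounded retries
            r_j = r_hat + rng.uniform(-cfg.d, cfg.d)
            for _ in range(100):
                if r_j > 0:
                    break
                r_j = r_hat + rng.uniform(-cfg.d, cfg.d)
            if r_j <= 0:
                continue
            try:
                res_j = _select(h, r_j, form, cfg.variant)
            except NoValidThresholdError:
                trace.append(TraceRecord(i, r_j, math.nan, False, temp, valid=False))
                continue
            s_j = score_of(res_j)
            trace.append(TraceRecord(i, r_j, s_j, False, temp))

            if best is None or (minimize and s_j < best[2]) \
                    or (not minimize and s_j > best[2]):
                best = (res_j.t_opt, r_j, s_j)
            if minimize and s_j <= cfg.e_ref:
                return (*best, tuple(trace), "reached_E_ref")
            if not minimize and s_j >= cfg.um_ref:
                return (*best, tuple(trace), "reached_UM_ref")

            baseline = prev_candidate_score if cfg.strict_paper else s_hat
            if baseline is None:
                accept = True  # first valid candidate of the walk
            else:
                delta = s_j - baseline
                improving = delta <= 0 if minimize else delta >= 0
                if improving:
                    accept = True
                else:
                    prob = math.exp(-abs(delta) / temp)
                    accept = rng.uniform(0.0, 1.0) < prob
            if accept:
                r_hat, s_hat = r_j, s_j
                trace[-1] = replace(trace[-1], accepted=True)
            prev_candidate_score = s_j
        i += 1
        temp *= cfg.cooling
    if best is None:
        raise NoValidThresholdError(
            f"no valid threshold for any candidate r (form {form})"
        )
    termination = "cooled" if temp <= cfg.t_min else "max_iter"
    return (*best, tuple(trace), termination)


def _run(img: GrayImage, cfg: SAConfig, gt: BinaryMask | None) -> SAResult:
    if gt is not None and gt.shape != img.shape:
        raise ValueError("ground-truth shape does not match image")
    rng = np.random.default_rng(cfg.seed)
    mode = "me" if gt is not None else "um"
    minimize = mode == "me"

    phases = []
    errors = []
    for form in (1, 2) if cfg.variant == "proposed" else (1,):
        try:
            t_opt, r_hat, s, trace, term = _run_phase(img, cfg, gt, form, rng)
        except NoValidThresholdError as exc:
            errors.append(exc)
            continue
        phases.append((t_opt, r_hat, s, trace, term, form))
        # the alternative form is only tried when the reference criterion
        # was not met (and the parameter is being optimized)
        if term in ("fix_par_bypass", "reached_E_ref", "reached_UM_ref"):
            break
    if not phases:
        raise NoValidThresholdError(
            "no valid threshold for any candidate parameter"
        ) from (errors[0] if errors else None)

    key = (lambda p: p[2]) if minimize else (lambda p: -p[2])
    t_opt, r_hat, s, trace, term, form = min(phases, key=key)
    full_trace = tuple(rec for p in phases for rec in p[3])
    return SAResult(
        t_opt=t_opt, r_hat=r_hat, best_score=s,
        score_trace=full_trace if len(phases) > 1 else trace,
        termination=term, form_used=form, mode=mode, seed=cfg.seed,
    )


def run_algorithm1(img: GrayImage, cfg: SAConfig | None = None,
                   gt: BinaryMask | None = None) -> SAResult:
    """Anneal r for the Masi/Shannon max-min criterion (both forms)."""
    cfg = cfg or SAConfig()
    if cfg.variant != "proposed":
        cfg = replace(cfg, variant="proposed")
    return _run(img, cfg, gt)


def run_algorithm_a1(img: GrayImage, cfg: SAConfig | None = None,
                     gt: BinaryMask | None = None) -> SAResult:
    """Anneal r for the plain Masi-sum criterion (ablation variant)."""
    cfg = cfg or SAConfig()
    cfg = replace(cfg, variant="masi_only")
    return _run(img, cfg, gt)
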