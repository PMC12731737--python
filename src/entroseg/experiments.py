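"""Experiment protocols: sensitivity, convergence, noise and repeated runs.

Each runner returns an :class:`ExperimentReport` that can be regenerated
bit-identically from its embedded configuration and seeds, and written as
CSV with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anneal import SAConfig, run_algorithm1, run_algorithm_a1
from .criteria import NoValidThresholdError, proposed_threshold
from .image import BinaryMask, GrayImage, binarize, compute_histogram
from .metrics import misclassification_error, uniformity
from .synthetic import FixtureSpec, add_gaussian_noise, make_bimodal

__all__ = ["ExperimentReport", "sensitivity_sweep", "convergence_test",
           "noise_sweep", "repeated_run_ablation"]

_SEED_MOD = 2 ** 31


@dataclass(frozen=True)
class ExperimentReport:
    experiment: str
    records: tuple[dict, ...]
    config: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records))

    def write(self, csv_path: str | Path) -> None:
        """CSV of the records plus a .json sidecar with the config."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"experiment": self.experiment, "config": self.config},
            indent=2, sort_keys=True, default=str) + "\n")


def sensitivity_sweep(img: GrayImage, gt: BinaryMask, r_hat: float,
                      delta_r: float = 0.01,
                      k_range: Iterable[int] = range(-3, 4),
                      form: int = 1) -> ExperimentReport:
    """ME response to perturbing r: r_k = r_hat + k * delta_r.

    The criterion runs with the parameter fixed at each r_k; sensitivity is
    |ME(k) - ME(0)|.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    ks = sorted(set(int(k) for k in k_range) | {0})
    h = compute_histogram(img)

    def me_at(r: float) -> float | None:
        try:
            res = proposed_threshold(h, r, form)
        except NoValidThresholdError:
            return None
        return misclassification_error(gt, binarize(img, res.t_opt))[0]

    me_ref = me_at(r_hat)
    records = []
    for k in ks:
        me_k = me_at(r_hat + k * delta_r)
        records.append({
            "k": k,
            "r": r_hat + k * delta_r,
            "me": me_k,
            "delta_me": abs(me_k - me_ref) if me_k is not None and me_ref is not None else None,
            "valid": me_k is not None,
        })
    return ExperimentReport(
        experiment="sensitivity",
        records=tuple(records),
        config={"r_hat": r_hat, "delta_r": delta_r, "k_range": ks, "form": form},
    )


def convergence_test(img: GrayImage, gt: BinaryMask, cfg: SAConfig,
                     n_restarts: int) -> ExperimentReport:
    """Chain annealing runs, each seeded with the previous run's r.

    Records ME per execution; stops early once ME reaches 0.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    records = []
    current = cfg
    for i in range(n_restarts):
        res = run_algorithm1(img, replace(current, seed=(cfg.seed + i) % _SEED_MOD), gt)
        records.append({
            "execution": i,
            "r_init": current.r_init,
            "r_hat": res.r_hat,
            "t_opt": res.t_opt,
            "me": res.best_score,
            "termination": res.termination,
            "form_used": res.form_used,
        })
        if res.best_score == 0:
            break
        current = replace(current, r_init=res.r_hat)
    return ExperimentReport(
        experiment="convergence",
        records=tuple(records),
        config={"n_restarts": n_restarts, **asdict(cfg)},
    )


def noise_sweep(spec: FixtureSpec, sigma_list: Sequence[float],
                replicates: int, cfg: SAConfig) -> ExperimentReport:
    """Mean ME under increasing Gaussian corruption.

    For each sigma, `replicates` corrupted copies of the fixture are
    generated with distinct sub-seeds; the annealer's output (r, t) is used
    to threshold each copy and the ME values are averaged.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    clean, gt = make_bimodal(replace(spec, noise_sigma=0.0))
    records = []
    for li, sigma in enumerate(sigma_list):
        mes = []
        for rep in range(replicates):
            sub = (cfg.seed * 100003 + li * 1009 + rep) % _SEED_MOD
            noisy = add_gaussian_noise(clean, float(sigma), seed=sub)
            res = run_algorithm1(noisy, replace(cfg, seed=sub), gt)
            mes.append(misclassification_error(
                gt, binarize(noisy, res.t_opt, invert=cfg.invert))[0])
        records.append({
            "sigma": float(sigma),
            "mean_me": float(np.mean(mes)),
            "me_per_replicate": tuple(mes),
            "replicates": replicates,
        })
    return ExperimentReport(
        experiment="noise",
        records=tuple(records),
        config={"sigma_list": [float(s) for s in sigma_list],
                "replicates": replicates, "spec": asdict(spec), **asdict(cfg)},
    )


def repeated_run_ablation(img: GrayImage, gt: BinaryMask | None,
                          cfg: SAConfig, n_runs: int,
                          variant: str = "proposed") -> ExperimentReport:
    """n seeded annealing runs; reports (r_hat, ME, UM) per run and the
    envelope [min r_hat, max r_hat] across runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runner = run_algorithm1 if variant == "proposed" else run_algorithm_a1
    records = []
    for i in range(n_runs):
        res = runner(img, replace(cfg, seed=(cfg.seed + i) % _SEED_MOD), gt)
        mask = binarize(img, res.t_opt, invert=cfg.invert)
        rec = {
            "run": i,
            "seed": (cfg.seed + i) % _SEED_MOD,
            "r_hat": res.r_hat,
            "t_opt": res.t_opt,
            "um": uniformity(img, mask),
            "termination": res.termination,
        }
        if gt is not None:
            rec["me"] = misclassification_error(gt, mask)[0]
        records.append(rec)
    r_values = [r["r_hat"] for r in records]
    return ExperimentReport(
        experiment="ablation",
        records=tuple(records),
        config={"n_runs": n_runs, "variant": variant,
                "r_envelope": [min(r_values), max(r_values)], **asdict(cfg)},
    )
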