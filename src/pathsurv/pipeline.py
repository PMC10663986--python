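"""Repeated cross-validation harness and the mask-ablation suite.

The protocol: 5-fold cross-validation repeated 3 times with different
shuffling seeds (15 iterations). At iteration i the test set is fold i, the
validation set fold (i+1) mod k, and the remaining folds train. Deep models
early-stop on the validation fold and are not re-trained afterwards; the
classical Cox-PH baseline is re-fit on train+validation. Test folds never
touch normalization statistics, early stopping, or the training-fold
baseline hazard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model import FoldAssignment, SurvivalDataset, make_folds
from .evaluation import (
    antolini_cindex,
    breslow_baseline,
    classification_metrics,
    cox_survival_curves,
    harrell_cindex,
    survival_curves,
)
from .networks import RiskModel, RiskModelConfig, build_model, fit_cox_ph, fit_model, forward_risk
from .pathway_matrix import PathwayMatrix, randomize, shuffle_rows

logger = logging.getLogger("pathsurv")


@dataclass
class ExperimentResult:
    """Per-iteration metrics of one model over the repeated-CV protocol."""

    model_id: str
    config: object
    records: list[dict] = field(default_factory=list)

    def metric(self, name: str = "cindex_td") -> np.ndarray:
        return np.array([r[name] for r in self.records
                         if not r.get("flagged") and name in r])

    def summary(self, name: str = "cindex_td") -> dict[str, float]:
        vals = self.metric(name)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "iqr": float(q3 - q1), "n_iterations": len(vals)}

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            for key in ("cindex_td", "cindex_harrell", "auroc", "auprc"):
                if key in r:
                    rows.append({"model": self.model_id, "seed": r["seed"],
                                 "repeat": r["repeat"], "fold": r["fold"],
                                 "metric_name": key, "value": r[key]})
        return pd.DataFrame(rows, columns=["model", "seed", "repeat", "fold",
                                           "metric_name", "value"])


def _evaluate_survival(model: RiskModel, train: SurvivalDataset,
                       test: SurvivalDataset, baseline_fold: str) -> dict:
    out: dict = {}
    if model.config.loss == "cox":
        risks_test = forward_risk(model, test.features)
        out["cindex_harrell"] = harrell_cindex(risks_test, test.events, test.durations)
        base_ds = train if baseline_fold == "train" else test
        base = breslow_baseline(forward_risk(model, base_ds.features),
                                base_ds.events, base_ds.durations)
        eval_times = np.unique(np.r_[base.times, test.durations])
        curves = cox_survival_curves(risks_test, base, times=eval_times)
    else:
        curves = survival_curves(model, test.features)
    out["cindex_td"] = antolini_cindex(curves, test.events, test.durations)
    return out


def _fit_select(grid: Sequence[RiskModelConfig], pm, train, val, it_seed: int):
    """Fit every candidate config and keep the best validation loss."""
    best, best_val = None, np.inf
    for cfg in grid:
        model = build_model(replace(cfg, seed=(cfg.seed + it_seed) % (2**31)),
                            pm if cfg.pathway_informed else None)
        fit_model(model, train, val)
        vl = min(model.val_history) if model.val_history else model.train_history[-1]
        if vl < best_val:
            best, best_val = model, vl
    return best


def run_cv(
    ds: SurvivalDataset,
    cfg: RiskModelConfig | str,
    pm: PathwayMatrix | None = None,
    k: int = 5,
    repeats: int = 3,
    seed: int = 0,
    grid: Sequence[RiskModelConfig] | None = None,
    baseline_fold: str = "train",
    model_id: str | None = None,
    assignments: list[FoldAssignment] | None = None,
) -> ExperimentResult:
    """Repeated patient-disjoint CV of one model (or small config grid).

    ``cfg`` may be the string ``"coxph"`` for the classical linear baseline,
    which is re-fit on train+validation; network configs train with early
    stopping on the validation fold and are evaluated as-is. Iterations
    whose test fold has no events are flagged and excluded from summaries.
    """
    if assignments is None:
        assignments = make_folds(ds, k=k, repeats=repeats, seed=seed)
    classical = isinstance(cfg, str)
    if classical and cfg != "coxph":
        raise ValueError(f"unknown classical model {cfg!r}")
    if model_id is None:
        model_id = "coxph" if classical else (
            ("pathway_informed" if cfg.pathway_informed else "dense")
            + f"_{cfg.loss}_d{cfg.depth}")
    result = ExperimentResult(model_id=model_id, config=cfg)
    for fa in assignments:
        train = ds.subset(fa.indices("train"))
        val = ds.subset(fa.indices("val"))
        test = ds.subset(fa.indices("test"))
        rec = {"seed": fa.seed, "repeat": fa.repeat, "fold": fa.iteration,
               "n_test": test.n_samples, "n_test_events": int(test.events.sum())}
        if rec["n_test_events"] == 0:
            logger.warning("fold %d of repeat %d has no test events; excluded",
                           fa.iteration, fa.repeat)
            rec["flagged"] = True
            result.records.append(rec)
            continue
        it_seed = fa.seed * 101 + fa.iteration
        if classical:
            # re-fit on train + validation for the final model
            tv_idx = np.r_[fa.indices("train"), fa.indices("val")]
            tv = ds.subset(tv_idx)
            mu, sdv = tv.features.mean(axis=0), tv.features.std(axis=0)
            sdv = np.where(sdv > 1e-12, sdv, 1.0)
            beta = fit_cox_ph((tv.features - mu) / sdv, tv.events, tv.durations)
            risks_test = (test.features - mu) / sdv @ beta
            rec["cindex_harrell"] = harrell_cindex(risks_test, test.events,
                                                   test.durations)
            base = breslow_baseline((tv.features - mu) / sdv @ beta,
                                    tv.events, tv.durations)
            eval_times = np.unique(np.r_[base.times, test.durations])
            curves = cox_survival_curves(risks_test, base, times=eval_times)
            rec["cindex_td"] = antolini_cindex(curves, test.events, test.durations)
        else:
            model = _fit_select(grid or [cfg], pm, train, val, it_seed)
            rec["epochs"] = model.epochs_trained
            if model.config.head == "classification":
                probs = forward_risk(model, test.features)
                if len(np.unique(test.malignancy)) < 2:
                    rec["flagged"] = True
                    result.records.append(rec)
                    continue
                rec.update(classification_metrics(probs, test.malignancy))
            else:
                rec.update(_evaluate_survival(model, train, test, baseline_fold))
        result.records.append(rec)
    return result


ABLATIONS = ("dense138", "random_matrix", "shuffled_matrix", "dropout_sweep",
             "sample_size_sweep")


def run_ablation(
    ds: SurvivalDataset,
    base_cfg: RiskModelConfig,
    pm: PathwayMatrix,
    which: str,
    params: dict | None = None,
    k: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> list[ExperimentResult]:
    """Mask-ablation suite under the identical CV protocol.

    * ``dense138``: fully connected first layer width-matched to the number
      of pathways.
    * ``random_matrix`` / ``shuffled_matrix``: edge-count-matched random or
      row-permuted masks, resampled per repeat seed.
    * ``dropout_sweep``: dense baseline with first-layer dropout rates.
    * ``sample_size_sweep``: patient subsets drawn without replacement
      before folding.
    """
    params = params or {}
    if which not in ABLATIONS:
        raise ValueError(f"unknown ablation {which!r}; choose from {ABLATIONS}")
    if which == "dense138":
        cfg = replace(base_cfg, pathway_informed=False, first_width=pm.shape[1])
        return [run_cv(ds, cfg, None, k=k, repeats=repeats, seed=seed,
                       model_id=f"dense{pm.shape[1]}_{cfg.loss}_d{cfg.depth}")]
    if which in ("random_matrix", "shuffled_matrix"):
        make = randomize if which == "random_matrix" else shuffle_rows
        result = ExperimentResult(model_id=f"{which}_{base_cfg.loss}_d{base_cfg.depth}",
                                  config=base_cfg)
        for rep in range(repeats):
            rep_seed = (seed + 9973 * rep) % (2**31)
            pm_r = make(pm, seed=rep_seed)
            sub = run_cv(ds, base_cfg, pm_r, k=k, repeats=1, seed=rep_seed)
            for r in sub.records:
                r["repeat"] = rep
                result.records.append(r)
        return [result]
    if which == "dropout_sweep":
        rates = params.get("rates", (0.5, 0.6, 0.7, 0.8, 0.9))
        out = []
        for rate in rates:
            cfg = replace(base_cfg, pathway_informed=False, dropout_rate=rate)
            out.append(run_cv(ds, cfg, None, k=k, repeats=repeats, seed=seed,
                              model_id=f"dense_dropout{rate}_{cfg.loss}_d{cfg.depth}"))
        return out
    # sample_size_sweep
    sizes = params.get("sizes", (50, 100, 200))
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        patients = list(dict.fromkeys(ds.patient_ids))
        if size > len(patients):
            raise ValueError(f"requested subsample {size} exceeds "
                             f"{len(patients)} patients")
        chosen = set(rng.choice(len(patients), size=size, replace=False))
        keep_ids = {patients[i] for i in chosen}
        idx = np.array([i for i, p in enumerate(ds.patient_ids) if p in keep_ids])
        sub = ds.subset(idx)
        out.append(run_cv(sub, base_cfg, pm if base_cfg.pathway_informed else None,
                          k=k, repeats=repeats, seed=seed,
                          model_id=f"n{size}_" + ("pathway_informed"
                                                  if base_cfg.pathway_informed
                                                  else "dense")))
    return out
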