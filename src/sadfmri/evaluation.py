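"""Classification metrics, the repeated-subsampling protocol, and benchmarks.

Performance is summarised by the confusion-matrix rates (TPR, TNR, PPV, ACC,
F1, FNR, FPR, FDR, FOR) at a decision threshold plus the AUC computed from
raw scores via the rank (Mann-Whitney) formulation with midranks for ties.
The evaluation protocol repeatedly subsamples an equal number of voxels per
class without replacement (default 100 repeats of 500 per class) and reports
the mean and standard deviation of every metric across repeats.

``resolution_benchmark`` reruns the full semi-supervised pipeline on
progressively downsampled data, adapting the autocorrelation lag count
``h_max -> ceil(h_max / d)``, and tabulates one row of metrics per
temporal resolution. ``compare_sad_glm`` cross-tabulates the classifier's
decisions against GLM suprathreshold flags.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import glm as glm_mod
from .autocorr import adapt_hmax
from .simulate import LabelledSyntheticSet, degrade_resolution
from .ssl import TrainConfig, run_sad, predict

__all__ = [
    "ClassMetrics",
    "RepeatedEval",
    "confusion_metrics",
    "auc_rank",
    "repeated_eval",
    "resolution_benchmark",
    "compare_sad_glm",
]

METRIC_NAMES = ("TPR", "TNR", "PPV", "ACC", "F1", "FNR", "FPR", "FDR", "FOR", "AUC")


@dataclasses.dataclass
class ClassMetrics:
    """Confusion-derived rates and AUC for one evaluation."""

    TPR: float
    TNR: float
    PPV: float
    ACC: float
    F1: float
    FNR: float
    FPR: float
    FDR: float
    FOR: float
    AUC: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclasses.dataclass
class RepeatedEval:
    """Mean and spread of metrics across subsampling repeats."""

    per_repeat: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    repeats: int
    per_class_sample: int
    seed: int


def auc_rank(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation; ties get midranks."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(scores: np.ndarray, truth: np.ndarray,
                      threshold: float = 0.5) -> ClassMetrics:
    """Threshold the scores and compute all confusion rates plus AUC.

    A rate with an empty denominator is reported as NaN. AUC requires both
    classes; that is enforced (threshold metrics alone are available by
    catching the error upstream).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())

    def rate(num, den):
        return num / den if den > 0 else float("nan")

    tpr = rate(tp, tp + fn)
    tnr = rate(tn, tn + fp)
    ppv = rate(tp, tp + fp)
    acc = rate(tp + tn, tp + tn + fp + fn)
    f1 = rate(2 * tp, 2 * tp + fp + fn)
    return ClassMetrics(TPR=tpr, TNR=tnr, PPV=ppv, ACC=acc, F1=f1,
                        FNR=rate(fn, tp + fn), FPR=rate(fp, tn + fp),
                        FDR=rate(fp, tp + fp), FOR=rate(fn, tn + fn),
                        AUC=auc_rank(scores, truth),
                        n_pos=tp + fn, n_neg=tn + fp)


def repeated_eval(scores: np.ndarray, truth: np.ndarray, repeats: int = 100,
                  per_class_sample: int = 500, threshold: float = 0.5,
                  seed: int = 0) -> RepeatedEval:
    """Repeated equal-class subsampling evaluation.

    Each repeat draws ``per_class_sample`` voxels per class without
    replacement, computes :func:`confusion_metrics`, and the mean/sd of each
    metric is reported across repeats.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = np.flatnonzero(truth == 1)
    neg = np.flatnonzero(truth == 0)
    if pos.size < per_class_sample or neg.size < per_class_sample:
        raise ValueError(
            f"need >= {per_class_sample} voxels per class "
            f"(have {pos.size} positive, {neg.size} negative); "
            "reduce per_class_sample")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        take = np.concatenate([rng.choice(pos, per_class_sample, replace=False),
                               rng.choice(neg, per_class_sample, replace=False)])
        rows.append(confusion_metrics(scores[take], truth[take], threshold).as_dict())
    table = pd.DataFrame(rows)
    sd = table.std(ddof=1) if repeats > 1 else table.iloc[0] * 0.0
    return RepeatedEval(per_repeat=table, mean=table.mean(), sd=sd,
                        repeats=repeats, per_class_sample=per_class_sample,
                        seed=seed)


def resolution_benchmark(train_set: LabelledSyntheticSet,
                         test_set: LabelledSyntheticSet,
                         factors, config: TrainConfig | None = None,
                         repeats: int = 100, per_class_sample: int = 500,
                         eval_seed: int = 0) -> pd.DataFrame:
    """Full-pipeline metrics at progressively lower temporal resolutions.

    For each downsampling factor ``d`` the train and test sets are decimated,
    ``h_max`` is adapted to ``ceil(h_max / d)``, the semi-supervised loop is
    rerun from scratch, held-out voxels are scored, and the repeated
    subsampling protocol summarises the metrics. Returns one row per
    resolution with the adapted ``h_max`` and the iteration count logged.
    """
    factors = list(factors)
    if any(d < 1 for d in factors) or factors != sorted(factors):
        raise ValueError("factors must be ascending integers >= 1")
    if config is None:
        config = TrainConfig()
    rows = []
    for d in factors:
        tr = degrade_resolution(train_set, d)
        te = degrade_resolution(test_set, d)
        cfg = dataclasses.replace(config, h_max=adapt_hmax(config.h_max, d))
        result = run_sad(tr.series, cfg)
        _, p_pred, _ = predict(result.model, te.series,
                               threshold=cfg.final_threshold, h_max=cfg.h_max)
        ev = repeated_eval(p_pred, te.truth, repeats=repeats,
                           per_class_sample=per_class_sample,
                           threshold=cfg.final_threshold, seed=eval_seed)
        row = {"d": d, "dt_ms": tr.series.dt * 1000.0, "h_max": cfg.h_max,
               "iterations": result.n_iterations}
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = float(ev.mean[m])
            row[f"{m}_sd"] = float(ev.sd[m])
        rows.append(row)
    return pd.DataFrame(rows)


def compare_sad_glm(sad_scores: np.ndarray, glm_result: glm_mod.GlmBatchResult,
                    truth: np.ndarray | None = None,
                    voxel_ids: np.ndarray | None = None,
                    threshold: float = 0.5):
    """Cross-tabulate SAD decisions against GLM suprathreshold flags.

    Returns a 2x2 count table (rows: SAD 0/1; columns: GLM 0/1) and a
    DataFrame with per-voxel decisions and cell membership, ready for
    discordance inspection (e.g. mean time-courses per cell).
    """
    sad_scores = np.asarray(sad_scores, dtype=float)
    if glm_result.suprathreshold is None:
        raise ValueError("apply fwer_threshold to the GLM result first")
    flags = np.asarray(glm_result.suprathreshold).astype(int)
    if sad_scores.size == 0 or flags.size == 0:
        raise ValueError("empty inputs")
    if sad_scores.size != flags.size:
        raise ValueError("SAD scores and GLM flags are misaligned")
    if voxel_ids is None:
        voxel_ids = np.arange(sad_scores.size)
    voxel_ids = np.asarray(voxel_ids)
    if voxel_ids.size != sad_scores.size:
        raise ValueError("voxel_ids misaligned with scores")
    sad_cls = (sad_scores > threshold).astype(int)
    table = np.zeros((2, 2), dtype=int)
    for s in (0, 1):
        for g in (0, 1):
            table[s, g] = int(((sad_cls == s) & (flags == g)).sum())
    detail = pd.DataFrame({
        "voxel_id": voxel_ids,
        "sad_score": sad_scores,
        "sad_class": sad_cls,
        "glm_stat": glm_result.stat,
        "glm_suprathreshold": flags,
        "cell": [f"sad{s}_glm{g}" for s, g in zip(sad_cls, flags)],
    })
    if truth is not None:
        detail["truth"] = np.asarray(truth).astype(int)
    counts = pd.DataFrame(table, index=["sad0", "sad1"], columns=["glm0", "glm1"])
    return counts, detail
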