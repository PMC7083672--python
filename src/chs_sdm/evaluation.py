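"""Model evaluation: TSS, AUC, threshold search, and the run protocol.

The skill scores are the standard presence/absence ones.  With weighted
confusion counts a (true positives), b (false positives), c (false
negatives), d (true negatives):

    sensitivity = a / (a + c)
    specificity = d / (b + d)
    TSS         = sensitivity + specificity - 1

AUC is the rank-based (Mann-Whitney) area under the ROC curve with tie
correction and case weights.  The evaluation protocol mirrors common
ensemble-platform practice: for each pseudo-absence replicate and each
algorithm, repeat a stratified 70/30 split, fit on the training part, and
score TSS (at the TSS-optimal threshold) and AUC on the held-out part;
3 replicates x 10 algorithms x 10 repeats = 300 scored runs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .algorithms import AlgorithmSpec, FittedModel, TrainingSet, fit_model

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Weighted confusion counts: a=TP, b=FP, c=FN, d=TN."""

    a: float
    b: float
    c: float
    d: float


@dataclass
class EvaluationResult:
    sensitivity: float
    specificity: float
    tss: float
    auc: float
    threshold_used: float


@dataclass
class ModelRun:
    """One fitted (algorithm, pseudo-absence replicate, repeat) instance."""

    algorithm_id: str
    dataset_id: int
    repeat_id: int
    model: FittedModel
    evaluation: EvaluationResult | None = None
    failed: bool = False

    @property
    def run_id(self) -> str:
        return f"{self.algorithm_id}_{self.dataset_id}_{self.repeat_id}"


def confusion(scores, labels, weights=None, threshold=0.5) -> ConfusionCounts:
    """Weighted confusion counts; positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    weights = np.ones_like(scores) if weights is None else np.asarray(weights, float)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        a=float(weights[pred & pos].sum()),
        b=float(weights[pred & ~pos].sum()),
        c=float(weights[~pred & pos].sum()),
        d=float(weights[~pred & ~pos].sum()),
    )


def tss(conf: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) from confusion counts."""
    if conf.a + conf.c <= 0:
        raise ZeroDivisionError("no presences: sensitivity undefined")
    if conf.b + conf.d <= 0:
        raise ZeroDivisionError("no absences: specificity undefined")
    sens = conf.a / (conf.a + conf.c)
    spec = conf.d / (conf.b + conf.d)
    return sens, spec, sens + spec - 1.0


def auc(scores, labels, weights=None) -> float:
    """Weighted, tie-corrected Mann-Whitney AUC."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float),
                               sample_weight=weights))


def optimal_threshold(scores, labels, weights=None) -> tuple[float, float]:
    """Grid-scan the TSS over thresholds 0.00..1.00 (step 0.01).

    Returns (threshold, TSS at threshold); ties broken toward the lower
    threshold.
    """
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    best_t, best_tss = grid[0], -np.inf
    for t in grid:
        _, _, value = tss(confusion(scores, labels, weights, t))
        if value > best_tss + 1e-15:
            best_t, best_tss = t, value
    return float(best_t), float(best_tss)


def evaluate_scores(scores, labels, weights=None) -> EvaluationResult:
    """Held-out evaluation: TSS at its optimal threshold, plus AUC."""
    t, _ = optimal_threshold(scores, labels, weights)
    sens, spec, value = tss(confusion(scores, labels, weights, t))
    return EvaluationResult(
        sensitivity=sens, specificity=spec, tss=value,
        auc=auc(scores, labels, weights), threshold_used=t,
    )


def split_train_test(
    train_set: TrainingSet, fraction: float = 0.7, repeat_seed: int = 0
) -> tuple[TrainingSet, TrainingSet]:
    """Stratified random split preserving class proportions and weights."""
    y = train_set.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=repeat_seed % (2**32)
    )
    return train_set.subset(tr), train_set.subset(te)


def derive_seed(master_seed: int, *parts) -> int:
    """Stable stream seed from the master seed and a label tuple (< 2^31)."""
    label = ":".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(label.encode()) % (2**31)


def run_protocol(
    datasets: dict[int, TrainingSet],
    algorithms: list[AlgorithmSpec],
    n_repeats: int = 10,
    split_fraction: float = 0.7,
    master_seed: int = 0,
) -> list[ModelRun]:
    """The full evaluation protocol: datasets x algorithms x repeats.

    Each run gets its own derived seed for the split and the fit.  Failed
    fits are flagged (kept in the list so counts are auditable) and carry
    no evaluation.
    """
    if not datasets or not algorithms:
        raise ValueError("need at least one dataset and one algorithm")
    runs: list[ModelRun] = []
    for ds_id, ts in datasets.items():
        for spec in algorithms:
            for rep in range(1, n_repeats + 1):
                seed = derive_seed(master_seed, "run", spec.algorithm_id, ds_id, rep)
                tr, te = split_train_test(ts, split_fraction, repeat_seed=seed)
                model = fit_model(spec, tr, seed=seed)
                run = ModelRun(
                    algorithm_id=spec.algorithm_id, dataset_id=ds_id,
                    repeat_id=rep, model=model, failed=model.failed,
                )
                if not model.failed:
                    scores = model.predict01(te.X)
                    run.evaluation = evaluate_scores(scores, te.y, te.weights)
                else:
                    log.warning("run %s flagged: %s", run.run_id,
                                model.failure_reason)
                runs.append(run)
    return runs


def runs_to_frame(runs: list[ModelRun]):
    """Run-level metrics as a DataFrame (flagged runs carry NaN metrics)."""
    import pandas as pd

    rows = []
    for r in runs:
        e = r.evaluation
        rows.append({
            "algorithm": r.algorithm_id, "dataset": r.dataset_id,
            "repeat": r.repeat_id, "failed": r.failed,
            "tss": e.tss if e else np.nan,
            "auc": e.auc if e else np.nan,
            "sensitivity": e.sensitivity if e else np.nan,
            "specificity": e.specificity if e else np.nan,
            "threshold": e.threshold_used if e else np.nan,
        })
    return pd.DataFrame(rows)
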