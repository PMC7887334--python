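"""Evaluation statistics: ROC/PR with bootstrap CIs, the Youden-J operating
point, confusion metrics, per-category sensitivity, McNemar comparison and
the three-class reader-study harness.

AUROC is the Mann-Whitney concordance probability (ties count 1/2) and AUPRC
the area under the precision-recall step curve, both via scikit-learn.
Confidence intervals are percentile bootstrap over case resampling with 2000
replicates by default; resamples on which the metric is undefined
(single-class draws) are redrawn and logged.  McNemar's test is built on
per-case correctness indicators, exact binomial below 25 discordant pairs
and chi-square with continuity correction above.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ScoredCohort",
    "EvalReport",
    "ReaderStudy",
    "auroc",
    "auprc",
    "bootstrap_ci",
    "youden_cutoff",
    "confusion_metrics",
    "per_category_breakdown",
    "mcnemar_test",
    "reader_study_report",
    "evaluate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_reader_study_csv",
]

logger = logging.getLogger(__name__)

READER_CLASSES = ("hip_fracture", "pelvic_fracture", "normal")


@dataclass
class ScoredCohort:
    """Per-image score in [0, 1], binary truth, optional category labels."""

    scores: Sequence[float]
    labels: Sequence[int]
    categories: Optional[Sequence[Sequence[str]]] = None  # per image, may be empty
    difficult: Optional[Sequence[bool]] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary")

    def __len__(self):
        return len(self.scores)

    def subset(self, idx) -> "ScoredCohort":
        idx = np.asarray(idx)
        return ScoredCohort(
            scores=self.scores[idx],
            labels=self.labels[idx],
            categories=[self.categories[i] for i in idx] if self.categories is not None else None,
            difficult=[self.difficult[i] for i in idx] if self.difficult is not None else None,
        )

    def require_both_classes(self):
        if len(np.unique(self.labels)) < 2:
            raise ValueError("cohort must contain both classes")


def auroc(cohort: ScoredCohort) -> float:
    """Mann-Whitney concordance probability (ties counted 0.5)."""
    cohort.require_both_classes()
    return float(roc_auc_score(cohort.labels, cohort.scores))


def auprc(cohort: ScoredCohort) -> float:
    """Area under the precision-recall step curve over all thresholds."""
    if int(cohort.labels.sum()) == 0:
        raise ValueError("cohort must contain at least one positive")
    return float(average_precision_score(cohort.labels, cohort.scores))


def bootstrap_ci(
    metric: Callable[[ScoredCohort], float],
    cohort: ScoredCohort,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap CI over case resampling with replacement."""
    rng = np.random.default_rng(seed)
    n = len(cohort)
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            try:
                v = metric(cohort.subset(idx))
            except ValueError:
                redraws += 1
                continue
            if np.isnan(v):
                redraws += 1
                continue
            values[b] = v
            break
        else:
            raise ValueError("metric undefined on (virtually) all resamples")
    if redraws:
        logger.info("bootstrap redrew %d degenerate resample(s)", redraws)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def youden_cutoff(cohort: ScoredCohort) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct observed scores
    (plus one candidate below the minimum and one above the maximum); ties
    in J are broken toward the higher threshold, i.e. higher specificity.
    """
    cohort.require_both_classes()
    scores = np.asarray(cohort.scores)
    labels = np.asarray(cohort.labels)
    uniq = np.unique(scores)
    candidates = [uniq[0] - 0.5]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 0.5]
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


def confusion_metrics(cohort: ScoredCohort, cutoff: float) -> Dict[str, float]:
    """accuracy / sensitivity / specificity / PPV / NPV at score >= cutoff."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = cohort.scores >= cutoff
    truth = cohort.labels == 1
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())

    def safe(a, b):
        return a / b if b else float("nan")

    return {
        "accuracy": safe(tp + tn, tp + tn + fp + fn),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def per_category_breakdown(cohort: ScoredCohort, cutoff: float) -> pd.DataFrame:
    """Per-category detection among positives, plus an overall row.

    An image carrying multiple categories counts once per category and once
    in the overall row.
    """
    if cohort.categories is None:
        raise ValueError("cohort has no category labels")
    pred = cohort.scores >= cutoff
    rows = []
    pos_idx = np.flatnonzero(cohort.labels == 1)
    n_det = int(pred[pos_idx].sum())
    rows.append(
        {
            "category": "overall",
            "n_detected": n_det,
            "n_missed": len(pos_idx) - n_det,
            "sensitivity": n_det / len(pos_idx) if len(pos_idx) else float("nan"),
        }
    )
    cats = sorted({c for i in pos_idx for c in cohort.categories[i]})
    for cat in cats:
        idx = [i for i in pos_idx if cat in cohort.categories[i]]
        det = int(pred[idx].sum())
        rows.append(
            {
                "category": cat,
                "n_detected": det,
                "n_missed": len(idx) - det,
                "sensitivity": det / len(idx) if idx else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def mcnemar_test(
    calls_a: Sequence[int], calls_b: Sequence[int], truth: Sequence[int], exact_below: int = 25
) -> float:
    """Paired comparison of two raters' correctness against the truth.

    b = cases A right and B wrong, c = A wrong and B right; exact two-sided
    binomial(min(b,c); b+c, 1/2) when b + c < ``exact_below``, otherwise
    chi-square with continuity correction.  No discordance gives p = 1.
    """
    a = np.asarray(calls_a)
    bb = np.asarray(calls_b)
    t = np.asarray(truth)
    if not (len(a) == len(bb) == len(t)):
        raise ValueError("calls_a, calls_b and truth must have equal length")
    right_a = a == t
    right_b = bb == t
    b = int((right_a & ~right_b).sum())
    c = int((~right_a & right_b).sum())
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]  # only discordant cells matter
    res = _sm_mcnemar(table, exact=(b + c) < exact_below, correction=True)
    return float(min(1.0, res.pvalue))


@dataclass
class EvalReport:
    auroc: float
    auroc_ci: Tuple[float, float]
    auprc: float
    auprc_ci: Tuple[float, float]
    cutoff: float
    metrics: Dict[str, float]
    metrics_ci: Dict[str, Tuple[float, float]]
    per_category: Optional[pd.DataFrame] = None

    def to_dict(self) -> Dict:
        d = {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "auprc": self.auprc,
            "auprc_ci": list(self.auprc_ci),
            "cutoff": self.cutoff,
            "metrics": self.metrics,
            "metrics_ci": {k: list(v) for k, v in self.metrics_ci.items()},
        }
        if self.per_category is not None:
            d["per_category"] = self.per_category.to_dict(orient="records")
        return d

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_markdown(self) -> str:
        lines = [
            "| metric | value | 95% CI |",
            "| --- | --- | --- |",
            f"| AUROC | {self.auroc:.3f} | {self.auroc_ci[0]:.3f}-{self.auroc_ci[1]:.3f} |",
            f"| AUPRC | {self.auprc:.3f} | {self.auprc_ci[0]:.3f}-{self.auprc_ci[1]:.3f} |",
            f"| cutoff | {self.cutoff:.4f} | |",
        ]
        for k, v in self.metrics.items():
            lo, hi = self.metrics_ci[k]
            lines.append(f"| {k} | {v:.3f} | {lo:.3f}-{hi:.3f} |")
        if self.per_category is not None:
            lines.append("")
            lines.append(self.per_category.to_markdown(index=False))
        return "\n".join(lines)


def evaluate_cohort(
    cohort: ScoredCohort,
    cutoff: Optional[float] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """The full battery on one scored cohort.

    ``cutoff=None`` selects the Youden-J threshold on this cohort.
    """
    if cutoff is None:
        cutoff = youden_cutoff(cohort)
    a = auroc(cohort)
    p = auprc(cohort)
    a_ci = bootstrap_ci(auroc, cohort, n_boot=n_boot, seed=seed)
    p_ci = bootstrap_ci(auprc, cohort, n_boot=n_boot, seed=seed + 1)
    metrics = confusion_metrics(cohort, cutoff)
    metrics_ci = {}
    for i, key in enumerate(metrics):
        metrics_ci[key] = bootstrap_ci(
            lambda c, k=key: confusion_metrics(c, cutoff)[k],
            cohort,
            n_boot=n_boot,
            seed=seed + 2 + i,
        )
    per_cat = per_category_breakdown(cohort, cutoff) if cohort.categories is not None else None
    return EvalReport(
        auroc=a, auroc_ci=a_ci, auprc=p, auprc_ci=p_ci, cutoff=float(cutoff),
        metrics=metrics, metrics_ci=metrics_ci, per_category=per_cat,
    )


# ---------------------------------------------------------------------------
# reader study

@dataclass
class ReaderStudy:
    """Three-class truth plus per-reader and model predicted classes."""

    case_ids: List[str]
    truth: List[str]
    readers: Dict[str, List[str]]  # reader name -> predictions
    model: List[str]

    def __post_init__(self):
        n = len(self.case_ids)
        missing = []
        for name, preds in list(self.readers.items()) + [("model", self.model)]:
            if len(preds) != n:
                raise ValueError(f"{name}: expected {n} responses, got {len(preds)}")
            for cid, p in zip(self.case_ids, preds):
                if p not in READER_CLASSES:
                    missing.append((name, cid, p))
        if len(self.truth) != n:
            raise ValueError("truth must cover every case")
        for t in self.truth:
            if t not in READER_CLASSES:
                raise ValueError(f"unknown truth class {t!r}")
        if missing:
            ids = ", ".join(f"{name}:{cid}({p!r})" for name, cid, p in missing[:10])
            raise ValueError(f"invalid/missing responses for {ids}")


def _one_vs_rest_task(truth, preds, target: str):
    """Binary task on target-class + normal cases only (the Table-5 layout)."""
    idx = [i for i, t in enumerate(truth) if t in (target, "normal")]
    y = np.array([1 if truth[i] == target else 0 for i in idx])
    yhat = np.array([1 if preds[i] == target else 0 for i in idx])
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    return {
        "accuracy": (tp + tn) / len(idx),
        "sensitivity": tp / max(1, int((y == 1).sum())),
        "specificity": tn / max(1, int((y == 0).sum())),
        "_idx": idx,
        "_y": y,
        "_yhat": yhat,
    }


def balanced_accuracy(truth: Sequence[str], preds: Sequence[str]) -> float:
    """Mean of the per-class recalls over the three classes."""
    recalls = []
    for cls in READER_CLASSES:
        idx = [i for i, t in enumerate(truth) if t == cls]
        if idx:
            recalls.append(sum(1 for i in idx if preds[i] == cls) / len(idx))
    return float(np.mean(recalls))


def reader_study_report(study: ReaderStudy) -> pd.DataFrame:
    """Per-reader and model performance on the two fracture tasks.

    For each fracture class the task is one-vs-rest on its relevant cases
    (target-class plus normal); the McNemar p-value compares each reader with
    the model on those same cases, and misdiagnoses-detected counts the
    reader's misses that the model called correctly.
    """
    rows = []
    tasks = {"hip_fracture": "hip", "pelvic_fracture": "pelvic"}
    raters = [("model", study.model)] + sorted(study.readers.items())
    model_tasks = {t: _one_vs_rest_task(study.truth, study.model, t) for t in tasks}
    for name, preds in raters:
        row = {"reader": name, "balanced_accuracy": balanced_accuracy(study.truth, preds)}
        for target, short in tasks.items():
            res = _one_vs_rest_task(study.truth, preds, target)
            row[f"{short}_accuracy"] = res["accuracy"]
            row[f"{short}_sensitivity"] = res["sensitivity"]
            row[f"{short}_specificity"] = res["specificity"]
            if name == "model":
                row[f"{short}_mcnemar_p"] = 1.0
                row[f"{short}_misdiagnosis_detected"] = 0
            else:
                mres = model_tasks[target]
                row[f"{short}_mcnemar_p"] = mcnemar_test(res["_yhat"], mres["_yhat"], mres["_y"])
                # reader missed a true positive, model called it
                missed = (res["_y"] == 1) & (res["_yhat"] == 0) & (mres["_yhat"] == 1)
                row[f"{short}_misdiagnosis_detected"] = int(missed.sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(path, image_ids, cohort: ScoredCohort):
    df = pd.DataFrame(
        {
            "image_id": list(image_ids),
            "score": cohort.scores,
            "label": cohort.labels,
            "categories": [
                ";".join(c) for c in (cohort.categories or [[]] * len(cohort))
            ],
            "difficult": [int(bool(d)) for d in (cohort.difficult or [0] * len(cohort))],
        }
    )
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> Tuple[List[str], ScoredCohort]:
    df = pd.read_csv(path)
    cats = None
    if "categories" in df.columns:
        cats = [
            [] if (isinstance(c, float) and np.isnan(c)) or c == "" else str(c).split(";")
            for c in df["categories"].fillna("")
        ]
    difficult = [bool(d) for d in df["difficult"]] if "difficult" in df.columns else None
    cohort = ScoredCohort(
        scores=df["score"].to_numpy(),
        labels=df["label"].to_numpy(),
        categories=cats,
        difficult=difficult,
    )
    return list(df["image_id"]), cohort


def read_reader_study_csv(path) -> ReaderStudy:
    """CSV matrix: case_id, truth, reader_1..reader_k, model."""
    df = pd.read_csv(path)
    reader_cols = [c for c in df.columns if c not in ("case_id", "truth", "model")]
    return ReaderStudy(
        case_ids=[str(c) for c in df["case_id"]],
        truth=list(df["truth"]),
        readers={c: list(df[c]) for c in reader_cols},
        model=list(df["model"]),
    )
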