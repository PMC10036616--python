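"""Cross-validation harness, performance metrics, robustness checks, and
the clinical decision tree.

Cross-validation operates at the patient level (all of a patient's cores
travel together), pools out-of-fold predictions, and reports accuracy with
a normal-approximation 95% CI, ROC AUC with a stratified-bootstrap CI,
Cohen's kappa from the pooled confusion matrix, and per-fold metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeRegressor

from .model import ModelConfig, PatientDataset, train_model


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def stratified_kfold(table, k: int = 10, seed: int = 0) -> dict:
    """Seeded stratified fold assignment: patient_id -> fold index.

    Folds are sized ``floor(n/k)`` or ``ceil(n/k)`` and class proportions
    are preserved within one patient.
    """
    ids = np.asarray(table.patient_ids)
    labels = np.asarray(table.labels)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} patients")
    rng = np.random.default_rng(seed)
    folds = {}
    counter = 0
    for cls in np.unique(labels):
        cls_ids = ids[labels == cls]
        cls_ids = cls_ids[rng.permutation(len(cls_ids))]
        for pid in cls_ids:
            folds[str(pid)] = counter % k
            counter += 1
    return folds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a 2x2 (or ExE) confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / total ** 2
    if pe >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


def accuracy_ci(correct: int, n: int, z: float = 1.96) -> tuple:
    """Normal-approximation CI for a proportion: p +/- z sqrt(p(1-p)/n)."""
    p = correct / n
    half = z * np.sqrt(p * (1 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)


def auc_bootstrap_ci(labels: np.ndarray, scores: np.ndarray,
                     n_boot: int = 2000, seed: int = 0) -> tuple:
    """AUC with a stratified-bootstrap percentile 95% CI."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    auc = roc_auc_score(labels, scores)
    rng = np.random.default_rng(seed)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    boots = []
    for _ in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(auc), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    folds: dict                 # patient_id -> fold
    predictions: pd.DataFrame   # patient_id, label, fold, p_recurrence, ...
    confusion: np.ndarray       # 2x2, rows = truth, cols = prediction
    accuracy: float
    accuracy_ci: tuple
    auc: float
    auc_ci: tuple
    kappa: float
    per_fold: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps({
            "accuracy": self.accuracy, "accuracy_ci": list(self.accuracy_ci),
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "kappa": self.kappa,
            "confusion": self.confusion.tolist(),
            "n_patients": int(len(self.predictions)),
        }, indent=1)


def run_cross_validation(dataset: PatientDataset, config: ModelConfig,
                         table, k: int = 10, seed: int = 0) -> CVReport:
    """Patient-level stratified k-fold CV with pooled out-of-fold metrics."""
    folds = stratified_kfold(table, k=k, seed=seed)
    rows = []
    fold_rows = []
    for fold in range(k):
        test_ids = [p for p in dataset.patient_ids if folds[p] == fold]
        train_ids = [p for p in dataset.patient_ids if folds[p] != fold]
        if not test_ids:
            continue
        train_labels = {dataset.labels[p] for p in train_ids}
        if len(train_labels) < 2:
            raise ValueError(
                f"fold {fold}: training split contains a single class")
        net, _ = train_model(dataset.subset(train_ids),
                             ModelConfig(**{**config.__dict__,
                                            "seed": config.seed + fold}))
        correct = 0
        for pid in test_ids:
            pred, _, _ = net.predict(dataset.patchsets[pid],
                                     dataset.graphs[pid])
            truth = dataset.labels[pid]
            correct += int(pred.label == truth)
            rows.append({"patient_id": pid, "label": truth, "fold": fold,
                         "p_recurrence": pred.p_recurrence,
                         "predicted": pred.label,
                         "confidence": pred.confidence})
        fold_rows.append({"fold": fold, "n_test": len(test_ids),
                          "accuracy": correct / len(test_ids)})
    preds = pd.DataFrame(rows)
    assert set(preds["patient_id"]) == set(dataset.patient_ids), \
        "out-of-fold coverage must equal the patient set"
    y = preds["label"].to_numpy()
    yhat = preds["predicted"].to_numpy()
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, yhat):
        cm[t, p] += 1
    acc, lo, hi = accuracy_ci(int((y == yhat).sum()), len(y))
    if len(np.unique(y)) == 2:
        auc, alo, ahi = auc_bootstrap_ci(y, preds["p_recurrence"].to_numpy(),
                                         seed=seed)
    else:  # degenerate synthetic cohort
        auc, alo, ahi = np.nan, np.nan, np.nan
    return CVReport(folds=folds, predictions=preds, confusion=cm,
                    accuracy=acc, accuracy_ci=(lo, hi),
                    auc=auc, auc_ci=(alo, ahi),
                    kappa=cohens_kappa(cm), per_fold=pd.DataFrame(fold_rows))


# ---------------------------------------------------------------------------
# Prediction-confidence analysis
# ---------------------------------------------------------------------------

def confidence_analysis(predictions: pd.DataFrame, hi: float = 0.90,
                        lo: float = 0.50) -> pd.DataFrame:
    """Bucket patients by prediction confidence and correctness.

    Bands: ``(lo, hi)`` and ``>= hi``; confidences below ``lo`` are flagged
    as their own band (a binary max-probability is always >= 0.5).  Returns
    counts, per-band accuracy, and the high-confidence misclassifications.
    """
    if lo >= hi:
        raise ValueError("lo must be below hi")
    df = predictions.copy()
    df["correct"] = (df["label"] == df["predicted"]).astype(int)
    bands = np.where(df["confidence"] >= hi, f">={hi:.2f}",
                     np.where(df["confidence"] > lo,
                              f"({lo:.2f},{hi:.2f})", f"<={lo:.2f}"))
    df["band"] = bands
    out = (df.groupby("band")
             .agg(n=("correct", "size"), accuracy=("correct", "mean"))
             .reset_index())
    out["high_conf_misclassified"] = [
        list(df.loc[(df["band"] == b) & (df["correct"] == 0), "patient_id"])
        if b == f">={hi:.2f}" else [] for b in out["band"]]
    return out


# ---------------------------------------------------------------------------
# Replicate-staining robustness
# ---------------------------------------------------------------------------

def replicate_concordance(abund_a: pd.DataFrame,
                          abund_b: pd.DataFrame) -> pd.DataFrame:
    """Per-element Spearman r between paired replicate quantifications.

    Rows of the two frames must be paired by patient/core id; at least five
    pairs are required.
    """
    if list(abund_a.index) != list(abund_b.index):
        raise ValueError("replicate frames must be paired by identical index")
    if list(abund_a.columns) != list(abund_b.columns):
        raise ValueError("replicate frames must share element columns")
    if len(abund_a) < 5:
        raise ValueError("need at least 5 paired replicates")
    rows = []
    for col in abund_a.columns:
        a = abund_a[col].to_numpy()
        b = abund_b[col].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.spearmanr(a, b)
        rows.append({"element": col, "r": float(r), "p": float(p),
                     "significant_positive": bool(r > 0 and p < 0.05)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeReport:
    splits: list = field(default_factory=list)  # (feature, threshold, depth)
    leaf_purities: list = field(default_factory=list)
    depth: int = 0
    root_feature: str | None = None
    training_accuracy: float = 0.0
    tree_: object = None

    def to_json(self) -> str:
        return json.dumps({
            "splits": [{"feature": f, "threshold": t, "depth": d}
                       for f, t, d in self.splits],
            "leaf_purities": self.leaf_purities,
            "depth": self.depth,
            "root_feature": self.root_feature,
            "training_accuracy": self.training_accuracy}, indent=1)

    def to_text(self) -> str:
        lines = ["digraph decision_tree {"]
        for i, (f, t, d) in enumerate(self.splits):
            lines.append(f'  n{i} [label="{f} <= {t:.4f} (depth {d})"];')
        lines.append("}")
        return "\n".join(lines)


def fit_decision_tree(enrichments: pd.DataFrame, labels: np.ndarray,
                      max_depth: int = 3, seed: int = 0) -> TreeReport:
    """CART regression tree on normalized element abundances.

    Fit on {0,1} recurrence targets (variance-reduction splits, equivalent
    to Gini up to scaling); the split sequence is serialized in the report.
    Constant features yield a single-leaf tree with a warning.
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to fit the tree")
    X = enrichments.to_numpy(dtype=float)
    names = list(enrichments.columns)
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("all features constant; single-leaf tree")
        rep = TreeReport(depth=0,
                         training_accuracy=max(labels.mean(),
                                               1 - labels.mean()))
        rep.leaf_purities = [max(labels.mean(), 1 - labels.mean())]
        return rep
    tree = DecisionTreeRegressor(max_depth=max_depth if max_depth > 0 else 1,
                                 random_state=seed)
    if max_depth == 0:
        rep = TreeReport(depth=0,
                         training_accuracy=max(labels.mean(),
                                               1 - labels.mean()))
        rep.leaf_purities = [max(labels.mean(), 1 - labels.mean())]
        return rep
    tree.fit(X, labels)
    t = tree.tree_
    splits, purities = [], []

    def walk(node, depth):
        if t.children_left[node] == -1:
            frac = float(t.value[node].ravel()[0])
            purities.append(max(frac, 1 - frac))
            return
        splits.append((names[t.feature[node]],
                       float(t.threshold[node]), depth))
        walk(t.children_left[node], depth + 1)
        walk(t.children_right[node], depth + 1)

    walk(0, 0)
    pred = (tree.predict(X) >= 0.5).astype(int)
    rep = TreeReport(splits=splits, leaf_purities=purities,
                     depth=int(t.max_depth),
                     root_feature=splits[0][0] if splits else None,
                     training_accuracy=float((pred == labels).mean()),
                     tree_=tree)
    return rep
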