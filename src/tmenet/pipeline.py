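"""End-to-end workflows tying the stages together.

These functions are the programmatic counterparts of the command-line
subcommands: embed a cohort, train, quantify per-patient enrichment, run
the planted-structure recovery experiment, and run the replicate-staining
robustness experiment.  Every entry point takes a seed and is fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .evaluation import fit_decision_tree, replicate_concordance
from .io import normalize_channels, preprocess_core
from .model import ModelConfig, PatientDataset, assemble_dataset, train_model
from .patches import build_patchsets, standardize_patchsets
from .synthetic import (BatchEffectSpec, apply_batch_effect, generate_cohort,
                        two_class_config)

#: Model settings for planted-structure recovery on the synthetic cohort:
#: element counts match the planted 3 phenotypes / 2 neighborhoods / 2 areas,
#: and the phenotype head is cluster-warm-started with a mild confidence
#: regularizer so that elements carrying no class signal stay identified.
RECOVERY_MODEL = dict(P=3, N=2, A=2, K=2, hidden=32, epochs=60, lr=1e-3,
                      dropout=0.1, confidence_weight=0.05,
                      warmstart_epochs=3, classifier_polish_steps=500)

#: Embedding width for the handcrafted featureizer at desk scale (the 42
#: informative features, zero-padded).
RECOVERY_EMBED_DIM = 64


def embed_cohort(cores, table, *, d: int = RECOVERY_EMBED_DIM,
                 patch_size: int = 20, encoder=None,
                 standardize_on: list | None = None,
                 stats: tuple | None = None):
    """Patch, embed, and standardize a cohort into per-patient PatchSets.

    Returns ``(patchsets, stats)`` where ``stats`` are the standardization
    mean/sd actually used (frozen ``stats`` take precedence over refitting).
    """
    patchsets = build_patchsets(cores, table, patch_size=patch_size, d=d,
                                encoder=encoder)
    stats = standardize_patchsets(patchsets, fit_patients=standardize_on,
                                  stats=stats)
    return patchsets, stats


def preprocess_cohort(cores, window: int = 50, shrink: int | None = None,
                      normalize: str = "institution"):
    """Rolling-ball subtraction per channel, then per-group channel
    normalization (gain-tolerance across staining batches)."""
    cores = [preprocess_core(c, window=window, shrink=shrink) for c in cores]
    if normalize:
        cores = normalize_channels(cores, groupby=normalize)
    return cores


def quantify(net, dataset: PatientDataset):
    """Per-patient enrichment table, predictions, and assignment bundles."""
    enr_rows, pred_rows, bundles = [], [], {}
    for pid in dataset.patient_ids:
        pred, enr, bundle = net.predict(dataset.patchsets[pid],
                                        dataset.graphs[pid])
        enr_rows.append(pd.Series(enr.normalized, index=enr.feature_names(),
                                  name=pid))
        pred_rows.append({"patient_id": pid, "label": dataset.labels[pid],
                          "p_recurrence": pred.p_recurrence,
                          "predicted": pred.label,
                          "confidence": pred.confidence})
        bundles[pid] = bundle
    return pd.DataFrame(enr_rows), pd.DataFrame(pred_rows), bundles


def stratified_split(ids, labels, test_fraction: float, seed: int):
    """Deterministic stratified train/test patient split."""
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test = []
    for cls in np.unique(labels):
        cls_ids = np.sort(ids[labels == cls])
        k = max(1, int(round(test_fraction * len(cls_ids))))
        test += list(rng.choice(cls_ids, size=k, replace=False))
    train = [p for p in ids if p not in set(test)]
    return train, list(test)


def _argmax_labels(dataset: PatientDataset, bundles: dict, key: str):
    return np.concatenate([np.argmax(getattr(bundles[p], key), axis=1)
                           for p in dataset.patient_ids])


def _truth_labels(dataset: PatientDataset, gt, level: str):
    return np.concatenate([
        gt.flat_labels(level, dataset.patchsets[p].core_ids)
        for p in dataset.patient_ids])


def map_elements_to_planted(dataset: PatientDataset, bundles: dict, gt,
                            key: str, level: str) -> dict:
    """Map each learned element to the planted label it overlaps most."""
    pred = _argmax_labels(dataset, bundles, key)
    true = _truth_labels(dataset, gt, level)
    n_learned = getattr(bundles[dataset.patient_ids[0]], key).shape[1]
    mapping = {}
    for e in range(n_learned):
        sel = pred == e
        if sel.sum() == 0:
            mapping[e] = -1
            continue
        mapping[e] = int(np.bincount(true[sel]).argmax())
    return mapping


def recovery_experiment(seed: int = 0, n_patients: int = 40,
                        core_size: int = 512, cv_folds: int = 4,
                        preprocess: bool = True) -> dict:
    """Planted-structure recovery on the hot/cold synthetic cohort.

    Generates the two-class cohort (two cores per patient, balanced
    classes) and measures: held-out AUC for recurrence from pooled
    out-of-fold predictions of a stratified ``cv_folds``-fold
    cross-validation, patch-level adjusted Rand index of phenotype/
    neighborhood/area recovery by a final model trained on the full cohort,
    and the clinical decision tree's root split.
    """
    from .evaluation import run_cross_validation

    cfg = two_class_config(n_patients=n_patients, core_size=core_size,
                           seed=seed)
    cores, table, gt = generate_cohort(cfg)
    if preprocess:
        cores = preprocess_cohort(cores)
    labels = np.array(table.labels)
    patchsets, stats = embed_cohort(cores, table)
    dataset = assemble_dataset(patchsets, table)

    model_cfg = ModelConfig(seed=seed, **RECOVERY_MODEL)

    # held-out discrimination: pooled out-of-fold predictions
    cv = run_cross_validation(dataset, model_cfg, table, k=cv_folds,
                              seed=seed)
    auc = cv.auc

    # final model on the full cohort for structure recovery + deployment
    net, history = train_model(dataset, model_cfg)

    # structure recovery over the whole cohort
    enrich, pred, bundles = quantify(net, dataset)
    ari = {}
    for level, key in (("phenotype", "S_P"), ("neighborhood", "S_N"),
                       ("area", "S_A_patch")):
        ari[level] = adjusted_rand_score(
            _truth_labels(dataset, gt, level),
            _argmax_labels(dataset, bundles, key))

    # clinical decision support: tree on tissue-area abundances; the root
    # split should align with the planted cold/hot axis
    area_cols = [c for c in enrich.columns if c.startswith("A")]
    tree_area = fit_decision_tree(enrich[area_cols], labels, max_depth=3,
                                  seed=seed)
    area_map = map_elements_to_planted(dataset, bundles, gt, "S_A_patch",
                                       "area")
    root_idx = (int(tree_area.root_feature[1:]) - 1
                if tree_area.root_feature else -1)
    tree_full = fit_decision_tree(enrich, labels, max_depth=3, seed=seed)

    return {
        "auc": float(auc),
        "cv_report": cv,
        "ari": ari,
        "tree_area_root": tree_area.root_feature,
        "tree_area_root_planted": int(area_map.get(root_idx, -1)),
        "tree_area_accuracy": tree_area.training_accuracy,
        "tree_full_root": tree_full.root_feature,
        "tree_full_accuracy": tree_full.training_accuracy,
        "history": history,
        "net": net,
        "dataset": dataset,
        "table": table,
        "ground_truth": gt,
        "enrichment": enrich,
        "predictions": pred,
        "bundles": bundles,
        "area_map": area_map,
        "standardizer": stats,
    }


def robustness_experiment(net, standardizer, seed: int = 0,
                          n_patients: int = 19, core_size: int = 512,
                          gain_b: tuple = (1.8, 0.6, 1.5, 0.7, 1.3, 0.8, 1.9),
                          d: int = RECOVERY_EMBED_DIM) -> dict:
    """Replicate-staining robustness under gain-only batch effects.

    A replicate cohort is generated once; every core is then "stained"
    twice — institution A with unit gains, institution B with per-channel
    gains up to 2x.  Both replicates are quantified with the already
    trained model and its frozen standardization statistics (so the batch
    effect genuinely shifts the model inputs); reported are the per-element
    Spearman concordance of patient abundances across institutions and the
    agreement of predicted labels.
    """
    cfg = two_class_config(n_patients=n_patients, core_size=core_size,
                           seed=seed + 101,
                           institutions=[BatchEffectSpec()])
    cores, table, gt = generate_cohort(cfg)

    def replicate(spec: BatchEffectSpec, tag: int):
        reps = [apply_batch_effect(c, spec, seed=seed + tag + i)
                for i, c in enumerate(cores)]
        # each replicate set is one staining batch -> per-batch preprocessing
        reps = preprocess_cohort(reps, normalize="cohort")
        patchsets, _ = embed_cohort(reps, table, d=d, stats=standardizer)
        return assemble_dataset(patchsets, table)

    ds_a = replicate(BatchEffectSpec(), 0)
    ds_b = replicate(BatchEffectSpec(gain=tuple(gain_b)), 7919)

    enr_a, pred_a, _ = quantify(net, ds_a)
    enr_b, pred_b, _ = quantify(net, ds_b)
    conc = replicate_concordance(enr_a, enr_b)
    agree = float((pred_a["predicted"].to_numpy()
                   == pred_b["predicted"].to_numpy()).mean())
    return {
        "element_concordance": conc,
        "fraction_positive_r": float((conc["r"] > 0).mean()),
        "prediction_concordance": agree,
        "enrichment_a": enr_a,
        "enrichment_b": enr_b,
    }
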