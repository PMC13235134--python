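"""Generalization protocols, classification metrics, and the experiment runner.

Four split strategies probe different clinical questions: random pair k-fold
(interpolating to unseen pairs), leave-one-drug-out (new compounds),
leave-one-cell-line-out (new patients), and leave-one-cancer-type-out
(new disease contexts). Metrics are AUC (Mann-Whitney concordance) and AUPR
(step-wise precision-recall area), reported per fold and as mean +/- sample
standard deviation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import network as net_mod
from .drugs import DrugSet, ResponseRecord
from .hierarchy import BioHierarchy, masks_from_hierarchy, prune_hierarchy
from .network import TrainConfig, init_network, train
from .omics import OmicsMatrix, integrate_omics, minmax_scale

logger = logging.getLogger(__name__)

STRATEGIES = ("pair_kfold", "lodo", "loclo", "loco")


@dataclass
class SplitPlan:
    """Folds over a fixed record ordering; each fold is
    (fold_id, train indices, test indices)."""

    strategy: str
    folds: list[tuple[str, np.ndarray, np.ndarray]]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for fold_id, tr, te in self.folds:
            if set(tr) & set(te):
                raise ValueError(f"fold {fold_id}: train/test overlap")


def split_pair_kfold(records: list[ResponseRecord], k: int = 5,
                     seed: int = 0, stratified: bool = False) -> SplitPlan:
    """Seeded random partition of (cell, drug) pairs into k folds; no
    restriction on which drugs or cell lines appear on each side.

    ``stratified=True`` balances the label ratio across folds (off by
    default: the reference protocol splits purely at random).
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of records {n}")
    rng = np.random.default_rng(seed)
    if stratified:
        labels = np.array([r.label for r in records])
        fold_of = np.empty(n, dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            fold_of[idx] = np.arange(len(idx)) % k
    else:
        fold_of = rng.permutation(n) % k
    folds = []
    for f in range(k):
        te = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        folds.append((f"fold{f}", tr, te))
    return SplitPlan("pair_kfold", folds, seed=seed)


def _leave_one_group_out(records, group_of, strategy: str, noun: str) -> SplitPlan:
    groups = list(dict.fromkeys(group_of(r) for r in records))
    if len(groups) < 2:
        raise ValueError(f"need at least 2 distinct {noun}s, found {len(groups)}")
    keys = np.array([group_of(r) for r in records])
    folds = []
    for g in groups:
        te = np.flatnonzero(keys == g)
        tr = np.flatnonzero(keys != g)
        folds.append((str(g), tr, te))
    return SplitPlan(strategy, folds)


def split_lodo(records: list[ResponseRecord]) -> SplitPlan:
    """Leave-one-drug-out: one fold per drug, that drug's records held out."""
    return _leave_one_group_out(records, lambda r: r.drug_id, "lodo", "drug")


def split_loclo(records: list[ResponseRecord]) -> SplitPlan:
    """Leave-one-cell-line-out: one fold per cell line."""
    return _leave_one_group_out(records, lambda r: r.cell_id, "loclo", "cell line")


def split_loco(records: list[ResponseRecord],
               cancer_map: dict[str, str]) -> SplitPlan:
    """Leave-one-cancer-type-out: all cell lines of one type held out."""
    unmapped = sorted({r.cell_id for r in records} - set(cancer_map))
    if unmapped:
        raise ValueError(f"cell line(s) without cancer type: {unmapped[:5]}")
    return _leave_one_group_out(records, lambda r: cancer_map[r.cell_id],
                                "loco", "cancer type")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability:
    P(score_pos > score_neg) + 0.5 * P(tie), via average ranks."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by the step-wise
    (non-interpolated) rule: sum of precision * recall increments at each
    distinct threshold, descending."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied-score run
    boundary = np.append(s[1:] != s[:-1], True)
    tp_b = tp[boundary]
    precision = tp_b / pred_pos[boundary]
    recall = tp_b / n_pos
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * d_recall))


def accuracy(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    return float(((np.asarray(scores) >= threshold).astype(int)
                  == np.asarray(labels)).mean())


@dataclass
class DataBundle:
    """Everything one experiment needs: the (unfiltered) hierarchy, raw
    omics layers, the drug set, labelled responses and the cancer-type map."""

    hierarchy: BioHierarchy
    omics: list[OmicsMatrix]
    drugs: DrugSet
    responses: list[ResponseRecord]
    cancer_map: dict[str, str]


def prepare_model_inputs(bundle: DataBundle,
                         omics_subset: set[str] | None = None):
    """Scale + integrate the (optionally restricted) omics layers, then
    re-prune the hierarchy against the reduced gene universe and emit masks.

    Returns (features, masks, pruned_hierarchy). The network's input layer
    is exactly the pruned hierarchy's gene list.
    """
    layers = bundle.omics
    if omics_subset is not None:
        layers = [m for m in layers if m.kind in omics_subset]
        if not layers:
            raise ValueError(f"omics subset {omics_subset} matches no layer")
    feats = integrate_omics([minmax_scale(m) for m in layers])
    universe = set(feats.feature_ids)
    h = bundle.hierarchy
    restricted = replace(
        h,
        genes=[g for g in h.genes if g in universe],
        edges_gp={(g, p) for (g, p) in h.edges_gp if g in universe},
        gp_scores={e: s for e, s in h.gp_scores.items() if e[0] in universe},
    )
    pruned = prune_hierarchy(restricted)
    masks = masks_from_hierarchy(pruned)
    return feats, masks, pruned


def run_experiment(bundle: DataBundle, plan: SplitPlan, config: TrainConfig,
                   omics_subset: set[str] | None = None) -> pd.DataFrame:
    """Per-fold train -> predict -> score over a split plan.

    Each fold retrains from scratch with identical hyperparameters. Folds
    whose test set contains a single class are reported with NaN metrics
    rather than silently skipped. Returns a tidy table
    (strategy, fold_id, n_train, n_test, auc, aupr, accuracy).
    """
    feats, masks, pruned = prepare_model_inputs(bundle, omics_subset)
    records = bundle.responses
    rows = []
    for fold_id, tr_idx, te_idx in plan.folds:
        train_recs = [records[i] for i in tr_idx]
        test_recs = [records[i] for i in te_idx]
        net = init_network(masks, bundle.drugs.n_bits, config,
                           pk_scores=pruned.pk_scores)
        net, _ = train(net, feats, bundle.drugs, train_recs, config)
        scores = net_mod.predict(net, [(r.cell_id, r.drug_id) for r in test_recs],
                                 feats, bundle.drugs)
        y = np.array([r.label for r in test_recs])
        row = {"strategy": plan.strategy, "fold_id": fold_id,
               "n_train": len(train_recs), "n_test": len(test_recs)}
        if 0 < y.sum() < len(y):
            row.update(auc=auc(scores, y), aupr=aupr(scores, y),
                       accuracy=accuracy(scores, y))
        else:  # single-class fold: metric undefined
            row.update(auc=np.nan, aupr=np.nan, accuracy=accuracy(scores, y))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample standard deviation across folds, per strategy."""
    out = []
    for strategy, grp in metrics.groupby("strategy"):
        row = {"strategy": strategy, "n_folds": len(grp)}
        for m in ("auc", "aupr", "accuracy"):
            vals = grp[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def run_ablation(bundle: DataBundle, config: TrainConfig, k: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Omics-ablation harness: k-fold pair CV repeated for the all-omics
    configuration, each leave-one-omics-out configuration, and each
    single-omics configuration; reports mean accuracy/AUC/AUPR per
    configuration."""
    kinds = [m.kind for m in bundle.omics]
    configs: list[tuple[str, set[str] | None]] = [("all", None)]
    for kind in kinds:
        configs.append((f"w/o {kind}", set(kinds) - {kind}))
    for kind in kinds:
        configs.append((f"only {kind}", {kind}))
    plan = split_pair_kfold(bundle.responses, k=k, seed=seed)
    rows = []
    for name, subset in configs:
        metrics = run_experiment(bundle, plan, copy.deepcopy(config),
                                 omics_subset=subset)
        s = summarize(metrics).iloc[0]
        rows.append({"configuration": name,
                     "accuracy": s["accuracy_mean"], "auc": s["auc_mean"],
                     "aupr": s["aupr_mean"]})
        logger.info("ablation %-12s acc=%.4f auc=%.4f aupr=%.4f", name,
                    rows[-1]["accuracy"], rows[-1]["auc"], rows[-1]["aupr"])
    return pd.DataFrame(rows)
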