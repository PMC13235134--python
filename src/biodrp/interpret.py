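"""Multi-level feature importance for the masked network.

Gene-level importance combines four complementary views of a trained model
on a held-out test set: mean absolute loss gradient w.r.t. each input gene,
mean absolute input value, unbiased input variance, and the permutation
increase in loss when a gene's column is shuffled. Proteins, pathways and
drugs are scored by mean absolute activation of their layer nodes. Scores
from independent training runs are aggregated by top-k frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MaskedNetwork, bce_loss

GENE_SCORE_NAMES = ("grad", "act", "var", "perm")
LAYER_LEVELS = ("protein", "pathway", "drug")


@dataclass
class ImportanceReport:
    """Per-entity importance scores at one level of the hierarchy."""

    level: str  # gene | protein | pathway | drug
    entity_ids: list[str]
    scores: dict[str, np.ndarray]
    n_samples: int
    run_id: int = 0

    def __post_init__(self) -> None:
        for name, s in self.scores.items():
            s = np.asarray(s, dtype=np.float64)
            if s.shape != (len(self.entity_ids),):
                raise ValueError(f"score {name!r} misaligned with entity list")
            if not np.isfinite(s).all() or (s < 0).any():
                raise ValueError(f"score {name!r} must be finite and >= 0")
            self.scores[name] = s

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": self.level, "entity_id": e, "score_name": name,
             "value": float(s[i]), "run_id": self.run_id}
            for name, s in self.scores.items()
            for i, e in enumerate(self.entity_ids)
        ]
        return pd.DataFrame(rows)


def _check_nonempty(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    return X


def gradient_importance(net: MaskedNetwork, X: np.ndarray, FP: np.ndarray,
                        labels: np.ndarray) -> np.ndarray:
    """Mean absolute per-sample loss gradient w.r.t. each input gene,

        S_grad(i) = (1/N) sum_j |dL(f(x_j), y_j) / dx_ji|.
    """
    X = _check_nonempty(X)
    grads = net.loss_input_gradients(X, FP, labels)
    return np.abs(grads).mean(axis=0)


def activation_importance(X: np.ndarray) -> np.ndarray:
    """Mean absolute input value per gene, S_act(i) = (1/N) sum_j |x_ji|;
    model-independent."""
    X = _check_nonempty(X)
    return np.abs(X).mean(axis=0)


def variance_importance(X: np.ndarray) -> np.ndarray:
    """Unbiased (N-1 divisor) sample variance per gene."""
    X = _check_nonempty(X)
    if X.shape[0] < 2:
        raise ValueError("variance importance needs at least 2 samples")
    return X.var(axis=0, ddof=1)


def permutation_importance(net: MaskedNetwork, X: np.ndarray, FP: np.ndarray,
                           labels: np.ndarray, n_repeats: int = 5,
                           seed: int = 0) -> np.ndarray:
    """Permutation importance: clipped mean increase in BCE when a gene's
    column is shuffled across test samples,

        S_perm(i) = max(0, mean over repeats of [error_perm(i) - error_base]).
    """
    X = _check_nonempty(X)
    if X.shape[0] < 2:
        raise ValueError("permutation importance needs at least 2 samples")
    labels = np.asarray(labels, dtype=np.float64)
    rng = np.random.default_rng(seed)
    error_base = bce_loss(net.forward_batch(X, FP), labels)
    deltas = np.zeros(X.shape[1])
    for _ in range(n_repeats):
        for i in range(X.shape[1]):
            col = X[:, i].copy()
            Xp = X.copy()
            Xp[:, i] = rng.permutation(col)
            deltas[i] += bce_loss(net.forward_batch(Xp, FP), labels) - error_base
    return np.maximum(0.0, deltas / n_repeats)


def _minmax(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def combined_importance(grad: np.ndarray, act: np.ndarray, var: np.ndarray,
                        perm: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Average of the four gene scores.

    The four scores live on incommensurable scales, so by default each is
    min-max normalized across genes before averaging; ``normalize=False``
    averages the raw values instead.
    """
    vecs = [np.asarray(v, dtype=np.float64) for v in (grad, act, var, perm)]
    n = {v.shape for v in vecs}
    if len(n) != 1 or vecs[0].ndim != 1:
        raise ValueError("the four score vectors must be 1-D and aligned")
    if normalize:
        vecs = [_minmax(v) for v in vecs]
    return np.mean(vecs, axis=0)


def gene_importance_report(net: MaskedNetwork, X: np.ndarray, FP: np.ndarray,
                           labels: np.ndarray, n_repeats: int = 5,
                           seed: int = 0, run_id: int = 0) -> ImportanceReport:
    """All four gene-level scores plus their combination, in network gene
    order."""
    grad = gradient_importance(net, X, FP, labels)
    act = activation_importance(X)
    var = variance_importance(X)
    perm = permutation_importance(net, X, FP, labels, n_repeats=n_repeats, seed=seed)
    comb = combined_importance(grad, act, var, perm)
    return ImportanceReport(
        level="gene", entity_ids=list(net.genes),
        scores={"grad": grad, "act": act, "var": var, "perm": perm,
                "combined": comb},
        n_samples=int(np.atleast_2d(X).shape[0]), run_id=run_id)


def layer_importance(net: MaskedNetwork, X: np.ndarray, FP: np.ndarray,
                     level: str, run_id: int = 0) -> ImportanceReport:
    """Mean absolute activation per node of one hidden layer,
    S_layer(k) = (1/N) sum_j |a_jk|."""
    if level not in LAYER_LEVELS:
        raise ValueError(f"level must be one of {LAYER_LEVELS}, got {level!r}")
    X = _check_nonempty(X)
    acts = net.activations(X, FP)[level]
    ids = {"protein": net.proteins, "pathway": net.pathways, "drug": net.drugs}[level]
    return ImportanceReport(level=level, entity_ids=list(ids),
                            scores={"layer": np.abs(acts).mean(axis=0)},
                            n_samples=X.shape[0], run_id=run_id)


def aggregate_runs(reports: list[ImportanceReport], top_k: int = 20,
                   n_select: int = 10, score_name: str | None = None,
                   ) -> pd.DataFrame:
    """Aggregate independent runs by top-k membership frequency.

    Per run, the ``top_k`` entities by score are selected (ties broken by
    entity ID); entities are then ranked by how many runs selected them,
    ties broken by mean score across runs, then by ID. Returns the top
    ``n_select`` rows with columns (entity_id, frequency, mean_score).
    """
    if not reports:
        raise ValueError("no importance reports to aggregate")
    level = reports[0].level
    universe = reports[0].entity_ids
    if any(r.level != level or r.entity_ids != universe for r in reports):
        raise ValueError("reports must share level and entity universe")
    if score_name is None:
        score_name = "combined" if level == "gene" else "layer"

    counts: dict[str, int] = {e: 0 for e in universe}
    sums = {e: 0.0 for e in universe}
    for rep in reports:
        s = rep.scores[score_name]
        order = sorted(range(len(universe)), key=lambda i: (-s[i], universe[i]))
        for i in order[:top_k]:
            counts[universe[i]] += 1
        for e, v in zip(universe, s):
            sums[e] += float(v)
    mean_score = {e: sums[e] / len(reports) for e in universe}
    ranked = sorted(universe, key=lambda e: (-counts[e], -mean_score[e], e))
    top = [e for e in ranked if counts[e] > 0][:n_select]
    return pd.DataFrame({"entity_id": top,
                         "frequency": [counts[e] for e in top],
                         "mean_score": [mean_score[e] for e in top]})
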