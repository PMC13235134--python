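"""Biologically-masked feedforward network for drug-response classification.

The model is a three-hidden-layer feedforward classifier whose hidden layers
correspond to protein complexes, pathways and drugs. Each weight matrix
``W`` carries a binary mask ``M`` applied elementwise in every forward pass,

    y_l = ReLU((M_l * W_l)^T x_{l-1} + b_l),

so only biologically annotated connections carry signal, and — because the
loss reaches a weight only through ``M * W`` — the gradient at a masked-out
position is identically zero: masked weights never move under training.
The drug-layer output is concatenated with the sample's drug fingerprint and
mapped through a single sigmoid unit; training minimises mean binary
cross-entropy with mini-batch Adam.

The implementation is plain NumPy in float64 with hand-derived
backpropagation, which keeps gradients exact enough for tight
finite-difference checks and makes per-sample input gradients (used by the
interpretability module) a first-class output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .hierarchy import LayerMask

PROB_EPS = 1e-7  # probability clipping inside the loss, for numerical safety


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the reference settings
    (batch 64, 50 epochs, Adam with learning rate 0.001)."""

    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 0.001
    seed: int = 0
    optimizer: str = "adam"
    init_scheme: str = "glorot"  # or "glorot_enrichment"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.init_scheme not in ("glorot", "glorot_enrichment"):
            raise ValueError(f"unsupported init scheme {self.init_scheme!r}")


@dataclass
class MaskedNetwork:
    """Parameters and masks of the network; node orders come verbatim from
    the pruned hierarchy and index every layer consistently."""

    masks: list[LayerMask]            # gene->protein, protein->pathway, pathway->drug
    weights: list[np.ndarray]         # same shapes as the masks
    biases: list[np.ndarray]          # per-layer target-size vectors
    output_weights: np.ndarray        # length n_drugs + n_fingerprint_bits
    output_bias: float
    n_fingerprint_bits: int

    @property
    def genes(self) -> list[str]:
        return self.masks[0].source_ids

    @property
    def proteins(self) -> list[str]:
        return self.masks[0].target_ids

    @property
    def pathways(self) -> list[str]:
        return self.masks[1].target_ids

    @property
    def drugs(self) -> list[str]:
        return self.masks[2].target_ids

    def effective_weights(self) -> list[np.ndarray]:
        return [lm.mask * w for lm, w in zip(self.masks, self.weights)]

    def effective_parameter_count(self) -> int:
        """Trainable parameters that can influence the output: one per mask
        edge, plus biases, output weights and output bias."""
        n = sum(lm.n_edges for lm in self.masks)
        n += sum(b.size for b in self.biases)
        n += self.output_weights.size + 1
        return int(n)

    def dense_parameter_count(self) -> int:
        n = sum(w.size for w in self.weights)
        n += sum(b.size for b in self.biases)
        n += self.output_weights.size + 1
        return int(n)

    # ---- forward -------------------------------------------------------

    def _forward_cached(self, X: np.ndarray, FP: np.ndarray):
        """Batched forward pass keeping pre-activations for backprop.

        X: batch x n_genes; FP: batch x n_bits. Returns (probs, cache).
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        FP = np.atleast_2d(np.asarray(FP, dtype=np.float64))
        if X.shape[1] != len(self.genes):
            raise ValueError(
                f"cell feature length {X.shape[1]} != gene layer size {len(self.genes)}")
        if FP.shape[1] != self.n_fingerprint_bits:
            raise ValueError(
                f"fingerprint length {FP.shape[1]} != configured bits "
                f"{self.n_fingerprint_bits}")
        eff = self.effective_weights()
        Z, H = [], [X]
        h = X
        for W, b in zip(eff, self.biases):
            z = h @ W + b
            h = np.maximum(z, 0.0)
            Z.append(z)
            H.append(h)
        concat = np.concatenate([h, FP], axis=1)
        z_out = concat @ self.output_weights + self.output_bias
        probs = _sigmoid(z_out)
        return probs, {"Z": Z, "H": H, "concat": concat, "eff": eff, "FP": FP}

    def forward_batch(self, X: np.ndarray, FP: np.ndarray) -> np.ndarray:
        """Predicted sensitivity probabilities for a batch."""
        probs, _ = self._forward_cached(X, FP)
        return probs

    def activations(self, X: np.ndarray, FP: np.ndarray) -> dict[str, np.ndarray]:
        """Hidden-layer activations (batch x nodes) keyed by level name."""
        _, cache = self._forward_cached(X, FP)
        return {"protein": cache["H"][1], "pathway": cache["H"][2],
                "drug": cache["H"][3]}

    # ---- backward ------------------------------------------------------

    def _backward(self, cache, probs, labels, need_input_grad: bool = False):
        """Gradients of the mean BCE loss; optionally also the per-sample
        gradient of each sample's own loss w.r.t. its input row."""
        B = probs.shape[0]
        dz_out = probs - labels  # per-sample dL_n/dz_out for BCE∘sigmoid
        grad_w_out = cache["concat"].T @ dz_out / B
        grad_b_out = float(dz_out.mean())

        n_drugs = len(self.drugs)
        delta = dz_out[:, None] * self.output_weights[None, :n_drugs]
        grads_W, grads_b = [None] * 3, [None] * 3
        for layer in (2, 1, 0):
            delta = delta * (cache["Z"][layer] > 0)
            grads_W[layer] = self.masks[layer].mask * (cache["H"][layer].T @ delta) / B
            grads_b[layer] = delta.mean(axis=0)
            if layer > 0 or need_input_grad:
                delta = delta @ cache["eff"][layer].T
        input_grad = delta if need_input_grad else None
        return grads_W, grads_b, grad_w_out, grad_b_out, input_grad

    def loss_input_gradients(self, X: np.ndarray, FP: np.ndarray,
                             labels: np.ndarray) -> np.ndarray:
        """Per-sample d(loss_n)/d(x_n): rows align with input rows."""
        probs, cache = self._forward_cached(X, FP)
        *_, input_grad = self._backward(cache, probs, np.asarray(labels, float),
                                        need_input_grad=True)
        return input_grad

    # ---- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (lm, W, b) in enumerate(zip(self.masks, self.weights, self.biases)):
            arrays[f"mask{i}"] = lm.mask
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["w_out"] = self.output_weights
        np.savez(d / "model.npz", **arrays)
        meta = {
            "output_bias": self.output_bias,
            "n_fingerprint_bits": self.n_fingerprint_bits,
            "node_orders": {
                "gene": self.genes, "protein": self.proteins,
                "pathway": self.pathways, "drug": self.drugs,
            },
        }
        (d / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "MaskedNetwork":
        d = Path(directory)
        arrs = np.load(d / "model.npz")
        meta = json.loads((d / "model.json").read_text())
        orders = meta["node_orders"]
        level_ids = [orders["gene"], orders["protein"], orders["pathway"], orders["drug"]]
        masks = [LayerMask(level_ids[i], level_ids[i + 1], arrs[f"mask{i}"])
                 for i in range(3)]
        return cls(
            masks=masks,
            weights=[arrs[f"W{i}"] for i in range(3)],
            biases=[arrs[f"b{i}"] for i in range(3)],
            output_weights=arrs["w_out"],
            output_bias=float(meta["output_bias"]),
            n_fingerprint_bits=int(meta["n_fingerprint_bits"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(masks: tuple[LayerMask, LayerMask, LayerMask],
                 n_fingerprint_bits: int, config: TrainConfig,
                 pk_scores: Optional[dict[tuple[str, str], float]] = None,
                 ) -> MaskedNetwork:
    """Seeded Glorot-uniform initialization on unmasked positions.

    Masked positions start (and stay) at exactly zero. With
    ``init_scheme="glorot_enrichment"`` the protein->pathway initial weights
    are additionally scaled by the stored combined enrichment score of the
    edge, normalized to unit mean over present edges.
    """
    masks = list(masks)
    for a, b in zip(masks[:-1], masks[1:]):
        if a.target_ids != b.source_ids:
            raise ValueError(
                f"mask chain mismatch at junction {a.target_ids[:3]}... vs "
                f"{b.source_ids[:3]}...: targets of one layer must be the "
                "sources of the next")
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for lm in masks:
        fan_in, fan_out = lm.mask.shape
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=lm.mask.shape) * lm.mask
        weights.append(W)
        biases.append(np.zeros(fan_out))
    if config.init_scheme == "glorot_enrichment":
        if not pk_scores:
            raise ValueError("glorot_enrichment requires protein->pathway scores")
        lm = masks[1]
        scale = np.ones(lm.mask.shape)
        vals = [s for s in pk_scores.values() if s > 0]
        mean_s = float(np.mean(vals)) if vals else 1.0
        p_idx = {p: i for i, p in enumerate(lm.source_ids)}
        k_idx = {k: j for j, k in enumerate(lm.target_ids)}
        for (p, k), s in pk_scores.items():
            if p in p_idx and k in k_idx:
                scale[p_idx[p], k_idx[k]] = s / mean_s
        weights[1] = weights[1] * scale

    n_out_in = len(masks[2].target_ids) + n_fingerprint_bits
    limit = np.sqrt(6.0 / (n_out_in + 1))
    w_out = rng.uniform(-limit, limit, size=n_out_in)
    return MaskedNetwork(masks=masks, weights=weights, biases=biases,
                         output_weights=w_out, output_bias=0.0,
                         n_fingerprint_bits=n_fingerprint_bits)


def forward(net: MaskedNetwork, cell_features: np.ndarray,
            fingerprint: np.ndarray) -> float:
    """Single-sample forward pass; returns the sensitivity probability."""
    return float(net.forward_batch(cell_features[None, :], fingerprint[None, :])[0])


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to
    [1e-7, 1 - 1e-7]."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty inputs to bce_loss")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) over a list of
    parameter arrays. A parameter with identically-zero gradient keeps zero
    first/second moments, so its update is exactly zero."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def design_matrices(features, drugs, records):
    """Align response records with the feature matrix and fingerprints.

    ``features`` may be an IntegratedCellFeatures or any object with
    ``cell_ids``/``feature_ids``/``values``; rows of the returned X follow
    the record order. Raises on unresolvable IDs, listing offenders.
    """
    cell_idx = {c: i for i, c in enumerate(features.cell_ids)}
    bad_cells = sorted({r.cell_id for r in records} - set(cell_idx))
    bad_drugs = sorted({r.drug_id for r in records} - set(drugs.drug_ids))
    if bad_cells or bad_drugs:
        raise ValueError(
            f"unresolvable IDs in response records: cells={bad_cells[:5]}, "
            f"drugs={bad_drugs[:5]}")
    X = features.values[[cell_idx[r.cell_id] for r in records]]
    FP = np.stack([drugs.fingerprint_of(r.drug_id) for r in records])
    y = np.array([r.label for r in records], dtype=np.float64)
    return X, FP, y


def align_features(features, gene_order: list[str]):
    """Restrict/reorder an integrated feature matrix to the network's gene
    order (the pruned hierarchy may use a subset of the integrated genes)."""
    col = {g: j for j, g in enumerate(features.feature_ids)}
    missing = [g for g in gene_order if g not in col]
    if missing:
        raise ValueError(f"feature matrix lacks network genes: {missing[:5]}")
    from .omics import IntegratedCellFeatures
    idx = [col[g] for g in gene_order]
    return IntegratedCellFeatures(
        list(features.cell_ids), list(gene_order), features.values[:, idx],
        {g: features.provenance.get(g, []) for g in gene_order})


def train(net: MaskedNetwork, features, drugs, records, config: TrainConfig,
          ) -> tuple[MaskedNetwork, list[float]]:
    """Mini-batch Adam training; mutates ``net`` in place and returns it with
    the per-epoch mean training loss history.

    Shuffling is seeded from ``config.seed``; masked weights are provably
    untouched (their gradients are identically zero).
    """
    feats = align_features(features, net.genes)
    X, FP, y = design_matrices(feats, drugs, records)
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    params = list(net.weights) + list(net.biases) + [net.output_weights,
                                                     np.array([net.output_bias])]
    opt = _Adam(params, config.learning_rate)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, sizes = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs, cache = net._forward_cached(X[idx], FP[idx])
            losses.append(bce_loss(probs, y[idx]))
            sizes.append(len(idx))
            gW, gb, gw_out, gb_out, _ = net._backward(cache, probs, y[idx])
            grads = list(gW) + list(gb) + [gw_out, np.array([gb_out])]
            opt.step(params, grads)
            net.output_bias = float(params[-1][0])
        history.append(float(np.average(losses, weights=sizes)))
    return net, history


def predict(net: MaskedNetwork, pairs: list[tuple[str, str]], features, drugs,
            batch_size: int = 1024) -> np.ndarray:
    """Probabilities for (cell_id, drug_id) pairs, in input order.

    A pure function of the parameters: the result is invariant to batch
    partitioning and to duplicated pairs.
    """
    feats = align_features(features, net.genes)
    cell_idx = {c: i for i, c in enumerate(feats.cell_ids)}
    bad = sorted({c for c, _ in pairs if c not in cell_idx}
                 | {d for _, d in pairs if d not in set(drugs.drug_ids)})
    if bad:
        raise ValueError(f"unknown IDs in prediction pairs: {bad[:5]}")
    out = np.empty(len(pairs))
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        X = feats.values[[cell_idx[c] for c, _ in chunk]]
        FP = np.stack([drugs.fingerprint_of(d) for _, d in chunk])
        out[start:start + len(chunk)] = net.forward_batch(X, FP)
    return out
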