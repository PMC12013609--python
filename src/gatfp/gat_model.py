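"""Graph-attention encoder, prediction head and training loop.

The encoder stacks multi-head graph-attention layers.  For one head with
weight matrix ``W`` and attention vector ``a``, the coefficient between a
destination node *i* and a source neighbour *j* is

    alpha_ij = softmax_j( LeakyReLU( a^T [W h_i || W h_j || e_ij] ) ),

with the softmax over *j* in N(i) plus the self-loop added to every node.
Edge features ``e_ij`` (PMI, TF-IDF) enter the attention logit by
concatenation; self-loops carry zero edge features.  Heads are
concatenated by default, so the paper-scale configuration (4 heads x 256)
yields a 1024-wide layer output.  A graph embedding is the elementwise
max over node embeddings; a two-layer linear head and a sigmoid map it to
per-bit fingerprint probabilities.

Training minimizes binary cross-entropy with AdamW over mini-batches of
graphs, evaluated with k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autodiff import AdamW, Tensor, bce_with_logits, parameter, zeros_parameter
from .graph_builder import GraphSample


class ModelConfigError(ValueError):
    pass


class SplitError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published architecture: three GAT layers with
    4 heads of width 256 (1024 concatenated), ReLU, dropout 0.5,
    max-pool readout, two linear head layers, sigmoid output.
    ``use_edge_features=False`` is the FFe ablation; ``head_layers=1`` is
    the FL ablation.
    """

    in_dim: int = 38
    edge_dim: int = 2
    output_dim: int = 32
    n_gat_layers: int = 3
    n_heads: int = 4
    head_dim: int = 256
    aggregation: str = "concat"          # concat (Eq. 3 style) | average
    negative_slope: float = 0.2
    dropout: float = 0.5
    head_layers: int = 2
    head_hidden: int | None = None       # defaults to the layer width
    use_edge_features: bool = True
    dropout_on: str = "both"             # both | attn | input

    def __post_init__(self):
        if self.n_gat_layers < 1:
            raise ModelConfigError("need at least one GAT layer")
        if not (0.0 <= self.dropout < 1.0):
            raise ModelConfigError("dropout must be in [0, 1)")
        if self.aggregation not in ("concat", "average"):
            raise ModelConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.head_layers not in (1, 2):
            raise ModelConfigError("head_layers must be 1 or 2")
        if self.dropout_on not in ("both", "attn", "input"):
            raise ModelConfigError(f"unknown dropout_on {self.dropout_on!r}")

    @property
    def layer_width(self) -> int:
        return self.n_heads * self.head_dim if self.aggregation == "concat" \
            else self.head_dim


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 64
    epochs: int = 300
    seed: int = 0
    n_folds: int = 10

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.n_folds < 2:
            raise ModelConfigError("invalid training configuration")


@dataclass
class FoldSplit:
    """Sample-id → fold-index assignment for k-fold cross-validation."""

    fold_of: dict[str, int]
    n_folds: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def kfold_split(sample_ids: list[str], n_folds: int, seed: int) -> FoldSplit:
    """Seeded random partition into folds whose sizes differ by at most one."""
    ids = list(sample_ids)
    if n_folds > len(ids):
        raise SplitError(f"{n_folds} folds requested for {len(ids)} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[p]: k % n_folds for k, p in enumerate(perm)}
    return FoldSplit(fold_of=fold_of, n_folds=n_folds)


class GATLayer:
    """One multi-head attention layer with edge features in the logit."""

    def __init__(self, rng: np.random.Generator, in_dim: int, edge_dim: int,
                 n_heads: int, head_dim: int, aggregation: str = "concat",
                 negative_slope: float = 0.2, use_edge_features: bool = True):
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.aggregation = aggregation
        self.negative_slope = negative_slope
        self.use_edge_features = use_edge_features
        self.edge_dim = edge_dim if use_edge_features else 0
        self.W = [parameter(rng, (in_dim, head_dim)) for _ in range(n_heads)]
        attn_in = 2 * head_dim + self.edge_dim
        self.a = [parameter(rng, (attn_in, 1)) for _ in range(n_heads)]

    @property
    def params(self) -> list[Tensor]:
        return [*self.W, *self.a]

    def _with_self_loops(self, n: int, edge_index: np.ndarray,
                         edge_feats: np.ndarray):
        loops = np.arange(n, dtype=np.int64)
        if edge_index.size:
            src = np.concatenate([edge_index[:, 0], loops])
            dst = np.concatenate([edge_index[:, 1], loops])
            ef = np.vstack([edge_feats, np.zeros((n, edge_feats.shape[1]))])
        else:
            src = dst = loops
            ef = np.zeros((n, self.edge_dim or 1))
        e = Tensor(ef[:, : self.edge_dim]) if self.edge_dim else None
        return src, dst, e

    def _head_attention(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                        e: Tensor | None, k: int):
        """Projected features and softmax attention for one head."""
        n = x.data.shape[0]
        z = x @ self.W[k]                          # (n, head_dim)
        z_src = z.gather_rows(src)
        z_dst = z.gather_rows(dst)
        cat = z_dst.concat([z_src] + ([e] if e is not None else []), axis=1)
        logits = (cat @ self.a[k]).leaky_relu(self.negative_slope)  # (E,1)
        return z_src, logits.segment_softmax(dst, n)

    def attention_coefficients(self, x: Tensor, edge_index: np.ndarray,
                               edge_feats: np.ndarray, head: int) -> np.ndarray:
        """Per-edge attention weights for one head (eval mode).

        Returns an array aligned with *edge_index* rows followed by the n
        self-loops; the weights sum to 1 over each destination node.
        """
        src, dst, e = self._with_self_loops(x.data.shape[0], edge_index,
                                            edge_feats)
        _, alpha = self._head_attention(x, src, dst, e, head)
        return alpha.data[:, 0]

    def forward(self, x: Tensor, edge_index: np.ndarray, edge_feats: np.ndarray,
                *, attn_dropout_mask: np.ndarray | None = None) -> Tensor:
        """*edge_index* rows are (src, dst); self-loops are appended here."""
        n = x.data.shape[0]
        src, dst, e = self._with_self_loops(n, edge_index, edge_feats)

        heads = []
        for k in range(self.n_heads):
            z_src, alpha = self._head_attention(x, src, dst, e, k)
            if attn_dropout_mask is not None:
                alpha = alpha * Tensor(attn_dropout_mask[:, k : k + 1])
            heads.append((z_src * alpha).segment_sum(dst, n))

        if self.aggregation == "concat":
            out = heads[0].concat(heads[1:], axis=1) if len(heads) > 1 else heads[0]
        else:
            out = heads[0]
            for h in heads[1:]:
                out = out + h
            out = out * (1.0 / len(heads))
        return out


class FingerprintGAT:
    """Encoder + linear head predicting fingerprint-bit probabilities."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[GATLayer] = []
        in_dim = config.in_dim
        for _ in range(config.n_gat_layers):
            self.layers.append(GATLayer(
                rng, in_dim, config.edge_dim, config.n_heads, config.head_dim,
                aggregation=config.aggregation,
                negative_slope=config.negative_slope,
                use_edge_features=config.use_edge_features))
            in_dim = config.layer_width
        hidden = config.head_hidden or config.layer_width
        if config.head_layers == 2:
            self.head_W = [parameter(rng, (in_dim, hidden)),
                           parameter(rng, (hidden, config.output_dim))]
            self.head_b = [zeros_parameter((hidden,)),
                           zeros_parameter((config.output_dim,))]
        else:
            self.head_W = [parameter(rng, (in_dim, config.output_dim))]
            self.head_b = [zeros_parameter((config.output_dim,))]

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.layers:
            ps.extend(layer.params)
        ps.extend(self.head_W)
        ps.extend(self.head_b)
        return ps

    # -- forward -----------------------------------------------------------

    def _forward_logits(self, node_feats: np.ndarray, edge_index: np.ndarray,
                        edge_feats: np.ndarray, graph_ids: np.ndarray,
                        n_graphs: int, *, training: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        if node_feats.shape[0] == 0:
            raise ModelConfigError("cannot encode an empty graph")
        p = self.config.dropout if training else 0.0
        x = Tensor(node_feats)
        n_edges_total = edge_index.shape[0] + node_feats.shape[0]
        for li, layer in enumerate(self.layers):
            if p > 0 and self.config.dropout_on in ("both", "input"):
                keep = (rng.random(x.data.shape) >= p) / (1 - p)
                x = x * Tensor(keep)
            attn_mask = None
            if p > 0 and self.config.dropout_on in ("both", "attn"):
                attn_mask = (rng.random((n_edges_total, layer.n_heads)) >= p) / (1 - p)
            x = layer.forward(x, edge_index, edge_feats, attn_dropout_mask=attn_mask)
            x = x.relu()
            if not np.isfinite(x.data).all():
                raise DivergenceError(f"non-finite activations at GAT layer {li}")
        g = x.segment_max(graph_ids, n_graphs)
        for k, (W, b) in enumerate(zip(self.head_W, self.head_b)):
            g = g @ W + b
            if k < len(self.head_W) - 1:
                g = g.relu()
        return g

    # -- persistence -------------------------------------------------------

    def save(self, path, layout_hash: str = "") -> None:
        """Write parameters plus config to an .npz checkpoint."""
        import dataclasses
        import json as _json

        arrays = {f"p{k}": p.data for k, p in enumerate(self.params)}
        meta = _json.dumps({"encoder": dataclasses.asdict(self.config),
                            "layout_hash": layout_hash})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple["FingerprintGAT", str]:
        """Read a checkpoint; returns (model, fingerprint-layout hash)."""
        import json as _json

        with np.load(path) as z:
            meta = _json.loads(bytes(z["__meta__"]).decode())
            model = cls(EncoderConfig(**meta["encoder"]))
            for k, p in enumerate(model.params):
                p.data = z[f"p{k}"].astype(np.float64)
        return model, meta["layout_hash"]

    def predict(self, sample: GraphSample) -> np.ndarray:
        """Fingerprint-bit probabilities for one graph (eval mode)."""
        logits = self._forward_logits(
            sample.node_features, sample.edge_index, sample.edge_features,
            np.zeros(sample.node_features.shape[0], dtype=np.int64), 1)
        return logits.sigmoid().data[0]

    def predict_batch(self, samples: list[GraphSample]) -> np.ndarray:
        nf, ei, ef, gid = collate(samples)
        logits = self._forward_logits(nf, ei, ef, gid, len(samples))
        return logits.sigmoid().data


def collate(samples: list[GraphSample]):
    """Stack graphs into one disjoint-union graph with a graph-id per node."""
    nf = np.vstack([s.node_features for s in samples])
    offsets = np.cumsum([0] + [s.node_features.shape[0] for s in samples])
    ei = np.vstack([s.edge_index + off for s, off in zip(samples, offsets)])
    ef = np.vstack([s.edge_features for s in samples])
    gid = np.concatenate([
        np.full(s.node_features.shape[0], k, dtype=np.int64)
        for k, s in enumerate(samples)
    ])
    return nf, ei, ef, gid


def _epoch_loss(model: FingerprintGAT, samples: list[GraphSample],
                targets: np.ndarray) -> float:
    nf, ei, ef, gid = collate(samples)
    logits = model._forward_logits(nf, ei, ef, gid, len(samples))
    return float(bce_with_logits(logits, targets).data)


def train_single_split(dataset: list[GraphSample], encoder: EncoderConfig,
                       train: TrainConfig, train_idx: np.ndarray,
                       val_idx: np.ndarray | None = None,
                       log: list[dict] | None = None) -> FingerprintGAT:
    """Train one model on the indexed subset; returns the fitted model."""
    model = FingerprintGAT(encoder, seed=train.seed)
    opt = AdamW(model.params, lr=train.lr, weight_decay=train.weight_decay)
    rng = np.random.default_rng(train.seed + 1)
    train_samples = [dataset[i] for i in train_idx]
    for epoch in range(train.epochs):
        order = rng.permutation(len(train_samples))
        for lo in range(0, len(order), train.batch_size):
            batch = [train_samples[i] for i in order[lo : lo + train.batch_size]]
            nf, ei, ef, gid = collate(batch)
            targets = np.stack([s.target for s in batch])
            logits = model._forward_logits(nf, ei, ef, gid, len(batch),
                                           training=True, rng=rng)
            loss = bce_with_logits(logits, targets)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"NaN loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        if log is not None:
            entry = {"epoch": epoch,
                     "train_loss": _epoch_loss(model, train_samples,
                                               np.stack([s.target for s in train_samples]))}
            if val_idx is not None and len(val_idx):
                vs = [dataset[i] for i in val_idx]
                entry["val_loss"] = _epoch_loss(model, vs,
                                                np.stack([s.target for s in vs]))
            log.append(entry)
    return model


def train_model(dataset: list[GraphSample], encoder: EncoderConfig,
                train: TrainConfig, split: FoldSplit):
    """K-fold training and evaluation.

    For each fold: train on the other folds (reserving a validation subset
    the size of the test fold), evaluate on the held-out fold.  Returns
    ``(models, metrics)`` where *metrics* is a DataFrame with one row per
    fold plus a final mean row.
    """
    from .evaluation import accuracy_f1, binarize, confusion_counts, roc_pr_curves

    if not dataset:
        raise SplitError("empty dataset")
    index_of = {s.sample_id: i for i, s in enumerate(dataset)}
    rows, models = [], []
    rng = np.random.default_rng(train.seed)
    for fold in range(split.n_folds):
        test_ids = split.fold_ids(fold)
        if not test_ids:
            raise SplitError(f"fold {fold} has no test samples")
        train_ids = [s for s, f in split.fold_of.items() if f != fold]
        val_ids = list(rng.choice(train_ids, size=min(len(test_ids), len(train_ids)),
                                  replace=False))
        train_idx = np.array([index_of[s] for s in train_ids if s not in set(val_ids)])
        val_idx = np.array([index_of[s] for s in val_ids])
        test_idx = np.array([index_of[s] for s in test_ids])

        fold_cfg = replace(train, seed=train.seed + fold)
        model = train_single_split(dataset, encoder, fold_cfg, train_idx, val_idx)
        models.append(model)

        test_samples = [dataset[i] for i in test_idx]
        scores = model.predict_batch(test_samples)
        targets = np.stack([s.target for s in test_samples])
        roc, pr = roc_pr_curves(scores, targets)
        acc, f1 = accuracy_f1(confusion_counts(binarize(scores, 0.5), targets))
        rows.append({"fold": fold, "accuracy": acc, "f1": f1,
                     "roc_auc": roc.auc, "pr_auc": pr.auc,
                     "n_test": len(test_ids)})
    metrics = pd.DataFrame(rows)
    mean = metrics.drop(columns=["fold"]).mean()
    mean["fold"] = "mean"
    metrics = pd.concat([metrics, mean.to_frame().T], ignore_index=True)
    return models, metrics
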