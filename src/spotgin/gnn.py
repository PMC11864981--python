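"""Multi-task graph isomorphism network over k-hop spot subgraphs.

The backbone is a three-layer GIN: each layer aggregates summed messages
over edges (self-loops keep a node's own features in the sum) through a
two-layer perceptron with batch normalization, leaky-ReLU and dropout.
Global mean pooling yields a graph embedding which feeds one MLP head per
prediction task — methylation subclass, histology, MGMT promoter status,
CDKN2A/B status, or continuous targets. Categorical heads train with
cross-entropy, continuous heads with mean-squared-error plus L1, combined
as a weighted sum; Adam minimizes the total with gradients reset each
batch. k=0 degenerates to a linear model on the center spot's features.

Evaluation covers accuracy, macro precision/recall/F1, confusion matrices,
majority-vote participant aggregation and the Hand-Till multiclass AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .nn import (Adam, BatchNorm, Dense, Dropout, LeakyReLU, Sequential,
                 cross_entropy, mse_l1, softmax)

logger = logging.getLogger(__name__)


@dataclass
class HeadSpec:
    """One prediction task: categorical (with class vocabulary) or continuous."""

    task: str
    kind: str = "categorical"          # or "continuous"
    classes: list = field(default_factory=list)
    dim: int = 1                        # outputs for continuous heads

    @property
    def n_out(self) -> int:
        return len(self.classes) if self.kind == "categorical" else self.dim


@dataclass
class GinConfig:
    n_layers: int = 3
    hidden_dim: int = 128
    mlp_layers_per_gin: int = 2
    dropout_p: float = 0.3
    pooling: str = "global_mean"
    heads: list = field(default_factory=list)
    loss_weights: dict = field(default_factory=dict)
    k: int = 3
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    uncertainty_weighting: bool = False

    def weight(self, task: str) -> float:
        return float(self.loss_weights.get(task, 1.0))


# ---------------------------------------------------------------------- #
# batching
# ---------------------------------------------------------------------- #
def _batch_graphs(subgraphs: list) -> tuple[np.ndarray, sp.csr_matrix, sp.csr_matrix]:
    """Stack subgraphs into node features X, block adjacency A (with the
    per-node self-loops already present in edge_index) and a mean-pooling
    matrix P (graphs x nodes)."""
    feats, rows, cols = [], [], []
    p_rows, p_cols, p_vals = [], [], []
    offset = 0
    for g, sub in enumerate(subgraphs):
        n = sub.n_nodes
        feats.append(sub.features)
        rows.append(sub.edge_index[0] + offset)
        cols.append(sub.edge_index[1] + offset)
        p_rows.extend([g] * n)
        p_cols.extend(range(offset, offset + n))
        p_vals.extend([1.0 / n] * n)
        offset += n
    X = np.concatenate(feats, axis=0)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    A = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(offset, offset))
    P = sp.csr_matrix((p_vals, (p_rows, p_cols)),
                      shape=(len(subgraphs), offset))
    return X, A, P


def _targets(subgraphs: list, head: HeadSpec) -> tuple[np.ndarray, np.ndarray]:
    """Integer targets (or float vectors) plus a validity mask; labels
    outside the vocabulary ('unknown', None) are masked out of the loss."""
    if head.kind == "categorical":
        lut = {c: j for j, c in enumerate(head.classes)}
        t = np.zeros(len(subgraphs), dtype=int)
        mask = np.zeros(len(subgraphs), dtype=bool)
        for i, s in enumerate(subgraphs):
            lab = s.labels.get(head.task)
            if lab in lut:
                t[i] = lut[lab]
                mask[i] = True
        return t, mask
    t = np.zeros((len(subgraphs), head.dim))
    mask = np.zeros(len(subgraphs), dtype=bool)
    for i, s in enumerate(subgraphs):
        val = s.labels.get(head.task)
        if val is not None:
            t[i] = val
            mask[i] = True
    return t, mask


# ---------------------------------------------------------------------- #
# model
# ---------------------------------------------------------------------- #
class _GinLayer:
    """Sum aggregation over A (incl. self-loops) followed by a 2-layer MLP."""

    def __init__(self, n_in: int, hidden: int, dropout: float,
                 rng: np.random.Generator):
        self.mlp = Sequential([
            Dense(n_in, hidden, rng), BatchNorm(hidden), LeakyReLU(),
            Dropout(dropout, rng),
            Dense(hidden, hidden, rng), BatchNorm(hidden), LeakyReLU(),
        ])
        self._A = None

    def params(self):
        return self.mlp.params()

    def forward(self, X, A, train):
        self._A = A
        return self.mlp.forward(A @ X, train)

    def backward(self, grad):
        return self._A.T @ self.mlp.backward(grad)


class GinModel:
    """Three-layer GIN with global mean pooling and per-task MLP heads.

    With ``config.k == 0`` the model is the no-neighborhood baseline: one
    linear layer per task applied directly to the center spot's features.
    """

    def __init__(self, config: GinConfig, feature_width: int):
        if feature_width <= 0:
            raise ValueError("feature_width must be positive")
        if not config.heads:
            raise ValueError("configure at least one head")
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.gin_layers: list[_GinLayer] = []
        self.is_linear = config.k == 0 or config.n_layers == 0
        if self.is_linear:
            logger.info("k=0: building linear baseline on node features")
            embed_dim = feature_width
        else:
            dims = [feature_width] + [config.hidden_dim] * config.n_layers
            for a, b in zip(dims[:-1], dims[1:]):
                self.gin_layers.append(
                    _GinLayer(a, b, config.dropout_p, self.rng))
            embed_dim = config.hidden_dim
        self.heads: dict[str, Sequential] = {}
        for head in config.heads:
            if self.is_linear:
                net = Sequential([Dense(embed_dim, head.n_out, self.rng)])
            else:
                net = Sequential([
                    Dense(embed_dim, config.hidden_dim, self.rng), LeakyReLU(),
                    Dense(config.hidden_dim, head.n_out, self.rng)])
            self.heads[head.task] = net

    def params(self):
        out = []
        for layer in self.gin_layers:
            out.extend(layer.params())
        for net in self.heads.values():
            out.extend(net.params())
        return out

    # -------------------------------------------------------------- #
    def forward(self, subgraphs: list, train: bool = False) -> dict:
        """Logit (or regression output) matrix per task for a subgraph batch."""
        X, A, P = _batch_graphs(subgraphs)
        H = X
        for layer in self.gin_layers:
            H = layer.forward(H, A, train)
        pooled = P @ H
        self._P = P
        return {task: net.forward(pooled, train)
                for task, net in self.heads.items()}

    def backward(self, grads: dict) -> None:
        dpooled = None
        for task, g in grads.items():
            d = self.heads[task].backward(g)
            dpooled = d if dpooled is None else dpooled + d
        dH = self._P.T @ dpooled
        for layer in reversed(self.gin_layers):
            dH = layer.backward(dH)


def init_model(config: GinConfig, feature_width: int) -> GinModel:
    return GinModel(config, feature_width)


# ---------------------------------------------------------------------- #
# training
# ---------------------------------------------------------------------- #
def train(model: GinModel, subgraphs: list,
          config: GinConfig | None = None) -> list:
    """Mini-batch Adam training; returns the per-epoch mean total loss.

    Each categorical task needs at least two classes among the unmasked
    training labels. Gradients are reset after every batch; a non-finite
    loss aborts with the offending epoch/batch and learning rate.
    """
    cfg = config or model.config
    heads = {h.task: h for h in cfg.heads}
    for head in heads.values():
        t, mask = _targets(subgraphs, head)
        if head.kind == "categorical" and len(np.unique(t[mask])) < 2:
            raise ValueError(
                f"task {head.task!r} has fewer than two classes in training data")
    params = model.params()
    log_vars: dict = {}
    if cfg.uncertainty_weighting:
        # learnable per-task log-variances: total = sum exp(-s_t) L_t + s_t
        from .nn import Param
        log_vars = {task: Param(np.zeros(1)) for task in heads}
        params = params + list(log_vars.values())
    opt = Adam(params, lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed + 1)
    history = []
    n = len(subgraphs)
    for epoch in range(cfg.epochs):
        perm = order_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [subgraphs[i] for i in perm[start:start + cfg.batch_size]]
            outputs = model.forward(batch, train=True)
            opt.zero_grad()
            total = 0.0
            grads = {}
            for task, out in outputs.items():
                head = heads[task]
                t, mask = _targets(batch, head)
                if head.kind == "categorical":
                    loss, g = cross_entropy(out, t, mask)
                else:
                    loss, g = mse_l1(out, t, mask)
                if cfg.uncertainty_weighting:
                    s_t = log_vars[task]
                    w = float(np.exp(-s_t.value[0]))
                    total += w * loss + float(s_t.value[0])
                    s_t.grad += -w * loss + 1.0
                else:
                    w = cfg.weight(task)
                    total += w * loss
                grads[task] = w * g
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch "
                    f"{start // cfg.batch_size} (lr={cfg.lr})")
            model.backward(grads)
            opt.step()
            losses.append(total)
        history.append(float(np.mean(losses)))
    return history


def predict(model: GinModel, subgraphs: list, batch_size: int = 256) -> dict:
    """Per-subgraph outputs per task (evaluation mode, no dropout)."""
    outs: dict[str, list] = {task: [] for task in model.heads}
    for start in range(0, len(subgraphs), batch_size):
        batch = subgraphs[start:start + batch_size]
        for task, out in model.forward(batch, train=False).items():
            outs[task].append(out)
    return {task: np.concatenate(chunks, axis=0)
            for task, chunks in outs.items()}


def predicted_classes(logits: np.ndarray, classes: list) -> np.ndarray:
    return np.asarray(classes, dtype=object)[logits.argmax(axis=1)]


# ---------------------------------------------------------------------- #
# aggregation and metrics
# ---------------------------------------------------------------------- #
def predict_participant(logits: np.ndarray, classes: list,
                        participants: list) -> pd.DataFrame:
    """Majority vote over subgraph predictions per participant.

    Ties are broken by the higher mean softmax score among the tied
    classes. Returns one row per participant with the winning class and
    the vote fractions (summing to one).
    """
    probs = softmax(logits)
    pred_idx = logits.argmax(axis=1)
    rows = []
    frame = pd.DataFrame({"participant": participants, "pred": pred_idx})
    for participant, grp in frame.groupby("participant", sort=True):
        votes = np.bincount(grp["pred"], minlength=len(classes))
        fractions = votes / votes.sum()
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if len(tied) > 1:
            mean_scores = probs[grp.index].mean(axis=0)
            winner = tied[np.argmax(mean_scores[tied])]
        else:
            winner = int(tied[0])
        rows.append({"participant": participant,
                     "predicted": classes[winner],
                     "vote_fraction": float(fractions[winner]),
                     "fractions": fractions.tolist(),
                     "n_subgraphs": int(len(grp))})
    return pd.DataFrame(rows).set_index("participant")


@dataclass
class ModelReport:
    """Per-task metrics: accuracy, macro precision/recall/F1, confusion."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: pd.DataFrame
    n: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "n": self.n,
                "confusion": self.confusion.to_dict()}


def evaluate(predictions, truth, classes: list) -> ModelReport:
    """Macro-averaged metrics with a fixed class ordering.

    A class present in truth but never predicted contributes precision 0
    (flagged via a log message rather than a warning).
    """
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    never = set(truth) - set(predictions)
    if never:
        logger.info("classes never predicted (precision 0): %s", sorted(never))
    acc = float((predictions == truth).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predictions, labels=list(classes), average="macro",
        zero_division=0)
    cm = confusion_matrix(truth, predictions, labels=list(classes))
    confusion = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    return ModelReport(accuracy=acc, precision=float(prec), recall=float(rec),
                       f1=float(f1), confusion=confusion, n=len(truth))


# ---------------------------------------------------------------------- #
# Hand-Till multiclass AUC
# ---------------------------------------------------------------------- #
def _pairwise_rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-sum AUC (midrank ties): P(score_pos > score_neg) + 0.5 ties."""
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("empty class in pairwise AUC")
    ranks = rankdata(np.concatenate([pos, neg]))
    s = ranks[:n_pos].sum()
    return float((s - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hand_till_auc(scores: np.ndarray, truth, classes: list | None = None) -> float:
    """Hand-Till M: average over unordered class pairs of A(i,j).

    ``scores`` is items x classes (class-membership scores, e.g. softmax
    probabilities); A(i,j) = [A(i|j) + A(j|i)] / 2 where A(i|j) is the
    rank-sum AUC of the class-i score separating class-i from class-j
    items. Classes without items are excluded pairwise and logged.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    if classes is None:
        classes = sorted(set(truth))
    present = [c for c in classes if (truth == c).any()]
    absent = set(classes) - set(present)
    if absent:
        logger.info("classes without items excluded from AUC: %s",
                    sorted(absent))
    if len(present) < 2:
        raise ValueError("need at least two populated classes")
    col = {c: j for j, c in enumerate(classes)}
    aucs = []
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            ci, cj = present[a], present[b]
            items_i = scores[truth == ci]
            items_j = scores[truth == cj]
            a_ij = _pairwise_rank_auc(items_i[:, col[ci]], items_j[:, col[ci]])
            a_ji = _pairwise_rank_auc(items_j[:, col[cj]], items_i[:, col[cj]])
            aucs.append(0.5 * (a_ij + a_ji))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------- #
# k-hop ablation
# ---------------------------------------------------------------------- #
def khop_ablation(bundles: list, config: GinConfig,
                  ks=(0, 1, 2, 3), task: str = "methylation_subclass",
                  val_sections: set | None = None,
                  tumor_filter: bool = True,
                  center_stride: int = 1) -> pd.DataFrame:
    """Train one network per k on an identical section-level split.

    Returns a table with one row per k (accuracy, macro precision /
    recall / F1 on the held-out subgraphs). k=0 is the linear baseline.
    """
    from .graphs import make_training_set

    head = next(h for h in config.heads if h.task == task)
    if val_sections is None:
        probe = make_training_set(bundles, k=0, tumor_filter=tumor_filter,
                                  seed=config.seed,
                                  center_stride=center_stride)
        val_sections = {s["section"] for s in probe.manifest["sections"]
                        if s["role"] == "validation"}
    rows = []
    for k in ks:
        ts = make_training_set(bundles, k=k, tumor_filter=tumor_filter,
                               val_sections=val_sections, seed=config.seed,
                               center_stride=center_stride)
        cfg = GinConfig(**{**config.__dict__, "k": k, "heads": [head]})
        model = init_model(cfg, ts.train[0].features.shape[1])
        train(model, ts.train, cfg)
        logits = predict(model, ts.validation)[task]
        pred = predicted_classes(logits, head.classes)
        true = [s.labels[task] for s in ts.validation]
        report = evaluate(pred, true, head.classes)
        rows.append({"k": k, "accuracy": report.accuracy,
                     "precision": report.precision, "recall": report.recall,
                     "f1": report.f1, "n_validation": report.n})
    return pd.DataFrame(rows).set_index("k")
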