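"""Feed-forward imputers for heterogeneous association vectors.

Four predictors — F_DDI, F_DSIE, F_DDIS, F_PDIS — reconstruct an
entity's binary association row from the concatenation of its dense
embedding and the row itself: ``row_hat = F([embedding; row])``.  During
training the true row is present in the input and the model learns an
identity-like map regularized by dropout; at prediction time the row
part is **zero-masked** (``[embedding; 0]``), so the association vector
of an unseen entity is recovered from its embedding alone.  Sigmoid
outputs in [0, 1] are used directly as feature values, never
thresholded.

At benchmark scale the hidden stacks are 1024/512/128 (F_DDI) and
4096/2048/1024 (F_DSIE, F_DDIS, F_PDIS) with dropout 0.5; both are
configurable for smaller problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core_data import EmbeddingTable, HeteroMatrix
from .evaluation import SingleClassError, roc_auc_scores

IMPUTABLE = ("DDI", "DSIE", "DDIS", "PDIS")

#: hidden stacks at full benchmark scale
PAPER_HIDDEN_DIMS = {
    "DDI": (1024, 512, 128),
    "DSIE": (4096, 2048, 1024),
    "DDIS": (4096, 2048, 1024),
    "PDIS": (4096, 2048, 1024),
}


@dataclass
class ImputerModel:
    target: str
    embedding_dim: int
    target_dim: int
    hidden_dims: tuple[int, int, int]
    dropout_rate: float
    seed: int
    net: nn.Sequential

    @property
    def input_dim(self) -> int:
        return self.embedding_dim + self.target_dim

    def _forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(X, train=train)

    def predict_from_full_input(self, X: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self._forward_logits(X, train=False))


@dataclass
class ImputerTrainConfig:
    """Optimizer and regularization settings for imputer training.

    ``input_mask_rate`` randomly zeroes entries of the association part
    of the input during training (a denoising-autoencoder scheme), so
    the fully zero-masked prediction regime lies near the training
    distribution.  Early stopping monitors reconstruction loss on a
    held-out entity slice **with zero-masked inputs** — the deployment
    condition — rather than with visible rows.
    """

    learning_rate: float = 1e-3
    max_epochs: int = 600
    batch_size: int = 16
    #: 0 disables the held-out slice: at desk scale a 10%-of-entities slice
    #: is too small to track zero-masked generalization, and weight decay
    #: already regularizes; set > 0 to enable early stopping
    validation_fraction: float = 0.0
    patience: int = 60
    weight_decay: float = 1.0
    input_mask_rate: float = 0.7
    loss: str = "bce"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss != "bce":
            raise ValueError("only binary cross entropy loss is supported")
        if not 0.0 <= self.input_mask_rate <= 1.0:
            raise ValueError("input_mask_rate must lie in [0, 1]")


def build_imputer(
    target: str,
    embedding_dim: int,
    target_dim: int,
    hidden_dims: tuple[int, int, int] | None = None,
    seed: int = 0,
    dropout_rate: float = 0.5,
) -> ImputerModel:
    """Construct an imputer with three hidden layers and seeded init."""
    if target not in IMPUTABLE:
        raise ValueError(f"no imputer defined for target {target!r}")
    if embedding_dim <= 0 or target_dim <= 0:
        raise ValueError("dimensions must be positive")
    if hidden_dims is None:
        hidden_dims = PAPER_HIDDEN_DIMS[target]
    hidden_dims = tuple(int(h) for h in hidden_dims)
    if len(hidden_dims) != 3 or min(hidden_dims) <= 0:
        raise ValueError("hidden_dims must be three positive integers")
    rng = np.random.default_rng(seed)
    dims = (embedding_dim + target_dim, *hidden_dims)
    layers: list[nn.Layer] = []
    for i in range(3):
        layers += [nn.Linear(dims[i], dims[i + 1], rng), nn.ReLU(), nn.Dropout(dropout_rate)]
    layers.append(nn.Linear(dims[3], target_dim, rng))
    return ImputerModel(
        target=target,
        embedding_dim=embedding_dim,
        target_dim=target_dim,
        hidden_dims=hidden_dims,
        dropout_rate=dropout_rate,
        seed=seed,
        net=nn.Sequential(layers),
    )


def train_imputer(
    model: ImputerModel,
    embeddings: EmbeddingTable,
    matrix: HeteroMatrix,
    entity_subset: list[str],
    cfg: ImputerTrainConfig,
) -> list[dict]:
    """Train in place on ``[embedding_i; row_i] -> row_i`` reconstruction.

    Unique entities only (duplicates in the subset are dropped); loss is
    element-wise binary cross entropy on sigmoid outputs.  The
    association part of each training input is randomly masked at
    ``cfg.input_mask_rate`` and L2 weight decay is applied, both of
    which force the model to route information through the embedding —
    the only input available at prediction time.  Early stopping
    monitors zero-masked reconstruction loss on a held-out entity
    slice.  Returns the per-epoch history.
    """
    seen = set()
    subset = [e for e in entity_subset if not (e in seen or seen.add(e))]
    if not subset:
        raise ValueError("entity subset is empty")
    E = embeddings.values[embeddings.registry.indices(subset)]
    R = matrix.values[matrix.rows.indices(subset)]

    rng = np.random.default_rng(cfg.seed)
    for layer in model.net.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = rng

    n = E.shape[0]
    n_val = int(round(cfg.validation_fraction * n))
    if n_val >= 1 and n - n_val >= 1:
        perm = rng.permutation(n)
        val_i, train_i = perm[:n_val], perm[n_val:]
    else:
        val_i, train_i = np.array([], dtype=int), np.arange(n)
    Et, Rt = E[train_i], R[train_i]
    Ev, Rv = E[val_i], R[val_i]
    Xv = np.concatenate([Ev, np.zeros_like(Rv)], axis=1)  # deployment condition

    params = model.net.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    bad = 0
    n_train = Et.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            b = order[start : start + cfg.batch_size]
            Rb = Rt[b]
            if cfg.input_mask_rate > 0:
                keep = rng.random(Rb.shape) >= cfg.input_mask_rate
                Rin = Rb * keep
            else:
                Rin = Rb
            X = np.concatenate([Et[b], Rin], axis=1)
            probs = nn.sigmoid(model.net.forward(X, train=True))
            epoch_loss += nn.binary_cross_entropy(probs, Rb) * b.size
            opt.zero_grad()
            model.net.backward((probs - Rb) / probs.size)
            if cfg.weight_decay > 0:
                for p in params:  # decoupled L2 decay
                    p.value *= 1.0 - cfg.learning_rate * cfg.weight_decay
            opt.step()
        entry = {"epoch": epoch, "train_loss": epoch_loss / n_train}
        if Ev.shape[0] > 0:
            val_probs = model.predict_from_full_input(Xv)
            val_loss = nn.binary_cross_entropy(val_probs, Rv)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = nn.get_state(model.net)
                bad = 0
            else:
                bad += 1
        history.append(entry)
        if Ev.shape[0] > 0 and bad >= cfg.patience:
            break
    if best_state is not None:
        nn.set_state(model.net, best_state)
    return history


def impute(model: ImputerModel, embedding: np.ndarray) -> np.ndarray:
    """Predict association vector(s) from embedding(s) with zero-masked rows.

    Accepts a single ``(embedding_dim,)`` vector or a batch
    ``(n, embedding_dim)``; the association part of the input is all
    zeros, dropout is disabled, and the sigmoid output lies in
    ``[0, 1]^target_dim``.
    """
    emb = np.asarray(embedding, dtype=float)
    single = emb.ndim == 1
    if single:
        emb = emb[None, :]
    if emb.shape[1] != model.embedding_dim:
        raise ValueError(
            f"embedding width {emb.shape[1]} != expected {model.embedding_dim}"
        )
    X = np.concatenate([emb, np.zeros((emb.shape[0], model.target_dim))], axis=1)
    out = model.predict_from_full_input(X)
    return out[0] if single else out


def reconstruction_auc(
    model: ImputerModel,
    embeddings: EmbeddingTable,
    matrix: HeteroMatrix,
    held_out: list[str],
) -> tuple[float, dict[str, float]]:
    """Ranking AUC of imputed scores against true binary cells on held-out rows.

    Returns the pooled AUC over all (entity, column) cells plus per-row
    AUCs; rows that are entirely 0 or entirely 1 have no defined AUC and
    are excluded from the per-row table (pooling still uses their cells).
    """
    if not held_out:
        raise ValueError("held_out is empty")
    E = embeddings.values[embeddings.registry.indices(held_out)]
    scores = impute(model, E)
    truth = matrix.values[matrix.rows.indices(held_out)]
    pooled = roc_auc_scores(scores.ravel(), truth.ravel().astype(int))
    per_row: dict[str, float] = {}
    for eid, s, t in zip(held_out, scores, truth):
        try:
            per_row[eid] = roc_auc_scores(s, t.astype(int))
        except SingleClassError:
            continue
    return pooled, per_row


# ---------------------------------------------------------------------------
# Checkpointing: single .npz with a JSON header entry


def save_imputer(model: ImputerModel, path: str | Path) -> None:
    header = json.dumps(
        {
            "target": model.target,
            "embedding_dim": model.embedding_dim,
            "target_dim": model.target_dim,
            "hidden_dims": list(model.hidden_dims),
            "dropout_rate": model.dropout_rate,
            "seed": model.seed,
        }
    )
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.parameters())}
    np.savez(path, header=np.array(header), **arrays)


def load_imputer(path: str | Path) -> ImputerModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["header"]))
    model = build_imputer(
        meta["target"],
        meta["embedding_dim"],
        meta["target_dim"],
        tuple(meta["hidden_dims"]),
        seed=meta["seed"],
        dropout_rate=meta["dropout_rate"],
    )
    state = [data[f"p{i}"] for i in range(len(model.net.parameters()))]
    nn.set_state(model.net, state)
    return model
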