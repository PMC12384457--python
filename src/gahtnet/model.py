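"""GAH-TNet assembly, loss, optimisation schedule and ablation switchboard.

The full network is GATE -> HADTE -> linear classifier with softmax.
Training follows the published schedule: Adam at learning rate 0.001,
batch size 64, up to 1000 epochs with early stopping at patience 300.  The
monitored quantity is accuracy on a stratified validation split held out of
the training trials (the test partition never influences stopping); the
best-epoch weights are restored.

Ablation flags remove stages exactly as in the published ablation grid:

- ``channel_attention``: SE gate bypassed (Z' = Z).
- ``ts_encoder``: the temporal-spatial encoder is replaced by an
  average-pooling adapter (pool 56) so the graph+SE output reaches HADTE at
  the same sequence length T'.
- ``residual_eca`` / ``local_mha`` / ``global_mha``: that HADTE stage is an
  exact identity.
- ``hadte``: the whole HADTE block is an identity; the classifier consumes
  the GATE output directly (its last-position feature vector).

One integer seed drives weight initialisation, the validation split, batch
shuffling and dropout, so a fixed seed reproduces training bit-for-bit on
one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .gate import GateBlock, GateConfig, gate_output_length
from .hadte import HadteBlock, HadteConfig
from .io import TrialSet
from .montage import SpatialGraph
from .nn import Adam, Tensor, log_softmax

__all__ = [
    "ABLATION_FLAGS",
    "TABLE_VARIANTS",
    "ModelConfig",
    "TrainConfig",
    "TrainHistory",
    "GAHTNet",
    "build_model",
    "predict_proba",
    "predict_labels",
    "cross_entropy",
    "train_model",
    "ablate_variant",
    "extract_embeddings",
    "export_embeddings",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATION_FLAGS = frozenset(
    {"channel_attention", "ts_encoder", "residual_eca", "local_mha",
     "global_mha", "hadte"}
)

#: The seven ablation variants of the published grid, by row label.
TABLE_VARIANTS: dict[str, frozenset[str]] = {
    "w/o Channel Attention": frozenset({"channel_attention"}),
    "w/o Temporal-Spatial Convolutional Encoder": frozenset({"ts_encoder"}),
    "w/o Residual-ECA": frozenset({"residual_eca"}),
    "w/o Local Masked Multi-Head Attention": frozenset({"local_mha"}),
    "w/o Global Multi-Head Attention": frozenset({"global_mha"}),
    "w/o Local Masked Multi-Head Attention and Global Multi-Head Attention":
        frozenset({"local_mha", "global_mha"}),
    "w/o HADTE": frozenset({"hadte"}),
}


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int
    n_electrodes: int
    input_samples: int = 1125
    gate: GateConfig = field(default_factory=GateConfig)
    hadte: HadteConfig = field(default_factory=HadteConfig)
    ablation_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.ablation_flags) - ABLATION_FLAGS
        if unknown:
            raise ValueError(
                f"unknown ablation flags {sorted(unknown)}; "
                f"valid: {sorted(ABLATION_FLAGS)}"
            )


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 300
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def ablate_variant(cfg: ModelConfig, flag: str) -> ModelConfig:
    """Return a config with ``flag`` added to the bypass set (idempotent)."""
    if flag not in ABLATION_FLAGS:
        raise ValueError(
            f"unknown ablation flag {flag!r}; valid: {sorted(ABLATION_FLAGS)}"
        )
    return replace(cfg, ablation_flags=frozenset(cfg.ablation_flags | {flag}))


class GAHTNet(nn.Module):
    """GATE + HADTE + linear softmax classifier."""

    def __init__(self, cfg: ModelConfig, graph: SpatialGraph, seed: int = 0):
        super().__init__()
        if graph.n_channels != cfg.n_electrodes:
            raise ValueError(
                f"graph has {graph.n_channels} electrodes, "
                f"config says {cfg.n_electrodes}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        flags = cfg.ablation_flags
        self.gate = GateBlock(
            rng, graph, cfg.gate,
            use_channel_attention="channel_attention" not in flags,
            use_ts_encoder="ts_encoder" not in flags,
        )
        no_hadte = "hadte" in flags
        self.hadte = HadteBlock(
            rng, self.gate.out_dim, cfg.hadte,
            use_residual_eca=not no_hadte and "residual_eca" not in flags,
            use_local_mha=not no_hadte and "local_mha" not in flags,
            use_global_mha=not no_hadte and "global_mha" not in flags,
            use_tcn=not no_hadte,
        )
        self.classifier = nn.Linear(rng, self.gate.out_dim, cfg.n_classes)

    @property
    def seq_length(self) -> int:
        return gate_output_length(self.cfg.input_samples, self.cfg.gate)

    def logits(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.cfg.n_electrodes:
            raise ValueError(
                f"expected (batch, {self.cfg.n_electrodes}, T) input, "
                f"got {x.shape}"
            )
        f = self.gate(x, rng)  # (B, F, T')
        f = f.transpose(0, 2, 1)  # (B, T', F)
        emb = self.hadte(f, rng)  # (B, F)
        return self.classifier(emb)

    def embeddings(self, X: np.ndarray) -> np.ndarray:
        """Pre-classifier feature vectors (for external visualisation)."""
        self.eval()
        f = self.gate(Tensor(np.asarray(X, dtype=float))).transpose(0, 2, 1)
        return self.hadte(f).data


def build_model(cfg: ModelConfig, graph: SpatialGraph, seed: int = 0) -> GAHTNet:
    return GAHTNet(cfg, graph, seed=seed)


def predict_proba(model: GAHTNet, X: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1) for a (batch, C, T) array."""
    model.eval()
    logits = model.logits(Tensor(np.asarray(X, dtype=float))).data
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_labels(model: GAHTNet, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    parts = [
        np.argmax(predict_proba(model, X[i : i + batch_size]), axis=1)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood; probabilities clipped at 1e-12."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if labels.ndim == 2:  # one-hot
        labels = np.argmax(labels, axis=1)
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def _loss_and_correct(model: GAHTNet, xb: np.ndarray, yb: np.ndarray,
                      rng: np.random.Generator) -> tuple[Tensor, int]:
    logits = model.logits(Tensor(xb), rng)
    logp = log_softmax(logits, axis=1)
    picked = logp[np.arange(len(yb)), yb]
    loss = -picked.mean()
    correct = int((np.argmax(logits.data, axis=1) == yb).sum())
    return loss, correct


def _stratified_holdout(labels: np.ndarray, val_fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_model(
    model: GAHTNet, train: TrialSet, tcfg: TrainConfig
) -> tuple[GAHTNet, TrainHistory]:
    """Adam + early stopping on a stratified validation holdout.

    Stops once validation accuracy has not improved for ``patience`` epochs
    and restores the best-epoch weights.
    """
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    rng = np.random.default_rng(tcfg.seed)
    tr_idx, val_idx = _stratified_holdout(train.labels, tcfg.val_fraction, rng)
    X_tr, y_tr = train.data[tr_idx], train.labels[tr_idx]
    X_val, y_val = train.data[val_idx], train.labels[val_idx]

    opt = Adam(model.parameters(), lr=tcfg.lr)
    hist = TrainHistory()
    best_val, best_state, since_best = -np.inf, None, 0
    for epoch in range(1, tcfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(X_tr))
        losses, n_correct = [], 0
        for start in range(0, len(order), tcfg.batch_size):
            b = order[start : start + tcfg.batch_size]
            loss, correct = _loss_and_correct(model, X_tr[b], y_tr[b], rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
            n_correct += correct
        val_pred = predict_labels(model, X_val, tcfg.batch_size)
        val_acc = float((val_pred == y_val).mean())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(n_correct / len(X_tr))
        hist.val_acc.append(val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                hist.stopped_epoch = epoch
                break
    if hist.stopped_epoch < 0:
        hist.stopped_epoch = len(hist.train_loss)
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, hist


def extract_embeddings(model: GAHTNet, trials: TrialSet,
                       batch_size: int = 64) -> np.ndarray:
    parts = [
        model.embeddings(trials.data[i : i + batch_size])
        for i in range(0, trials.n_trials, batch_size)
    ]
    return np.concatenate(parts)


def export_embeddings(model: GAHTNet, trials: TrialSet, path: str | Path) -> None:
    """Write pre-classifier feature vectors to HDF5 (for external t-SNE etc.)."""
    import h5py

    emb = extract_embeddings(model, trials)
    with h5py.File(path, "w") as f:
        f.create_dataset("embeddings", data=emb)
        f.create_dataset("labels", data=trials.labels)
        f.attrs["dim"] = emb.shape[1]


def save_checkpoint(model: GAHTNet, path: str | Path) -> None:
    """Single-file archive of named parameter arrays plus the JSON config."""
    cfg = model.cfg
    meta = {
        "n_classes": cfg.n_classes,
        "n_electrodes": cfg.n_electrodes,
        "input_samples": cfg.input_samples,
        "ablation_flags": sorted(cfg.ablation_flags),
        "gate": vars(cfg.gate),
        "hadte": vars(cfg.hadte),
    }
    np.savez(path, __config__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **model.state_arrays())


def load_checkpoint(path: str | Path, graph: SpatialGraph) -> GAHTNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__config__"}
    cfg = ModelConfig(
        n_classes=meta["n_classes"],
        n_electrodes=meta["n_electrodes"],
        input_samples=meta["input_samples"],
        gate=GateConfig(**meta["gate"]),
        hadte=HadteConfig(**meta["hadte"]),
        ablation_flags=frozenset(meta["ablation_flags"]),
    )
    model = GAHTNet(cfg, graph)
    model.load_state_arrays(arrays)
    return model
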