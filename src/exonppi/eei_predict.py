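"""Exon-pair interaction predictors: PPMax and PPDL.

Both predictors post-process an upstream residue-pair score matrix into
one score per inter-protein exon pair.

* **PPMax** scores an exon pair by the maximum predicted residue-pair
  score inside its block — no training, predictor-scale output.
* **PPDL** resizes each exon-pair block to a fixed grid (bilinear, so
  exon lengths spanning orders of magnitude all fit one input without
  padding-to-max) and feeds it to a small convolutional network trained
  with class-weighted binary cross-entropy and early stopping on
  validation AU-PRC. Output is a probability in [0, 1].

A trained model also supports confidence flagging of novel predictions:
a candidate exon pair is flagged iff its score strictly exceeds the
maximum score the model assigns to the training non-interacting pairs
(the background distribution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, SmallCNN, weighted_bce_from_logits
from .scores import ExonPairSubmatrix


@dataclass(frozen=True)
class EEIPrediction:
    """One scored inter-protein exon pair."""

    exon1_id: str
    exon2_id: str
    score: float
    method: str  # ppmax | ppdl

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("EEI score must be finite")
        if self.method not in ("ppmax", "ppdl"):
            raise ValueError(f"unknown method {self.method!r}")


def ppmax(block: ExonPairSubmatrix) -> EEIPrediction:
    """Exon-pair score = maximum residue-pair score in the block."""
    if np.all(np.isnan(block.block)):
        raise ValueError("all block entries missing")
    return EEIPrediction(
        exon1_id=block.exon1_id,
        exon2_id=block.exon2_id,
        score=float(np.nanmax(block.block)),
        method="ppmax",
    )


def resize_block(block: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resampling of a score block to a fixed grid.

    Output grid coordinates map linearly onto the input index range, so
    an already-(H, W) block passes through unchanged, constant blocks
    stay constant, and every output value lies within [min, max] of the
    input.
    """
    a = np.asarray(block, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("block must be a non-empty 2-D array")
    h, w = a.shape
    ys = np.linspace(0.0, h - 1.0, height) if height > 1 else np.array([(h - 1) / 2.0])
    xs = np.linspace(0.0, w - 1.0, width) if width > 1 else np.array([(w - 1) / 2.0])
    y0 = np.clip(np.floor(ys).astype(int), 0, max(h - 2, 0))
    x0 = np.clip(np.floor(xs).astype(int), 0, max(w - 2, 0))
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    top = a[np.ix_(y0, x0)] * (1 - fx) + a[np.ix_(y0, x1)] * fx
    bot = a[np.ix_(y1, x0)] * (1 - fx) + a[np.ix_(y1, x1)] * fx
    return top * (1 - fy) + bot * fy


@dataclass
class PPDLConfig:
    """Training configuration for the convolutional exon-pair classifier.

    Class weights are set inversely proportional to class frequencies
    unless given explicitly (exon-level data runs roughly 1:4
    positive:negative, so the positive class is typically up-weighted).
    """

    input_height: int = 32
    input_width: int = 32
    conv_channels: tuple[int, int] = (16, 32)
    dense_units: int = 64
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    class_weights: tuple[float, float] | None = None  # (negative, positive)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["conv_channels"] = list(self.conv_channels)
        d["class_weights"] = (
            list(self.class_weights) if self.class_weights is not None else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PPDLConfig":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        if d.get("class_weights") is not None:
            d["class_weights"] = tuple(d["class_weights"])
        return cls(**d)


@dataclass
class PPDLModel:
    """Trained convolutional exon-pair classifier.

    Prediction is deterministic given the weights (dropout is a
    training-time regularizer only); serialization round-trips are
    bit-identical.
    """

    config: PPDLConfig
    weights: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def _network(self) -> SmallCNN:
        net = SmallCNN(
            (self.config.input_height, self.config.input_width),
            self.config.conv_channels,
            self.config.dense_units,
            self.config.dropout,
            np.random.default_rng(0),
        )
        net.set_weights(self.weights)
        return net

    def predict(self, block: ExonPairSubmatrix) -> EEIPrediction:
        score = float(self.predict_scores([block.block])[0])
        return EEIPrediction(
            exon1_id=block.exon1_id,
            exon2_id=block.exon2_id,
            score=score,
            method="ppdl",
        )

    def predict_scores(self, blocks) -> np.ndarray:
        """Scores in [0, 1] for a sequence of raw (unresized) blocks."""
        x = _stack_blocks(blocks, self.config)
        return self._network().predict_proba(x)

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"config": self.config.to_dict(), "metadata": self.metadata})
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **self.weights)

    @classmethod
    def load(cls, path: str | Path) -> "PPDLModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            config=PPDLConfig.from_dict(meta["config"]),
            weights=weights,
            metadata=meta["metadata"],
        )


def _stack_blocks(blocks, config: PPDLConfig) -> np.ndarray:
    arrs = [
        resize_block(
            b.block if isinstance(b, ExonPairSubmatrix) else b,
            config.input_height,
            config.input_width,
        )
        for b in blocks
    ]
    return np.stack(arrs).astype(np.float32)[:, None, :, :]


def _au_prc(labels: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import average_precision_score

    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(average_precision_score(labels, scores))


def train_ppdl(
    train_blocks,
    train_labels,
    valid_blocks,
    valid_labels,
    config: PPDLConfig | None = None,
) -> PPDLModel:
    """Train the convolutional exon-pair classifier.

    Keeps the epoch checkpoint with the best validation AU-PRC and stops
    after ``config.patience`` epochs without improvement. Training is
    bit-reproducible for a fixed ``config.seed``.
    """
    config = config or PPDLConfig()
    y = np.asarray(train_labels, dtype=np.float32)
    yv = np.asarray(valid_labels, dtype=np.float32)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    x = _stack_blocks(train_blocks, config)
    xv = _stack_blocks(valid_blocks, config)

    if config.class_weights is not None:
        w_neg, w_pos = config.class_weights
    else:  # inverse class-frequency weighting, normalized to mean 1
        n_pos, n_neg = float(y.sum()), float(len(y) - y.sum())
        w_pos = len(y) / (2.0 * n_pos)
        w_neg = len(y) / (2.0 * n_neg)
    sample_w = np.where(y == 1, np.float32(w_pos), np.float32(w_neg))

    rng = np.random.default_rng(config.seed)
    net = SmallCNN(
        (config.input_height, config.input_width),
        config.conv_channels,
        config.dense_units,
        config.dropout,
        rng,
    )
    opt = Adam(net.layers, lr=config.learning_rate)

    best_auprc = -np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    trace: list[float] = []
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x))
        for s in range(0, len(x), config.batch_size):
            idx = order[s : s + config.batch_size]
            z = net.forward(x[idx], train=True)
            _, dz = weighted_bce_from_logits(z, y[idx], sample_w[idx])
            net.backward(dz)
            opt.step()
        val_scores = net.predict_proba(xv)
        auprc = _au_prc(yv, val_scores)
        trace.append(auprc)
        if np.isfinite(auprc) and auprc > best_auprc:
            best_auprc, best_epoch, stale = auprc, epoch, 0
            best_weights = net.get_weights()
        else:
            stale += 1
            if stale >= config.patience:
                break
    return PPDLModel(
        config=config,
        weights=best_weights,
        metadata={
            "seed": config.seed,
            "epochs_run": len(trace),
            "best_epoch": best_epoch,
            "best_val_auprc": float(best_auprc),
            "val_auprc_trace": [float(v) for v in trace],
            "class_weights": [float(w_neg), float(w_pos)],
            "resize": "bilinear",
        },
    )


def predict_ppdl(model: PPDLModel, block: ExonPairSubmatrix) -> EEIPrediction:
    """Score one exon-pair block with a trained model (deterministic)."""
    return model.predict(block)


def flag_novel_eeis(
    candidates: list[EEIPrediction], background: np.ndarray
) -> list[EEIPrediction]:
    """Confidence filter for predictions on unseen protein pairs.

    A candidate is kept iff its score is strictly greater than the
    maximum score of the background distribution (the model's scores on
    training non-interacting exon pairs); an equal score already has
    nonzero empirical false-discovery rate.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background distribution is empty")
    cut = float(background.max())
    return [c for c in candidates if c.score > cut]


def write_predictions_tsv(
    predictions: list[EEIPrediction],
    path: str | Path,
    flagged: set[tuple[str, str]] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("exon1_id\texon2_id\tmethod\tscore\tflagged\n")
        for p in predictions:
            flag = int(flagged is not None and (p.exon1_id, p.exon2_id) in flagged)
            fh.write(f"{p.exon1_id}\t{p.exon2_id}\t{p.method}\t{p.score:.8g}\t{flag}\n")
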