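"""The 3-d residual U-net for protein/solvent map segmentation.

Architecture (default window 48, base filters 24): four encoding blocks of
two 3x3x3 convolutions each with batch normalization and ReLU, max pooling
after the first three; filters start at 24 and double per block
(24, 48, 96, 192).  Three decoding blocks each apply a stride-2 transposed
convolution (halving filters, doubling the spatial dims), concatenate with
the same-resolution encoder output (the skip/residual connections), and
finish with one 3x3x3 convolution + batch norm + ReLU.  A final 1x1x1
convolution reduces to two classes (protein = 0, solvent = 1).  The default
configuration has about three million trainable parameters.

Training uses per-voxel sparse categorical cross-entropy and Adam; windows
are re-sampled and re-augmented every epoch, and the epoch with the best
validation voxel accuracy is kept.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .map_io import BinaryMask, MapGrid, ProbabilityGrid
from .windowing import DEFAULT_WINDOW, Window, reassemble, sample_windows, tile_map

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "Metrics",
    "UNet3D",
    "build_unet",
    "count_parameters",
    "train",
    "predict_window",
    "segment_map",
    "compute_metrics",
    "f_score",
    "prevalence_from_rates",
    "accuracy_from_rates",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters of the segmentation U-net."""

    window: int = DEFAULT_WINDOW
    in_channels: int = 1
    base_filters: int = 24
    encoding_blocks: int = 4
    classes: int = 2
    batch_norm: bool = True
    # optional BN+ReLU after transposed convolutions (off in the reference
    # architecture, which applies them only to the ordinary convolutions)
    transpose_bn_relu: bool = False

    @property
    def decoding_blocks(self) -> int:
        return self.encoding_blocks - 1

    def __post_init__(self) -> None:
        pools = 2 ** (self.encoding_blocks - 1)
        if self.window % pools:
            raise ValueError(
                f"window edge {self.window} must be divisible by {pools} "
                f"(2^(encoding blocks - 1))"
            )


@dataclass
class TrainConfig:
    """Optimization hyper-parameters."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    train_windows: int = 512
    val_windows: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class Metrics:
    """Classification metrics on the solvent (positive) class.

    Ratios whose denominator is zero are reported as None (missing), never 0.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (the F1 score)."""
    return 2.0 * precision * recall / (precision + recall)


def prevalence_from_rates(precision: float, recall: float, specificity: float) -> float:
    """Positive-class prevalence implied by a (precision, recall, specificity)
    triple on a single population.

    From precision = pi*r / (pi*r + (1-pi)(1-s)), solved for pi.
    """
    return precision * (1 - specificity) / (
        recall * (1 - precision) + precision * (1 - specificity)
    )


def accuracy_from_rates(precision: float, recall: float, specificity: float) -> float:
    """Accuracy implied by a (precision, recall, specificity) triple."""
    pi = prevalence_from_rates(precision, recall, specificity)
    return pi * recall + (1 - pi) * specificity


def compute_metrics(pred: BinaryMask, truth: BinaryMask) -> Metrics:
    """Confusion-matrix metrics with solvent (1) as the positive class."""
    if pred.dims != truth.dims:
        raise ValueError(f"mask dims differ: {pred.dims} vs {truth.dims}")
    p = pred.values.astype(bool)
    t = truth.values.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = f_score(precision, recall)
    return Metrics(
        accuracy=(tp + tn) / (tp + fp + fn + tn),
        precision=precision,
        recall=recall,
        specificity=_ratio(tn, tn + fp),
        f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


class UNet3D:
    """Encoder-decoder network mapping density windows to class scores."""

    def __init__(self, cfg: UNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        nb = cfg.encoding_blocks
        self.enc_filters = [f * 2**i for i in range(nb)]
        self.enc_blocks: list[list[nn.Layer]] = []
        c_prev = cfg.in_channels
        for c in self.enc_filters:
            block = []
            for _ in range(2):
                block.append(nn.Conv3d(c_prev, c, 3, rng=rng))
                if cfg.batch_norm:
                    block.append(nn.BatchNorm(c))
                block.append(nn.ReLU())
                c_prev = c
            self.enc_blocks.append(block)
        self.pools = [nn.MaxPool3d() for _ in range(nb - 1)]
        self.dec_tconvs: list[nn.ConvTranspose3d] = []
        self.dec_extra: list[list[nn.Layer]] = []
        self.dec_convs: list[list[nn.Layer]] = []
        for i in range(cfg.decoding_blocks):
            c_in = self.enc_filters[nb - 1 - i]
            c_out = self.enc_filters[nb - 2 - i]
            self.dec_tconvs.append(nn.ConvTranspose3d(c_in, c_out, rng=rng))
            extra: list[nn.Layer] = []
            if cfg.transpose_bn_relu:
                extra = [nn.BatchNorm(c_out), nn.ReLU()]
            self.dec_extra.append(extra)
            conv: list[nn.Layer] = [nn.Conv3d(2 * c_out, c_out, 3, rng=rng)]
            if cfg.batch_norm:
                conv.append(nn.BatchNorm(c_out))
            conv.append(nn.ReLU())
            self.dec_convs.append(conv)
        self.final = nn.Conv3d(self.enc_filters[0], cfg.classes, 1, rng=rng)

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for block in self.enc_blocks:
            out.extend(block)
        out.extend(self.pools)
        for t, e, c in zip(self.dec_tconvs, self.dec_extra, self.dec_convs):
            out.append(t)
            out.extend(e)
            out.extend(c)
        out.append(self.final)
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class scores for a batch ``(N, w, w, w, 1)`` of density windows."""
        skips = []
        h = x.astype(np.float32)
        nb = self.cfg.encoding_blocks
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h, training)
            if i < nb - 1:
                skips.append(h)
                h = self.pools[i].forward(h, training)
        for i in range(self.cfg.decoding_blocks):
            h = self.dec_tconvs[i].forward(h, training)
            for layer in self.dec_extra[i]:
                h = layer.forward(h, training)
            skip = skips[-(i + 1)]
            h = np.concatenate([h, skip], axis=-1)
            for layer in self.dec_convs[i]:
                h = layer.forward(h, training)
        return self.final.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.final.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * (self.cfg.encoding_blocks - 1)
        for i in reversed(range(self.cfg.decoding_blocks)):
            for layer in reversed(self.dec_convs[i]):
                dh = layer.backward(dh)
            c = dh.shape[-1] // 2
            dskips[-(i + 1)] = dh[..., c:]
            dh = np.ascontiguousarray(dh[..., :c])
            for layer in reversed(self.dec_extra[i]):
                dh = layer.backward(dh)
            dh = self.dec_tconvs[i].backward(dh)
        nb = self.cfg.encoding_blocks
        for i in reversed(range(nb)):
            if i < nb - 1:
                dh = self.pools[i].backward(dh)
                dh = dh + dskips[i]
            for layer in reversed(self.enc_blocks[i]):
                dh = layer.backward(dh)

    # -- weight (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                state[f"{li}.{name}"] = p.copy()
            if isinstance(layer, nn.BatchNorm):
                state[f"{li}.running_mean"] = layer.running_mean.copy()
                state[f"{li}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"{li}.{name}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"{li}.running_mean"]
                layer.running_var[...] = state[f"{li}.running_var"]


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet3D:
    """Instantiate the segmentation U-net with seeded He-normal weights."""
    return UNet3D(cfg or UNetConfig(), seed=seed)


def count_parameters(cfg: UNetConfig | None = None) -> int:
    """Trainable parameter count of the configured network.

    Batch-norm scale/shift parameters count; running statistics do not.
    """
    return build_unet(cfg or UNetConfig()).n_params


def save_model(model: UNet3D, path: str | Path) -> None:
    """Save weights plus architecture config as a .npz checkpoint."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(str(path), **state)


def load_model(path: str | Path) -> UNet3D:
    with np.load(str(path)) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg = UNetConfig(**json.loads(cfg_json))
        model = build_unet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model


def _windows_to_batch(pairs: list[tuple[Window, Window]]
                      ) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p[0].values for p in pairs]).astype(np.float32)[..., None]
    y = np.stack([p[1].values for p in pairs]).astype(np.int8)
    return x, y


def _batched_eval(model: UNet3D, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, float]:
    """(loss, voxel accuracy) without updating weights or BN statistics."""
    losses, correct, total = [], 0, 0
    for s in range(0, len(x), batch_size):
        logits = model.forward(x[s:s + batch_size], training=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[s:s + batch_size])
        losses.append(loss * len(x[s:s + batch_size]))
        pred = logits.argmax(axis=-1)
        correct += int((pred == y[s:s + batch_size]).sum())
        total += y[s:s + batch_size].size
    return float(np.sum(losses) / len(x)), correct / total


def train(
    model: UNet3D,
    data: list[tuple[MapGrid, BinaryMask]],
    cfg: TrainConfig,
    val_data: list[tuple[MapGrid, BinaryMask]] | None = None,
) -> tuple[UNet3D, list[dict]]:
    """Train on windows re-sampled from ``data`` every epoch.

    Loss is per-voxel sparse categorical cross-entropy over the two classes;
    the optimizer is Adam at ``cfg.learning_rate``.  Windows are drawn on the
    fly each epoch (epoch-indexed seeds) with flip/rotation augmentation.
    Validation windows are sampled once from ``val_data`` (or from ``data``
    when absent); the epoch with the best validation accuracy is restored
    into the returned model.

    Returns the trained model and a per-epoch history of working and
    validation loss/accuracy.
    """
    if not data:
        raise ValueError("no training data")
    w = model.cfg.window
    val_source = val_data if val_data else data
    rng = np.random.default_rng([cfg.seed, 0x7A1])
    val_pairs = []
    per_map = max(1, math.ceil(cfg.val_windows / len(val_source)))
    for g, m in val_source:
        val_pairs.extend(sample_windows(g, m, per_map, seed=int(rng.integers(2**31)),
                                        w=w, augment=False))
    val_pairs = val_pairs[:cfg.val_windows]
    xv, yv = _windows_to_batch(val_pairs)

    opt = nn.Adam(model.layers(), lr=cfg.learning_rate)
    history: list[dict] = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        t0 = time.time()
        ep_rng = np.random.default_rng([cfg.seed, 1 + epoch])
        pairs = []
        per_map = max(1, math.ceil(cfg.train_windows / len(data)))
        for g, m in data:
            pairs.extend(sample_windows(g, m, per_map,
                                        seed=int(ep_rng.integers(2**31)), w=w))
        pairs = pairs[:cfg.train_windows]
        order = ep_rng.permutation(len(pairs))
        x, y = _windows_to_batch([pairs[i] for i in order])
        losses, correct, total = [], 0, 0
        for s in range(0, len(x), cfg.batch_size):
            xb, yb = x[s:s + cfg.batch_size], y[s:s + cfg.batch_size]
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"loss became non-finite at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(xb))
            correct += int((logits.argmax(axis=-1) == yb).sum())
            total += yb.size
        val_loss, val_acc = _batched_eval(model, xv, yv, cfg.batch_size)
        entry = {
            "epoch": epoch,
            "loss": float(np.sum(losses) / len(x)),
            "accuracy": correct / total,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
            "seconds": time.time() - t0,
        }
        history.append(entry)
        logger.info("epoch %d: loss %.4f acc %.4f val_loss %.4f val_acc %.4f (%.1fs)",
                    epoch, entry["loss"], entry["accuracy"], val_loss, val_acc,
                    entry["seconds"])
        if val_acc > best[0]:
            best = (val_acc, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def predict_window(model: UNet3D, window: Window) -> Window:
    """Per-voxel solvent probability (softmax class 1) for one window."""
    w = model.cfg.window
    if window.values.shape != (w, w, w):
        raise ValueError(f"window shape {window.values.shape} != ({w},{w},{w})")
    logits = model.forward(window.values.astype(np.float32)[None, ..., None])
    probs = nn.softmax(logits)[0, ..., 1]
    return Window(probs, window.origin)


def segment_map(model: UNet3D, grid: MapGrid, threshold: float = 0.5,
                standardize: bool = True, batch_size: int = 8,
                ) -> tuple[ProbabilityGrid, BinaryMask]:
    """Segment a full-cell map into solvent probabilities and a binary mask.

    The map is standardized with the same zero-mean/unit-variance scaling
    used at training time, tiled into non-overlapping windows (edge-aligned
    extras where the dims are not divisible), each window is predicted, and
    the probabilities are reassembled with averaging on any overlaps.  The
    mask is ``probability > threshold`` (class argmax at 0.5).
    """
    g = grid.standardized() if standardize else grid
    tiles = tile_map(g, model.cfg.window)
    out: list[Window] = []
    for s in range(0, len(tiles), batch_size):
        chunk = tiles[s:s + batch_size]
        x = np.stack([t.values for t in chunk]).astype(np.float32)[..., None]
        probs = nn.softmax(model.forward(x))[..., 1]
        out.extend(Window(p, t.origin) for p, t in zip(probs, chunk))
    prob_grid = reassemble(out, g.dims, grid_like=grid)
    mask = BinaryMask((prob_grid.values > threshold).astype(np.int8),
                      grid.cell, list(grid.symmetry_ops))
    return prob_grid, mask
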