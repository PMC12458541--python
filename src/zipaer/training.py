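"""Gene-weighted reconstruction loss and the accumulation training loop.

The loss addresses the orders-of-magnitude imbalance between gene channels:
with s_i the total transcript count of gene i over the training split,

    L = 1e6 * mean_i [ median(s+) / s_i * MSE_i ]        (s_i > 0 only)

where MSE_i is the per-gene mean squared reconstruction error averaged over
batch and both spatial axes, s+ is the set of positive totals, and the mean
runs over genes with positive totals.  A gene whose total equals the median
contributes with weight exactly 1; zero-total genes get weight 0 and are
excluded from the mean's denominator (the weight is undefined at s_i = 0).
The 1e6 factor is purely cosmetic, keeping printed losses in a readable range.

Training uses Adam with gradient accumulation: each micro-batch loss is
divided by the number of accumulation steps before backprop, so one optimizer
update equals the mean-loss gradient over the effective batch
(devices x per-device batch x accumulation steps).  The learning rate follows
a reduce-on-plateau policy on the validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError, DataError, TrainingError
from .model import Autoencoder
from .transcript_store import SparsePatchStore

LOSS_SCALE = 1e6


@dataclass
class GeneWeightTable:
    s: np.ndarray        # per-gene total expression over the training split
    weight: np.ndarray   # median(s+)/s_i for s_i > 0, else 0
    median_positive: float

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    scheduler_factor: float = 0.3
    scheduler_patience: int = 8
    scheduler_threshold: float = 0.01  # relative
    per_device_batch: int = 2
    n_devices: int = 1
    accumulation_steps: int = 4
    max_epochs: int = 30
    seed: int = 0
    val_fraction: float = 0.2

    def validate(self) -> None:
        if min(self.learning_rate, self.scheduler_factor) <= 0:
            raise ConfigurationError("learning_rate and scheduler_factor must be > 0")
        if min(self.scheduler_patience, self.per_device_batch, self.n_devices,
               self.accumulation_steps, self.max_epochs) < 1:
            raise ConfigurationError("counts must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")


@dataclass
class LossReport:
    per_gene_mse: np.ndarray
    total: float


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    checkpoint_paths: list[Path] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs, columns=["epoch", "train_loss", "val_loss", "lr"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_gene_weights(source, n_genes: int | None = None) -> GeneWeightTable:
    """Per-gene totals and loss weights from a patch store or a dense stack.

    ``source`` is either a :class:`SparsePatchStore` (``n_genes`` required) or
    a dense array of shape (N, G, H, W).  Totals are transcript counts summed
    over the given patches — compute this on the training split only.
    """
    if isinstance(source, SparsePatchStore):
        if n_genes is None:
            raise ConfigurationError("n_genes is required with a sparse patch store")
        s = source.gene_totals(n_genes).astype(np.float64)
    else:
        arr = np.asarray(source)
        if arr.ndim != 4:
            raise ConfigurationError("dense source must have shape (N, G, H, W)")
        s = arr.sum(axis=(0, 2, 3)).astype(np.float64)
    positive = s > 0
    if not positive.any():
        raise DataError("all gene totals are zero; cannot form loss weights")
    med = float(np.median(s[positive]))
    weight = np.where(positive, med / np.where(positive, s, 1.0), 0.0)
    return GeneWeightTable(s=s, weight=weight, median_positive=med)


def _loss_and_grad(recon: np.ndarray, target: np.ndarray, weights: np.ndarray):
    if recon.shape != target.shape:
        from .errors import ShapeError
        raise ShapeError(f"reconstruction {recon.shape} vs target {target.shape}")
    if recon.shape[1] != len(weights):
        from .errors import ShapeError
        raise ShapeError(f"{recon.shape[1]} channels but {len(weights)} weights")
    diff = recon - target
    per_gene_mse = np.square(diff).mean(axis=(0, 2, 3))
    active = weights > 0
    n_active = int(active.sum())
    if n_active == 0:
        raise DataError("no gene has a positive weight")
    total = LOSS_SCALE * float((weights[active] * per_gene_mse[active]).mean())
    B, G, H, W = recon.shape
    grad = diff * (LOSS_SCALE * 2.0 / (B * H * W * n_active)) * weights[None, :, None, None]
    return LossReport(per_gene_mse=per_gene_mse, total=total), grad


def weighted_mse_loss(recon: np.ndarray, target: np.ndarray,
                      weights: np.ndarray | GeneWeightTable) -> LossReport:
    """Evaluate the gene-weighted reconstruction loss (see module docstring)."""
    w = weights.weight if isinstance(weights, GeneWeightTable) else np.asarray(weights, float)
    report, _ = _loss_and_grad(np.asarray(recon, float), np.asarray(target, float), w)
    return report


def effective_batch_size(n_devices: int, per_device_batch: int, accumulation_steps: int) -> int:
    """Samples contributing to one optimizer update."""
    if min(n_devices, per_device_batch, accumulation_steps) < 1:
        raise ConfigurationError("all factors must be >= 1")
    return n_devices * per_device_batch * accumulation_steps


def steps_per_epoch(n_samples: int, effective_batch: int) -> int:
    """ceil(n_samples / effective_batch)."""
    if n_samples < 1 or effective_batch < 1:
        raise ConfigurationError("n_samples and effective_batch must be >= 1")
    return -(-n_samples // effective_batch)


def plateau_scheduler_step(val_history, current_lr: float, config: TrainConfig) -> float:
    """Replay a validation-loss history through the plateau policy.

    Starts from ``current_lr`` and returns the learning rate in force after
    the last epoch of ``val_history``.
    """
    if len(val_history) == 0:
        raise DataError("validation-loss history is empty")

    class _Opt:
        lr = current_lr

    sched = nn.ReduceLROnPlateau(
        _Opt(), factor=config.scheduler_factor,
        patience=config.scheduler_patience, threshold=config.scheduler_threshold,
    )
    lr = current_lr
    for v in val_history:
        lr = sched.step(float(v))
    return lr


def train_val_split(patch_ids, val_fraction: float, seed: int):
    """Disjoint, exhaustive, seed-deterministic split of patch ids."""
    ids = np.asarray(patch_ids)
    if not 0 < val_fraction < 1:
        raise ConfigurationError("val_fraction must be in (0, 1)")
    if len(ids) < 2:
        raise DataError("need at least 2 patches to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = int(round(val_fraction * len(ids)))
    n_val = min(max(n_val, 1), len(ids) - 1)
    return ids[perm[n_val:]], ids[perm[:n_val]]


def save_checkpoint(model: Autoencoder, path: str | Path, **meta) -> Path:
    """Write model state (incl. batch-norm buffers) + metadata to one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)
    return path

def load_checkpoint(model: Autoencoder, path: str | Path) -> dict:
    """Restore model state in place; returns the checkpoint metadata."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model.load_state({k: data[k] for k in data.files if k != "__meta__"})
    return meta


def _validation_loss(model: Autoencoder, patches: np.ndarray,
                     weights: np.ndarray, batch: int) -> float:
    """Loss over the whole validation set in eval mode, per-gene MSE pooled
    across batches so the result is independent of the batch partition."""
    G = patches.shape[1]
    sq_sum = np.zeros(G)
    n_px = 0
    for i in range(0, len(patches), batch):
        xb = patches[i:i + batch].astype(model.dtype)
        recon = model.forward(xb, training=False)
        diff = recon.astype(np.float64) - xb.astype(np.float64)
        sq_sum += np.square(diff).sum(axis=(0, 2, 3))
        n_px += diff.shape[0] * diff.shape[2] * diff.shape[3]
    mse = sq_sum / n_px
    active = weights > 0
    return LOSS_SCALE * float((weights[active] * mse[active]).mean())


def fit(model: Autoencoder, train_patches: np.ndarray, val_patches: np.ndarray,
        weights: np.ndarray | GeneWeightTable, config: TrainConfig,
        checkpoint_dir: str | Path | None = None) -> tuple[Autoencoder, TrainingLog]:
    """Train the autoencoder with Adam + gradient accumulation + plateau lr.

    ``train_patches``/``val_patches`` are dense stacks (N, G, H, W); weights
    must come from the training split only.  Checkpoints are written on every
    validation-loss improvement when ``checkpoint_dir`` is given, and the last
    one restores to exactly the logged validation loss.
    """
    config.validate()
    w = weights.weight if isinstance(weights, GeneWeightTable) else np.asarray(weights, float)
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise DataError("train and validation splits must both be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, factor=config.scheduler_factor,
                                 patience=config.scheduler_patience,
                                 threshold=config.scheduler_threshold)
    micro = config.per_device_batch * config.n_devices
    accum = config.accumulation_steps
    log = TrainingLog()
    best_val = np.inf

    for epoch in range(1, config.max_epochs + 1):
        lr_in_force = opt.lr
        perm = rng.permutation(len(train_patches))
        loss_sum, n_seen = 0.0, 0
        micro_starts = list(range(0, len(perm), micro))
        for g0 in range(0, len(micro_starts), accum):
            opt.zero_grad()
            for start in micro_starts[g0:g0 + accum]:
                idx = perm[start:start + micro]
                xb = train_patches[idx].astype(model.dtype)
                recon = model.forward(xb, training=True)
                report, grad = _loss_and_grad(
                    recon.astype(np.float64), xb.astype(np.float64), w
                )
                if not np.isfinite(report.total):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, sample offset {start}"
                    )
                loss_sum += report.total * len(idx)
                n_seen += len(idx)
                model.backward((grad / accum).astype(model.dtype))
            opt.step()

        val_loss = _validation_loss(model, val_patches, w, batch=micro)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        log.epochs.append(
            {"epoch": epoch, "train_loss": loss_sum / n_seen,
             "val_loss": val_loss, "lr": lr_in_force}
        )
        if checkpoint_dir is not None and val_loss < best_val:
            p = save_checkpoint(
                model, Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz",
                epoch=epoch, val_loss=val_loss,
            )
            log.checkpoint_paths.append(p)
        best_val = min(best_val, val_loss)
        sched.step(val_loss)

    return model, log
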