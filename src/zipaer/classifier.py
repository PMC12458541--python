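"""Patch classification on latent features vs. a from-scratch baseline.

The experiment: label each cell-centered patch by whether its central cell
expresses a binary marker gene, then train (a) a small convolutional
classifier on the *pretrained* encoder's latent tensors and (b) a baseline of
identical architecture — the untrained encoder followed by the same classifier
head — where every parameter learns from scratch.  Both arms share parameter
count and complexity; the comparison isolates the value of the pretrained
latent representation.

The reference head mirrors the published design: five 3x3 stride-2 unpadded
convolutions compressing a 512 x 74 x 74 latent through (128,36,36),
(64,17,17), (32,8,8), (16,3,3) to (16,1,1), then flatten, dropout 0.5
(training only) and a 2-way fully connected output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError, DataError, SpecError
from .model import Autoencoder, ModelSpec, build_autoencoder, conv_out_side
from .transcript_store import GeneVocabulary


@dataclass(frozen=True)
class ClassifierSpec:
    input_shape: tuple[int, int, int] = (512, 74, 74)
    channels: tuple[int, ...] = (128, 64, 32, 16, 16)
    kernel: int = 3
    stride: int = 2
    padding: int = 0
    dropout_p: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        if not self.channels:
            raise SpecError("classifier needs at least one conv layer")


def classifier_shape_trace(spec: ClassifierSpec) -> list[tuple[int, int]]:
    """(channels, side) after each conv layer; closed-form oracle."""
    side = spec.input_shape[1]
    trace = []
    for c in spec.channels:
        side = conv_out_side(side, spec.kernel, spec.stride, spec.padding)
        trace.append((c, side))
    return trace


def build_classifier(spec: ClassifierSpec, seed: int = 0, dtype=np.float64) -> nn.Sequential:
    """Instantiate the conv classifier head; validates the shape trace."""
    trace = classifier_shape_trace(spec)
    if trace[-1][1] < 1:
        raise SpecError("classifier spatial side collapses to 0")
    layers: list[nn.Module] = []
    rng = np.random.default_rng(seed)
    chans = [spec.input_shape[0], *spec.channels]
    for i in range(len(spec.channels)):
        layers.append(nn.Conv2d(chans[i], chans[i + 1], spec.kernel, spec.stride,
                                spec.padding, rng=rng, dtype=dtype))
        layers.append(nn.LeakyReLU())
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout_p, seed=seed))
    c_last, s_last = trace[-1]
    layers.append(nn.Linear(c_last * s_last * s_last, spec.n_classes, rng=rng, dtype=dtype))
    return nn.Sequential(layers)


class PatchClassifier:
    """Encoder (optionally frozen) composed with the classifier head.

    With ``encoder=None`` the head consumes latent tensors directly.  The
    baseline arm wraps an *untrained* encoder with ``train_encoder=True`` so
    every parameter learns from scratch; the comparison arm wraps the
    pretrained encoder, frozen by default.
    """

    def __init__(self, head: nn.Sequential, encoder: Autoencoder | None = None,
                 train_encoder: bool = False):
        self.head = head
        self.encoder = encoder
        self.train_encoder = train_encoder

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.encoder is not None:
            # A frozen encoder always runs in eval mode (fixed BN statistics).
            enc_training = training and self.train_encoder
            x = self.encoder.encode(x, training=enc_training)
        return self.head.forward(x, training=training)

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out)
        if self.encoder is not None and self.train_encoder:
            self.encoder.encoder.backward(g)

    def trainable_parameters(self) -> list[nn.Parameter]:
        params = list(self.head.parameters())
        if self.encoder is not None and self.train_encoder:
            params = self.encoder.encoder.parameters() + params
        return params

    @property
    def n_parameters(self) -> int:
        """All parameters of the arm (trainable or not) — equal across arms."""
        n = self.head.n_parameters
        if self.encoder is not None:
            n += sum(p.size for p in self.encoder.encoder.parameters())
        return n


def build_baseline(encoder_spec: ModelSpec, clf_spec: ClassifierSpec,
                   seed: int = 0, dtype=np.float64) -> PatchClassifier:
    """Untrained encoder + classifier head, all parameters trained from scratch."""
    enc = build_autoencoder(encoder_spec, seed=seed, dtype=dtype)
    head = build_classifier(clf_spec, seed=seed + 1, dtype=dtype)
    return PatchClassifier(head, encoder=enc, train_encoder=True)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    specificity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        def pct(v):
            return "undefined" if np.isnan(v) else f"{100 * v:.1f}%"
        return (f"accuracy {pct(self.accuracy)}, recall {pct(self.recall)}, "
                f"precision {pct(self.precision)}, specificity {pct(self.specificity)} "
                f"(TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn})")


def evaluate(predictions, labels) -> MetricsReport:
    """Confusion counts and the four standard binary metrics.

    A metric with a zero denominator is reported as NaN (undefined), not 0.
    """
    p = np.asarray(predictions, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape:
        raise DataError("predictions and labels differ in length")
    if not np.isin(y, [0, 1]).all() or not np.isin(p, [0, 1]).all():
        raise DataError("labels and predictions must be binary")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        recall=ratio(tp, tp + fn),
        precision=ratio(tp, tp + fp),
        specificity=ratio(tn, tn + fp),
    )


def label_patches(transcripts: pd.DataFrame, cells: pd.DataFrame, marker_gene: str,
                  vocab: GeneVocabulary, eligible_cell_ids=None) -> pd.DataFrame:
    """Binary patch labels from the central cell's marker expression.

    A patch (identified by its central cell id) is positive iff at least one
    marker-gene transcript is *assigned to that cell* (cell_id match — not
    merely present in the patch area).  Cells outside ``eligible_cell_ids``
    (the stand-in for the real experiment's cell-type eligibility) are
    excluded.  Returns a frame with columns patch_id, label.
    """
    if marker_gene not in vocab:
        raise ConfigurationError(f"marker gene {marker_gene!r} not in vocabulary")
    cell_ids = cells["cell_id"].to_numpy()
    if eligible_cell_ids is not None:
        keep = np.isin(cell_ids, np.asarray(list(eligible_cell_ids)))
        cell_ids = cell_ids[keep]
    marker_cells = set(
        transcripts.loc[transcripts["gene"] == marker_gene, "cell_id"].unique()
    )
    return pd.DataFrame(
        {"patch_id": cell_ids,
         "label": np.array([1 if c in marker_cells else 0 for c in cell_ids], dtype=np.int64)}
    )


def stratified_split(labels, test_fraction: float = 0.3, seed: int = 0):
    """Seed-deterministic stratified train/test index split."""
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return np.sort(train_idx), np.sort(test_idx)


def train_classifier(arm: PatchClassifier, X: np.ndarray, y: np.ndarray,
                     epochs: int = 30, lr: float = 1e-3, batch: int = 8,
                     seed: int = 0) -> PatchClassifier:
    """Cross-entropy training of one arm with Adam."""
    rng = np.random.default_rng(seed)
    for d in arm.head.dropout_layers():
        d.reseed(seed)
    opt = nn.Adam(arm.trainable_parameters(), lr=lr)
    for _ in range(epochs):
        perm = rng.permutation(len(X))
        for i in range(0, len(perm), batch):
            idx = perm[i:i + batch]
            logits = arm.forward(X[idx], training=True)
            _, grad = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            arm.backward(grad)
            opt.step()
    return arm


def predict(arm: PatchClassifier, X: np.ndarray, batch: int = 16) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch):
        out.append(arm.forward(X[i:i + batch], training=False).argmax(axis=1))
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def compare_pretrained_vs_scratch(
    patches: np.ndarray,
    labels: np.ndarray,
    encoder_spec: ModelSpec,
    clf_channels: tuple[int, ...],
    pretrained: Autoencoder,
    seeds=(0, 1, 2),
    test_fraction: float = 0.3,
    epochs: int = 30,
    lr: float = 1e-3,
) -> pd.DataFrame:
    """Run both arms over several seeds; returns one row per (seed, arm).

    The pretrained arm encodes patches once (encoder frozen, eval mode) and
    trains only the head on latents; the baseline trains encoder + head end
    to end from scratch.  Both heads share the architecture implied by
    ``clf_channels`` on the pretrained encoder's latent shape.
    """
    from .model import latent_shape

    lat = latent_shape(encoder_spec)
    clf_spec = ClassifierSpec(input_shape=(lat.channels, lat.side, lat.side),
                              channels=tuple(clf_channels))
    rows = []
    patches = np.asarray(patches, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    for seed in seeds:
        tr, te = stratified_split(labels, test_fraction=test_fraction, seed=seed)
        latents = pretrained.encode(patches, training=False)

        head = build_classifier(clf_spec, seed=seed)
        arm_latent = PatchClassifier(head, encoder=None)
        train_classifier(arm_latent, latents[tr], labels[tr], epochs=epochs,
                         lr=lr, seed=seed)
        m_lat = evaluate(predict(arm_latent, latents[te]), labels[te])

        arm_base = build_baseline(encoder_spec, clf_spec, seed=seed)
        train_classifier(arm_base, patches[tr], labels[tr], epochs=epochs,
                         lr=lr, seed=seed)
        m_base = evaluate(predict(arm_base, patches[te]), labels[te])

        for arm_name, m in (("pretrained_latent", m_lat), ("scratch_baseline", m_base)):
            rows.append({"seed": seed, "arm": arm_name, "accuracy": m.accuracy,
                         "recall": m.recall, "precision": m.precision,
                         "specificity": m.specificity})
    return pd.DataFrame(rows)
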