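"""Densification of sparse patch records into gene x height x width tensors.

The reduction parameter ``r`` coarsens the spatial grid by floor-dividing
local pixel coordinates: record ``(g, x, y)`` lands in cell
``(g, y // r, x // r)``.  Count mode accumulates transcripts per cell (the
default — gene totals survive reduction); binary mode records presence only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .transcript_store import PATCH_STORE_COLUMNS, GeneVocabulary, SparsePatchStore


@dataclass(frozen=True)
class PatchConfig:
    patch_size_px: int = 600
    reduction_r: int = 2
    aggregation: str = "count"  # or "binary"

    def __post_init__(self):
        if self.patch_size_px <= 0 or self.reduction_r <= 0:
            raise ConfigurationError("patch size and reduction must be positive")
        if self.patch_size_px % self.reduction_r != 0:
            raise ConfigurationError(
                f"patch_size_px {self.patch_size_px} not divisible by "
                f"reduction_r {self.reduction_r}"
            )
        if self.aggregation not in ("count", "binary"):
            raise ConfigurationError("aggregation must be 'count' or 'binary'")

    @property
    def side(self) -> int:
        return reduced_patch_side(self.patch_size_px, self.reduction_r)


@dataclass
class PatchTensor:
    values: np.ndarray  # (G, H, W), counts or {0,1}
    patch_id: int
    config: PatchConfig


def reduced_patch_side(patch_size_px: int, reduction_r: int) -> int:
    """Spatial side of the dense tensor: patch_size_px / reduction_r."""
    if reduction_r <= 0 or patch_size_px <= 0:
        raise ConfigurationError("patch size and reduction must be positive")
    if patch_size_px % reduction_r != 0:
        raise ConfigurationError(
            f"patch_size_px {patch_size_px} not divisible by reduction_r {reduction_r}"
        )
    return patch_size_px // reduction_r


def densify(
    records: pd.DataFrame,
    config: PatchConfig,
    vocab: GeneVocabulary | int,
    patch_id: int | None = None,
) -> PatchTensor:
    """Rasterize one patch's sparse records into a dense (G, H, W) tensor."""
    n_genes = vocab if isinstance(vocab, int) else len(vocab)
    side = config.side
    values = np.zeros((n_genes, side, side), dtype=np.int64)
    if len(records):
        ids = records["patch_id"].unique()
        if len(ids) > 1:
            raise ValidationError(f"records span multiple patches: {sorted(ids)}")
        if patch_id is None:
            patch_id = int(ids[0])
        g = records["gene_index"].to_numpy(dtype=np.int64)
        x = records["x_local"].to_numpy(dtype=np.int64)
        y = records["y_local"].to_numpy(dtype=np.int64)
        bad = (
            (g < 0) | (g >= n_genes)
            | (x < 0) | (x >= config.patch_size_px)
            | (y < 0) | (y >= config.patch_size_px)
        )
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"record out of bounds: gene_index={g[i]}, x_local={x[i]}, "
                f"y_local={y[i]} (patch size {config.patch_size_px}, {n_genes} genes)"
            )
        r = config.reduction_r
        np.add.at(values, (g, y // r, x // r), 1)
        if config.aggregation == "binary":
            values = (values > 0).astype(np.int64)
    return PatchTensor(values=values, patch_id=-1 if patch_id is None else int(patch_id),
                       config=config)


def densify_all(
    store: SparsePatchStore,
    config: PatchConfig,
    vocab: GeneVocabulary | int,
    patch_ids=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Densify many patches into a (N, G, H, W) stack; returns (stack, ids)."""
    ids = np.asarray(store.patch_ids if patch_ids is None else patch_ids)
    n_genes = vocab if isinstance(vocab, int) else len(vocab)
    side = config.side
    out = np.zeros((len(ids), n_genes, side, side), dtype=np.int64)
    for i, pid in enumerate(ids):
        out[i] = densify(store.records_for(int(pid)), config, n_genes, patch_id=int(pid)).values
    return out, ids


def sparsify(tensor: PatchTensor) -> pd.DataFrame:
    """Inverse of densify at r=1: emit one record per transcript count.

    Output coordinates live on the reduced grid, so
    ``densify(sparsify(t), r=1)`` reproduces ``t`` exactly for count tensors.
    """
    if tensor.config.aggregation != "count":
        raise ValidationError("sparsify requires a count-mode tensor")
    g, y, x = np.nonzero(tensor.values)
    counts = tensor.values[g, y, x]
    return pd.DataFrame(
        {
            "patch_id": np.int64(tensor.patch_id),
            "gene_index": np.repeat(g, counts),
            "x_local": np.repeat(x, counts),
            "y_local": np.repeat(y, counts),
        }
    )[PATCH_STORE_COLUMNS]


def save_dense_patches(path: str | Path, stack: np.ndarray, ids: np.ndarray,
                       config: PatchConfig) -> None:
    """Persist dense patches in a chunked array container (one array each)."""
    import zarr

    root = zarr.open_group(str(path), mode="w")
    root.attrs.update(
        patch_size_px=config.patch_size_px,
        reduction_r=config.reduction_r,
        aggregation=config.aggregation,
    )
    for pid, arr in zip(ids, stack):
        a = root.create_array(f"patch_{int(pid)}", shape=arr.shape, dtype=arr.dtype)
        a[:] = arr


def load_dense_patches(path: str | Path) -> tuple[np.ndarray, np.ndarray, PatchConfig]:
    """Load a stack written by :func:`save_dense_patches`."""
    import zarr

    root = zarr.open_group(str(path), mode="r")
    config = PatchConfig(
        patch_size_px=int(root.attrs["patch_size_px"]),
        reduction_r=int(root.attrs["reduction_r"]),
        aggregation=str(root.attrs["aggregation"]),
    )
    ids = sorted(int(k.split("_", 1)[1]) for k in root.array_keys())
    stack = np.stack([root[f"patch_{pid}"][:] for pid in ids]) if ids else \
        np.zeros((0, 0, config.side, config.side), dtype=np.int64)
    return stack, np.asarray(ids, dtype=np.int64), config
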