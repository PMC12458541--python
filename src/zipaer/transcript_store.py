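"""Columnar transcript I/O and the transcript-to-patch distance join.

Transcript and patch-store tables live in either CSV (header row) or Parquet;
Parquet reads are column-selective, so a caller that only needs coordinates
never materializes gene names or compartments.  The patch store is the sparse
columnar layout ``(patch_id, gene_index, x_local, y_local)`` produced by the
join, queryable by patch id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .errors import ParseError, SchemaError, ValidationError

PATCH_STORE_COLUMNS = ["patch_id", "gene_index", "x_local", "y_local"]


@dataclass(frozen=True)
class TranscriptRecord:
    fov: int
    cell_id: int
    gene: str
    x_px: float
    y_px: float
    z: int = 0
    compartment: str = "none"


class GeneVocabulary:
    """Ordered gene names; line order in the on-disk file is channel order."""

    def __init__(self, genes: list[str]):
        self.genes = list(genes)
        self._index = {g: i for i, g in enumerate(self.genes)}
        if len(self._index) != len(self.genes):
            raise ValidationError("duplicate gene names in vocabulary")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise SchemaError(f"gene {gene!r} not in vocabulary") from None

    def indices(self, genes) -> np.ndarray:
        return np.array([self.index(g) for g in genes], dtype=np.int64)

    @classmethod
    def from_transcripts(cls, transcripts: pd.DataFrame) -> "GeneVocabulary":
        return cls(sorted(transcripts["gene"].unique()))

    @classmethod
    def read(cls, path: str | Path) -> "GeneVocabulary":
        lines = Path(path).read_text().splitlines()
        return cls([l.strip() for l in lines if l.strip()])

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")


def _is_parquet(path: Path) -> bool:
    return path.suffix.lower() in {".parquet", ".pq"}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV or Parquet depending on the file extension."""
    path = Path(path)
    if _is_parquet(path):
        pq.write_table(pa.Table.from_pandas(df, preserve_index=False), path)
    else:
        df.to_csv(path, index=False)


def read_transcripts(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a transcript table, materializing only the requested columns.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ParseError` (with the row number) on malformed CSV rows.
    """
    path = Path(path)
    if _is_parquet(path):
        available = set(pq.read_schema(path).names)
        if columns is not None:
            missing = [c for c in columns if c not in available]
            if missing:
                raise SchemaError(f"missing column(s) {missing} in {path.name}")
        return pq.read_table(path, columns=columns).to_pandas()
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(f"malformed CSV in {path.name}: {e}") from e
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s) {missing} in {path.name}")
        df = df[list(columns)]
    return df


def assign_transcripts_to_patches(
    transcripts: pd.DataFrame,
    centers: pd.DataFrame,
    patch_size_px: int,
    vocab: GeneVocabulary,
    fov_size_px: int | None = None,
) -> pd.DataFrame:
    """Join transcripts to cell-centered square patches.

    A transcript at global ``(x, y)`` belongs to the patch of a center
    ``(cx, cy)`` in the same FOV iff ``cx - S/2 <= x < cx + S/2`` and likewise
    for y, with ``S = patch_size_px`` (box membership with half-width S/2 —
    the only reading that yields S x S patches centered on each cell).
    Centers are floored to integer pixels.  Local coordinates are offsets from
    the patch's low corner; a transcript may land in several overlapping
    patches but at most once per patch.

    ``centers`` needs columns cell_id (used as patch_id), fov, x_px, y_px.
    Returns the sparse patch store (patch_id, gene_index, x_local, y_local).
    """
    if patch_size_px % 2 != 0:
        raise ValidationError("patch_size_px must be even")
    half = patch_size_px // 2

    if fov_size_px is not None and len(centers):
        bad = (
            (centers["x_px"] < 0) | (centers["x_px"] >= fov_size_px)
            | (centers["y_px"] < 0) | (centers["y_px"] >= fov_size_px)
        )
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} patch center(s) outside the {fov_size_px}-px FOV"
            )

    if len(transcripts) == 0 or len(centers) == 0:
        return pd.DataFrame({c: pd.Series(dtype=np.int64) for c in PATCH_STORE_COLUMNS})

    tx = transcripts
    x = tx["x_px"].to_numpy(dtype=np.float64)
    y = tx["y_px"].to_numpy(dtype=np.float64)
    tfov = tx["fov"].to_numpy()
    gidx = vocab.indices(tx["gene"])

    chunks = []
    for _, c in centers.iterrows():
        cx = int(np.floor(c["x_px"]))
        cy = int(np.floor(c["y_px"]))
        x0, y0 = cx - half, cy - half
        m = (
            (tfov == c["fov"])
            & (x >= x0) & (x < cx + half)
            & (y >= y0) & (y < cy + half)
        )
        if not m.any():
            continue
        chunks.append(
            pd.DataFrame(
                {
                    "patch_id": np.int64(c["cell_id"]),
                    "gene_index": gidx[m],
                    "x_local": np.floor(x[m]).astype(np.int64) - x0,
                    "y_local": np.floor(y[m]).astype(np.int64) - y0,
                }
            )
        )
    if not chunks:
        return pd.DataFrame({c: pd.Series(dtype=np.int64) for c in PATCH_STORE_COLUMNS})
    return pd.concat(chunks, ignore_index=True)[PATCH_STORE_COLUMNS]


class SparsePatchStore:
    """In-memory view over the sparse patch table, queryable by patch id."""

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in PATCH_STORE_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"patch store missing column(s) {missing}")
        self.records = records[PATCH_STORE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patch_ids(self) -> np.ndarray:
        return np.sort(self.records["patch_id"].unique())

    def records_for(self, patch_id: int) -> pd.DataFrame:
        """Records of one patch; empty frame (not an error) for unknown ids."""
        return self.records[self.records["patch_id"] == patch_id].reset_index(drop=True)

    def gene_totals(self, n_genes: int) -> np.ndarray:
        """Transcript count per gene channel across all stored patches."""
        return np.bincount(
            self.records["gene_index"].to_numpy(), minlength=n_genes
        ).astype(np.int64)


def write_patch_store(records: pd.DataFrame | SparsePatchStore, path: str | Path) -> None:
    df = records.records if isinstance(records, SparsePatchStore) else records
    df = df[PATCH_STORE_COLUMNS] if len(df) else pd.DataFrame(
        {c: pd.Series(dtype=np.int64) for c in PATCH_STORE_COLUMNS}
    )
    schema = pa.schema([(c, pa.int64()) for c in PATCH_STORE_COLUMNS])
    pq.write_table(pa.Table.from_pandas(df, schema=schema, preserve_index=False), Path(path))


def read_patch_store(path: str | Path, patch_id: int | None = None) -> SparsePatchStore:
    """Read the Parquet patch store; with ``patch_id``, push the filter down."""
    filters = [("patch_id", "==", patch_id)] if patch_id is not None else None
    table = pq.read_table(Path(path), filters=filters)
    return SparsePatchStore(table.to_pandas())
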