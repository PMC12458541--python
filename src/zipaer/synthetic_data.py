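"""Synthetic CosMx-style transcript tables with controlled statistics.

The generator emulates the structure of an in-situ imaging experiment at desk
scale: per-FOV transcript point clouds scattered around cell centers, a
long-tailed per-gene abundance distribution (the regime the gene-weighted
reconstruction loss is designed for), a uniform extracellular background, and
a binary marker gene whose presence in a cell both defines the cell's label
and shifts a block of the cell's expression program — giving the latent
classifier something real to detect.

Model: per-gene mean expression is log-normal (``gene_abundance_spread`` is
the log-scale sd, so a spread of 1 already covers several orders of
magnitude); per-cell, per-gene counts are Poisson around those means;
transcript positions are isotropic Gaussian around the cell center, clipped
to the FOV.  Marker-positive cells emit at least one marker transcript and
have ``marker_effect_genes`` genes upscaled by ``marker_effect_scale``;
marker-negative cells emit none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

TRANSCRIPT_COLUMNS = ["fov", "cell_id", "gene", "x_px", "y_px", "z", "compartment"]
CELL_COLUMNS = ["cell_id", "fov", "x_px", "y_px"]

_COMPARTMENTS = np.array(["nuclear", "membrane", "cytoplasmic"])


@dataclass
class SimConfig:
    """Desk-scale defaults: 1 FOV of 2000 px, 50 cells, 100 genes."""

    n_fovs: int = 1
    fov_size_px: int = 2000
    n_cells_per_fov: int = 50
    n_genes: int = 100
    gene_abundance_spread: float = 1.5
    cell_spread_px: float = 15.0
    background_fraction: float = 0.1
    marker_gene_index: int = 0
    marker_positive_fraction: float = 0.5
    seed: int = 0
    mean_transcripts_per_cell: float = 300.0
    marker_effect_genes: int = 10
    marker_effect_scale: float = 3.0

    def validate(self) -> None:
        if min(self.n_fovs, self.fov_size_px, self.n_cells_per_fov, self.n_genes) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_genes > 0 and not 0 <= self.marker_gene_index < self.n_genes:
            raise ConfigurationError("marker_gene_index out of range")
        for name in ("background_fraction", "marker_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.gene_abundance_spread < 0 or self.cell_spread_px < 0:
            raise ConfigurationError("spreads must be non-negative")
        if self.mean_transcripts_per_cell < 0:
            raise ConfigurationError("mean_transcripts_per_cell must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, for downstream verification."""

    cell_centers: pd.DataFrame  # cell_id, fov, x_px, y_px
    cell_labels: pd.DataFrame   # cell_id, label (1 = marker-positive)
    gene_means: pd.DataFrame    # gene, mean_expression


def gene_names(n_genes: int, marker_gene_index: int | None = None) -> list[str]:
    """Stable gene vocabulary; the marker gene is named MARKER for readability."""
    names = [f"G{i:04d}" for i in range(n_genes)]
    if marker_gene_index is not None and 0 <= marker_gene_index < n_genes:
        names[marker_gene_index] = "MARKER"
    return names


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw transcript and cell tables plus the ground truth behind them.

    Returns ``(transcripts, cells, truth)``.  Background transcripts carry
    ``cell_id`` 0; real cells are numbered from 1 across all FOVs.
    Identical seeds give byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    names = gene_names(G, config.marker_gene_index)

    # Long-tailed per-gene means, scaled to the requested per-cell depth.
    raw = np.exp(rng.normal(0.0, config.gene_abundance_spread, size=G)) if G else np.array([])
    if G and raw.sum() > 0 and config.mean_transcripts_per_cell > 0:
        means = raw * (config.mean_transcripts_per_cell / raw.sum())
    else:
        means = raw * 0.0

    n_cells = config.n_fovs * config.n_cells_per_fov
    cell_rows, tx_chunks = [], []
    labels = np.zeros(n_cells, dtype=np.int64)
    if n_cells and G:
        n_pos = int(round(config.marker_positive_fraction * n_cells))
        pos_ids = rng.choice(n_cells, size=n_pos, replace=False)
        labels[pos_ids] = 1

    # Genes the marker program upregulates (never the marker itself).
    eff = [g for g in range(G) if g != config.marker_gene_index][: config.marker_effect_genes]

    cell_id = 0
    n_cell_tx = 0
    for fov in range(config.n_fovs):
        centers = rng.uniform(0, config.fov_size_px, size=(config.n_cells_per_fov, 2))
        for cx, cy in centers:
            cell_id += 1
            cell_rows.append((cell_id, fov, cx, cy))
            mu = means.copy()
            positive = labels[cell_id - 1] == 1
            if positive and eff:
                mu[eff] *= config.marker_effect_scale
            counts = rng.poisson(mu)
            if G:
                counts[config.marker_gene_index] = 0
                if positive:
                    counts[config.marker_gene_index] = 1 + rng.poisson(
                        means[config.marker_gene_index]
                    )
            total = int(counts.sum())
            n_cell_tx += total
            if total == 0:
                continue
            gidx = np.repeat(np.arange(G), counts)
            xy = rng.normal([cx, cy], config.cell_spread_px, size=(total, 2))
            xy = np.clip(xy, 0.0, np.nextafter(config.fov_size_px, 0.0))
            tx_chunks.append(
                pd.DataFrame(
                    {
                        "fov": fov,
                        "cell_id": cell_id,
                        "gene": np.array(names, dtype=object)[gidx],
                        "x_px": xy[:, 0],
                        "y_px": xy[:, 1],
                        "z": 0,
                        "compartment": rng.choice(_COMPARTMENTS, size=total),
                    }
                )
            )

    # Extracellular background: cell_id 0, uniform positions, genes drawn
    # from the overall abundance profile.
    f = config.background_fraction
    if G and f > 0 and f < 1 and n_cell_tx > 0:
        n_bg_total = int(round(f / (1.0 - f) * n_cell_tx))
        per_fov = rng.multinomial(n_bg_total, np.full(config.n_fovs, 1.0 / config.n_fovs)) \
            if config.n_fovs else []
        p = means / means.sum() if means.sum() > 0 else None
        for fov, nb in enumerate(per_fov):
            if nb == 0 or p is None:
                continue
            gidx = rng.choice(G, size=nb, p=p)
            xy = rng.uniform(0, config.fov_size_px, size=(nb, 2))
            tx_chunks.append(
                pd.DataFrame(
                    {
                        "fov": fov,
                        "cell_id": 0,
                        "gene": np.array(names, dtype=object)[gidx],
                        "x_px": xy[:, 0],
                        "y_px": xy[:, 1],
                        "z": 0,
                        "compartment": "none",
                    }
                )
            )

    if tx_chunks:
        transcripts = pd.concat(tx_chunks, ignore_index=True)[TRANSCRIPT_COLUMNS]
    else:
        transcripts = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                TRANSCRIPT_COLUMNS,
                [np.int64, np.int64, object, np.float64, np.float64, np.int64, object],
            )}
        )
    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)

    truth = GroundTruth(
        cell_centers=cells.copy(),
        cell_labels=pd.DataFrame(
            {"cell_id": np.arange(1, n_cells + 1), "label": labels}
        ),
        gene_means=pd.DataFrame({"gene": names, "mean_expression": means}),
    )
    return transcripts, cells, truth


def write_simulation(outdir: str | Path, transcripts: pd.DataFrame,
                     cells: pd.DataFrame, truth: GroundTruth) -> dict[str, Path]:
    """Persist tables in CSV + Parquet, ground truth as CSV, vocab as text."""
    from .transcript_store import GeneVocabulary, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stem, df in (("transcripts", transcripts), ("cells", cells)):
        for ext in ("csv", "parquet"):
            p = outdir / f"{stem}.{ext}"
            write_table(df, p)
            paths[f"{stem}_{ext}"] = p
    for stem, df in (
        ("ground_truth_labels", truth.cell_labels),
        ("ground_truth_gene_means", truth.gene_means),
    ):
        p = outdir / f"{stem}.csv"
        df.to_csv(p, index=False)
        paths[stem] = p
    vocab = GeneVocabulary(list(truth.gene_means["gene"]))
    p = outdir / "genes.txt"
    vocab.write(p)
    paths["genes"] = p
    return paths
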