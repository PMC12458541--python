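"""Columnar I/O contracts and the transcript-to-patch box join, held to a
brute-force double-loop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zipaer as z


def _tiny_transcripts():
    return pd.DataFrame(
        {
            "fov": [0, 0, 0],
            "cell_id": [1, 2, 0],
            "gene": ["G1", "G2", "G1"],
            "x_px": [10.5, 20.0, 30.25],
            "y_px": [15.0, 25.5, 35.0],
            "z": [0, 0, 0],
            "compartment": ["nuclear", "membrane", "none"],
        }
    )


@pytest.mark.parametrize("ext", ["csv", "parquet"])
def test_write_read_round_trip(tmp_path, ext):
    df = _tiny_transcripts()
    path = tmp_path / f"tx.{ext}"
    z.write_table(df, path)
    back = z.read_transcripts(path)
    pd.testing.assert_frame_equal(back, df)


@pytest.mark.parametrize("ext", ["csv", "parquet"])
def test_column_projection(tmp_path, ext):
    df = _tiny_transcripts()
    path = tmp_path / f"tx.{ext}"
    z.write_table(df, path)
    got = z.read_transcripts(path, columns=["gene", "x_px", "y_px"])
    assert list(got.columns) == ["gene", "x_px", "y_px"]
    assert len(got) == 3
    assert list(got["gene"]) == ["G1", "G2", "G1"]  # row order preserved


@pytest.mark.parametrize("ext", ["csv", "parquet"])
def test_missing_column_names_the_column(tmp_path, ext):
    df = _tiny_transcripts().drop(columns=["x_px"])
    path = tmp_path / f"tx.{ext}"
    z.write_table(df, path)
    with pytest.raises(z.SchemaError, match="x_px"):
        z.read_transcripts(path, columns=["gene", "x_px"])


def test_vocabulary_bijection_and_round_trip(tmp_path):
    vocab = z.GeneVocabulary(["B", "A", "C"])
    assert [vocab.index(g) for g in ["B", "A", "C"]] == [0, 1, 2]
    vocab.write(tmp_path / "genes.txt")
    assert z.GeneVocabulary.read(tmp_path / "genes.txt").genes == ["B", "A", "C"]
    with pytest.raises(z.ValidationError):
        z.GeneVocabulary(["A", "A"])
    with pytest.raises(z.SchemaError):
        vocab.index("missing")


def _centers(rows):
    return pd.DataFrame(rows, columns=["cell_id", "fov", "x_px", "y_px"])


def test_transcript_at_center_maps_to_midpoint():
    vocab = z.GeneVocabulary(["G1"])
    tx = pd.DataFrame({"fov": [0], "gene": ["G1"], "x_px": [100.0], "y_px": [100.0]})
    rec = z.assign_transcripts_to_patches(tx, _centers([(1, 0, 100, 100)]), 60, vocab)
    assert len(rec) == 1
    assert rec.loc[0, "x_local"] == 30 and rec.loc[0, "y_local"] == 30


def test_neighboring_patches_overlap():
    """Two cells 100 px apart with 600-px patches: a midway transcript lands
    in both patches' record sets."""
    vocab = z.GeneVocabulary(["G1"])
    tx = pd.DataFrame({"fov": [0], "gene": ["G1"], "x_px": [1050.0], "y_px": [1000.0]})
    centers = _centers([(1, 0, 1000, 1000), (2, 0, 1100, 1000)])
    rec = z.assign_transcripts_to_patches(tx, centers, 600, vocab)
    assert sorted(rec["patch_id"]) == [1, 2]


def test_center_outside_fov_rejected():
    vocab = z.GeneVocabulary(["G1"])
    tx = pd.DataFrame({"fov": [0], "gene": ["G1"], "x_px": [10.0], "y_px": [10.0]})
    with pytest.raises(z.ValidationError):
        z.assign_transcripts_to_patches(
            tx, _centers([(1, 0, 2500, 100)]), 60, vocab, fov_size_px=2000
        )


def _brute_force_join(tx, centers, S):
    out = set()
    for _, t in tx.iterrows():
        for _, c in centers.iterrows():
            cx, cy = int(np.floor(c["x_px"])), int(np.floor(c["y_px"]))
            if t["fov"] != c["fov"]:
                continue
            if cx - S // 2 <= t["x_px"] < cx + S // 2 and cy - S // 2 <= t["y_px"] < cy + S // 2:
                out.add(
                    (
                        int(c["cell_id"]),
                        t["gene"],
                        int(np.floor(t["x_px"])) - (cx - S // 2),
                        int(np.floor(t["y_px"])) - (cy - S // 2),
                    )
                )
    return out


def test_join_matches_brute_force_oracle(rng):
    genes = [f"G{i}" for i in range(5)]
    vocab = z.GeneVocabulary(genes)
    tx = pd.DataFrame(
        {
            "fov": rng.integers(0, 2, 50),
            "gene": rng.choice(genes, 50),
            "x_px": rng.uniform(0, 200, 50),
            "y_px": rng.uniform(0, 200, 50),
        }
    )
    centers = _centers(
        [(i + 1, int(rng.integers(0, 2)), rng.uniform(0, 200), rng.uniform(0, 200))
         for i in range(5)]
    )
    rec = z.assign_transcripts_to_patches(tx, centers, 60, vocab)
    got = {
        (int(r.patch_id), vocab.genes[int(r.gene_index)], int(r.x_local), int(r.y_local))
        for r in rec.itertuples()
    }
    assert got == _brute_force_join(tx, centers, 60)
    # row-order invariance (set equality under input shuffling)
    rec2 = z.assign_transcripts_to_patches(
        tx.sample(frac=1.0, random_state=0).reset_index(drop=True), centers, 60, vocab
    )
    got2 = {
        (int(r.patch_id), vocab.genes[int(r.gene_index)], int(r.x_local), int(r.y_local))
        for r in rec2.itertuples()
    }
    assert got2 == got


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n_tx=st.integers(0, 40),
    n_patches=st.integers(1, 6),
    size=st.sampled_from([4, 10, 60]),
)
def test_join_property_bounds_and_oracle(seed, n_tx, n_patches, size):
    rng = np.random.default_rng(seed)
    vocab = z.GeneVocabulary(["G0", "G1"])
    tx = pd.DataFrame(
        {
            "fov": np.zeros(n_tx, dtype=int),
            "gene": rng.choice(["G0", "G1"], n_tx),
            "x_px": rng.uniform(0, 100, n_tx),
            "y_px": rng.uniform(0, 100, n_tx),
        }
    )
    centers = _centers(
        [(i + 1, 0, rng.uniform(0, 100), rng.uniform(0, 100)) for i in range(n_patches)]
    )
    rec = z.assign_transcripts_to_patches(tx, centers, size, vocab)
    assert ((rec["x_local"] >= 0) & (rec["x_local"] < size)).all()
    assert ((rec["y_local"] >= 0) & (rec["y_local"] < size)).all()
    got = {
        (int(r.patch_id), vocab.genes[int(r.gene_index)], int(r.x_local), int(r.y_local))
        for r in rec.itertuples()
    }
    assert got == _brute_force_join(tx, centers, size)


def test_patch_store_round_trip(tmp_path, rng):
    n = 100
    df = pd.DataFrame(
        {
            "patch_id": rng.integers(1, 6, n),
            "gene_index": rng.integers(0, 10, n),
            "x_local": rng.integers(0, 60, n),
            "y_local": rng.integers(0, 60, n),
        }
    )
    path = tmp_path / "store.parquet"
    z.write_patch_store(df, path)
    store = z.read_patch_store(path)
    assert len(store) == n
    # partition: union of per-patch queries recovers every record
    assert sum(len(store.records_for(int(p))) for p in store.patch_ids) == n
    pd.testing.assert_frame_equal(
        store.records.sort_values(list(df.columns)).reset_index(drop=True),
        df.astype(np.int64).sort_values(list(df.columns)).reset_index(drop=True),
    )
    # filter pushdown on read
    one = z.read_patch_store(path, patch_id=int(store.patch_ids[0]))
    assert set(one.records["patch_id"]) == {int(store.patch_ids[0])}
    # unknown id -> empty result, not an error
    assert len(store.records_for(999)) == 0


def test_empty_patch_store_round_trip(tmp_path):
    path = tmp_path / "empty.parquet"
    z.write_patch_store(pd.DataFrame(), path)
    store = z.read_patch_store(path)
    assert len(store) == 0 and len(store.patch_ids) == 0
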