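import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from wmc.preprocessing import (
    EmptyResultError,
    ParseError,
    QCThresholds,
    RawCountMatrix,
    compute_qc_metrics,
    filter_cells,
    filter_genes,
    log_normalize,
    read_counts,
    write_counts,
)


def test_qc_metrics_hand_computed(fixture_counts):
    m = compute_qc_metrics(fixture_counts)
    assert np.allclose(m.count_depth, [5, 10, 5, 0])
    assert np.array_equal(m.n_genes, [2, 3, 4, 0])
    assert np.allclose(m.mito_fraction, [0.0, 0.5, 0.2, 0.0])


def test_qc_metrics_mito_arithmetic():
    """Cell with 3 counts on an ordinary gene and 2 on a mito gene:
    depth 5, 2 detected genes, mito fraction 0.4."""
    X = RawCountMatrix(
        sp.csr_matrix(np.array([[3], [2]])),
        gene_ids=np.array(["g1", "MT-1"], dtype=object),
        barcodes=np.array(["c1"], dtype=object),
    )
    m = compute_qc_metrics(X)
    assert m.count_depth[0] == 5 and m.n_genes[0] == 2
    assert np.isclose(m.mito_fraction[0], 0.4)


def test_mtx_round_trip(fixture_counts, tmp_path):
    write_counts(fixture_counts, tmp_path, format="10x-mtx")
    back = read_counts(str(tmp_path), format="10x-mtx")
    assert np.array_equal(back.counts.toarray(), fixture_counts.counts.toarray())
    assert np.array_equal(back.gene_ids, fixture_counts.gene_ids)
    assert np.array_equal(back.barcodes, fixture_counts.barcodes)
    assert np.array_equal(back.mito_mask, fixture_counts.mito_mask)


def test_csv_round_trip(fixture_counts, tmp_path):
    write_counts(fixture_counts, tmp_path, format="csv")
    back = read_counts(str(tmp_path / "counts.csv"), format="csv")
    assert np.array_equal(back.counts.toarray(), fixture_counts.counts.toarray())


def test_negative_entry_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("gene,c1,c2\ng1,1,2\ng2,-3,0\n")
    with pytest.raises(ParseError, match="negative"):
        read_counts(str(p), format="csv")


def test_triplet_dimension_mismatch(fixture_counts, tmp_path):
    write_counts(fixture_counts, tmp_path, format="10x-mtx")
    feat = tmp_path / "features.tsv"
    lines = feat.read_text().splitlines()
    feat.write_text("\n".join(lines + ["EXTRA\tEXTRA\tGene Expression"]) + "\n")
    with pytest.raises(ParseError, match="features"):
        read_counts(str(tmp_path), format="10x-mtx")


def test_missing_path():
    with pytest.raises(FileNotFoundError):
        read_counts("/no/such/dir", format="10x-mtx")


def _cells_with_n_genes(n_detected_list, mito_fracs=None, n_genes_total=3600):
    """Matrix whose cell j detects exactly n_detected_list[j] ordinary
    genes (count 1 each); optional extra mito counts set the mito
    fraction."""
    p = len(n_detected_list)
    cols = []
    for j, nd in enumerate(n_detected_list):
        col = np.zeros(n_genes_total)
        col[:nd] = 1
        cols.append(col)
    counts = np.column_stack(cols)
    gene_ids = [f"g{i}" for i in range(n_genes_total - 1)] + ["MT-1"]
    if mito_fracs:
        for j, f in enumerate(mito_fracs):
            if f:
                depth = counts[:, j].sum()
                counts[-1, j] = int(f / (1 - f) * depth)  # floor: frac stays <= f
    return RawCountMatrix(
        sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=np.array([f"c{j}" for j in range(p)], dtype=object),
    )


def test_cell_filter_boundaries():
    """150 and 3500 detected genes are removed; exactly 200 and exactly
    3000 are retained; mito 0.06 removed, 0.05 retained."""
    X = _cells_with_n_genes([150, 200, 3000, 3500, 1000, 1000],
                            mito_fracs=[0, 0, 0, 0, 0.06, 0.05])
    m = compute_qc_metrics(X)
    kept, log = filter_cells(X, m)
    assert list(kept.barcodes) == ["c1", "c2", "c5"]
    removed = log.loc[~log["kept"]]
    assert set(removed["barcode"]) == {"c0", "c3", "c4"}
    reasons = dict(zip(removed["barcode"], removed["reason"]))
    assert "below" in reasons["c0"]
    assert "above" in reasons["c3"]
    assert "mito" in reasons["c4"]


def test_cell_filter_preserves_values_and_is_idempotent():
    X = _cells_with_n_genes([150, 500, 600])
    m = compute_qc_metrics(X)
    kept, _ = filter_cells(X, m)
    assert np.array_equal(
        kept.counts.toarray(), X.counts.toarray()[:, 1:]
    )
    again, log = filter_cells(kept, compute_qc_metrics(kept))
    assert log["kept"].all()
    assert np.array_equal(again.counts.toarray(), kept.counts.toarray())


def test_gene_filter_boundary():
    """Genes detected in 19 cells are removed, in exactly 20 retained."""
    p = 25
    counts = np.zeros((3, p))
    counts[0, :19] = 1
    counts[1, :20] = 1
    counts[2, :] = 1
    X = RawCountMatrix(
        sp.csr_matrix(counts),
        gene_ids=np.array(["a19", "b20", "c25"], dtype=object),
        barcodes=np.array([f"c{j}" for j in range(p)], dtype=object),
    )
    out = filter_genes(X)
    assert list(out.gene_ids) == ["b20", "c25"]
    assert np.array_equal(filter_genes(out).gene_ids, out.gene_ids)  # idempotent


def test_all_cells_removed_raises():
    X = _cells_with_n_genes([10, 20, 30])
    with pytest.raises(EmptyResultError):
        filter_cells(X, compute_qc_metrics(X))


def test_all_genes_removed_raises(fixture_counts):
    with pytest.raises(EmptyResultError):
        filter_genes(fixture_counts, QCThresholds(min_cells_per_gene=20))


def test_log_normalize_values(fixture_counts):
    """Library-size values match an independent per-entry recomputation;
    zeros stay zero; within-cell order is preserved."""
    keep = RawCountMatrix(
        fixture_counts.counts[:, :3], fixture_counts.gene_ids,
        fixture_counts.barcodes[:3],
    )
    out = log_normalize(keep, scale_factor=1e4)
    raw = keep.counts.toarray().astype(float)
    for g in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            expect = np.log(1 + 1e4 * raw[g, c] / raw[:, c].sum())
            assert np.isclose(out.values[g, c], expect)
    assert np.all(out.values[raw == 0] == 0)
    for c in range(raw.shape[1]):
        order = np.argsort(raw[:, c], kind="stable")
        assert np.all(np.diff(out.values[order, c]) >= 0)


def test_log_normalize_depth_example():
    """Count 1 in a depth-10000 cell with scale 10000 maps to ln 2."""
    counts = np.zeros((2, 1))
    counts[0, 0] = 1
    counts[1, 0] = 9999
    X = RawCountMatrix(sp.csr_matrix(counts),
                       gene_ids=np.array(["a", "b"], dtype=object),
                       barcodes=np.array(["c"], dtype=object))
    out = log_normalize(X, scale_factor=1e4)
    assert np.isclose(out.values[0, 0], np.log(2))


def test_log_normalize_plain_log1p(fixture_counts):
    keep = RawCountMatrix(fixture_counts.counts[:, :3],
                          fixture_counts.gene_ids, fixture_counts.barcodes[:3])
    out = log_normalize(keep, method="plain-log1p")
    assert np.allclose(out.values, np.log1p(keep.counts.toarray()))


def test_log_normalize_zero_depth_errors(fixture_counts):
    with pytest.raises(ValueError, match="QC"):
        log_normalize(fixture_counts)  # c4 has depth 0


def test_identifier_validation():
    with pytest.raises(ParseError, match="unique"):
        RawCountMatrix(sp.csr_matrix(np.ones((2, 1))),
                       gene_ids=np.array(["g", "g"], dtype=object),
                       barcodes=np.array(["c"], dtype=object))
    with pytest.raises(ParseError, match="non-integer"):
        RawCountMatrix(sp.csr_matrix(np.array([[0.5]])),
                       gene_ids=np.array(["g"], dtype=object),
                       barcodes=np.array(["c"], dtype=object))
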