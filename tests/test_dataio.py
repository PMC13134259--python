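"""I/O, QC filtering and normalization contracts."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screlmap import (
    load_cakut_gene_set,
    normalize_log1p,
    qc_filter,
    read_gene_lengths,
    read_gene_set,
    read_mtx_dataset,
    write_mtx_dataset,
)
from screlmap.dataio import lengths_from_gtf
from screlmap.errors import DegenerateInputError, FormatError, SchemaError

from conftest import make_dataset


def _write_bundle(tmp_path, ds):
    return write_mtx_dataset(ds, tmp_path / "bundle")


class TestMtxRoundTrip:
    def test_write_read_identity_on_counts(self, tmp_path, toy_dataset):
        d = _write_bundle(tmp_path, toy_dataset)
        back = read_mtx_dataset(
            d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"
        )
        assert list(back.cell_ids) == list(toy_dataset.cell_ids)
        assert list(back.gene_ids) == list(toy_dataset.gene_ids)
        assert (back.counts != toy_dataset.counts).nnz == 0
        assert back.cell_type.tolist() == toy_dataset.cell_type.tolist()

    def test_omitted_zero_entries_read_as_zero(self, tmp_path):
        d = tmp_path
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 3 2\n1 1 5\n2 3 7\n"
        )
        (d / "genes.tsv").write_text("gA\ngB\n")
        (d / "barcodes.tsv").write_text("c1\nc2\nc3\n")
        (d / "meta.tsv").write_text("barcode\tcell_type\nc1\tX\nc2\tX\nc3\tY\n")
        ds = read_mtx_dataset(d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "meta.tsv")
        dense = ds.counts.toarray()  # cells x genes after transpose
        assert dense[0, 0] == 5 and dense[2, 1] == 7
        assert dense.sum() == 12  # every unlisted entry is zero

    def test_gene_row_count_mismatch_is_format_error(self, tmp_path, toy_dataset):
        d = _write_bundle(tmp_path, toy_dataset)
        (d / "genes.tsv").write_text("g0\ng1\ng2\ng3\ng4\n")  # 5 rows vs 4 genes
        with pytest.raises(FormatError):
            read_mtx_dataset(
                d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"
            )

    def test_missing_cell_type_column_is_schema_error(self, tmp_path, toy_dataset):
        d = _write_bundle(tmp_path, toy_dataset)
        meta = pd.read_csv(d / "cell_meta.tsv", sep="\t", index_col=0)
        meta.rename(columns={"cell_type": "annotation"}).to_csv(d / "cell_meta.tsv", sep="\t")
        with pytest.raises(SchemaError):
            read_mtx_dataset(
                d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"
            )

    def test_cells_without_metadata_are_dropped(self, tmp_path, toy_dataset):
        d = _write_bundle(tmp_path, toy_dataset)
        meta = pd.read_csv(d / "cell_meta.tsv", sep="\t", index_col=0)
        meta.iloc[:-1].to_csv(d / "cell_meta.tsv", sep="\t")
        ds = read_mtx_dataset(
            d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"
        )
        assert ds.n_cells == toy_dataset.n_cells - 1


class TestGeneSet:
    def test_packaged_curated_set_has_91_entries(self):
        gs = load_cakut_gene_set()
        assert len(gs) == 91
        assert "PAX2" in gs.symbols and "COL4A1" in gs.symbols

    def test_duplicate_rows_deduplicated(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("symbol\tensembl\nEYA1\tE1\nEYA1\tE1\nPAX2\tE2\n")
        gs = read_gene_set(p)
        assert len(gs) == 2

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("hgnc_symbol\nZZZ3\nAAA1\nMMM2\n")
        assert read_gene_set(p).symbols == ["ZZZ3", "AAA1", "MMM2"]

    def test_empty_file_is_schema_error(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("hgnc_symbol\tensembl_id\n")
        with pytest.raises(SchemaError):
            read_gene_set(p)

    def test_map_to_prefers_ensembl_then_symbol(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("hgnc_symbol\tensembl_id\nPAX2\tENSX1\nEYA1\tENSX2\nNOPE\tENSX3\n")
        gs = read_gene_set(p)
        mapped, unmapped = gs.map_to(pd.Index(["ENSX1", "EYA1", "OTHER"]))
        assert mapped == ["ENSX1", "EYA1"]
        assert unmapped == ["NOPE"]


class TestQCFilter:
    def test_zero_thresholds_identity(self, toy_dataset):
        out, rep = qc_filter(toy_dataset, 0, 0)
        assert out.n_cells == toy_dataset.n_cells and out.n_genes == toy_dataset.n_genes
        assert rep.n_cells_removed == 0 and rep.n_genes_removed == 0

    def test_cell_with_too_few_detected_genes_removed(self):
        # cell c2 detects only 1 gene
        counts = [[1, 1, 0], [0, 2, 3], [0, 4, 0], [1, 0, 1], [2, 2, 2]]
        ds = make_dataset(counts, list("AABBB"))
        out, rep = qc_filter(ds, min_genes_per_cell=2, min_cells_per_gene=0)
        assert out.n_cells == 4 and rep.n_cells_removed == 1
        assert "c2" not in out.cell_ids

    def test_rare_gene_removed(self):
        # gene g2 detected in a single cell
        counts = [[1, 1, 0], [2, 1, 0], [1, 2, 0], [1, 1, 5]]
        ds = make_dataset(counts, list("AABB"))
        out, _ = qc_filter(ds, min_genes_per_cell=0, min_cells_per_gene=3)
        assert "g2" not in out.gene_ids and out.n_genes == 2

    def test_idempotent_at_fixed_thresholds(self, planted_dataset):
        ds, _ = planted_dataset
        once, _ = qc_filter(ds, 5, 3)
        twice, rep = qc_filter(once, 5, 3)
        assert twice.n_cells == once.n_cells and twice.n_genes == once.n_genes
        assert rep.n_cells_removed == 0 and rep.n_genes_removed == 0

    def test_all_cells_removed_is_degenerate(self, toy_dataset):
        with pytest.raises(DegenerateInputError):
            qc_filter(toy_dataset, min_genes_per_cell=100, min_cells_per_gene=0)


class TestNormalizeLog1p:
    def test_hand_computed_values(self):
        ds = make_dataset([[1, 1, 2]], ["A"])
        out = normalize_log1p(ds, target_sum=10_000)
        expected = np.log1p([2500.0, 2500.0, 5000.0])
        np.testing.assert_allclose(out.normalized.toarray()[0], expected)

    def test_single_nonzero_scales_to_target_sum(self):
        ds = make_dataset([[0, 7, 0]], ["A"])
        out = normalize_log1p(ds, target_sum=10_000)
        assert out.normalized.toarray()[0, 1] == pytest.approx(np.log1p(10_000))
        assert out.normalized.toarray()[0, 0] == 0.0  # log1p(0) = 0

    def test_prelog_rowsums_equal_target(self, planted_dataset):
        ds, _ = planted_dataset
        prelog = np.expm1(ds.normalized.toarray())
        np.testing.assert_allclose(prelog.sum(axis=1), 10_000.0, rtol=1e-6)

    def test_monotone_within_cell(self, planted_dataset):
        ds, _ = planted_dataset
        c = ds.counts.toarray()[0]
        n = ds.normalized.toarray()[0]
        order = np.argsort(c)
        assert (np.diff(n[order]) >= -1e-12).all()

    def test_counts_layer_untouched(self, toy_dataset):
        before = toy_dataset.counts.toarray().copy()
        out = normalize_log1p(toy_dataset)
        np.testing.assert_array_equal(out.counts.toarray(), before)

    def test_zero_total_cell_is_degenerate(self):
        ds = make_dataset([[1, 2], [0, 0]], ["A", "A"])
        with pytest.raises(DegenerateInputError):
            normalize_log1p(ds)


class TestGeneLengths:
    def test_length_table_roundtrip(self, tmp_path):
        p = tmp_path / "len.tsv"
        p.write_text("gene_id\tlength_bp\ng1\t1500\ng2\t800\n")
        ann = read_gene_lengths(p)
        assert ann.lengths["g1"] == 1500.0
        assert ann.coverage(pd.Index(["g1", "g3"])) == 0.5

    def test_nonpositive_length_rejected(self, tmp_path):
        p = tmp_path / "len.tsv"
        p.write_text("gene_id\tlength_bp\ng1\t0\n")
        with pytest.raises(SchemaError):
            read_gene_lengths(p)

    def test_union_exon_length_merges_overlaps(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tx\texon\t150\t300\t.\t+\t.\tgene_id "gA";\n'  # overlaps -> union 100-300
            'chr1\tx\texon\t500\t600\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tx\texon\t10\t19\t.\t-\t.\tgene_id "gB";\n'
        )
        ann = lengths_from_gtf(gtf)
        assert ann.lengths["gA"] == 201 + 101
        assert ann.lengths["gB"] == 10
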