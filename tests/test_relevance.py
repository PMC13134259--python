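"""Matched-control machinery: binning, sampling, scoring, empirical p/z,
association and heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screlmap import (
    ControlConfig,
    bin_genes,
    celltype_association,
    empirical_p_and_z,
    sample_control_sets,
    score_and_associate,
    score_cells,
)
from screlmap.errors import ContractError

from conftest import make_dataset


def _bins(mean_expr, cfg, lengths=None):
    return bin_genes(pd.Series(mean_expr), cfg, lengths=lengths)


class TestBinGenes:
    def test_single_bin_when_one_expression_bin(self):
        cfg = ControlConfig(n_expr_bins=1, match_length=False, min_bin_occupancy=1)
        bins = _bins(pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)]), cfg)
        assert bins.labels.nunique() == 1

    def test_quantile_bins_are_balanced(self):
        idx = [f"g{i}" for i in range(100)]
        cfg = ControlConfig(n_expr_bins=4, match_length=False, min_bin_occupancy=1)
        bins = _bins(pd.Series(np.random.default_rng(0).random(100), index=idx), cfg)
        assert sorted(bins.labels.value_counts()) == [25, 25, 25, 25]

    def test_joint_bins_with_independent_lengths(self):
        """Nested length bins split each 25-gene expression bin into
        equal halves, giving 12-13 genes per joint bin."""
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(100)]
        expr = pd.Series(rng.random(100), index=idx)
        lengths = pd.Series(rng.lognormal(8, 0.5, 100), index=idx)
        cfg = ControlConfig(n_expr_bins=4, n_len_bins=2, match_length=True, min_bin_occupancy=1)
        bins = _bins(expr, cfg, lengths=lengths)
        counts = bins.labels.value_counts()
        assert len(counts) == 8
        assert set(counts) == {12, 13}

    def test_nested_length_bins_rank_within_expression_bin(self):
        """Within one expression bin, the length sub-bin orders by length."""
        rng = np.random.default_rng(2)
        idx = [f"g{i}" for i in range(100)]
        expr = pd.Series(rng.random(100), index=idx)
        lengths = pd.Series(rng.lognormal(8, 0.5, 100), index=idx)
        cfg = ControlConfig(n_expr_bins=4, n_len_bins=2, match_length=True, min_bin_occupancy=1)
        bins = _bins(expr, cfg, lengths=lengths)
        for e in range(4):
            in_bin = bins.labels[bins.labels.map(lambda b: b[0] == e)]
            lo = lengths[in_bin[in_bin.map(lambda b: b[1] == 0)].index]
            hi = lengths[in_bin[in_bin.map(lambda b: b[1] == 1)].index]
            assert lo.max() <= hi.min()

    def test_missing_lengths_is_contract_error(self):
        idx = [f"g{i}" for i in range(20)]
        expr = pd.Series(np.arange(20.0), index=idx)
        lengths = pd.Series([1000.0] * 10, index=idx[:10])
        cfg = ControlConfig(n_expr_bins=2, match_length=True)
        with pytest.raises(ContractError):
            bin_genes(expr, cfg, lengths=lengths)

    def test_small_bins_merged_to_min_occupancy(self):
        idx = [f"g{i}" for i in range(30)]
        expr = pd.Series(np.arange(30.0), index=idx)
        cfg = ControlConfig(n_expr_bins=10, match_length=False, min_bin_occupancy=10)
        bins = _bins(expr, cfg)
        assert (bins.labels.value_counts() >= 10).all()


class TestSampleControlSets:
    def _setup(self, n_genes=60, set_size=6, k=20, **cfg_kw):
        rng = np.random.default_rng(7)
        idx = pd.Index([f"g{i}" for i in range(n_genes)])
        expr = pd.Series(rng.random(n_genes), index=idx)
        cfg = ControlConfig(n_control_sets=k, n_expr_bins=3, match_length=False,
                            min_bin_occupancy=2, **cfg_kw)
        bins = bin_genes(expr, cfg)
        gene_set = list(idx[:set_size])
        return idx, bins, cfg, gene_set

    def test_controls_share_seed_gene_bins(self):
        idx, bins, cfg, gene_set = self._setup()
        coll = sample_control_sets(gene_set, bins, cfg, idx)
        for k in range(coll.n_sets):
            for slot, seed_gene in enumerate(gene_set):
                ctrl = idx[coll.sets[k, slot]]
                assert bins.labels[ctrl] == bins.labels[seed_gene]

    def test_seed_genes_excluded_from_controls(self):
        idx, bins, cfg, gene_set = self._setup()
        coll = sample_control_sets(gene_set, bins, cfg, idx)
        for k in range(coll.n_sets):
            assert set(coll.set_gene_ids(k)).isdisjoint(gene_set)

    def test_same_seed_identical_collections(self):
        idx, bins, cfg, gene_set = self._setup(seed=42)
        c1 = sample_control_sets(gene_set, bins, cfg, idx)
        c2 = sample_control_sets(gene_set, bins, cfg, idx)
        np.testing.assert_array_equal(c1.sets, c2.sets)

    def test_without_replacement_when_pool_allows(self):
        idx, bins, cfg, gene_set = self._setup(n_genes=90, set_size=6)
        coll = sample_control_sets(gene_set, bins, cfg, idx)
        for k in range(coll.n_sets):
            ids = coll.set_gene_ids(k)
            assert len(set(ids)) == len(ids)

    def test_exhausted_bin_falls_back_with_replacement(self):
        # 1 expression bin over 5 genes, 3 of them seeds -> pool of 2 < 3 seeds
        idx = pd.Index(["g0", "g1", "g2", "g3", "g4"])
        expr = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=idx)
        cfg = ControlConfig(n_control_sets=5, n_expr_bins=1, min_bin_occupancy=1)
        bins = bin_genes(expr, cfg)
        coll = sample_control_sets(["g0", "g1", "g2"], bins, cfg, idx)
        assert coll.with_replacement_bins
        assert set(idx[coll.sets.ravel()]) <= {"g3", "g4"}


class TestScoreCells:
    def test_degenerate_identity_controls_equal_set(self):
        """When every control set IS the gene set, norm=0 and mc_p=1."""
        vals = np.random.default_rng(0).random((8, 4))
        ds = make_dataset((vals > 0).astype(int), ["A"] * 8, normalized=vals)
        from screlmap.relevance import ControlSetCollection

        sets = np.tile(np.arange(4), (10, 1))
        coll = ControlSetCollection(
            sets=sets,
            seed_positions=np.arange(4),
            seed_bins=pd.Series([(0, 0)] * 4, index=ds.gene_ids),
            gene_ids=ds.gene_ids,
            seed=0,
        )
        scores = score_cells(ds, list(ds.gene_ids), coll)
        assert (scores.table["norm_score"] == 0).all()
        assert (scores.table["mc_p"] == 1.0).all()
        assert scores.table["sd_zero_flag"].all()

    def test_mc_p_formula_when_observed_beats_all_controls(self, planted_dataset):
        ds, truth = planted_dataset
        cfg = ControlConfig(n_control_sets=100, seed=3)
        scores, _, _ = score_and_associate(ds, list(truth.program_genes), cfg)
        beat_all = (scores.control_raw < scores.table["raw_score"].to_numpy()[:, None]).all(axis=1)
        np.testing.assert_allclose(
            scores.table.loc[beat_all, "mc_p"], 1.0 / 101.0
        )

    def test_program_type_scores_higher(self, planted_dataset):
        ds, truth = planted_dataset
        cfg = ControlConfig(n_control_sets=100, seed=4)
        scores, _, _ = score_and_associate(ds, list(truth.program_genes), cfg)
        ns = scores.table["norm_score"]
        in_prog = ds.cell_type == "prog"
        from scipy.stats import ttest_ind

        t = ttest_ind(ns[in_prog.to_numpy()], ns[~in_prog.to_numpy()], alternative="greater")
        assert t.pvalue < 1e-6


class TestEmpiricalPZ:
    def test_observed_above_all_1000_nulls(self):
        nulls = np.linspace(-1, 1, 1000)
        p, z = empirical_p_and_z(2.0, nulls)
        assert p == pytest.approx(1.0 / 1001.0)
        assert z > 0

    def test_observed_below_all_nulls_gives_p_one(self):
        nulls = [1.0, 2.0, 3.0]
        p, _ = empirical_p_and_z(0.0, nulls)
        assert p == 1.0

    def test_degenerate_sd_flags_z(self):
        p, z = empirical_p_and_z(0.0, [0.0, 0.0, 0.0, 0.0])
        assert p == 1.0 and np.isnan(z)

    def test_toy_direct_count(self):
        p, _ = empirical_p_and_z(2.5, [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx((1 + 2) / 5)

    def test_z_matches_hand_formula(self):
        nulls = np.array([1.0, 2.0, 3.0, 4.0])
        _, z = empirical_p_and_z(5.0, nulls)
        assert z == pytest.approx((5.0 - 2.5) / nulls.std(ddof=1), abs=1e-12)

    @given(
        observed=st.floats(-5, 5),
        nulls=st.lists(st.floats(-5, 5), min_size=2, max_size=50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_granularity(self, observed, nulls):
        """Every empirical p lies on the (r+1)/(n+1) grid, minimum 1/(n+1)."""
        p, _ = empirical_p_and_z(observed, nulls)
        n = len(nulls)
        grid = {(r + 1) / (n + 1) for r in range(n + 1)}
        assert min(abs(p - g) for g in grid) < 1e-12
        assert 1 / (n + 1) <= p <= 1.0


class TestAssociation:
    def _scores_from_matrix(self, norm, control_norm, cell_ids):
        from screlmap.relevance import CellScoreTable

        table = pd.DataFrame(
            {
                "raw_score": norm,
                "norm_score": norm,
                "mc_p": np.ones(len(norm)),
                "sd_zero_flag": False,
            },
            index=pd.Index(cell_ids, name="cell"),
        )
        return CellScoreTable(table=table, control_raw=control_norm, control_norm=control_norm)

    def test_toy_association_direct_count(self):
        """K=4 nulls {1,2,3,4} per aggregate, observed 2.5 -> p=(1+2)/5."""
        # 2 cells in one type; control columns average to 1, 2, 3, 4
        norm = np.array([2.0, 3.0])
        control = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        scores = self._scores_from_matrix(norm, control, ["c0", "c1"])
        res = celltype_association(
            scores, pd.Series(["T", "T"], index=["c0", "c1"]), min_cells_per_type=1
        )
        assert res.table.loc["T", "empirical_p"] == pytest.approx(0.6)
        assert res.table.loc["T", "observed"] == pytest.approx(2.5)

    def test_toy_heterogeneity_direct_count(self):
        """Null within-type variances {0.5, 2, 4.5, 8}; observed 12.5 -> p=1/5."""
        norm = np.array([0.0, 5.0])  # var (ddof=1) = 12.5
        control = np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]])
        scores = self._scores_from_matrix(norm, control, ["c0", "c1"])
        res = celltype_association(
            scores, pd.Series(["T", "T"], index=["c0", "c1"]), min_cells_per_type=1
        )
        assert res.table.loc["T", "heterogeneity_statistic"] == pytest.approx(12.5)
        assert res.table.loc["T", "heterogeneity_p"] == pytest.approx(0.2)

    def test_constant_scores_give_heterogeneity_p_one(self):
        norm = np.array([1.0, 1.0, 1.0])
        control = np.random.default_rng(0).normal(size=(3, 6))
        scores = self._scores_from_matrix(norm, control, ["c0", "c1", "c2"])
        res = celltype_association(
            scores, pd.Series(["T"] * 3, index=["c0", "c1", "c2"]), min_cells_per_type=1
        )
        assert res.table.loc["T", "heterogeneity_statistic"] == 0.0
        assert res.table.loc["T", "heterogeneity_p"] == 1.0

    def test_relabeling_types_permutes_rows(self, planted_dataset):
        ds, truth = planted_dataset
        cfg = ControlConfig(n_control_sets=50, seed=5)
        scores, assoc, _ = score_and_associate(ds, list(truth.program_genes), cfg)
        relabeled = ds.cell_type.map({"prog": "zz", "other1": "aa", "other2": "mm"})
        assoc2 = celltype_association(scores, relabeled)
        for old, new in [("prog", "zz"), ("other1", "aa"), ("other2", "mm")]:
            pd.testing.assert_series_equal(
                assoc.table.loc[old], assoc2.table.loc[new], check_names=False
            )

    def test_mixed_type_detected_by_heterogeneity(self):
        """A 50/50 mix of strong-program and null cells is heterogeneous."""
        rng = np.random.default_rng(8)
        n, k = 120, 200
        control = rng.normal(size=(n, k))
        norm = rng.normal(size=n)
        norm[:30] += 4.0  # half of type 'mix' carries a strong program
        types = ["mix"] * 60 + ["homog"] * 60
        scores = self._scores_from_matrix(norm, control, [f"c{i}" for i in range(n)])
        res = celltype_association(scores, pd.Series(types, index=scores.table.index))
        assert res.table.loc["mix", "heterogeneity_p"] < 0.05
        assert res.table.loc["homog", "heterogeneity_p"] > 0.05
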