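import numpy as np
import pandas as pd
import pytest

from atlasfuse.atlas import VOI, region_voxels
from atlasfuse.errors import FilterError
from atlasfuse.queries import (
    QUERIES,
    cell_type_specificity,
    coverage_table,
    enrichment,
    gene_ranks,
    mean_expression,
    region_specificity,
    select_samples,
    write_query_tsv,
)
from conftest import make_random_dataset
from helpers import brute_query, brute_selection


def random_voi(rng, shape=(4, 4, 4), p=0.4):
    mask = rng.random(shape) < p
    return VOI.from_mask(mask), mask


class TestSelection:
    def test_parent_voi_selects_all_child_annotated_samples(
        self, small_ontology, small_parcellation, random_dataset
    ):
        # samples annotated at leaves; a VOI at their common parent selects all
        voi = region_voxels(small_parcellation, small_ontology, 1)
        sel = select_samples(random_dataset, voi, small_ontology, small_parcellation)
        assert len(sel.V) == random_dataset.n_samples

    def test_empty_voi_selects_nothing(self, small_ontology, small_parcellation, random_dataset):
        voi = VOI((4, 4, 4), np.empty(0, dtype=np.int64))
        sel = select_samples(random_dataset, voi, small_ontology, small_parcellation)
        assert len(sel) == 0

    def test_unknown_metadata_attribute_raises(self, small_ontology, small_parcellation, random_dataset):
        voi = region_voxels(small_parcellation, small_ontology, 1)
        with pytest.raises(FilterError):
            select_samples(random_dataset, voi, small_ontology, small_parcellation,
                           meta={"nonexistent": {"x"}})

    @pytest.mark.parametrize("seed", range(10))
    def test_random_filters_match_full_scan(self, seed, small_ontology, small_parcellation):
        rng = np.random.default_rng(seed)
        ds = make_random_dataset(rng)
        voi, mask = random_voi(rng)
        cts = {"exc"} if rng.random() < 0.5 else None
        meta = {"age": {"adult"}} if rng.random() < 0.5 else None
        sel = select_samples(ds, voi, small_ontology, small_parcellation, cts, meta)
        V, C, F = brute_selection(ds, mask, small_ontology, small_parcellation, cts, meta)
        assert list(sel.V) == V and list(sel.C) == C and list(sel.F) == F

    def test_enlarging_filters_never_shrinks_selection(self, small_ontology, small_parcellation):
        rng = np.random.default_rng(11)
        ds = make_random_dataset(rng)
        voi, _ = random_voi(rng)
        small = select_samples(ds, voi, small_ontology, small_parcellation, {"exc"})
        large = select_samples(ds, voi, small_ontology, small_parcellation, {"exc", "inh"})
        assert set(small.selected) <= set(large.selected)


class TestQueryFormulas:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("kind", sorted(QUERIES))
    def test_matches_brute_force_on_random_fixtures(self, seed, kind, small_ontology, small_parcellation):
        rng = np.random.default_rng(100 + seed)
        ds = make_random_dataset(rng)
        voi, mask = random_voi(rng)
        cts = {"inh"}
        meta = {"age": {"adult"}}
        sel = select_samples(ds, voi, small_ontology, small_parcellation, cts, meta)
        res = QUERIES[kind](ds, sel)
        V, C, F = brute_selection(ds, mask, small_ontology, small_parcellation, cts, meta)
        if not (set(V) & set(C) & set(F)):
            assert res.empty
            return
        expected = brute_query(ds, V, C, F, kind)
        for g in ds.genes:
            if np.isnan(expected[g]):
                assert np.isnan(res.scores[g])
            else:
                assert res.scores[g] == pytest.approx(expected[g], rel=1e-12)

    def test_mean_two_samples(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(0), n_per_group=1, cell_types=("t",),
                                 leaves=(4, 5), n_genes=2)
        ds.values.iloc[0] = [2.0, 4.0]
        voi = region_voxels(small_parcellation, small_ontology, 1)
        sel = select_samples(ds, voi, small_ontology, small_parcellation)
        assert mean_expression(ds, sel).scores.iloc[0] == 3.0

    def test_region_specificity_is_one_for_whole_brain_voi(self, small_ontology, small_parcellation, random_dataset):
        voi = region_voxels(small_parcellation, small_ontology, 1)
        sel = select_samples(random_dataset, voi, small_ontology, small_parcellation)
        scores = region_specificity(random_dataset, sel).scores
        assert np.allclose(scores, 1.0)

    def test_celltype_specificity_is_one_for_single_type_data(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(2), cell_types=("only",))
        voi = region_voxels(small_parcellation, small_ontology, 2)
        sel = select_samples(ds, voi, small_ontology, small_parcellation, {"only"})
        assert np.allclose(cell_type_specificity(ds, sel).scores, 1.0)

    def test_enrichment_is_one_without_filters(self, small_ontology, small_parcellation, random_dataset):
        voi = region_voxels(small_parcellation, small_ontology, 3)
        sel = select_samples(random_dataset, voi, small_ontology, small_parcellation)
        assert np.allclose(enrichment(random_dataset, sel).scores, 1.0)

    def test_planted_marker_hand_evaluation(self, small_ontology, small_parcellation):
        # two cell types, equal group sizes; marker expressed 8x in 'inh':
        # specificity = 8 * 2 / (8 + 1)
        ds = make_random_dataset(np.random.default_rng(3), n_genes=3)
        inh = ds.sample_meta["cell_type"] == "inh"
        ds.values.iloc[0] = np.where(inh, 8.0, 1.0)
        voi = region_voxels(small_parcellation, small_ontology, 1)
        sel = select_samples(ds, voi, small_ontology, small_parcellation, {"inh"})
        score = cell_type_specificity(ds, sel).scores.iloc[0]
        assert score == pytest.approx(8 * 2 / 9)

    def test_silent_gene_is_undefined_in_ratio(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(4), n_genes=2)
        ds.values.iloc[1] = 0.0
        voi = region_voxels(small_parcellation, small_ontology, 4)
        sel = select_samples(ds, voi, small_ontology, small_parcellation)
        res = region_specificity(ds, sel)
        assert np.isnan(res.scores.iloc[1])

    def test_scale_invariance_of_ratio_queries(self, small_ontology, small_parcellation):
        rng = np.random.default_rng(6)
        ds = make_random_dataset(rng)
        voi, _ = random_voi(rng)
        sel = select_samples(ds, voi, small_ontology, small_parcellation, {"exc"})
        before = {k: QUERIES[k](ds, sel).scores for k in ("region-specificity", "celltype-specificity", "enrichment")}
        ds2 = ds.with_norm(ds.values.mul(
            pd.Series(rng.uniform(0.5, 20.0, ds.n_genes), index=ds.genes), axis=0), ds.norm)
        sel2 = select_samples(ds2, voi, small_ontology, small_parcellation, {"exc"})
        for k, s in before.items():
            after = QUERIES[k](ds2, sel2).scores
            assert np.allclose(s.dropna(), after.dropna())


class TestHierarchicalInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_subregion_voi_equals_annotation_level_voi(self, seed, small_ontology, small_parcellation):
        """A VOI strictly inside an annotated region selects the same samples
        and yields identical scores as the full region VOI."""
        rng = np.random.default_rng(200 + seed)
        ds = make_random_dataset(rng)
        full = region_voxels(small_parcellation, small_ontology, 4)
        sub_lin = rng.choice(full.linear, size=max(1, len(full) // 4), replace=False)
        sub = VOI((4, 4, 4), sub_lin)
        for kind in QUERIES:
            sel_full = select_samples(ds, full, small_ontology, small_parcellation, {"inh"})
            sel_sub = select_samples(ds, sub, small_ontology, small_parcellation, {"inh"})
            assert list(sel_full.selected) == list(sel_sub.selected)
            a = QUERIES[kind](ds, sel_full).scores
            b = QUERIES[kind](ds, sel_sub).scores
            assert a.equals(b)


class TestRanks:
    def test_simple_descending_ranks(self):
        from atlasfuse.queries import QueryResult

        res = QueryResult(scores=pd.Series([5.0, 2.0, 9.0], index=list("abc")))
        assert gene_ranks(res).ranks.tolist() == [2.0, 3.0, 1.0]

    def test_ties_get_average_rank(self):
        from atlasfuse.queries import QueryResult

        res = QueryResult(scores=pd.Series([4.0, 4.0], index=list("ab")))
        assert gene_ranks(res).ranks.tolist() == [1.5, 1.5]

    def test_undefined_scores_unranked_and_random_matches_sort_oracle(self):
        from atlasfuse.queries import QueryResult

        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        s = pd.Series(scores, index=[f"g{i}" for i in range(30)])
        s.iloc[5] = np.nan
        ranked = gene_ranks(QueryResult(scores=s))
        assert np.isnan(ranked.ranks.iloc[5])
        defined = s.dropna()
        order = defined.sort_values(ascending=False)
        for pos, gene in enumerate(order.index, start=1):
            assert ranked.ranks[gene] == pos  # distinct floats: no ties


class TestCoverage:
    def test_counts_match_planted_layout_and_zero_cells(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(0), leaves=(4, 5), n_per_group=3)
        table = coverage_table([ds], small_ontology, small_parcellation, [4, 5, 6], ["cell_type"])
        assert table.loc[("fixture", "exc"), 4] == 3
        assert table.loc[("fixture", "inh"), 5] == 3
        assert (table[6] == 0).all()

    def test_parent_column_equals_sum_over_disjoint_children(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(1))
        table = coverage_table([ds], small_ontology, small_parcellation, [2, 4, 5])
        assert (table[2] == table[4] + table[5]).all()

    def test_annotation_provenance_recorded(self, small_ontology, small_parcellation):
        ds = make_random_dataset(np.random.default_rng(2), leaves=(4,))
        table = coverage_table([ds], small_ontology, small_parcellation, [2])
        ann = table.attrs["sample_region_annotations"]
        assert ann[(("fixture",), 2)] == [4]


def test_query_tsv_export(tmp_path, small_ontology, small_parcellation, random_dataset):
    voi = region_voxels(small_parcellation, small_ontology, 2)
    sel = select_samples(random_dataset, voi, small_ontology, small_parcellation)
    res = gene_ranks(mean_expression(random_dataset, sel))
    out = tmp_path / "q.tsv"
    write_query_tsv(res, out)
    lines = out.read_text().splitlines()
    header = [l for l in lines if l.startswith("#")]
    body = [l for l in lines if not l.startswith("#")]
    assert any("query" in h for h in header)
    assert body[0] == "gene_id\tscore\trank"
    assert len(body) == 1 + random_dataset.n_genes
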