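"""Operator semantics: worked examples, conservation laws, oracle agreement."""

from __future__ import annotations

import pytest

import _oracles as oracle
from conftest import random_dataset
from genometric import (
    ANY,
    AggregateSpec,
    ArgumentError,
    GDMDataset,
    GenometricClause,
    MetadataSet,
    Region,
    Sample,
    Schema,
    op_cover,
    op_difference,
    op_extend,
    op_filter,
    op_group,
    op_join,
    op_map,
    op_merge,
    op_order,
    op_project,
    op_union,
    parse_genometric_clause,
    parse_predicate,
    parse_scalar_expr,
)


def _dataset(schema_attrs, sample_defs, name="d"):
    schema = Schema(tuple(schema_attrs))
    samples = [
        Sample(sid, [Region(*r) for r in regions], MetadataSet(meta))
        for sid, regions, meta in sample_defs
    ]
    return GDMDataset(schema, samples, name=name)


class TestFilter:
    def test_meta_predicate_selects_samples(self, tiny_dataset):
        out = op_filter(tiny_dataset, meta_predicate=parse_predicate("age < 65"))
        assert [s.id for s in out.samples] == ["S_00001"]

    def test_region_predicate_keeps_matching_regions_and_empty_samples(self):
        d = _dataset(
            [("count_mut", "integer")],
            [
                ("a", [("chr1", 0, 10, "*", (0,)), ("chr1", 20, 30, "*", (1,)), ("chr1", 40, 50, "*", (2,))], []),
                ("b", [("chr1", 0, 10, "*", (0,))], []),
            ],
        )
        out = op_filter(d, region_predicate=parse_predicate("count_mut >= 1"))
        assert [s.n_regions for s in out.samples] == [2, 0]
        assert len(out) == 2  # emptied sample retained

    def test_semijoin_not_in_self_excludes_all(self, tiny_dataset):
        out = op_filter(tiny_dataset, semijoin=(["cell"], tiny_dataset, "NOT_IN"))
        assert len(out) == 0

    def test_semijoin_in(self, tiny_dataset):
        other = _dataset([], [("x", [], [("cell", "K562")])])
        out = op_filter(tiny_dataset, semijoin=(["cell"], other, "IN"))
        assert [s.id for s in out.samples] == ["S_00002"]

    def test_semijoin_empty_keys_rejected(self, tiny_dataset):
        with pytest.raises(ArgumentError):
            op_filter(tiny_dataset, semijoin=([], tiny_dataset, "IN"))


class TestProject:
    def test_region_length_update(self):
        d = _dataset([], [("a", [("chr1", 100, 200, "+", ())], [])])
        out = op_project(d, regions_update=[("length", parse_scalar_expr("right - left"))])
        assert out.schema.attributes == (("length", "integer"),)
        assert out.samples[0].regions[0].values == (100,)

    def test_drop_all_metadata_and_attributes(self, tiny_dataset):
        out = op_project(tiny_dataset, keep_region_attrs=[], keep_meta_keys=[])
        assert len(out.schema) == 0
        assert all(len(s.metadata) == 0 for s in out.samples)
        assert out.n_regions == tiny_dataset.n_regions

    def test_update_overwrites_in_place(self, tiny_dataset):
        out = op_project(
            tiny_dataset, regions_update=[("score", parse_scalar_expr("score * 2"))]
        )
        assert out.schema.names == tiny_dataset.schema.names
        pairs = zip(
            [r for s in tiny_dataset.samples for r in s.regions],
            [r for s in out.samples for r in s.regions],
        )
        for before, after in pairs:
            expected = None if before.values[0] is None else before.values[0] * 2
            assert after.values[0] == expected

    def test_reserved_name_update_rejected(self, tiny_dataset):
        from genometric import SchemaError

        with pytest.raises(SchemaError):
            op_project(tiny_dataset, regions_update=[("left", parse_scalar_expr("left"))])


class TestExtend:
    def test_count_becomes_metadata(self):
        d = _dataset([], [("a", [("chr1", 0, 1), ("chr1", 5, 9)], []), ("b", [], [])])
        out = op_extend(d, [AggregateSpec("COUNT", "geneMut_count")])
        assert out.samples[0].metadata.values("geneMut_count") == ["2"]
        assert out.samples[1].metadata.values("geneMut_count") == ["0"]

    def test_sum_formatting_and_empty_aggregate_absent(self):
        d = _dataset(
            [("length", "integer")],
            [("a", [("chr1", 0, 1, "*", (10,)), ("chr1", 5, 9, "*", (20,))], []), ("b", [], [])],
        )
        out = op_extend(d, [AggregateSpec("SUM", "sum_len", "length"),
                            AggregateSpec("MIN", "min_len", "length")])
        assert out.samples[0].metadata.values("sum_len") == ["30"]
        assert "min_len" not in out.samples[1].metadata


class TestOrder:
    def _aged(self):
        return _dataset(
            [],
            [
                ("a", [], [("age", "3")]),
                ("b", [], [("age", "1")]),
                ("c", [], [("age", "2")]),
            ],
        )

    def test_meta_sort_and_mtop(self):
        out = op_order(self._aged(), meta_keys=[("age", "asc")], mtop=2)
        assert [s.metadata.values("age")[0] for s in out.samples] == ["1", "2"]

    def test_rtop_keeps_shortest_region(self):
        d = _dataset(
            [],
            [("a", [("chr1", 0, 100), ("chr1", 50, 60), ("chr2", 0, 5)], [])],
        )
        out = op_order(d, region_keys=[("right", "asc")], rtop=1)
        # sorting regions by an expression over coordinates then keeping one
        region = out.samples[0].regions[0]
        assert (region.chrom, region.left, region.right) == ("chr2", 0, 5)

    def test_stability_on_ties(self):
        d = _dataset([], [("b", [], [("k", "1")]), ("a", [], [("k", "1")])])
        out = op_order(d, meta_keys=[("k", "asc")])
        assert [s.id for s in out.samples] == ["a", "b"]

    def test_numeric_sort_when_all_numeric(self):
        d = _dataset([], [("a", [], [("v", "10")]), ("b", [], [("v", "9")])])
        out = op_order(d, meta_keys=[("v", "asc")])
        assert [s.id for s in out.samples] == ["b", "a"]

    def test_invalid_k_rejected(self, tiny_dataset):
        with pytest.raises(ArgumentError):
            op_order(tiny_dataset, mtop=0)


class TestGroup:
    def test_grouping_by_shared_values(self):
        d = _dataset(
            [],
            [
                ("a", [], [("tumor", "A")]),
                ("b", [], [("tumor", "A")]),
                ("c", [], [("tumor", "B")]),
            ],
        )
        out = op_group(d, ["tumor"])
        groups = [s.metadata.values("_group")[0] for s in out.samples]
        assert groups == ["1", "1", "2"]

    def test_missing_key_forms_own_group(self):
        d = _dataset([], [("a", [], [("k", "x")]), ("b", [], [])])
        out = op_group(d, ["k"])
        groups = {s.id: s.metadata.values("_group")[0] for s in out.samples}
        assert groups["a"] != groups["b"]

    def test_all_distinct_gives_one_group_each(self):
        d = _dataset([], [(f"s{i}", [], [("k", str(i))]) for i in range(4)])
        out = op_group(d, ["k"])
        assert len({s.metadata.values("_group")[0] for s in out.samples}) == 4


class TestMergeUnionDifference:
    def test_merge_conserves_regions_and_unions_metadata(self):
        d = _dataset(
            [],
            [
                ("a", [("chr1", 0, 1)] * 1 + [("chr1", 2, 3)], [("k", "a")]),
                ("b", [("chr1", 4, 5)] * 1 + [("chr2", 0, 1), ("chr2", 2, 3)], [("k", "b")]),
                ("c", [("chr3", 0, 9)] * 1 + [("chr3", 1, 2)] * 1 + [("chr3", 5, 6), ("chr3", 7, 8)], []),
            ],
        )
        out = op_merge(d)
        assert len(out) == 1
        assert out.samples[0].n_regions == 2 + 3 + 4
        assert out.samples[0].metadata.values("k") == ["a", "b"]

    def test_merge_groupby_single_shared_value(self):
        d = _dataset(
            [],
            [
                ("a", [("chr1", 0, 1)], [("biosample_term_name", "H1-hESC")]),
                ("b", [("chr1", 5, 6)], [("biosample_term_name", "H1-hESC")]),
            ],
        )
        out = op_merge(d, groupby=["biosample_term_name"])
        assert len(out) == 1

    def test_union_counts_and_schema_coercion(self):
        a = _dataset([("x", "integer")], [("a1", [("chr1", 0, 1, "*", (1,))], []),
                                          ("a2", [], [])], name="a")
        b = _dataset([("y", "float")], [("b1", [("chr1", 5, 6, "*", (2.0,))], []),
                                        ("b2", [], []), ("b3", [], [])], name="b")
        out = op_union(a, b)
        assert len(out) == 5
        assert out.schema == a.schema
        b_regions = out.sample("right_b1").regions
        assert b_regions[0].values == (None,)  # y dropped, x missing

    def test_difference_removes_overlaps(self):
        a = _dataset([], [("a", [("chr1", 100, 200)], [("k", "v")])])
        b = _dataset([], [("b", [("chr1", 150, 160)], [])])
        out = op_difference(a, b)
        assert out.samples[0].n_regions == 0
        assert out.samples[0].metadata.values("k") == ["v"]

    def test_difference_with_empty_b_is_identity(self, tiny_dataset):
        empty = GDMDataset(Schema(), [])
        out = op_difference(tiny_dataset, empty)
        assert out == tiny_dataset

    def test_difference_respects_strand(self):
        a = _dataset([], [("a", [("chr1", 100, 200, "+", ())], [])])
        b = _dataset([], [("b", [("chr1", 100, 200, "-", ())], [])])
        assert op_difference(a, b).samples[0].n_regions == 1


class TestMap:
    def test_overlap_count_oracle_example(self):
        ref = _dataset([], [("r", [("chr1", 100, 200)], [])], name="genes")
        exp = _dataset([], [("e", [("chr1", 150, 160), ("chr1", 190, 250)], [])], name="muts")
        out = op_map(ref, exp)
        assert out.schema.names == ("count_genes_muts",)
        assert out.samples[0].regions[0].values == (2,)

    def test_empty_experiment_gives_zero_counts(self):
        ref = _dataset([], [("r", [("chr1", 0, 10), ("chr2", 0, 10)], [])])
        exp = _dataset([], [("e", [], [])])
        out = op_map(ref, exp)
        assert [r.values[0] for r in out.samples[0].regions] == [0, 0]

    def test_all_pairs_when_no_joinby(self):
        ref = _dataset([], [(f"r{i}", [], []) for i in range(2)])
        exp = _dataset([], [(f"e{i}", [], []) for i in range(3)])
        assert len(op_map(ref, exp)) == 6

    def test_joinby_restricts_pairs(self):
        ref = _dataset([], [("r1", [], [("cell", "A")]), ("r2", [], [("cell", "B")])])
        exp = _dataset([], [("e1", [], [("cell", "A")]), ("e2", [], [("cell", "C")])])
        assert len(op_map(ref, exp, joinby=["cell"])) == 1

    def test_metadata_prefixes(self):
        ref = _dataset([], [("r", [], [("k", "a")])])
        exp = _dataset([], [("e", [], [("k", "b")])])
        out = op_map(ref, exp)
        meta = out.samples[0].metadata
        assert meta.values("left.k") == ["a"]
        assert meta.values("right.k") == ["b"]


class TestJoin:
    def test_md1_picks_nearest(self):
        anchor = _dataset([], [("a", [("chr1", 100, 200)], [])])
        exp = _dataset([], [("e", [("chr1", 250, 300), ("chr1", 500, 600)], [])])
        out = op_join(anchor, exp, [GenometricClause("MD", k=1)], output="RIGHT")
        region = out.samples[0].regions[0]
        assert (region.left, region.right) == (250, 300)

    def test_dle_zero_matches_adjacent(self):
        anchor = _dataset([], [("a", [("chr1", 100, 200)], [])])
        exp = _dataset([], [("e", [("chr1", 200, 300)], [])])
        out = op_join(anchor, exp, [parse_genometric_clause("DLE(0)")])
        assert out.samples[0].n_regions == 1

    def test_both_mode_carries_candidate_coords(self):
        anchor = _dataset([], [("a", [("chr1", 100, 200)], [])])
        exp = _dataset([], [("e", [("chr1", 250, 300)], [])])
        out = op_join(anchor, exp, [GenometricClause("MD", k=1)], output="BOTH")
        region = out.samples[0].regions[0]
        assert (region.left, region.right) == (100, 200)
        schema = out.schema
        assert region.value("right.left", schema) == 250
        assert region.value("right.right", schema) == 300

    def test_int_mode_drops_non_overlapping_pairs(self):
        anchor = _dataset([], [("a", [("chr1", 100, 200)], [])])
        exp = _dataset([], [("e", [("chr1", 150, 300), ("chr1", 400, 500)], [])])
        out = op_join(anchor, exp, [parse_genometric_clause("DLE(1000)")], output="INT")
        assert [(r.left, r.right) for r in out.samples[0].regions] == [(150, 200)]

    def test_upstream_clause_is_strand_aware(self):
        exp = _dataset([], [("e", [("chr1", 0, 50), ("chr1", 300, 350)], [])])
        plus = _dataset([], [("a", [("chr1", 100, 200, "+", ())], [])])
        minus = _dataset([], [("a", [("chr1", 100, 200, "-", ())], [])])
        up_plus = op_join(plus, exp, [GenometricClause("UP")], output="RIGHT")
        up_minus = op_join(minus, exp, [GenometricClause("UP")], output="RIGHT")
        assert [(r.left, r.right) for r in up_plus.samples[0].regions] == [(0, 50)]
        assert [(r.left, r.right) for r in up_minus.samples[0].regions] == [(300, 350)]

    def test_predicate_validation(self):
        anchor = _dataset([], [("a", [], [])])
        with pytest.raises(ArgumentError):
            op_join(anchor, anchor, [])
        with pytest.raises(ArgumentError):
            op_join(anchor, anchor, [GenometricClause("MD", k=1)] * 2)


class TestCover:
    def test_three_region_accumulation_example(self):
        d = _dataset(
            [],
            [("a", [("chr1", 100, 200), ("chr1", 150, 250), ("chr1", 180, 300)], [])],
        )
        out = op_cover(d, 2, ANY)
        regions = out.samples[0].regions
        assert [(r.left, r.right) for r in regions] == [(150, 250)]
        assert regions[0].value("AccIndex", out.schema) == 3

    def test_cover_1_any_on_disjoint_regions_is_identity_on_coords(self):
        d = _dataset([], [("a", [("chr1", 0, 10), ("chr1", 20, 30)], [])])
        out = op_cover(d, 1, ANY)
        assert [(r.left, r.right) for r in out.samples[0].regions] == [(0, 10), (20, 30)]
        assert all(r.value("AccIndex", out.schema) == 1 for r in out.samples[0].regions)

    def test_groupby_experiment_target(self):
        d = _dataset(
            [],
            [
                ("a", [("chr1", 0, 10)], [("experiment_target", "CTCF")]),
                ("b", [("chr1", 5, 15)], [("experiment_target", "CTCF")]),
                ("c", [("chr1", 100, 110)], [("experiment_target", "POLR2A")]),
            ],
        )
        out = op_cover(d, 1, ANY, groupby=["experiment_target"])
        assert len(out) == 2

    def test_invalid_bounds_rejected(self, tiny_dataset):
        with pytest.raises(ArgumentError):
            op_cover(tiny_dataset, 3, 2)

    def test_aggregates_over_contributing_regions(self):
        d = _dataset(
            [("score", "integer")],
            [("a", [("chr1", 0, 10, "*", (1,)), ("chr1", 5, 15, "*", (3,)),
                    ("chr1", 100, 110, "*", (10,))], [])],
        )
        out = op_cover(d, 1, ANY, aggregates=[AggregateSpec("SUM", "s", "score")])
        values = {(r.left, r.right): r.value("s", out.schema) for r in out.samples[0].regions}
        assert values == {(0, 15): 4, (100, 110): 10}


class TestRandomizedOracles:
    """Brute-force agreement on small random datasets (the acceptance suite
    runs the deeper 50-seed sweep over every operator)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_difference_matches_double_loop(self, seed):
        ref = random_dataset(seed * 2 + 100)
        exp = random_dataset(seed * 2 + 101)
        out = op_difference(ref, exp)
        b_regions = [r for s in exp.samples for r in s.regions]
        for sample, orig in zip(out.samples, ref.samples):
            expected = oracle.difference_regions(orig.regions, b_regions)
            assert [r.sort_key[:4] for r in sample.regions] == [
                r.sort_key[:4] for r in expected
            ]

    @pytest.mark.parametrize("seed", range(5))
    def test_map_counts_match_double_loop(self, seed):
        ref = random_dataset(seed * 2 + 200, n_samples=1)
        exp = random_dataset(seed * 2 + 201, n_samples=1)
        out = op_map(ref, exp)
        count_idx = out.schema.index(f"count_{ref.name}_{exp.name}")
        got = [r.values[count_idx] for r in out.samples[0].regions]
        assert got == oracle.map_counts(ref.samples[0].regions, exp.samples[0].regions)

    @pytest.mark.parametrize("seed", range(5))
    def test_cover_runs_match_per_base_counting(self, seed):
        d = random_dataset(seed + 300, n_samples=2)
        unstranded = _star_stranded(d)
        out = op_cover(unstranded, 2, 3)
        got = [
            (r.chrom, r.left, r.right, r.value("AccIndex", out.schema))
            for s in out.samples
            for r in s.regions
        ]
        regions = [r for s in unstranded.samples for r in s.regions]
        assert sorted(got) == sorted(oracle.cover_runs(regions, 2, 3))


def _star_stranded(dataset: GDMDataset) -> GDMDataset:
    """Copy with every strand forced to '*' (per-base oracles are unstranded)."""
    samples = [
        Sample(
            s.id,
            [Region(r.chrom, r.left, r.right, "*", r.values) for r in s.regions],
            s.metadata.copy(),
        )
        for s in dataset.samples
    ]
    return GDMDataset(dataset.schema, samples, name=dataset.name)
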