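import itertools
from math import comb

import numpy as np
import pytest

from grndiff.differential import DifferentialSubnetwork
from grndiff.enrichment import (
    EnrichmentError,
    GeneSetCollection,
    ora,
    read_gmt,
    run_enrichment,
    significant,
)


def _collection(**sets):
    return GeneSetCollection(
        {name: (name, frozenset(members)) for name, members in sets.items()}
    )


class TestReadGmt:
    def test_single_line(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\n")
        col = read_gmt(path)
        assert len(col) == 1
        assert col.members("setA") == {"g1", "g2", "g3"}

    def test_duplicate_member_counted_once(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("setA\tdesc\tg1\tg1\tg2\n")
        assert len(read_gmt(path).members("setA")) == 2

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("setA\tdesc\tg1\nsetB\tdesc\n")
        with pytest.raises(EnrichmentError, match=":2:"):
            read_gmt(path)

    def test_sizes_match_field_counting_oracle(self, tmp_path, rng):
        lines = []
        expected = {}
        for i in range(20):
            members = [f"g{rng.integers(200)}" for _ in range(int(rng.integers(3, 15)))]
            lines.append(f"s{i}\td{i}\t" + "\t".join(members))
            expected[f"s{i}"] = len(set(members))
        path = tmp_path / "many.gmt"
        path.write_text("\n".join(lines) + "\n")
        col = read_gmt(path)
        assert {name: len(col.members(name)) for name in expected} == expected


class TestOra:
    def test_query_equals_set_equals_background(self):
        col = _collection(s={"a", "b", "c"})
        (res,) = ora({"a", "b", "c"}, col, {"a", "b", "c"})
        assert res.overlap == 3
        assert res.p == pytest.approx(1.0)

    def test_full_overlap_exact_probability(self):
        # drawing all 5 set members in a query of 5 from 20: 1 / C(20,5)
        background = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        col = _collection(s=members)
        (res,) = ora(members, col, background)
        assert res.p == pytest.approx(1 / comb(20, 5))

    def test_zero_overlap_cross_checked_by_pmf_summation(self):
        background = {f"g{i}" for i in range(10)}
        col = _collection(s={"g0", "g1", "g2"})
        query = {"g7", "g8", "g9"}
        (res,) = ora(query, col, background)
        # oracle: sum the full hypergeometric pmf over k >= 0
        M, K, n = 10, 3, 3
        total = sum(
            comb(K, k) * comb(M - K, n - k) / comb(M, n)
            for k in range(0, min(K, n) + 1)
        )
        assert res.p == pytest.approx(total) == pytest.approx(1.0)

    def test_monotone_decreasing_in_overlap(self):
        background = {f"g{i}" for i in range(30)}
        col = _collection(s={f"g{i}" for i in range(8)})
        ps = []
        for k in range(1, 6):
            query = {f"g{i}" for i in range(k)} | {f"g{20 + i}" for i in range(5 - k)}
            (res,) = ora(query, col, background)
            ps.append(res.p)
        assert ps == sorted(ps, reverse=True)

    def test_matches_exhaustive_enumeration_oracle(self):
        # brute force over every possible query of size n from a small
        # background: P(overlap >= observed)
        background = sorted(f"g{i}" for i in range(11))
        members = {"g0", "g1", "g2", "g3"}
        col = _collection(s=members)
        for query in ({"g0", "g1", "g5"}, {"g4", "g5", "g6"}, {"g0", "g1", "g2"}):
            (res,) = ora(query, col, set(background))
            observed = len(query & members)
            n = len(query)
            hits = total = 0
            for draw in itertools.combinations(background, n):
                total += 1
                hits += len(set(draw) & members) >= observed
            assert res.p == pytest.approx(hits / total)

    def test_bh_preserves_order_and_bounds(self, rng):
        background = {f"g{i}" for i in range(50)}
        col = _collection(
            **{f"s{i}": set(rng.choice(sorted(background), size=8, replace=False))
               for i in range(6)}
        )
        query = set(rng.choice(sorted(background), size=10, replace=False))
        results = ora(query, col, background)
        raws = [r.p for r in results]
        adjs = [r.p_adj for r in results]
        assert all(a >= p for p, a in zip(raws, adjs))
        assert all(a <= 1.0 for a in adjs)
        # results sorted by raw p; adjusted follows the same ordering
        assert raws == sorted(raws)
        assert adjs == sorted(adjs)

    def test_query_outside_background_errors(self):
        with pytest.raises(EnrichmentError):
            ora({"zz"}, _collection(s={"a"}), {"a", "b"})

    def test_empty_inputs_error(self):
        with pytest.raises(EnrichmentError):
            ora(set(), _collection(s={"a"}), {"a"})
        with pytest.raises(EnrichmentError):
            ora({"a"}, _collection(s={"a"}), set())


class TestRunEnrichment:
    def _subnets(self):
        sub_g = DifferentialSubnetwork(
            "GR", (("tf1", "g1", 1.0), ("tf1", "g2", 1.1), ("tf1", "g3", 0.9))
        )
        sub_p = DifferentialSubnetwork("PR", ())
        return sub_g, sub_p

    def test_tf_without_genes_is_skipped(self):
        sub_g, sub_p = self._subnets()
        background = {"tf1", "tf2", "g1", "g2", "g3", "g4"}
        col = _collection(s={"g1", "g2"})
        tables = run_enrichment(sub_g, sub_p, col, background, tfs=["tf1", "tf2"])
        assert ("GR", "tf1") in tables
        assert ("GR", "tf2") not in tables      # no connected genes
        assert all(group == "GR" for group, _ in tables)  # PR subnetwork empty

    def test_planted_pathway_ranks_first(self, rng):
        sub_g, sub_p = self._subnets()
        background = {f"g{i}" for i in range(40)} | {"tf1"}
        planted = {"g1", "g2", "g3", "tf1"}
        col = _collection(
            planted=planted,
            decoy1=set(rng.choice(sorted(background - planted), 6, replace=False)),
            decoy2=set(rng.choice(sorted(background - planted), 6, replace=False)),
        )
        tables = run_enrichment(sub_g, sub_p, col, background)
        results = tables[("GR", "tf1")]
        assert results[0].set_name == "planted"
        assert results[0].p < min(r.p for r in results[1:])

    def test_bh_scoped_within_each_query(self):
        # two disjoint queries must each be adjusted over their own batch
        sub_g = DifferentialSubnetwork("GR", (("tf1", "g1", 1.0),))
        sub_p = DifferentialSubnetwork("PR", (("tf2", "g9", -1.0),))
        background = {f"g{i}" for i in range(12)} | {"tf1", "tf2"}
        col = _collection(a={"g1", "g2"}, b={"g9", "g8"}, c={"g5", "g6"})
        tables = run_enrichment(sub_g, sub_p, col, background)
        for key, results in tables.items():
            solo = ora(
                {"tf1", "g1"} if key[1] == "tf1" else {"tf2", "g9"}, col, background
            )
            assert [(r.set_name, r.p_adj) for r in results] == [
                (r.set_name, r.p_adj) for r in solo
            ]

    def test_significant_filters_on_adjusted_p(self):
        sub_g, sub_p = self._subnets()
        background = {f"g{i}" for i in range(500)} | {"tf1"}
        col = _collection(hit={"g1", "g2", "g3"}, miss={"g400", "g401"})
        tables = run_enrichment(sub_g, sub_p, col, background)
        frame = significant(tables, alpha=0.001)
        assert list(frame["set_name"]) == ["hit"]
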