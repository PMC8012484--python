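import math

import numpy as np
import pytest

from grndiff.differential import (
    DifferentialError,
    EesTable,
    UndefinedScoreError,
    differential_edges,
    edge_enrichment_score,
    ees_table,
    export_subnetwork,
    read_subnetwork,
    select_top_tfs,
)
from grndiff.resample import AggregateNetwork

from conftest import TABLE2_COUNTS, TABLE2_EES


def _agg(mean_z, tfs=("t1", "t2", "t3"), genes=("g1", "g2", "g3", "g4"), thr=0.0):
    return AggregateNetwork(tfs, genes, np.asarray(mean_z, dtype=float), hc_threshold=thr)


class TestEdgeEnrichmentScore:
    @pytest.mark.parametrize("tf", sorted(TABLE2_COUNTS))
    def test_printed_scores_reproduced(self, tf):
        k_g, k_p = TABLE2_COUNTS[tf]
        score = edge_enrichment_score(k_g, k_p, 1000, 1000)
        assert round(score, 3) == TABLE2_EES[tf]

    def test_equal_ratios_score_zero(self):
        assert edge_enrichment_score(30, 10, 300, 100) == pytest.approx(0.0)

    def test_group_swap_negates(self):
        a = edge_enrichment_score(582, 185, 900, 750)
        b = edge_enrichment_score(185, 582, 750, 900)
        assert a == pytest.approx(-b)

    @pytest.mark.parametrize("counts", [(0, 5, 10, 10), (5, 0, 10, 10), (5, 5, 0, 10)])
    def test_zero_count_is_undefined(self, counts):
        with pytest.raises(UndefinedScoreError):
            edge_enrichment_score(*counts)


class TestEesTable:
    def test_toy_aggregates_match_brute_force(self):
        zg = [[1.0, 2.0, -1.0, 0.5], [-0.5, -0.2, 0.3, -0.3], [0.2, 0.1, 0.4, -2.0]]
        zp = [[0.5, -1.0, 0.3, 0.1], [0.7, 0.2, -0.4, 0.6], [-0.1, -0.2, -0.3, -0.4]]
        agg_g, agg_p = _agg(zg), _agg(zp)
        table = ees_table(agg_g, agg_p)
        # brute force: loop over the masks
        for rec in table.records + table.undefined:
            i = agg_g.tf_ids.index(rec.tf)
            k_g = sum(1 for v in zg[i] if v > 0)
            k_p = sum(1 for v in zp[i] if v > 0)
            assert (rec.k_g, rec.k_p, rec.n_diff) == (k_g, k_p, k_g - k_p)
            if rec.defined:
                expected = math.log2((k_g / k_p) / (agg_g.n_edges / agg_p.n_edges))
                assert rec.ees == pytest.approx(expected)
        # t3 has k_p = 0 in zp -> undefined, reported separately
        assert [r.tf for r in table.undefined] == ["t3"]

    def test_identical_aggregates_score_zero(self, rng):
        z = rng.normal(size=(3, 4))
        table = ees_table(_agg(z), _agg(z))
        assert all(r.ees == pytest.approx(0.0) for r in table.records)
        assert all(r.n_diff == 0 for r in table.records)

    def test_sorted_descending_with_symbol_tiebreak(self):
        table = EesTable.from_counts(
            {"b": (20, 10), "a": (20, 10), "c": (5, 40)}, 100, 100
        )
        assert [r.tf for r in table.records] == ["a", "b", "c"]

    def test_printed_table_counts_replayed(self):
        table = EesTable.from_counts(TABLE2_COUNTS, 1000, 1000)
        frame = table.to_frame().set_index("tf")
        for tf, (k_g, k_p) in TABLE2_COUNTS.items():
            assert frame.loc[tf, "n_diff"] == k_g - k_p
            assert round(frame.loc[tf, "log2_ees"], 3) == TABLE2_EES[tf]
        # spot-check the printed n_diff arithmetic
        assert frame.loc["MXD1", "n_diff"] == 397
        assert frame.loc["CREM", "n_diff"] == 538
        assert frame.loc["HOXA1", "n_diff"] == -539

    def test_label_mismatch_errors(self, rng):
        z = rng.normal(size=(3, 4))
        with pytest.raises(DifferentialError):
            ees_table(_agg(z), _agg(z, tfs=("t1", "t2", "tX")))


class TestSelectTopTfs:
    def test_printed_table_selection(self):
        table = EesTable.from_counts(TABLE2_COUNTS, 1000, 1000)
        top = select_top_tfs(table, 5, 5)
        assert set(top[:5]) == {"MXD1", "NFYB", "E2F6", "CREM", "RFX2"}
        assert set(top[5:]) == {"ID3", "HOXA1", "JUNB", "PROX1", "SMAD7"}

    def test_exhaustive_when_table_size_matches(self):
        table = EesTable.from_counts(
            {f"tf{i}": (10 + i, 10) for i in range(10)}, 100, 100
        )
        assert set(select_top_tfs(table, 5, 5)) == {f"tf{i}" for i in range(10)}

    def test_agrees_with_sort_and_slice_oracle(self, rng):
        counts = {f"tf{i:02d}": (int(rng.integers(1, 500)), int(rng.integers(1, 500)))
                  for i in range(30)}
        table = EesTable.from_counts(counts, 777, 888)
        top = select_top_tfs(table, 5, 5)
        scored = sorted(
            ((math.log2((kg / kp) / (777 / 888)), tf) for tf, (kg, kp) in counts.items()),
            key=lambda t: (-t[0], t[1]),
        )
        assert top[:5] == [tf for _, tf in scored[:5]]
        assert set(top[5:]) == {tf for _, tf in scored[-5:]}

    def test_insufficient_records_error(self):
        table = EesTable.from_counts({"a": (1, 1), "b": (2, 1)}, 10, 10)
        with pytest.raises(DifferentialError):
            select_top_tfs(table, 5, 5)


class TestDifferentialEdges:
    def test_no_differences_gives_empty_subnetworks(self, rng):
        z = rng.normal(size=(3, 4))
        sub_g, sub_p = differential_edges(_agg(z), _agg(z), ["t1", "t2"])
        assert sub_g.edges == () and sub_p.edges == ()

    def test_single_forced_edge(self):
        zg = [[0.9, -0.5, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        zp = [[0.1, -0.5, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        sub_g, sub_p = differential_edges(
            _agg(zg, tfs=("t1", "t2")), _agg(zp, tfs=("t1", "t2")), ["t1", "t2"]
        )
        assert [(t, g) for t, g, _ in sub_g.edges] == [("t1", "g1")]
        assert sub_g.edges[0][2] == pytest.approx(0.8)
        assert sub_p.edges == ()

    def test_matches_per_edge_conditional_oracle(self, rng):
        zg = rng.normal(size=(3, 4))
        zp = rng.normal(size=(3, 4))
        agg_g, agg_p = _agg(zg), _agg(zp)
        tfs = ["t1", "t2", "t3"]
        sub_g, sub_p = differential_edges(agg_g, agg_p, tfs, delta=0.75)
        got_g = {(t, g) for t, g, _ in sub_g.edges}
        got_p = {(t, g) for t, g, _ in sub_p.edges}
        for i, tf in enumerate(agg_g.tf_ids):
            for j, gene in enumerate(agg_g.gene_ids):
                d = zg[i, j] - zp[i, j]
                assert ((tf, gene) in got_g) == (d > 0.75 and zg[i, j] > 0)
                assert ((tf, gene) in got_p) == (-d > 0.75 and zp[i, j] > 0)

    def test_edges_exclusive_between_subnetworks(self, rng):
        zg, zp = rng.normal(size=(3, 4), scale=2), rng.normal(size=(3, 4), scale=2)
        sub_g, sub_p = differential_edges(_agg(zg), _agg(zp), ["t1", "t2", "t3"])
        pairs_g = {(t, g) for t, g, _ in sub_g.edges}
        pairs_p = {(t, g) for t, g, _ in sub_p.edges}
        assert pairs_g.isdisjoint(pairs_p)

    def test_unknown_tf_errors(self, rng):
        z = rng.normal(size=(3, 4))
        with pytest.raises(DifferentialError):
            differential_edges(_agg(z), _agg(z), ["nope"])


class TestGroupSwapAntisymmetry:
    def test_swapping_groups_negates_and_exchanges(self, rng):
        zg, zp = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        tfs = tuple(f"t{i}" for i in range(4))
        genes = tuple(f"g{j}" for j in range(6))
        agg_g = _agg(zg, tfs=tfs, genes=genes)
        agg_p = _agg(zp, tfs=tfs, genes=genes)
        fwd = ees_table(agg_g, agg_p)
        rev = ees_table(agg_p, agg_g)
        fwd_by = {r.tf: r for r in fwd.records}
        rev_by = {r.tf: r for r in rev.records}
        assert set(fwd_by) == set(rev_by)
        for tf, r in fwd_by.items():
            assert rev_by[tf].ees == pytest.approx(-r.ees)
            assert rev_by[tf].n_diff == -r.n_diff
        sel = list(tfs)
        f_g, f_p = differential_edges(agg_g, agg_p, sel)
        r_g, r_p = differential_edges(agg_p, agg_g, sel)
        assert {(t, g) for t, g, _ in f_g.edges} == {(t, g) for t, g, _ in r_p.edges}
        assert {(t, g) for t, g, _ in f_p.edges} == {(t, g) for t, g, _ in r_g.edges}


class TestExport:
    def test_empty_subnetwork_round_trips(self, tmp_path, rng):
        z = rng.normal(size=(3, 4))
        sub_g, _ = differential_edges(_agg(z), _agg(z), ["t1"])
        path = tmp_path / "empty.tsv"
        export_subnetwork(sub_g, path)
        assert read_subnetwork(path, "GR").edges == ()

    def test_three_edge_round_trip_and_sif(self, tmp_path):
        zg = [[2.0, 2.0, 2.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        zp = [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        sub_g, _ = differential_edges(
            _agg(zg, tfs=("t1", "t2")), _agg(zp, tfs=("t1", "t2")), ["t1"]
        )
        assert len(sub_g.edges) == 3
        tsv = tmp_path / "sub.tsv"
        export_subnetwork(sub_g, tsv)
        assert read_subnetwork(tsv, "GR").edges == sub_g.edges
        sif = tmp_path / "sub.sif"
        export_subnetwork(sub_g, sif, fmt="sif")
        lines = sif.read_text().splitlines()
        assert lines == [f"t1\tregulates\tg{j}" for j in (1, 2, 3)]

    def test_networkx_view_labels_roles(self):
        zg = [[2.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        zp = [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]]
        sub_g, _ = differential_edges(
            _agg(zg, tfs=("t1", "t2")), _agg(zp, tfs=("t1", "t2")), ["t1"]
        )
        graph = sub_g.to_networkx()
        assert graph.nodes["t1"]["role"] == "tf"
        assert graph.nodes["g1"]["role"] == "gene"
        assert graph.has_edge("t1", "g1")

    def test_unknown_format_errors(self, tmp_path, rng):
        z = rng.normal(size=(3, 4))
        sub_g, _ = differential_edges(_agg(z), _agg(z), ["t1"])
        with pytest.raises(DifferentialError):
            export_subnetwork(sub_g, tmp_path / "x", fmt="graphml")
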