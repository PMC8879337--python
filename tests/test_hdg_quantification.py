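"""Hit filtering, RPKG normalisation, cluster aggregation and ratio flags."""

import math

import numpy as np
import pandas as pd
import pytest

from hdgkit.hdg_quantification import (
    SampleScale,
    aggregate_clusters,
    filter_hits,
    group_totals,
    ratio_flags,
    rpkg_normalize,
)
from hdgkit.io_formats import HmmHitRecord


def hit(contig, gene, e=1e-20, score=100.0, sample="S", ali=(1, 100), mlen=333):
    return HmmHitRecord(contig, sample, gene, mlen, score, e, *ali)


SCALE = SampleScale("S", 50.0, 1_000_000)


class TestFilterHits:
    def test_evalue_threshold(self):
        hits = [hit("c1", "almA", e=1e-10), hit("c2", "almA", e=1e-3)]
        assert len(filter_hits(hits)) == 1

    def test_score_threshold(self):
        hits = [hit("c1", "almA", score=30.0), hit("c2", "almA", score=10.0)]
        assert len(filter_hits(hits)) == 1

    def test_dedup_keeps_best_scoring_domain(self):
        hits = [hit("c1", "almA", score=50.0, ali=(1, 80)),
                hit("c1", "almA", score=90.0, ali=(90, 170))]
        kept = filter_hits(hits)
        assert len(kept) == 1 and kept[0].bit_score == 90.0

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(2)
        hits = [
            hit(f"c{rng.integers(10)}", rng.choice(["almA", "rubB", "gst"]),
                e=float(10 ** rng.uniform(-30, 0)), score=float(rng.uniform(0, 200)))
            for _ in range(300)
        ]
        kept = filter_hits(hits, 1e-5, 25.0)
        passing = [h for h in hits if h.e_value <= 1e-5 and h.bit_score >= 25.0]
        best = {}
        for h in passing:
            key = (h.sample_id, h.contig_id, h.gene_symbol)
            if key not in best or h.bit_score > best[key].bit_score:
                best[key] = h
        assert {(k.contig_id, k.gene_symbol, k.bit_score) for k in kept} == {
            (v.contig_id, v.gene_symbol, v.bit_score) for v in best.values()
        }

    def test_idempotent_under_input_duplication(self):
        hits = [hit(f"c{i}", "almA") for i in range(5)]
        assert filter_hits(hits) == filter_hits(hits + hits)


class TestRpkgNormalize:
    def test_direct_formula(self, catalog):
        # 100 hits on a 333 aa model (0.999 kb) at 50 genome equivalents
        hits = [hit(f"c{i}", "chnB", mlen=542) for i in range(100)]
        table = rpkg_normalize(hits, catalog, SCALE)
        expected = 100 / (3 * 542 / 1000 * 50.0)
        got = table.loc[table.unit_id == "chnB", "rpkg"].iloc[0]
        assert got == pytest.approx(expected)

    def test_zero_hit_genes_have_explicit_zero_rows(self, catalog):
        table = rpkg_normalize([], catalog, SCALE)
        assert len(table) == len(catalog)
        assert (table["rpkg"] == 0).all()

    def test_doubling_genome_equivalents_halves_rpkg(self, catalog):
        hits = [hit(f"c{i}", "almA", mlen=480) for i in range(40)]
        t1 = rpkg_normalize(hits, catalog, SampleScale("S", 50.0, 100))
        t2 = rpkg_normalize(hits, catalog, SampleScale("S", 100.0, 100))
        merged = t1.merge(t2, on="unit_id", suffixes=("_1", "_2"))
        nz = merged[merged["rpkg_1"] > 0]
        assert np.allclose(nz["rpkg_1"], 2 * nz["rpkg_2"])

    def test_alignment_length_variant(self, catalog):
        hits = [hit("c1", "almA", mlen=480, ali=(1, 240))]
        t = rpkg_normalize(hits, catalog, SCALE, length_from="alignment")
        got = t.loc[t.unit_id == "almA", "rpkg"].iloc[0]
        assert got == pytest.approx(1 / (3 * 240 / 1000 * 50.0))


def gene_row(sample, unit, group, rpkg):
    return {"sample_id": sample, "unit_id": unit, "unit_kind": "gene",
            "functional_group": group, "rpkg": rpkg}


class TestAggregateClusters:
    def test_reductase_subunit_excluded_from_mean(self, toy_catalog):
        table = pd.DataFrame([
            gene_row("S", "todC1", "MAH", 2.0),
            gene_row("S", "todC2", "MAH", 4.0),
            gene_row("S", "todA", "MAH", 10.0),
        ])
        agg = aggregate_clusters(table, toy_catalog)
        cluster = agg[(agg.unit_kind == "cluster") & (agg.unit_id == "tod")]
        assert cluster["rpkg"].iloc[0] == pytest.approx(3.0)

    def test_single_structural_subunit_passthrough(self, catalog):
        table = pd.DataFrame(
            [gene_row("S", g, catalog.entry(g).functional_group, 0.0)
             for g in catalog.symbols]
        )
        table.loc[table.unit_id == "cymAa", "rpkg"] = 7.5
        agg = aggregate_clusters(table, catalog)
        got = agg[(agg.unit_kind == "cluster") & (agg.unit_id == "cymAab")]["rpkg"]
        assert got.iloc[0] == pytest.approx(7.5)  # cymAb is the reductase subunit

    def test_gene_rows_unchanged(self, toy_catalog):
        table = pd.DataFrame([
            gene_row("S", "xylA", "MAH", 1.0),
            gene_row("S", "xylM", "MAH", 3.0),
        ])
        agg = aggregate_clusters(table, toy_catalog)
        genes = agg[agg.unit_kind == "gene"].reset_index(drop=True)
        pd.testing.assert_frame_equal(genes, table)

    def test_matches_group_by_oracle(self, catalog):
        rng = np.random.default_rng(9)
        rows = [
            gene_row(s, g, catalog.entry(g).functional_group, float(rng.random() * 5))
            for s in ("A", "B") for g in catalog.symbols
        ]
        table = pd.DataFrame(rows)
        agg = aggregate_clusters(table, catalog)
        lookup = table.set_index(["sample_id", "unit_id"])["rpkg"]
        from hdgkit.gene_catalog import cluster_members
        for s in ("A", "B"):
            for cid in catalog.cluster_ids:
                structural = cluster_members(catalog, cid, "structural")
                expected = np.mean([lookup[(s, g)] for g in structural])
                got = agg[(agg.sample_id == s) & (agg.unit_id == cid)
                          & (agg.unit_kind == "cluster")]["rpkg"].iloc[0]
                assert got == pytest.approx(expected)


class TestGroupTotals:
    def test_simple_sum(self, toy_catalog):
        table = pd.DataFrame([
            gene_row("S", "almA", "alkane", 1.5),
            gene_row("S", "rubB", "alkane", 2.5),
        ])
        agg = aggregate_clusters(table, toy_catalog)
        totals = group_totals(agg, toy_catalog)
        alk = totals[(totals.functional_group == "alkane")]["rpkg"].iloc[0]
        assert alk == pytest.approx(4.0)

    def test_cluster_members_not_double_counted(self, toy_catalog):
        table = pd.DataFrame([
            gene_row("S", "xylA", "MAH", 2.0),
            gene_row("S", "xylM", "MAH", 4.0),
        ])
        agg = aggregate_clusters(table, toy_catalog)
        totals = group_totals(agg, toy_catalog)
        # only the cluster mean (3.0) enters; member genes do not
        mah = totals[totals.functional_group == "MAH"]["rpkg"].iloc[0]
        assert mah == pytest.approx(3.0)

    def test_empty_table_totals_zero(self, catalog):
        table = rpkg_normalize([], catalog, SCALE)
        totals = group_totals(aggregate_clusters(table, catalog), catalog)
        assert (totals["rpkg"] == 0).all()

    def test_matches_independent_summation(self, catalog):
        rng = np.random.default_rng(4)
        table = pd.DataFrame([
            gene_row("S", g, catalog.entry(g).functional_group, float(rng.random()))
            for g in catalog.symbols
        ])
        agg = aggregate_clusters(table, catalog)
        totals = group_totals(agg, catalog)
        unit_ids = {u for u, _, _ in catalog.units()}
        expected = agg[agg.apply(
            lambda r: (r.unit_kind == "cluster") or (r.unit_id in unit_ids and r.unit_kind == "gene"),
            axis=1)]["rpkg"].sum()
        got = totals[totals.functional_group == "all"]["rpkg"].iloc[0]
        assert got == pytest.approx(expected)


def unit_row(sample, unit, group, rpkg, kind="gene"):
    return {"sample_id": sample, "unit_id": unit, "unit_kind": kind,
            "functional_group": group, "rpkg": rpkg}


class TestRatioFlags:
    def test_hand_computed_mean_sd(self, catalog):
        # ratios {1, 1, 4}: mean 2, sample SD sqrt(3); 4 > 2 + sqrt(3)
        num = {"gst": 1.0, "nahB": 2.0, "nahC": 8.0}
        den = {"gst": 1.0, "nahB": 2.0, "nahC": 2.0}
        rows = (
            [unit_row("N", u, "PAH", v) for u, v in num.items()]
            + [unit_row("D", u, "PAH", v) for u, v in den.items()]
        )
        flags = ratio_flags(pd.DataFrame(rows), catalog, "N", "D")
        by_unit = flags.set_index("unit_id")
        assert by_unit.loc["nahC", "flag"] == "above"
        assert by_unit.loc["gst", "flag"] == "within"
        assert by_unit.loc["nahC", "group_mean"] == pytest.approx(2.0)
        assert by_unit.loc["nahC", "group_sd"] == pytest.approx(math.sqrt(3))

    def test_undetected_sentinels_excluded_from_stats(self, catalog):
        rows = [
            unit_row("N", "gst", "PAH", 1.0), unit_row("D", "gst", "PAH", 1.0),
            unit_row("N", "nahB", "PAH", 2.0), unit_row("D", "nahB", "PAH", 1.0),
            unit_row("N", "nahC", "PAH", 3.0), unit_row("D", "nahC", "PAH", 0.0),
            unit_row("N", "phdF", "PAH", 0.0), unit_row("D", "phdF", "PAH", 2.0),
        ]
        flags = ratio_flags(pd.DataFrame(rows), catalog, "N", "D")
        by_unit = flags.set_index("unit_id")
        assert by_unit.loc["nahC", "flag"] == "undetected_in_denominator"
        assert by_unit.loc["phdF", "flag"] == "undetected_in_numerator"
        # stats over the two finite ratios {1.0, 2.0} only
        assert by_unit.loc["gst", "group_mean"] == pytest.approx(1.5)
        assert by_unit.loc["gst", "group_sd"] == pytest.approx(np.std([1, 2], ddof=1))

    def test_identical_ratios_all_within(self, catalog):
        rows = []
        for u in ("gst", "nahB", "nahC"):
            rows += [unit_row("N", u, "PAH", 3.0), unit_row("D", u, "PAH", 1.0)]
        flags = ratio_flags(pd.DataFrame(rows), catalog, "N", "D")
        assert (flags["flag"] == "within").all()
        assert (flags["group_sd"] == 0).all()

    def test_single_ratio_group_sd_null(self, catalog):
        rows = [unit_row("N", "gst", "PAH", 2.0), unit_row("D", "gst", "PAH", 1.0)]
        flags = ratio_flags(pd.DataFrame(rows), catalog, "N", "D")
        assert flags["flag"].iloc[0] == "within"
        assert flags["group_sd"].isna().all()

    def test_flag_counts_partition_units(self, catalog):
        rng = np.random.default_rng(6)
        rows = []
        n_detected_somewhere = 0
        for g in catalog.symbols:
            entry = catalog.entry(g)
            if entry.subunit_role != "standalone":
                continue
            a = float(rng.choice([0.0, rng.random() * 4]))
            b = float(rng.choice([0.0, rng.random() * 4]))
            if a > 0 or b > 0:
                n_detected_somewhere += 1
            rows += [
                unit_row("N", g, entry.functional_group, a),
                unit_row("D", g, entry.functional_group, b),
            ]
        flags = ratio_flags(pd.DataFrame(rows), catalog, "N", "D")
        assert len(flags) == n_detected_somewhere
        assert set(flags["flag"]) <= {
            "within", "above", "below",
            "undetected_in_numerator", "undetected_in_denominator",
        }
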