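"""Counting-window derivation, exclusion rules, read assignment and
housekeeping normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dielshift import quantify
from dielshift.models import (
    Compartment,
    CountMatrix,
    GeneModel,
    GeneStatus,
    GeneType,
    HousekeepingRole,
    Interval,
)
from tests.conftest import brute_force_counts


def nuclear_gene(gid, exons, strand="+", role=HousekeepingRole.NONE):
    return GeneModel(gene_id=gid, contig="nuclear",
                     compartment=Compartment.NUCLEAR, strand=strand,
                     exons=exons, housekeeping_role=role)


class TestDeriveCountWindow:
    def test_plus_strand_last_403_of_terminal_exon(self):
        # 1-based exon [1001, 2000] -> window [1598, 2000]
        g = nuclear_gene("g", [Interval(1000, 2000)], "+")
        w = quantify.derive_count_window(g)
        assert (w.interval.start1, w.interval.end1) == (1598, 2000)
        assert len(w.interval) == 403

    def test_minus_strand_mirror(self):
        g = nuclear_gene("g", [Interval(1000, 2000)], "-")
        w = quantify.derive_count_window(g)
        assert (w.interval.start1, w.interval.end1) == (1001, 1403)

    def test_short_terminal_exon_clipped_not_extended(self):
        g = nuclear_gene("g", [Interval(0, 400), Interval(550, 850)], "+")
        w = quantify.derive_count_window(g)
        assert (w.interval.start, w.interval.end) == (550, 850)
        assert w.basis.value == "terminal_403"

    def test_chloroplast_full_cds_span(self):
        g = GeneModel(gene_id="cp", contig="chloro",
                      compartment=Compartment.CHLOROPLAST, strand="+",
                      exons=[Interval(100, 600)], cds=Interval(100, 600))
        w = quantify.derive_count_window(g)
        assert w.interval == Interval(100, 600)
        assert w.basis.value == "full_span"

    def test_gene_without_exons_rejected_at_construction(self):
        with pytest.raises(ValueError, match="without exons"):
            nuclear_gene("g", [])


class TestFlagExclusions:
    def test_same_strand_overlap_not_excluded(self):
        a = nuclear_gene("a", [Interval(0, 500)], "+")
        b = nuclear_gene("b", [Interval(400, 900)], "+")
        status, _ = quantify.flag_exclusions([a, b])
        assert status["a"] is GeneStatus.COUNTED
        assert status["b"] is GeneStatus.COUNTED

    def test_convergent_pair_with_1bp_window_overlap_excluded(self):
        a = nuclear_gene("a", [Interval(0, 500)], "+")     # window [97, 500)
        b = nuclear_gene("b", [Interval(499, 999)], "-")   # window [499, 902)
        status, _ = quantify.flag_exclusions([a, b])
        assert status["a"] is GeneStatus.EXCLUDED_OVERLAP
        assert status["b"] is GeneStatus.EXCLUDED_OVERLAP

    def test_opposite_strands_without_window_overlap_kept(self):
        a = nuclear_gene("a", [Interval(0, 500)], "+")
        b = nuclear_gene("b", [Interval(500, 1000)], "-")
        status, _ = quantify.flag_exclusions([a, b])
        assert all(s is GeneStatus.COUNTED for s in status.values())

    def test_identical_window_sequences_merged(self):
        genome = {"nuclear": "ACGT" * 300}
        a = nuclear_gene("a", [Interval(0, 500)], "+")
        b = nuclear_gene("b", [Interval(600, 1100)], "+")
        # windows [97,500) and [697,1100) are identical (period-4 sequence)
        status, groups = quantify.flag_exclusions([a, b], genome=genome)
        assert groups == [("a", "b")]
        assert status["a"] is GeneStatus.MERGED_IDENTICAL

    def test_synthetic_fixture_flags_planted_pairs(self, genome_bundle,
                                                   quantified):
        contigs, annotation, truth = genome_bundle
        _, counts, _ = quantified
        (ca, cb), = truth.convergent_pairs
        assert counts.status[ca] is GeneStatus.EXCLUDED_OVERLAP
        assert counts.status[cb] is GeneStatus.EXCLUDED_OVERLAP
        (ia, ib), = truth.identical_pairs
        assert counts.status[ia] is GeneStatus.MERGED_IDENTICAL
        assert f"{ia}+{ib}" in counts.counts.index
        assert ia not in counts.counts.index


def make_aln(rows, sample="s1"):
    return pd.DataFrame(
        [
            {"sample_id": sample, "read_id": f"r{i}", "reference": ref,
             "start": s, "end": e, "strand": st}
            for i, (ref, s, e, st) in enumerate(rows)
        ]
    )


class TestCountReads:
    def chloro_windows(self):
        genes = [
            GeneModel(gene_id=f"g{i}", contig="chloro",
                      compartment=Compartment.CHLOROPLAST, strand="+",
                      exons=[iv], cds=iv)
            for i, iv in enumerate(
                [Interval(99, 600), Interval(700, 1200), Interval(1150, 1600)]
            )
        ]
        return {g.gene_id: quantify.derive_count_window(g) for g in genes}

    def test_empty_table_all_zero(self):
        windows = self.chloro_windows()
        cm = quantify.count_reads(make_aln([]), windows)
        assert (cm.counts == 0).all().all()

    def test_read_inside_span_counted(self):
        # 1-based gene span [100, 600], read [150, 200]
        windows = self.chloro_windows()
        cm = quantify.count_reads(make_aln([("chloro", 149, 200, "+")]), windows)
        assert cm.counts.loc["g0", "s1"] == 1

    def test_tied_overlap_dropped(self):
        windows = self.chloro_windows()
        # read overlapping g1 [700,1200) and g2 [1150,1600) equally
        cm = quantify.count_reads(make_aln([("chloro", 1140, 1210, "+")]),
                                  windows)
        assert cm.counts["s1"].sum() == 0

    def test_greater_overlap_wins(self):
        windows = self.chloro_windows()
        cm = quantify.count_reads(make_aln([("chloro", 1130, 1210, "+")]),
                                  windows)
        assert cm.counts.loc["g1", "s1"] == 1

    def test_malformed_interval_names_read(self):
        windows = self.chloro_windows()
        with pytest.raises(ValueError, match="r0"):
            quantify.count_reads(make_aln([("chloro", 500, 400, "+")]), windows)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        windows = self.chloro_windows()
        rows = []
        for _ in range(200):
            s = int(rng.integers(0, 1700))
            rows.append(("chloro", s, s + 50, rng.choice(["+", "-"])))
        aln = make_aln(rows)
        cm = quantify.count_reads(aln, windows)
        oracle = brute_force_counts(aln, list(windows.values()))
        assert (cm.counts["s1"] == oracle["s1"]).all()

    def test_strand_flip_invariance(self, quantified, alignments):
        windows, counts, _ = quantified
        flipped = alignments.copy()
        flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
        cm2 = quantify.count_reads(flipped, windows, dict(counts.status),
                                   counts.merge_groups)
        pd.testing.assert_frame_equal(counts.counts, cm2.counts)

    def test_each_read_assigned_at_most_once(self, quantified, alignments):
        _, counts, _ = quantified
        assert counts.counts.to_numpy().sum() <= len(alignments)


def hk_annotation():
    genes = [
        GeneModel(gene_id="rrl_a", contig="chloro",
                  compartment=Compartment.CHLOROPLAST, strand="+",
                  exons=[Interval(0, 100)], gene_type=GeneType.RRNA,
                  housekeeping_role=HousekeepingRole.CHLORO_NORM),
        GeneModel(gene_id="rrl_b", contig="chloro",
                  compartment=Compartment.CHLOROPLAST, strand="+",
                  exons=[Interval(200, 300)], gene_type=GeneType.RRNA,
                  housekeeping_role=HousekeepingRole.CHLORO_NORM),
        GeneModel(gene_id="cp1", contig="chloro",
                  compartment=Compartment.CHLOROPLAST, strand="+",
                  exons=[Interval(400, 500)], cds=Interval(400, 500)),
        GeneModel(gene_id="gapdh", contig="nuclear",
                  compartment=Compartment.NUCLEAR, strand="+",
                  exons=[Interval(0, 500)],
                  housekeeping_role=HousekeepingRole.NUCLEAR_NORM),
        GeneModel(gene_id="n1", contig="nuclear",
                  compartment=Compartment.NUCLEAR, strand="+",
                  exons=[Interval(600, 1100)]),
    ]
    return genes


def matrix(genes, data):
    counts = pd.DataFrame(data).T
    counts.index.name = "gene_id"
    return CountMatrix(counts=counts,
                       status={g.gene_id: GeneStatus.COUNTED for g in genes})


class TestNormalize:
    def test_ratio_is_exact_division(self):
        genes = hk_annotation()
        cm = matrix(genes, {"rrl_a": {"s1": 60000}, "rrl_b": {"s1": 40000},
                            "cp1": {"s1": 500}, "gapdh": {"s1": 1000},
                            "n1": {"s1": 10}})
        nm = quantify.normalize(cm, genes)
        # both 23S copies pooled into one denominator
        assert nm.ratios.loc["cp1", "s1"] == pytest.approx(0.005)
        assert nm.ratios.loc["n1", "s1"] == pytest.approx(0.01)

    def test_scale_invariance_per_sample(self):
        genes = hk_annotation()
        base = {"rrl_a": {"s1": 1000, "s2": 1000},
                "rrl_b": {"s1": 0, "s2": 0},
                "cp1": {"s1": 50, "s2": 50},
                "gapdh": {"s1": 200, "s2": 200},
                "n1": {"s1": 20, "s2": 20}}
        cm = matrix(genes, base)
        scaled = matrix(genes, base)
        scaled.counts["s2"] *= 10
        a = quantify.normalize(cm, genes)
        b = quantify.normalize(scaled, genes)
        pd.testing.assert_frame_equal(a.ratios, b.ratios)

    def test_housekeeping_self_ratio_is_one(self, quantified):
        _, _, norm = quantified
        gapdh = [g for g in norm.ratios.index if g == "nc01"]
        assert gapdh
        assert np.allclose(norm.ratios.loc["nc01"], 1.0)

    def test_zero_housekeeping_count_is_hard_error_naming_sample(self):
        genes = hk_annotation()
        cm = matrix(genes, {"rrl_a": {"s1": 0}, "rrl_b": {"s1": 0},
                            "cp1": {"s1": 500}, "gapdh": {"s1": 100},
                            "n1": {"s1": 10}})
        with pytest.raises(ValueError, match="s1"):
            quantify.normalize(cm, genes)
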