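"""Generator contracts: determinism, planted features, read placement
biases, and the closed-form behavior of the FCM/growth/qPCR simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dielshift._seq import ends_at_stop, has_internal_stop
from dielshift.sim import (
    SimConfig,
    generate_genome_annotation,
    lightshift_fcm_params,
    simulate_alignments,
    simulate_fcm,
    simulate_growth,
    simulate_qpcr,
)
from dielshift.sim.genome import PackingError


class TestGenomeGeneration:
    def test_identical_seed_and_config_give_identical_outputs(self):
        a = generate_genome_annotation(SimConfig(seed=3))
        b = generate_genome_annotation(SimConfig(seed=3))
        assert a[0] == b[0]
        assert [g.gene_id for g in a[1]] == [g.gene_id for g in b[1]]
        pd.testing.assert_frame_equal(a[2].expected_counts, b[2].expected_counts)

    def test_planted_orf_absent_from_annotation_but_in_truth(self, genome_bundle):
        _, annotation, truth = genome_bundle
        assert len(truth.novel_orfs) == 1
        orf = truth.novel_orfs[0]
        for g in annotation:
            if g.contig != orf["contig"]:
                continue
            assert not (g.span.start < orf["end"] and orf["start"] < g.span.end)

    def test_truncated_gene_extension_is_90_and_translates(self, genome_bundle):
        contigs, annotation, truth = genome_bundle
        (gid, info), = truth.truncated_genes.items()
        assert info["extension_nt"] == 90
        assert info["extension_nt"] % 3 == 0
        gene = next(g for g in annotation if g.gene_id == gid)
        a, b = info["true_cds"]
        seq = contigs[gene.contig][a:b]
        if gene.strand == "-":
            from dielshift._seq import revcomp

            seq = revcomp(seq)
        assert seq.startswith("ATG")
        assert ends_at_stop(seq)
        assert not has_internal_stop(seq)
        # the annotated model stops short of the true stop
        assert len(gene.cds) == len(seq) - 90

    def test_all_annotated_cds_are_codon_multiples(self, genome_bundle):
        _, annotation, _ = genome_bundle
        for g in annotation:
            if g.cds is not None:
                assert len(g.cds) % 3 == 0

    def test_housekeeping_true_folds_are_one_everywhere(self, genome_bundle):
        _, annotation, truth = genome_bundle
        hk = [g.gene_id for g in annotation
              if g.housekeeping_role.value != "none"]
        assert len(hk) == 3
        for gid in hk:
            for (cond, time) in truth.fold_map.get(gid, {}):
                assert truth.fold_map[gid][(cond, time)] == 1.0
            assert truth.true_contrast_fold(gid, ("HLUV", "T1"),
                                            ("control", "T1")) == 1.0

    def test_nuclear_free_config_gives_chloroplast_only_annotation(self):
        cfg = SimConfig(seed=2, n_nuclear_genes=0, total_reads_per_sample=1000)
        _, annotation, truth = generate_genome_annotation(cfg)
        assert all(g.compartment.value == "chloroplast" for g in annotation)
        nuclear_rows = [g for g in truth.expected_counts.index
                        if g.startswith("nc")]
        assert nuclear_rows == []

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_genome_annotation(SimConfig(seed=0, chloroplast_length=2000))

    def test_special_nuclear_cases_present(self, genome_bundle):
        _, annotation, truth = genome_bundle
        assert len(truth.convergent_pairs) == 1
        assert len(truth.identical_pairs) == 1
        short = [g for g in annotation if g.compartment.value == "nuclear"
                 and len(g.terminal_exon) < 403]
        assert short, "a terminal exon shorter than 403 nt must exist"


class TestAlignmentSimulation:
    def test_pure_chloroplast_fraction_boundary(self):
        cfg = SimConfig(seed=5, chloroplast_read_fraction=1.0,
                        total_reads_per_sample=2000)
        contigs, annotation, truth = generate_genome_annotation(cfg)
        sample = truth.expected_counts.columns[0]
        aln = simulate_alignments(annotation, truth, cfg, samples=[sample])
        assert (aln["reference"] == "chloro").all()

    def test_default_chloroplast_share_near_half(self):
        cfg = SimConfig(seed=7, total_reads_per_sample=100_000)
        contigs, annotation, truth = generate_genome_annotation(cfg)
        samples = list(truth.expected_counts.columns[:6])
        aln = simulate_alignments(annotation, truth, cfg, samples=samples)
        frac = (aln["reference"] == "chloro").mean()
        # pooled over 6 samples; tolerance covers the NB overdispersion
        # of compartment totals, which exceeds the binomial SE
        assert abs(frac - 0.5) < 0.02

    def test_full_bias_puts_nuclear_reads_within_8_read_lengths(self):
        cfg = SimConfig(seed=4, three_prime_bias=1.0,
                        total_reads_per_sample=20_000)
        contigs, annotation, truth = generate_genome_annotation(cfg)
        sample = truth.expected_counts.columns[0]
        aln = simulate_alignments(annotation, truth, cfg, samples=[sample])
        nuc = aln[aln["reference"] == "nuclear"]
        spans = {g: iv for g, (c, iv) in truth.true_spans.items()
                 if c == "nuclear"}
        window = 8 * cfg.read_length
        for _, read in nuc.sample(min(len(nuc), 400),
                                  random_state=0).iterrows():
            containing = [
                (g, iv) for g, iv in spans.items()
                if iv.start <= read["start"] and read["end"] <= iv.end
            ]
            assert containing
            ok = False
            for g, iv in containing:
                gene = next(x for x in truth.genes if x.gene_id == g)
                if gene.strand == "+":
                    ok |= read["start"] >= iv.end - window
                else:
                    ok |= read["end"] <= iv.start + window
            assert ok

    def test_zero_depth_gives_empty_table(self):
        cfg = SimConfig(seed=2, total_reads_per_sample=0)
        contigs, annotation, truth = generate_genome_annotation(cfg)
        sample = truth.expected_counts.columns[0]
        aln = simulate_alignments(annotation, truth, cfg, samples=[sample])
        assert len(aln) == 0

    def test_reads_lie_within_contigs(self, genome_bundle, alignments):
        contigs, _, _ = genome_bundle
        for contig, sub in alignments.groupby("reference"):
            assert sub["start"].min() >= 0
            assert sub["end"].max() <= len(contigs[contig])


class TestFCMSimulation:
    def test_bead_location_constant_across_samples(self, sim_config):
        params = lightshift_fcm_params(sim_config)[:10]
        events = simulate_fcm(params, sim_config)
        bead_means = events[events["population"] == "bead"].groupby(
            "sample_id"
        )["fals"].mean()
        spread = bead_means.std() / bead_means.mean()
        assert spread < 0.02  # sampling noise only

    def test_uv_red_endpoint_matches_configuration(self, sim_config):
        params = lightshift_fcm_params(sim_config, uv_red_endpoint=0.07)
        events = simulate_fcm(params, sim_config)
        cells = events[events["population"] == "cell"]
        uv = cells[cells["condition"] == "HLUV"]
        t0 = uv[uv["time_h"] == 0.0]["red"].mean()
        t_end = uv[uv["time_h"] == 19.5]["red"].mean()
        pct = 100 * (t_end - t0) / t0
        assert pct == pytest.approx(-93.0, abs=3.0)

    def test_zero_events_gives_empty_table(self, sim_config):
        events = simulate_fcm(
            [{"sample_id": "s", "cell_fals": 1.0, "cell_red": 1.0,
              "n_events": 0}],
            sim_config,
        )
        assert events.empty

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            simulate_fcm([], SimConfig(seed=0, fcm_log_scale=0.0))


class TestGrowthAndQPCRSimulation:
    def test_noiseless_doubling_per_day(self):
        series = simulate_growth({100: np.log(2)}, noise=0.0, seed=0,
                                 n_transfers=1, replicates=1)
        f = series.sort_values("time_d")["fluorescence"].to_numpy()
        assert np.allclose(f[1:] / f[:-1], 2.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_growth({100: 1.0}, times=[0, 2, 1])

    def test_noiseless_fold32_is_5_cycles_after_endogenous_correction(self):
        plate = simulate_qpcr(
            {"X": {("control", "T0"): 1.0, ("HLUV", "T1"): 32.0}},
            seed=0, ct_noise=0.0, replicates=2,
        )
        r = plate.records
        dct = (
            r[r["target"] == "X"].set_index("sample_id")["ct"]
            - r[r["target"] == "Actin"].set_index("sample_id")["ct"]
        )
        cal = dct[dct.index.str.startswith("control.T0")].mean()
        treat = dct[dct.index.str.startswith("HLUV.T1")].mean()
        assert treat - cal == pytest.approx(-5.0)

    def test_tenfold_dilution_spacing_at_perfect_efficiency(self):
        plate = simulate_qpcr({"X": {("control", "T0"): 1.0}}, seed=0,
                              ct_noise=0.0)
        dil = plate.dilution_series
        sub = dil[dil["target"] == "X"].sort_values("log10_quantity")
        spacing = np.diff(sub["ct"].to_numpy())
        assert np.allclose(spacing, -np.log2(10.0))

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            simulate_qpcr({"X": {("control", "T0"): 1.0}},
                          efficiencies={"X": 1.5})
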