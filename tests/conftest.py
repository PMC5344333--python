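"""Shared fixtures: one small synthetic experiment reused session-wide,
plus an exhaustive per-read counting oracle independent of the
vectorized implementation."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from dielshift import quantify
from dielshift.models import CountWindow
from dielshift.sim import SimConfig, generate_genome_annotation, simulate_alignments

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1, total_reads_per_sample=20_000)


@pytest.fixture(scope="session")
def genome_bundle(sim_config):
    contigs, annotation, truth = generate_genome_annotation(sim_config)
    return contigs, annotation, truth


@pytest.fixture(scope="session")
def alignments(sim_config, genome_bundle) -> pd.DataFrame:
    contigs, annotation, truth = genome_bundle
    return simulate_alignments(annotation, truth, sim_config)


@pytest.fixture(scope="session")
def quantified(genome_bundle, alignments):
    contigs, annotation, truth = genome_bundle
    windows = {g.gene_id: quantify.derive_count_window(g) for g in annotation}
    status, merge_groups = quantify.flag_exclusions(
        annotation, genome=contigs, windows=windows
    )
    counts = quantify.count_reads(alignments, windows, status, merge_groups)
    norm = quantify.normalize(counts, annotation)
    return windows, counts, norm


def brute_force_counts(
    aln: pd.DataFrame, windows: list[CountWindow]
) -> pd.DataFrame:
    """Exhaustive per-read overlap enumeration (greatest overlap wins,
    exact ties dropped) -- the oracle for count_reads."""
    samples = sorted(aln["sample_id"].unique()) if "sample_id" in aln else ["sample"]
    counts = pd.DataFrame(0, index=[w.gene_id for w in windows], columns=samples)
    for _, read in aln.iterrows():
        best, best_ov, tied = None, 0, False
        for w in windows:
            if w.contig != read["reference"]:
                continue
            ov = min(read["end"], w.interval.end) - max(
                read["start"], w.interval.start
            )
            if ov <= 0:
                continue
            if ov > best_ov:
                best, best_ov, tied = w.gene_id, ov, False
            elif ov == best_ov:
                tied = True
        if best is not None and not tied:
            s = read.get("sample_id", "sample")
            counts.loc[best, s] += 1
    return counts
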