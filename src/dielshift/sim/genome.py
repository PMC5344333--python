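"""Synthetic genome + annotation with planted features and ground truth.

The generator writes two reference sequences (a small chloroplast and a
nuclear contig) and an annotation that deliberately contains the
awkward cases the pipeline must handle: a truncated CDS whose true stop
lies downstream, an expressed ORF absent from the annotation, a
convergent overlapping 3'-UTR pair, a pair of genes identical over the
counting window, and a terminal exon shorter than the 403-nt window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielshift._seq import STOP_CODONS, revcomp
from dielshift.models import (
    Compartment,
    GeneModel,
    GeneType,
    HousekeepingRole,
    Interval,
)
from dielshift.sim.config import GroundTruth, SimConfig, default_design

CHLORO_CONTIG = "chloro"
NUCLEAR_CONTIG = "nuclear"

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

# default growth-rate truth (d^-1) per irradiance (umol photons m^-2 s^-1):
# slow growth at 6, maximum near 240, photoinhibition by 750
DEFAULT_MU_BY_IRRADIANCE = {
    6: 0.28, 55: 1.04, 150: 1.45, 240: 1.78,
    350: 1.60, 470: 1.45, 620: 1.22, 750: 0.96,
}

# default qPCR truths (fold vs the T0-control calibrator): an LHCSR-like
# photoprotection gene induced massively by UV, an LHC antenna gene
# repressed, and a one-helix-protein gene induced in the 10-30x band
DEFAULT_QPCR_TRUE_FOLDS = {
    "LHCSR2": {
        ("control", "T0"): 1.0, ("control", "T1"): 1.0, ("control", "T2.5"): 1.2,
        ("HL", "T1"): 1.6, ("HL", "T2.5"): 1.1,
        ("HLUV", "T1"): 33.0, ("HLUV", "T2.5"): 42.0,
    },
    "LHCP1": {
        ("control", "T0"): 1.0, ("control", "T1"): 1 / 1.7, ("control", "T2.5"): 1 / 1.6,
        ("HL", "T1"): 1 / 2.7, ("HL", "T2.5"): 1 / 3.2,
        ("HLUV", "T1"): 1 / 3.9, ("HLUV", "T2.5"): 1 / 3.7,
    },
    "OHP2": {
        ("control", "T0"): 1.0, ("control", "T1"): 1 / 1.5, ("control", "T2.5"): 1 / 2.0,
        ("HL", "T1"): 1 / 3.0, ("HL", "T2.5"): 1 / 5.0,
        ("HLUV", "T1"): 15.0, ("HLUV", "T2.5"): 22.0,
    },
}

# cyclic treatment-effect patterns: high light modest, high light + UV
# drastic; each entry maps (condition, time) -> true fold factor relative
# to the time-matched control
_EFFECT_PATTERNS: list[dict[tuple[str, str], float]] = [
    {},                                                        # null
    {("HLUV", "T1"): 1 / 32, ("HLUV", "T2.5"): 1 / 32},        # drastic down
    {("HLUV", "T1"): 10.0, ("HLUV", "T2.5"): 10.0},            # strong up
    {("HLUV", "T1"): 1 / 4, ("HLUV", "T2.5"): 1 / 4,
     ("HL", "T1"): 1 / 2, ("HL", "T2.5"): 1 / 2},              # moderate down
    {("HL", "T1"): 2.0, ("HL", "T2.5"): 2.0},                  # modest up
    {("HLUV", "T1"): 32.0, ("HLUV", "T2.5"): 32.0},            # drastic up
    {("HLUV", "T1"): 1 / 30, ("HLUV", "T2.5"): 1 / 50},        # deepening down
    {},                                                        # null
]


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) sense codons + one stop codon."""
    if n_codons < 2:
        raise ValueError("ORF needs at least start + stop")
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(body) + stop


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _write(seq: np.ndarray, start: int, insert: str) -> None:
    seq[start:start + len(insert)] = list(insert)


class PackingError(ValueError):
    """Planted features do not fit on the configured contig."""


def generate_genome_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Build genome FASTA sequences, GFF3-ready gene models, and truth.

    The planted unannotated ORF and the true extension of the truncated
    CDS appear only in the returned :class:`GroundTruth`, never in the
    annotation itself.
    """
    rng = config.rng("genome")
    genes: list[GeneModel] = []
    true_spans: dict[str, tuple[str, Interval]] = {}
    novel_orfs: list[dict] = []
    truncated: dict[str, dict] = {}
    weights: dict[str, float] = {}

    # ------------------------------------------------ chloroplast contig
    cseq = _random_seq(rng, config.chloroplast_length)
    cursor = int(rng.integers(100, 200))
    truncated_idx = config.n_chloro_genes // 2 if config.n_chloro_genes else -1
    rrna_after = config.n_chloro_genes // 3
    orf_after = (2 * config.n_chloro_genes) // 3

    for i in range(config.n_chloro_genes):
        gid = f"cp{i + 1:02d}"
        strand = "+" if i % 2 == 0 else "-"
        n_codons = int(rng.integers(70, 131))
        if i == truncated_idx:
            # full ORF, but annotate only up to 90 nt before the true stop
            extension = 90
            orf = _random_orf(rng, n_codons + extension // 3)
            true_len, ann_len = len(orf), len(orf) - extension
        else:
            extension = 0
            orf = _random_orf(rng, n_codons)
            true_len = ann_len = len(orf)
        start = cursor
        end_true = start + true_len
        if end_true > config.chloroplast_length:
            raise PackingError(
                f"chloroplast genes exceed contig length at {gid}"
            )
        _write(cseq, start, orf if strand == "+" else revcomp(orf))
        if strand == "+":
            ann_iv = Interval(start, start + ann_len)
        else:  # annotated 5'->3' runs rightward in revcomp space
            ann_iv = Interval(start + (true_len - ann_len), end_true)
        genes.append(
            GeneModel(
                gene_id=gid, contig=CHLORO_CONTIG,
                compartment=Compartment.CHLOROPLAST, strand=strand,
                exons=[ann_iv], cds=ann_iv, gene_type=GeneType.PROTEIN,
            )
        )
        true_spans[gid] = (CHLORO_CONTIG, Interval(start, end_true))
        weights[gid] = float(rng.lognormal(0.0, 0.5))
        if extension:
            truncated[gid] = {
                "annotated_cds": (ann_iv.start, ann_iv.end),
                "true_cds": (start, end_true),
                "extension_nt": extension,
            }
        cursor = end_true + int(rng.integers(80, 161))

        if i == rrna_after:
            # 23S rRNA housekeeping gene (chloroplast denominator)
            iv = Interval(cursor, cursor + 1200)
            if iv.end > config.chloroplast_length:
                raise PackingError("23S rRNA exceeds contig length")
            genes.append(
                GeneModel(
                    gene_id="rrl_23S", contig=CHLORO_CONTIG,
                    compartment=Compartment.CHLOROPLAST, strand="+",
                    exons=[iv], cds=None, gene_type=GeneType.RRNA,
                    housekeeping_role=HousekeepingRole.CHLORO_NORM,
                    name="23S rRNA",
                )
            )
            true_spans["rrl_23S"] = (CHLORO_CONTIG, iv)
            cursor = iv.end + int(rng.integers(80, 161))
        if i == orf_after:
            # planted expressed ORF, absent from the annotation
            n_orf_codons = 603
            orf_seq = _random_orf(rng, n_orf_codons)
            start_o = cursor + 3
            end_o = start_o + len(orf_seq)
            if end_o > config.chloroplast_length:
                raise PackingError("planted novel ORF exceeds contig length")
            # in-frame stop immediately upstream pins the ORF start
            _write(cseq, cursor, "TAA" + orf_seq)
            novel_orfs.append(
                {
                    "contig": CHLORO_CONTIG, "start": start_o, "end": end_o,
                    "strand": "+", "length_codons": n_orf_codons,
                }
            )
            true_spans["novel_orf_1"] = (CHLORO_CONTIG, Interval(start_o, end_o))
            weights["novel_orf_1"] = float(np.median(list(weights.values())) or 1.0)
            cursor = end_o + int(rng.integers(80, 161))

    if config.n_chloro_genes == 0:
        # degenerate but valid: still provide the housekeeping gene
        iv = Interval(100, 1300)
        genes.append(
            GeneModel(
                gene_id="rrl_23S", contig=CHLORO_CONTIG,
                compartment=Compartment.CHLOROPLAST, strand="+",
                exons=[iv], gene_type=GeneType.RRNA,
                housekeeping_role=HousekeepingRole.CHLORO_NORM,
            )
        )
        true_spans["rrl_23S"] = (CHLORO_CONTIG, iv)

    # the 23S pool receives as much signal as all protein genes combined:
    # a high-copy, heavily expressed, stable denominator
    protein_weight = sum(
        w for g, w in weights.items() if g != "novel_orf_1"
    ) or 1.0
    weights["rrl_23S"] = protein_weight

    # ------------------------------------------------ nuclear contig
    nseq = _random_seq(rng, config.nuclear_length)
    ngenes: list[GeneModel] = []
    cursor = int(rng.integers(100, 200))
    convergent_pair: list[str] = []
    identical_pair: list[str] = []

    def _place_single(gid, length, strand="+", role=HousekeepingRole.NONE,
                      name=None):
        nonlocal cursor
        iv = Interval(cursor, cursor + length)
        if iv.end > config.nuclear_length:
            raise PackingError(f"nuclear genes exceed contig length at {gid}")
        g = GeneModel(
            gene_id=gid, contig=NUCLEAR_CONTIG,
            compartment=Compartment.NUCLEAR, strand=strand,
            exons=[iv], gene_type=GeneType.PROTEIN,
            housekeeping_role=role, name=name,
        )
        ngenes.append(g)
        true_spans[gid] = (NUCLEAR_CONTIG, iv)
        cursor = iv.end + int(rng.integers(150, 301))
        return g

    for i in range(config.n_nuclear_genes):
        gid = f"nc{i + 1:02d}"
        if i == 0:
            g = _place_single(gid, 600, role=HousekeepingRole.NUCLEAR_NORM,
                              name="GAPDH")
            weights[gid] = 0.0  # set after the loop
        elif i == 1:
            g = _place_single(gid, 600, role=HousekeepingRole.QPCR_ENDOGENOUS,
                              name="Actin")
            weights[gid] = 0.0
        elif i == 2:
            # convergent overlapping 3'-UTR pair: + gene then - gene whose
            # 3' terminus (its reference start) lies inside the + gene's
            # terminal window
            a = Interval(cursor, cursor + 500)
            b = Interval(a.end - 50, a.end - 50 + 500)
            if b.end > config.nuclear_length:
                raise PackingError("nuclear genes exceed contig length")
            ga = GeneModel(gene_id=gid, contig=NUCLEAR_CONTIG,
                           compartment=Compartment.NUCLEAR, strand="+",
                           exons=[a], gene_type=GeneType.PROTEIN)
            gb = GeneModel(gene_id=f"{gid}b", contig=NUCLEAR_CONTIG,
                           compartment=Compartment.NUCLEAR, strand="-",
                           exons=[b], gene_type=GeneType.PROTEIN)
            ngenes.extend([ga, gb])
            true_spans[gid] = (NUCLEAR_CONTIG, a)
            true_spans[f"{gid}b"] = (NUCLEAR_CONTIG, b)
            convergent_pair = [gid, f"{gid}b"]
            weights[gid] = float(rng.lognormal(0.0, 0.5))
            weights[f"{gid}b"] = float(rng.lognormal(0.0, 0.5))
            cursor = b.end + int(rng.integers(150, 301))
            continue
        elif i == 3:
            g = _place_single(gid, 520)
            identical_pair.append(gid)
            weights[gid] = float(rng.lognormal(0.0, 0.5))
            continue
        elif i == 4:
            g = _place_single(gid, 520)
            identical_pair.append(gid)
            weights[gid] = float(rng.lognormal(0.0, 0.5))
            continue
        elif i == 5:
            # two-exon gene whose terminal exon is shorter than 403 nt
            e1 = Interval(cursor, cursor + 400)
            e2 = Interval(e1.end + 150, e1.end + 150 + 300)
            if e2.end > config.nuclear_length:
                raise PackingError("nuclear genes exceed contig length")
            g = GeneModel(gene_id=gid, contig=NUCLEAR_CONTIG,
                          compartment=Compartment.NUCLEAR, strand="+",
                          exons=[e1, e2], gene_type=GeneType.PROTEIN)
            ngenes.append(g)
            true_spans[gid] = (NUCLEAR_CONTIG, Interval(e1.start, e2.end))
            weights[gid] = float(rng.lognormal(0.0, 0.5))
            cursor = e2.end + int(rng.integers(150, 301))
            continue
        else:
            n_exons = int(rng.integers(1, 4))
            exons, s = [], cursor
            for _ in range(n_exons):
                ln = int(rng.integers(420, 701))
                exons.append(Interval(s, s + ln))
                s = s + ln + int(rng.integers(100, 251))
            if exons[-1].end > config.nuclear_length:
                raise PackingError(
                    f"nuclear genes exceed contig length at {gid}"
                )
            strand = "+" if i % 2 == 0 else "-"
            g = GeneModel(gene_id=gid, contig=NUCLEAR_CONTIG,
                          compartment=Compartment.NUCLEAR, strand=strand,
                          exons=exons, gene_type=GeneType.PROTEIN)
            ngenes.append(g)
            true_spans[gid] = (NUCLEAR_CONTIG,
                               Interval(exons[0].start, exons[-1].end))
            weights[gid] = float(rng.lognormal(0.0, 0.5))
            cursor = exons[-1].end + int(rng.integers(150, 301))
            continue
        weights[g.gene_id] = 0.0  # placeholder for housekeeping weights

    # make the two identical-pair genes share their terminal 403 nt
    if len(identical_pair) == 2:
        g1 = next(g for g in ngenes if g.gene_id == identical_pair[0])
        g2 = next(g for g in ngenes if g.gene_id == identical_pair[1])
        w1, w2 = g1.terminal_exon, g2.terminal_exon
        nseq[w2.end - 403:w2.end] = nseq[w1.end - 403:w1.end]

    # housekeeping nuclear weights: GAPDH carries a sizeable stable share
    other_nuclear = [g.gene_id for g in ngenes
                     if g.housekeeping_role is HousekeepingRole.NONE]
    base = sum(weights[g] for g in other_nuclear) or 1.0
    for g in ngenes:
        if g.housekeeping_role is HousekeepingRole.NUCLEAR_NORM:
            weights[g.gene_id] = 0.5 * base
        elif g.housekeeping_role is HousekeepingRole.QPCR_ENDOGENOUS:
            weights[g.gene_id] = 0.15 * base

    genes.extend(ngenes)

    # ------------------------------------------------ effects / truth
    design = default_design(config.replicates)
    fold_map = _build_fold_map(genes, identical_pair, config)
    expected = _expected_counts(genes, weights, fold_map, design, config)

    truth = GroundTruth(
        design=design,
        genes=genes,
        fold_map=fold_map,
        expected_counts=expected,
        true_spans=true_spans,
        novel_orfs=novel_orfs,
        truncated_genes=truncated,
        identical_pairs=[tuple(identical_pair)] if len(identical_pair) == 2 else [],
        convergent_pairs=[tuple(convergent_pair)] if convergent_pair else [],
        mu_by_irradiance=dict(DEFAULT_MU_BY_IRRADIANCE),
        qpcr_true_folds={k: dict(v) for k, v in DEFAULT_QPCR_TRUE_FOLDS.items()},
    )
    contigs = {CHLORO_CONTIG: "".join(cseq), NUCLEAR_CONTIG: "".join(nseq)}
    return contigs, genes, truth


def _build_fold_map(
    genes: list[GeneModel],
    identical_pair: list[str],
    config: SimConfig,
) -> dict[str, dict[tuple[str, str], float]]:
    """Assign diel drift and treatment effects; housekeeping genes stay 1."""
    amp = config.diel_amplitude
    fold_map: dict[str, dict[tuple[str, str], float]] = {}
    eligible = [g for g in genes
                if g.housekeeping_role is HousekeepingRole.NONE
                and g.gene_type is GeneType.PROTEIN]
    pair_pattern: dict[str, int] = {}
    for k, g in enumerate(eligible):
        pat_idx = pair_pattern.get(g.gene_id, k % len(_EFFECT_PATTERNS))
        if g.gene_id in identical_pair:
            # indistinguishable genes share their true effect
            for other in identical_pair:
                pair_pattern[other] = pat_idx
        pattern = _EFFECT_PATTERNS[pat_idx]
        diel = (1.0, 1.0 + amp / 2, 1.0 + amp) if k % 3 == 0 else (1.0, 1.0, 1.0)
        entry: dict[tuple[str, str], float] = {}
        for cond in ("control", "HL", "HLUV"):
            for t, d in zip(("T0", "T1", "T2.5"), diel):
                treat = pattern.get((cond, t), 1.0)
                entry[(cond, t)] = d * treat
        fold_map[g.gene_id] = entry
    return fold_map


def _expected_counts(
    genes: list[GeneModel],
    weights: dict[str, float],
    fold_map: dict[str, dict[tuple[str, str], float]],
    design: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Expected reads per feature per sample.

    Within each compartment the per-sample gene weights are renormalized
    so that the compartment's total read share is fixed (sequencing
    depth is a budget, not a meter): this reproduces the compositional
    coupling that housekeeping normalization is designed to remove.
    """
    chloro_ids = [g.gene_id for g in genes
                  if g.compartment is Compartment.CHLOROPLAST]
    if "novel_orf_1" in weights:
        chloro_ids.append("novel_orf_1")
    nuclear_ids = [g.gene_id for g in genes
                   if g.compartment is Compartment.NUCLEAR]

    cols = {}
    for _, s in design.iterrows():
        key = (s["condition"], s["time"])
        col = {}
        for ids, frac in (
            (chloro_ids, config.chloroplast_read_fraction),
            (nuclear_ids, 1.0 - config.chloroplast_read_fraction),
        ):
            if not ids:
                continue
            w = np.array([
                weights[g] * fold_map.get(g, {}).get(key, 1.0) for g in ids
            ])
            total = w.sum()
            share = w / total if total > 0 else np.zeros_like(w)
            for g, p in zip(ids, share):
                col[g] = frac * config.total_reads_per_sample * p
        cols[s["sample_id"]] = col
    return pd.DataFrame(cols).fillna(0.0)
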