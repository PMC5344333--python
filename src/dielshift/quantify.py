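"""Compartment-specific read counting and housekeeping normalization.

Chloroplast genes are counted over their full CDS span.  Nuclear genes
are counted only over the last 403 nucleotides of the terminal (3'-most)
exon, reflecting the strong 3' bias of the library chemistry; when the
terminal exon is shorter than 403 nt the window is clipped to the exon
rather than extended across a splice junction.  Because libraries are
non-directional, recorded read strand is ignored everywhere.

Counts are normalized per compartment to a housekeeping denominator:
the 23S rRNA count (pooled over duplicated copies) for chloroplast
genes and the GAPDH count for nuclear genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielshift.io import ALIGNMENT_COLUMNS
from dielshift.models import (
    Compartment,
    CountMatrix,
    CountWindow,
    GeneModel,
    GeneStatus,
    HousekeepingRole,
    Interval,
    NormalizedMatrix,
    WindowBasis,
)

TERMINAL_WINDOW_NT = 403


def derive_count_window(gene: GeneModel) -> CountWindow:
    """The interval within which reads are credited to ``gene``.

    Chloroplast: the full CDS span (gene span for RNAs without a CDS).
    Nuclear: the last 403 nt of the terminal exon in transcript
    orientation; on the minus strand that is the first 403 nt, in
    reference coordinates, of the 5'-most reference-coordinate exon.
    """
    if gene.compartment is Compartment.CHLOROPLAST:
        iv = gene.cds if gene.cds is not None else gene.span
        return CountWindow(gene.gene_id, gene.contig, iv,
                           WindowBasis.FULL_SPAN, gene.strand)
    term = gene.terminal_exon
    n = min(TERMINAL_WINDOW_NT, len(term))
    if gene.strand == "+":
        iv = Interval(term.end - n, term.end)
    else:
        iv = Interval(term.start, term.start + n)
    return CountWindow(gene.gene_id, gene.contig, iv,
                       WindowBasis.TERMINAL_403, gene.strand)


def flag_exclusions(
    annotation: list[GeneModel],
    genome: dict[str, str] | None = None,
    windows: dict[str, CountWindow] | None = None,
) -> tuple[dict[str, GeneStatus], list[tuple[str, ...]]]:
    """Per-gene status flags plus identical-window merge groups.

    Both members of a convergent opposite-strand pair whose count
    windows overlap are flagged ``excluded_overlap`` (gene-specific
    assignment of non-directional 3'-biased reads is impossible
    there).  Genes whose window sequences are identical are flagged
    ``merged_identical`` and downstream reported as one joint record;
    this check needs the genome and is skipped when it is not given.
    """
    windows = windows or {g.gene_id: derive_count_window(g) for g in annotation}
    by_id = {g.gene_id: g for g in annotation}
    status = {g.gene_id: GeneStatus.COUNTED for g in annotation}

    genes = list(annotation)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if a.contig != b.contig or a.strand == b.strand:
                continue
            wa, wb = windows[a.gene_id], windows[b.gene_id]
            if wa.interval.overlap(wb.interval) >= 1:
                status[a.gene_id] = GeneStatus.EXCLUDED_OVERLAP
                status[b.gene_id] = GeneStatus.EXCLUDED_OVERLAP

    merge_groups: list[tuple[str, ...]] = []
    if genome is not None:
        seqs: dict[str, list[str]] = {}
        for gid, w in windows.items():
            if status[gid] is not GeneStatus.COUNTED:
                continue
            seq = genome[w.contig][w.interval.start:w.interval.end]
            if w.strand == "-":
                from dielshift._seq import revcomp

                seq = revcomp(seq)
            seqs.setdefault(seq.upper(), []).append(gid)
        for members in seqs.values():
            if len(members) > 1:
                group = tuple(sorted(members, key=lambda g: by_id[g].span.start))
                merge_groups.append(group)
                for gid in members:
                    status[gid] = GeneStatus.MERGED_IDENTICAL
    return status, merge_groups


def count_reads(
    alignments: pd.DataFrame,
    windows: dict[str, CountWindow] | list[CountWindow],
    status: dict[str, GeneStatus] | None = None,
    merge_groups: list[tuple[str, ...]] | None = None,
) -> CountMatrix:
    """Assign reads to count windows, irrespective of recorded strand.

    A read is credited to the window it overlaps by the greatest number
    of bases; reads tied between several windows are dropped, keeping
    counts integral and deterministic.  ``alignments`` uses 0-based
    half-open coordinates; a ``sample_id`` column partitions the matrix
    columns (a single column named ``sample`` is used if absent).
    """
    if isinstance(windows, dict):
        windows = list(windows.values())
    aln = alignments.copy()
    if aln.empty:
        aln = pd.DataFrame(columns=["sample_id", *ALIGNMENT_COLUMNS])
    if "sample_id" not in aln.columns:
        aln["sample_id"] = "sample"
    bad = aln["start"] > aln["end"]
    if bad.any():
        name = aln.loc[bad, "read_id"].iloc[0]
        raise ValueError(f"malformed interval for read {name!r} (start > end)")

    gene_ids = [w.gene_id for w in windows]
    samples = list(pd.unique(aln["sample_id"]))
    counts = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene_id"), columns=samples,
        dtype=np.int64,
    )

    for (contig, sample), sub in aln.groupby(
        ["reference", "sample_id"], sort=False, observed=True
    ):
        ws = [w for w in windows if w.contig == contig]
        if not ws or sub.empty:
            continue
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        ov = np.zeros((len(ws), len(sub)), dtype=np.int64)
        for k, w in enumerate(ws):
            ov[k] = np.clip(
                np.minimum(ends, w.interval.end)
                - np.maximum(starts, w.interval.start),
                0, None,
            )
        best = ov.max(axis=0)
        keep = (best > 0) & ((ov == best[None, :]).sum(axis=0) == 1)
        assigned = ov.argmax(axis=0)[keep]
        per_gene = np.bincount(assigned, minlength=len(ws))
        counts.loc[[w.gene_id for w in ws], sample] += per_gene

    status = dict(status or {})
    for gid in gene_ids:
        status.setdefault(gid, GeneStatus.COUNTED)
    merge_groups = merge_groups or []
    counts = _merge_identical(counts, merge_groups)
    return CountMatrix(counts=counts, status=status, merge_groups=merge_groups)


def _merge_identical(
    counts: pd.DataFrame, merge_groups: list[tuple[str, ...]]
) -> pd.DataFrame:
    """Report each identical-window group as one joint record."""
    for group in merge_groups:
        present = [g for g in group if g in counts.index]
        if not present:
            continue
        joint = counts.loc[present].sum(axis=0)
        joint.name = "+".join(group)
        counts = counts.drop(index=present)
        counts = pd.concat([counts, joint.to_frame().T])
    return counts


def normalize(
    counts: CountMatrix,
    annotation: list[GeneModel],
) -> NormalizedMatrix:
    """Divide each gene's counts by its compartment's housekeeping count.

    Chloroplast genes are divided by the sample's 23S rRNA count
    (summed over both copies when the gene is duplicated); nuclear
    genes by the sample's GAPDH count.  A zero housekeeping count in
    any sample is a hard error naming the sample: silently adding a
    pseudocount would corrupt every ratio in that sample.
    """
    comp_of = {g.gene_id: g.compartment for g in annotation}
    hk = {
        Compartment.CHLOROPLAST: [
            g.gene_id for g in annotation
            if g.housekeeping_role is HousekeepingRole.CHLORO_NORM
        ],
        Compartment.NUCLEAR: [
            g.gene_id for g in annotation
            if g.housekeeping_role is HousekeepingRole.NUCLEAR_NORM
        ],
    }
    for comp, ids in hk.items():
        if not ids and any(c is comp for c in comp_of.values()):
            raise ValueError(f"no housekeeping gene annotated for {comp.value}")

    mat = counts.counts
    denominators = pd.DataFrame(index=["chloroplast", "nuclear"],
                                columns=mat.columns, dtype=float)
    for comp, ids in hk.items():
        ids_present = [g for g in ids if g in mat.index]
        if not ids_present:
            continue
        denom = mat.loc[ids_present].sum(axis=0).astype(float)
        zero = denom[denom == 0]
        if len(zero):
            raise ValueError(
                f"housekeeping count for {comp.value} is zero in sample "
                f"{zero.index[0]!r}"
            )
        denominators.loc[comp.value] = denom

    ratios = pd.DataFrame(index=mat.index, columns=mat.columns, dtype=float)
    for gid in mat.index:
        comp = comp_of.get(gid.split("+", 1)[0])
        if comp is None:
            continue
        ratios.loc[gid] = mat.loc[gid] / denominators.loc[comp.value]
    return NormalizedMatrix(
        ratios=ratios.dropna(how="all"),
        housekeeping={
            "chloroplast": "+".join(hk[Compartment.CHLOROPLAST]),
            "nuclear": "+".join(hk[Compartment.NUCLEAR]),
        },
        housekeeping_counts=denominators,
        status=dict(counts.status),
    )
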