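"""Coverage-driven refinement of organelle gene models.

Two passes, both read-evidence based and strictly separate from
quantification: (i) extension of annotated CDSs that stop short of a
true in-frame stop codon, and (ii) discovery of expressed ORFs in
unannotated regions.  Extension never shortens a model and every
emitted CDS ends at a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from dielshift._seq import START_CODON, is_stop, revcomp
from dielshift.models import GeneModel, Interval


@dataclass
class CoverageProfile:
    """Per-base read depth over one contig."""

    contig: str
    depth: np.ndarray

    def mean_depth(self, start: int, end: int) -> float:
        return float(self.depth[start:end].mean()) if end > start else 0.0


@dataclass
class ExtensionResult:
    gene: GeneModel
    extended: bool
    extension_nt: int
    flag: str  # "", "unsupported", "no_stop"


@dataclass(frozen=True)
class NovelORF:
    contig: str
    start: int          # 0-based half-open, includes the stop codon
    end: int
    strand: str
    frame: int
    length_codons: int
    mean_depth: float


def compute_coverage(
    alignments: pd.DataFrame,
    contig: str,
    contig_length: int,
) -> CoverageProfile:
    """Depth at base b = number of reads whose interval contains b."""
    sub = alignments[alignments["reference"] == contig]
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    if len(starts) and (starts.min() < 0 or ends.max() > contig_length):
        raise ValueError(f"reads fall outside contig {contig!r}")
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return CoverageProfile(contig, np.cumsum(delta[:-1]))


def extend_cds(
    gene: GeneModel,
    coverage: CoverageProfile,
    genome: dict[str, str],
    min_depth: float = 5.0,
) -> ExtensionResult:
    """Extend a CDS that lacks a stop codon to the first in-frame stop.

    Extension proceeds codon by codon downstream of the annotated end;
    each sense codon must carry mean read depth >= ``min_depth`` to be
    traversed (the closing stop codon itself is exempt from the gate:
    reaching it is a frame closure, not an expression claim).  A gene
    already ending at a stop codon is a fixed point.  If coverage runs
    out or the contig ends before an in-frame stop, the gene is left
    unmodified and flagged.
    """
    if gene.cds is None:
        return ExtensionResult(gene, False, 0, "")
    seq = genome[gene.contig]
    cds = gene.cds
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length not a multiple of 3")

    last = (
        seq[cds.end - 3:cds.end]
        if gene.strand == "+"
        else revcomp(seq[cds.start:cds.start + 3])
    )
    if is_stop(last):
        return ExtensionResult(gene, False, 0, "")

    n_ext = 0
    pos = cds.end if gene.strand == "+" else cds.start
    while True:
        if gene.strand == "+":
            if pos + 3 > len(seq):
                return ExtensionResult(gene, False, 0, "no_stop")
            codon = seq[pos:pos + 3]
            lo, hi = pos, pos + 3
        else:
            if pos - 3 < 0:
                return ExtensionResult(gene, False, 0, "no_stop")
            codon = revcomp(seq[pos - 3:pos])
            lo, hi = pos - 3, pos
        if is_stop(codon):
            n_ext += 3
            break
        if coverage.mean_depth(lo, hi) < min_depth:
            return ExtensionResult(gene, False, 0, "unsupported")
        n_ext += 3
        pos = pos + 3 if gene.strand == "+" else pos - 3

    if gene.strand == "+":
        new_cds = Interval(cds.start, cds.end + n_ext)
    else:
        new_cds = Interval(cds.start - n_ext, cds.end)
    new_exons = [
        Interval(min(e.start, new_cds.start), max(e.end, new_cds.end))
        if e.overlap(cds) or e == gene.terminal_exon
        else e
        for e in gene.exons
    ]
    refined = replace(gene, exons=new_exons, cds=new_cds)
    return ExtensionResult(refined, True, n_ext, "")


def unannotated_intervals(
    annotation: list[GeneModel], contig: str, contig_length: int
) -> list[Interval]:
    """Maximal intervals not covered by any annotated gene span
    (either strand)."""
    spans = sorted(
        (g.span for g in annotation if g.contig == contig),
        key=lambda iv: iv.start,
    )
    out, cursor = [], 0
    for iv in spans:
        if iv.start > cursor:
            out.append(Interval(cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < contig_length:
        out.append(Interval(cursor, contig_length))
    return out


def detect_novel_orfs(
    coverage: CoverageProfile,
    annotation: list[GeneModel],
    genome: dict[str, str],
    min_codons: int = 100,
    min_depth: float = 5.0,
    start_codon: str = START_CODON,
) -> list[NovelORF]:
    """Expressed ORFs in unannotated regions of one contig.

    Within each maximal unannotated interval whose mean depth is at
    least ``min_depth``, every ORF (start codon to in-frame stop, both
    strands, fully inside the interval) with at least ``min_codons``
    codons (stop included) is reported; the longest ORF of each
    interval comes first.  Only ATG starts are considered by default.
    """
    contig = coverage.contig
    seq = genome[contig]
    results: list[NovelORF] = []
    for iv in unannotated_intervals(annotation, contig, len(seq)):
        if coverage.mean_depth(iv.start, iv.end) < min_depth:
            continue
        region = seq[iv.start:iv.end]
        found = []
        for strand, s in (("+", region), ("-", revcomp(region))):
            found.extend(_scan_orfs(s, min_codons, start_codon, strand))
        orfs = []
        for strand, frame, o_start, o_end in found:
            if strand == "+":
                a, b = iv.start + o_start, iv.start + o_end
            else:
                a, b = iv.end - o_end, iv.end - o_start
            orfs.append(
                NovelORF(
                    contig=contig, start=a, end=b, strand=strand, frame=frame,
                    length_codons=(o_end - o_start) // 3,
                    mean_depth=coverage.mean_depth(a, b),
                )
            )
        orfs.sort(key=lambda o: (-o.length_codons, o.start))
        results.extend(orfs)
    return results


def _scan_orfs(
    seq: str, min_codons: int, start_codon: str, strand: str
) -> list[tuple[str, int, int, int]]:
    """ORFs (5'-most start per stop) in one orientation of a region."""
    out = []
    n = len(seq)
    for frame in range(3):
        pending_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if pending_start is None and codon == start_codon:
                pending_start = i
            elif pending_start is not None and is_stop(codon):
                end = i + 3
                if (end - pending_start) // 3 >= min_codons:
                    out.append((strand, frame, pending_start, end))
                pending_start = None
    return out


# ----------------------------------------------------- gene inventory

def tally_inventory(annotation: list[GeneModel]) -> dict[str, int]:
    """Gene counts by type, plus the grand total."""
    counts = {"protein": 0, "tRNA": 0, "rRNA": 0}
    for g in annotation:
        counts[g.gene_type.value] += 1
    counts["total"] = sum(counts.values())
    return counts


def refined_inventory(
    prior: dict[str, int],
    novel_protein_genes: int,
    recognized_rrna_copies: int = 0,
) -> dict[str, int]:
    """Bookkeeping of an improved organelle gene inventory.

    ``prior`` holds the previously reported counts per type; novel
    protein-coding genes found by :func:`detect_novel_orfs` and rRNA
    copies recognized as distinct duplicated loci are added.
    """
    out = {
        "protein": prior.get("protein", 0) + novel_protein_genes,
        "tRNA": prior.get("tRNA", 0),
        "rRNA": prior.get("rRNA", 0) + recognized_rrna_copies,
    }
    out["total"] = out["protein"] + out["tRNA"] + out["rRNA"]
    return out
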