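"""Core domain types shared across the pipeline.

Coordinate convention: all in-memory intervals are 0-based, half-open
``[start, end)``.  File formats that use 1-based inclusive coordinates
(GFF3, the tab-delimited alignment table) are converted at the I/O
boundary only (see :mod:`dielshift.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class Compartment(str, Enum):
    CHLOROPLAST = "chloroplast"
    NUCLEAR = "nuclear"


class GeneType(str, Enum):
    PROTEIN = "protein"
    TRNA = "tRNA"
    RRNA = "rRNA"


class HousekeepingRole(str, Enum):
    NONE = "none"
    CHLORO_NORM = "chloro_norm"        # 23S rRNA: chloroplast denominator
    NUCLEAR_NORM = "nuclear_norm"      # GAPDH: nuclear denominator
    QPCR_ENDOGENOUS = "qpcr_endogenous"  # Actin: qPCR endogenous control


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def start1(self) -> int:
        """1-based inclusive start (GFF3 convention)."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end (GFF3 convention)."""
        return self.end


@dataclass
class GeneModel:
    """A gene's coordinate substrate for counting and refinement.

    Exons are sorted, non-overlapping intervals on the reference; the CDS
    lies within the exon union.  Single-exon genes (the organelle case)
    simply carry one exon spanning the CDS.
    """

    gene_id: str
    contig: str
    compartment: Compartment
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: Interval | None = None
    gene_type: GeneType = GeneType.PROTEIN
    housekeeping_role: HousekeepingRole = HousekeepingRole.NONE
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def terminal_exon(self) -> Interval:
        """The 3'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def three_prime_end(self) -> int:
        """Reference coordinate of the transcript 3' terminus (0-based)."""
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start


class WindowBasis(str, Enum):
    FULL_SPAN = "full_span"
    TERMINAL_403 = "terminal_403"


@dataclass(frozen=True)
class CountWindow:
    """The interval within which reads are credited to a gene."""

    gene_id: str
    contig: str
    interval: Interval
    basis: WindowBasis
    strand: str


class GeneStatus(str, Enum):
    COUNTED = "counted"
    EXCLUDED_OVERLAP = "excluded_overlap"
    MERGED_IDENTICAL = "merged_identical"


@dataclass
class CountMatrix:
    """Raw gene x sample read counts plus per-gene status flags.

    ``counts`` is a pandas DataFrame (index gene_id, columns sample ids,
    non-negative integers); ``status`` maps gene_id -> GeneStatus;
    ``merge_groups`` lists identical-window gene groups, each reported as
    one joint record under the joined id.
    """

    counts: "pandas.DataFrame"  # noqa: F821 - typing only
    status: dict[str, GeneStatus]
    merge_groups: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class NormalizedMatrix:
    """Gene x sample abundance ratios to compartment housekeeping counts."""

    ratios: "pandas.DataFrame"  # noqa: F821
    housekeeping: dict[str, str]       # compartment name -> denominator label
    housekeeping_counts: "pandas.DataFrame"  # noqa: F821 - denominator per sample
    status: dict[str, GeneStatus] = field(default_factory=dict)


def spliced_sequence(gene: GeneModel, contig_seq: str) -> str:
    """Transcript-oriented spliced sequence of a gene's CDS (or exons)."""
    from dielshift._seq import revcomp

    ivs = [gene.cds] if gene.cds is not None else gene.exons
    if gene.cds is not None:
        parts = [contig_seq[gene.cds.start:gene.cds.end]]
    else:
        parts = [contig_seq[iv.start:iv.end] for iv in ivs]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq
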