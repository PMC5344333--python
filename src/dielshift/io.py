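"""Readers and writers for the toolkit's file formats.

All conversions between file coordinates (1-based inclusive: GFF3 and the
tab-delimited alignment table) and in-memory coordinates (0-based
half-open) happen here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dielshift.models import (
    Compartment,
    GeneModel,
    GeneType,
    HousekeepingRole,
    Interval,
)

ALIGNMENT_COLUMNS = ["read_id", "reference", "start", "end", "strand"]


# ---------------------------------------------------------------- FASTA

def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive, ID/Parent attributes)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.contig, g.span.start)):
        attrs = (
            f"ID={g.gene_id};compartment={g.compartment.value};"
            f"gene_type={g.gene_type.value};housekeeping_role={g.housekeeping_role.value}"
        )
        if g.name:
            attrs += f";Name={g.name}"
        span = g.span
        lines.append(
            f"{g.contig}\tdielshift\tgene\t{span.start1}\t{span.end1}\t.\t{g.strand}\t.\t{attrs}"
        )
        for i, ex in enumerate(g.exons, 1):
            lines.append(
                f"{g.contig}\tdielshift\texon\t{ex.start1}\t{ex.end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"
            )
        if g.cds is not None:
            lines.append(
                f"{g.contig}\tdielshift\tCDS\t{g.cds.start1}\t{g.cds.end1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3` (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        exons = [
            Interval(c.start - 1, c.end) for c in db.children(feat, featuretype="exon")
        ]
        cds_feats = list(db.children(feat, featuretype="CDS"))
        cds = Interval(cds_feats[0].start - 1, cds_feats[0].end) if cds_feats else None
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                compartment=Compartment(feat.attributes["compartment"][0]),
                strand=feat.strand,
                exons=exons or [Interval(feat.start - 1, feat.end)],
                cds=cds,
                gene_type=GeneType(feat.attributes["gene_type"][0]),
                housekeeping_role=HousekeepingRole(
                    feat.attributes.get("housekeeping_role", ["none"])[0]
                ),
                name=feat.attributes.get("Name", [None])[0],
            )
        )
    return genes


# ------------------------------------------------------- alignment table

def write_alignments(table: pd.DataFrame, path: str | Path) -> None:
    """Write an alignment table as TSV with 1-based inclusive coordinates.

    In-memory tables are 0-based half-open; columns are
    read_id, reference, start, end, strand.
    """
    out = table[ALIGNMENT_COLUMNS].copy()
    out["start"] = out["start"] + 1  # to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"reference": str, "read_id": str})
    table["start"] = table["start"] - 1  # to 0-based half-open
    return table[ALIGNMENT_COLUMNS]


# ------------------------------------------------------------- tabular

def write_csv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, index=index)


def read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, **kw)


# ------------------------------------------------------------ key-value

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
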