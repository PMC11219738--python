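"""Readers and writers for the formats the pipeline exchanges.

GTF is emitted 1-based inclusive, BED 0-based half-open; all TSVs carry a
one-line header.  FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Annotation, GeneModel, LongRead, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF

def write_gtf(annotation: Annotation, path: str | Path, source: str = "isodyn") -> None:
    """Emit gene/transcript/exon features, 1-based inclusive coordinates."""
    lines = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        attrs = f'gene_id "{gene.id}";'
        lines.append(
            "\t".join(
                [gene.chrom, source, "gene", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        for t in gene.isoforms:
            tattrs = f'gene_id "{gene.id}"; transcript_id "{t.id}";'
            lines.append(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start + 1), str(t.end),
                     ".", t.strand, ".", tattrs]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, source, "exon", str(s + 1), str(e),
                         ".", t.strand, ".", tattrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip('"')
    return out


def read_gtf(path: str | Path) -> Annotation:
    """Read exon features of a GTF into gene models."""
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = _gtf_attributes(f[8])
            tid = attrs["transcript_id"]
            meta[tid] = (f[0], f[6], attrs.get("gene_id", tid))
            exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
    genes: dict[str, list[TranscriptModel]] = {}
    for tid, ex in exons.items():
        chrom, strand, gid = meta[tid]
        model = TranscriptModel(
            id=tid, chrom=chrom, strand=strand, exons=tuple(sorted(ex)), gene_id=gid
        )
        genes.setdefault(gid, []).append(model)
    return Annotation(
        genes={
            gid: GeneModel(
                id=gid,
                chrom=ts[0].chrom,
                strand=ts[0].strand,
                isoforms=tuple(sorted(ts, key=lambda t: t.id)),
            )
            for gid, ts in genes.items()
        }
    )


# ---------------------------------------------------------------------------
# Reads (BED12-like TSV)

READS_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand",
    "block_starts", "block_sizes", "source_isoform", "truth_label",
]


def write_reads(reads: list[LongRead], path: str | Path) -> None:
    rows = []
    for r in reads:
        rows.append(
            {
                "read_id": r.id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "block_starts": ",".join(str(s - r.start) for s, _ in r.exons),
                "block_sizes": ",".join(str(e - s) for s, e in r.exons),
                "source_isoform": r.source_isoform or ".",
                "truth_label": r.truth_label or ".",
            }
        )
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads(path: str | Path) -> list[LongRead]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        starts = [int(x) for x in str(row.block_starts).split(",")]
        sizes = [int(x) for x in str(row.block_sizes).split(",")]
        exons = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
        out.append(
            LongRead(
                id=row.read_id,
                chrom=row.chrom,
                strand=row.strand,
                exons=exons,
                source_isoform=None if row.source_isoform == "." else row.source_isoform,
                truth_label=None if row.truth_label == "." else row.truth_label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: list[tuple[str, int, int, str, str]], path: str | Path) -> None:
    """Write BED6 rows given (chrom, start, end, name, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df
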