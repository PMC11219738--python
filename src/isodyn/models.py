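"""Core domain objects shared across the pipeline.

Coordinates are 0-based half-open genomic intervals throughout the
library; the GTF writer converts to 1-based inclusive and BED output
stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware ordered exon chain on one chromosome.

    ``exons`` are sorted by genomic start, non-overlapping, each with
    end > start.  The junction chain (ordered intron intervals) is the
    identity used for isoform classification.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty or inverted exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals in genomic order (0-based half-open)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def junction_chain(self) -> tuple[Interval, ...]:
        return self.introns

    @property
    def tss(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Genomic coordinate of the 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def donors(self) -> tuple[int, ...]:
        """Donor (5' splice) sites in genomic coordinates.

        On '+' the donor is the intron start; on '-' the intron end.
        """
        if self.strand == "+":
            return tuple(i[0] for i in self.introns)
        return tuple(i[1] for i in self.introns)

    def acceptors(self) -> tuple[int, ...]:
        if self.strand == "+":
            return tuple(i[1] for i in self.introns)
        return tuple(i[0] for i in self.introns)

    def with_id(self, new_id: str) -> "TranscriptModel":
        return replace(self, id=new_id)

    def transcript_position(self, genomic_pos: int) -> int:
        """Map a genomic coordinate lying inside an exon to the 0-based
        transcript coordinate (distance from the 5' end)."""
        offsets = []
        acc = 0
        for s, e in self.exons:
            offsets.append((s, e, acc))
            acc += e - s
        total = acc
        for s, e, off in offsets:
            if s <= genomic_pos < e:
                pos = off + (genomic_pos - s)
                return pos if self.strand == "+" else total - 1 - pos
        raise ValueError(f"position {genomic_pos} not exonic in {self.id}")


@dataclass(frozen=True)
class LongRead:
    """An observed exon chain with end coordinates.

    ``truth_label`` carries the ground-truth artifact class when the read
    was simulated: one of clean/truncation/mispriming/template_switch/
    fusion, or None for real data.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    source_isoform: str | None = None
    truth_label: str | None = None

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


ISOFORM_CLASSES = ("FSM", "ISM", "NIC", "NNC", "fusion")
ARTIFACT_LABELS = ("clean", "truncation", "mispriming", "template_switch", "fusion")


@dataclass
class IsoformRecord:
    """One collapsed isoform plus everything curation needs to know."""

    model: TranscriptModel
    read_support: int
    read_ids: tuple[str, ...] = ()
    isoform_class: str | None = None
    matched_reference: tuple[str, ...] = ()
    mispriming: bool | None = None
    template_switch: bool | None = None
    junction_canonical: tuple[bool, ...] | None = None
    junction_short_read_support: tuple[int, ...] | None = None
    tss_supported: bool | None = None
    tts_supported: bool | None = None
    polya_motif_found: bool | None = None
    retained: bool | None = None


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: a set of isoforms sharing strand and chromosome."""

    id: str
    chrom: str
    strand: str
    isoforms: tuple[TranscriptModel, ...]

    @property
    def start(self) -> int:
        return min(t.start for t in self.isoforms)

    @property
    def end(self) -> int:
        return max(t.end for t in self.isoforms)


@dataclass
class Annotation:
    """Reference annotation: gene models plus junction / site indexes."""

    genes: dict[str, GeneModel]

    def __post_init__(self) -> None:
        self._by_transcript: dict[str, TranscriptModel] = {}
        for g in self.genes.values():
            for t in g.isoforms:
                self._by_transcript[t.id] = t

    @property
    def transcripts(self) -> dict[str, TranscriptModel]:
        return self._by_transcript

    def transcripts_on(self, chrom: str, strand: str) -> list[TranscriptModel]:
        return [
            t
            for g in self.genes.values()
            if g.chrom == chrom and g.strand == strand
            for t in g.isoforms
        ]

    def gene_of(self, transcript_id: str) -> str:
        t = self._by_transcript[transcript_id]
        assert t.gene_id is not None
        return t.gene_id


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of counts/TPM/intensities with the
    time-course design attached.

    ``design`` is indexed by sample name with columns ``day`` (int) and
    ``replicate`` (int); sample names follow ``d{day}_r{rep}``.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    def samples_for_day(self, day: int) -> list[str]:
        return list(self.design.index[self.design["day"] == day])

    @property
    def days(self) -> list[int]:
        return sorted(self.design["day"].unique())


def make_design(n_days: int, replicates: int) -> pd.DataFrame:
    """Standard time-course design: days 0..n_days-1, numbered replicates."""
    rows = [
        (f"d{day}_r{rep}", day, rep)
        for day in range(n_days)
        for rep in range(1, replicates + 1)
    ]
    df = pd.DataFrame(rows, columns=["sample", "day", "replicate"])
    return df.set_index("sample")


@dataclass(frozen=True)
class SkippingEvent:
    """A cassette-exon event: target exon with flanking exons/introns.

    ``upstream_exon``/``downstream_exon`` are named in *transcript*
    orientation: on '-' the upstream exon lies 3' of the target in
    genomic coordinates.
    """

    id: str
    chrom: str
    strand: str
    upstream_exon: Interval
    target_exon: Interval
    downstream_exon: Interval
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand == "+":
            ordered = (
                self.upstream_exon[1] <= self.target_exon[0]
                and self.target_exon[1] <= self.downstream_exon[0]
            )
        else:
            ordered = (
                self.downstream_exon[1] <= self.target_exon[0]
                and self.target_exon[1] <= self.upstream_exon[0]
            )
        if not ordered:
            raise ValueError("event exons must be disjoint and consistent with strand")

    @property
    def upstream_intron(self) -> Interval:
        """Intron between upstream and target exon (genomic interval)."""
        if self.strand == "+":
            return (self.upstream_exon[1], self.target_exon[0])
        return (self.target_exon[1], self.upstream_exon[0])

    @property
    def downstream_intron(self) -> Interval:
        if self.strand == "+":
            return (self.target_exon[1], self.downstream_exon[0])
        return (self.downstream_exon[1], self.target_exon[0])
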