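"""Long-read isoform cataloging: collapse, five-class classification,
artifact flagging and per-class curation.

Classes follow the standard long-read vocabulary: FSM (all splice
junctions match one reference transcript), ISM (a contiguous subset of a
reference's junctions), NIC (novel combination of annotated donor and
acceptor sites), NNC (at least one unannotated donor or acceptor) and
fusion (junctions spanning two non-overlapping annotated loci).
"""

from __future__ import annotations

import dataclasses
from statistics import median

import pandas as pd

from .io import revcomp
from .models import Annotation, Interval, IsoformRecord, LongRead, TranscriptModel

CANONICAL_INTRON_DINUCS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


def junction_dinucleotides(
    genome: dict[str, str], chrom: str, strand: str, intron: Interval
) -> tuple[str, str]:
    """Intron-terminal dinucleotides on the transcript strand."""
    s, e = intron
    g = genome[chrom]
    if strand == "+":
        return g[s : s + 2], g[e - 2 : e]
    return revcomp(g[e - 2 : e]), revcomp(g[s : s + 2])


# ---------------------------------------------------------------------------
# Collapse


def _boundaries(exons: tuple[Interval, ...]) -> list[int]:
    return [x for exon in exons for x in exon]


def collapse_reads(
    reads: list[LongRead],
    internal_tol: int = 5,
    end_tol: int = 50,
    min_cluster: int = 3,
) -> list[IsoformRecord]:
    """Merge reads whose exon chains agree within ``internal_tol`` at every
    internal boundary and ``end_tol`` at the ends; drop clusters with fewer
    than ``min_cluster`` reads.  The cluster representative takes the
    per-boundary median."""
    groups: dict[tuple[str, str, int], list[LongRead]] = {}
    for r in reads:
        groups.setdefault((r.chrom, r.strand, len(r.exons)), []).append(r)

    records: list[IsoformRecord] = []
    for (chrom, strand, n_exons), members in sorted(groups.items()):
        clusters: list[dict] = []
        for read in members:
            b = _boundaries(read.exons)
            placed = False
            for cl in clusters:
                rep = cl["rep"]
                ok = abs(b[0] - rep[0]) <= end_tol and abs(b[-1] - rep[-1]) <= end_tol
                if ok:
                    for k in range(1, len(b) - 1):
                        if abs(b[k] - rep[k]) > internal_tol:
                            ok = False
                            break
                if ok:
                    cl["reads"].append(read)
                    cols = list(zip(*[_boundaries(r.exons) for r in cl["reads"]]))
                    cl["rep"] = [int(round(median(c))) for c in cols]
                    placed = True
                    break
            if not placed:
                clusters.append({"rep": list(b), "reads": [read]})

        for cl in clusters:
            if len(cl["reads"]) < min_cluster:
                continue
            rep = cl["rep"]
            exons = tuple((rep[i], rep[i + 1]) for i in range(0, len(rep), 2))
            records.append(
                IsoformRecord(
                    model=TranscriptModel(
                        id="pending", chrom=chrom, strand=strand, exons=exons
                    ),
                    read_support=len(cl["reads"]),
                    read_ids=tuple(r.id for r in cl["reads"]),
                )
            )
    records.sort(key=lambda r: (r.model.chrom, r.model.start, r.model.end, -r.read_support))
    for i, rec in enumerate(records):
        rec.model = rec.model.with_id(f"ISO_{i + 1:05d}")
    return records


# ---------------------------------------------------------------------------
# Classification


def _is_contiguous_subchain(
    sub: tuple[Interval, ...], full: tuple[Interval, ...]
) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def classify_isoform(
    model: TranscriptModel, annotation: Annotation, end_tol: int = 50
) -> tuple[str, tuple[str, ...]]:
    """Assign exactly one of FSM/ISM/NIC/NNC/fusion and the matched
    reference transcript (or gene) ids."""
    if len(model.exons) == 0:  # pragma: no cover - TranscriptModel forbids it
        raise ValueError("cannot classify a model with zero exons")
    refs = annotation.transcripts_on(model.chrom, model.strand)

    if len(model.exons) == 1:
        # mono-exon: FSM when contained in a mono-exon reference (+/- end_tol)
        matches = tuple(
            t.id
            for t in refs
            if len(t.exons) == 1
            and t.start - end_tol <= model.start
            and model.end <= t.end + end_tol
        )
        return ("FSM", matches) if matches else ("NNC", ())

    chain = model.introns
    fsm = tuple(t.id for t in refs if t.introns == chain)
    if fsm:
        return "FSM", fsm
    ism = tuple(
        t.id
        for t in refs
        if len(t.introns) > len(chain) and _is_contiguous_subchain(chain, t.introns)
    )
    if ism:
        return "ISM", ism

    # fusion: junctions hitting >= 2 non-overlapping gene loci
    gene_hits: dict[str, int] = {}
    for t in refs:
        hits = len(set(chain) & set(t.introns))
        if hits:
            gid = t.gene_id or t.id
            gene_hits[gid] = max(gene_hits.get(gid, 0), hits)
    if len(gene_hits) >= 2:
        gids = sorted(gene_hits)
        spans = {
            g: (annotation.genes[g].start, annotation.genes[g].end)
            for g in gids
            if g in annotation.genes
        }
        for i, a in enumerate(gids):
            for b in gids[i + 1 :]:
                if a in spans and b in spans:
                    (s1, e1), (s2, e2) = spans[a], spans[b]
                    if e1 <= s2 or e2 <= s1:
                        return "fusion", tuple(gids)

    donors = {(t.strand, d) for t in refs for d in t.donors()}
    acceptors = {(t.strand, a) for t in refs for a in t.acceptors()}
    known_sites = all(
        (model.strand, d) in donors for d in model.donors()
    ) and all((model.strand, a) in acceptors for a in model.acceptors())

    overlapping = tuple(
        sorted(
            {
                t.gene_id or t.id
                for t in refs
                if t.start < model.end and model.start < t.end
            }
        )
    )
    return ("NIC", overlapping) if known_sites else ("NNC", overlapping)


# ---------------------------------------------------------------------------
# Artifact flags


def detect_mispriming(
    model: TranscriptModel, genome: dict[str, str], window: int = 20
) -> bool:
    """True when the genomic window immediately 3' of the transcript end is
    at least 60% adenine on the transcript's sense strand."""
    g = genome[model.chrom]
    if model.strand == "+":
        w = g[model.tts : model.tts + window]
    else:
        w = revcomp(g[max(model.tts - window, 0) : model.tts])
    if not w:
        return False
    return w.upper().count("A") / len(w) >= 0.60


def junction_canonicality(
    model: TranscriptModel, genome: dict[str, str]
) -> tuple[bool, ...]:
    return tuple(
        junction_dinucleotides(genome, model.chrom, model.strand, intron)
        in CANONICAL_INTRON_DINUCS
        for intron in model.introns
    )


# ---------------------------------------------------------------------------
# End support


def _near_interval(pos: int, start: int, end: int, window: int) -> bool:
    return start - window <= pos <= end + window


def end_support(
    model: TranscriptModel,
    cage_peaks: list[tuple[str, int, int, str, str]],
    polya_sites: list[tuple[str, int, int, str, str]],
    genome: dict[str, str],
    polya_motifs: tuple[str, ...] = ("AATAAA", "ATTAAA"),
    tss_window: int = 50,
    tts_window: int = 50,
    motif_window: int = 50,
) -> tuple[bool, bool, bool]:
    """(tss_supported, tts_supported, polya_motif_found)."""
    tss_supported = any(
        c == model.chrom
        and st == model.strand
        and _near_interval(model.tss, s, e, tss_window)
        for c, s, e, _n, st in cage_peaks
    )
    tts_supported = any(
        c == model.chrom
        and st == model.strand
        and _near_interval(model.tts, s, e, tts_window)
        for c, s, e, _n, st in polya_sites
    )
    g = genome[model.chrom]
    if model.strand == "+":
        upstream = g[max(model.tts - motif_window, 0) : model.tts]
    else:
        upstream = revcomp(g[model.tts : model.tts + motif_window])
    upstream = upstream.upper()
    polya_motif_found = any(m.upper().replace("U", "T") in upstream for m in polya_motifs)
    return tss_supported, tts_supported, polya_motif_found


# ---------------------------------------------------------------------------
# Curation


def curate(
    records: list[IsoformRecord],
    junction_support: dict[tuple[str, int, int, str], int] | pd.DataFrame,
    min_junction_reads: int = 10,
) -> list[IsoformRecord]:
    """Apply the per-class retention rules in place and return the records.

    FSM/ISM: kept only if not misprimed, no template-switch junction, and
    TSS, TTS and polyA-motif support all present.  NIC/NNC/fusion: kept if
    not misprimed and every junction is canonical or has short-read
    support of at least ``min_junction_reads``.
    """
    if isinstance(junction_support, pd.DataFrame):
        junction_support = {
            (r.chrom, int(r.start), int(r.end), r.strand): int(r.reads)
            for r in junction_support.itertuples(index=False)
        }
    for rec in records:
        needed = (
            rec.isoform_class,
            rec.mispriming,
            rec.template_switch,
            rec.junction_canonical,
            rec.tss_supported,
            rec.tts_supported,
            rec.polya_motif_found,
        )
        if any(v is None for v in needed):
            raise ValueError(f"record {rec.model.id} is missing computed flags")
        support = tuple(
            junction_support.get(
                (rec.model.chrom, s, e, rec.model.strand), 0
            )
            for s, e in rec.model.introns
        )
        rec.junction_short_read_support = support
        if rec.isoform_class in ("FSM", "ISM"):
            rec.retained = (
                not rec.mispriming
                and not rec.template_switch
                and rec.tss_supported
                and rec.tts_supported
                and rec.polya_motif_found
            )
        else:
            junctions_ok = all(
                canon or supp >= min_junction_reads
                for canon, supp in zip(rec.junction_canonical, support)
            )
            rec.retained = (not rec.mispriming) and junctions_ok
    return records


# ---------------------------------------------------------------------------
# Orchestration + quantification


def build_catalog(
    reads: list[LongRead],
    annotation: Annotation,
    genome: dict[str, str],
    cage_peaks: list,
    polya_sites: list,
    junction_support,
    internal_tol: int = 5,
    end_tol: int = 50,
    min_cluster: int = 3,
    min_junction_reads: int = 10,
    polya_motifs: tuple[str, ...] = ("AATAAA", "ATTAAA"),
) -> list[IsoformRecord]:
    """Collapse reads and run classification, flagging and curation."""
    records = collapse_reads(reads, internal_tol, end_tol, min_cluster)
    for rec in records:
        cls, matched = classify_isoform(rec.model, annotation, end_tol)
        rec.isoform_class = cls
        rec.matched_reference = matched
        if cls in ("FSM", "ISM") and matched:
            ref = annotation.transcripts.get(matched[0])
            if ref is not None and ref.gene_id:
                rec.model = dataclasses.replace(rec.model, gene_id=ref.gene_id)
        rec.mispriming = detect_mispriming(rec.model, genome)
        rec.junction_canonical = junction_canonicality(rec.model, genome)
        rec.template_switch = not all(rec.junction_canonical)
        tss, tts, pa = end_support(
            rec.model, cage_peaks, polya_sites, genome, polya_motifs
        )
        rec.tss_supported = tss
        rec.tts_supported = tts
        rec.polya_motif_found = pa
    curate(records, junction_support, min_junction_reads)
    return records


def catalog_table(records: list[IsoformRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "isoform_id": rec.model.id,
                "chrom": rec.model.chrom,
                "strand": rec.model.strand,
                "n_exons": len(rec.model.exons),
                "start": rec.model.start,
                "end": rec.model.end,
                "read_support": rec.read_support,
                "class": rec.isoform_class,
                "matched_reference": ";".join(rec.matched_reference),
                "mispriming": rec.mispriming,
                "template_switch": rec.template_switch,
                "tss_supported": rec.tss_supported,
                "tts_supported": rec.tts_supported,
                "polya_motif_found": rec.polya_motif_found,
                "retained": rec.retained,
            }
        )
    return pd.DataFrame(rows)


def quantify_isoforms(
    reads: list[LongRead],
    records: list[IsoformRecord],
    internal_tol: int = 5,
) -> pd.DataFrame:
    """Assign each read to its single best-matching catalog isoform and
    report counts and TPM (effective length = summed exon length).

    Best match = most shared junctions (within ``internal_tol`` per
    boundary); ties go to the longest compatible isoform, then to the
    lexicographically smallest id.
    """
    models = [rec.model for rec in records]
    counts = {m.id: 0 for m in models}

    def junction_shared(read: LongRead, model: TranscriptModel) -> int:
        shared = 0
        for rs, re_ in read.introns:
            for ms, me in model.introns:
                if abs(rs - ms) <= internal_tol and abs(re_ - me) <= internal_tol:
                    shared += 1
                    break
        return shared

    def better(a: tuple[int, int, str], b: tuple[int, int, str]) -> bool:
        # more shared junctions, then longer isoform, then smaller id
        if a[0] != b[0]:
            return a[0] > b[0]
        if a[1] != b[1]:
            return a[1] > b[1]
        return a[2] < b[2]

    for read in reads:
        best = None
        for m in models:
            if m.chrom != read.chrom or m.strand != read.strand:
                continue
            score = junction_shared(read, m)
            if len(read.introns) == 0:
                # mono-exon read: containment decides
                score = 1 if (m.start - 50 <= read.start and read.end <= m.end + 50) else 0
            if score == 0:
                continue
            key = (score, m.length, m.id)
            if best is None or better(key, best):
                best = key
        if best is not None:
            counts[best[2]] += 1

    df = pd.DataFrame(
        {
            "isoform_id": [m.id for m in models],
            "length": [m.length for m in models],
            "count": [counts[m.id] for m in models],
        }
    ).set_index("isoform_id")
    rate = df["count"] / df["length"]
    total = rate.sum()
    df["tpm"] = 0.0 if total == 0 else rate / total * 1e6
    return df
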