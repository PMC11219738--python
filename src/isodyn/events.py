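"""Alternative transcription and splicing event annotation.

Each isoform is compared with the gene's hypothetical pre-mRNA (the union
of all exons across its isoforms) and with the other isoforms, yielding
events from the closed vocabulary: ATSS, ATTS, A3, A5, SES (single exon
skipping), MES (multiple exon skipping), MEE (mutually exclusive exons)
and IR (intron retention).  A5/A3 are named in transcript orientation
(A5 = alternative donor).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import Interval, TranscriptModel

EVENT_VOCAB = ("ATSS", "ATTS", "A3", "A5", "SES", "MES", "MEE", "IR")


@dataclass(frozen=True)
class SpliceEventLabel:
    type: str
    coords: tuple[int, ...]
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_VOCAB:
            raise ValueError(f"unknown event type {self.type}")


def build_premrna(isoforms: list[TranscriptModel]) -> tuple[Interval, ...]:
    """Union of all exon intervals, merged where overlapping, in genomic
    order (reverse for transcript orientation on '-')."""
    if not isoforms:
        raise ValueError("no isoforms given")
    intervals = sorted(i for t in isoforms for i in t.exons)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contains_exon(iso: TranscriptModel, union_exon: Interval) -> bool:
    return any(_overlaps(ex, union_exon) for ex in iso.exons)


def annotate_events(
    isoform: TranscriptModel,
    gene_isoforms: list[TranscriptModel],
    end_tol: int = 50,
) -> set[SpliceEventLabel]:
    """Events carried by ``isoform`` relative to its gene's pre-mRNA and
    sibling isoforms.  An isoform may carry several labels; none are
    prioritized over others."""
    ids = [t.id for t in gene_isoforms]
    if isoform.id not in ids:
        raise ValueError(f"{isoform.id} is not an isoform of this gene")
    others = [t for t in gene_isoforms if t.id != isoform.id]
    if not others:
        return set()

    events: set[SpliceEventLabel] = set()
    union = build_premrna(gene_isoforms)
    internal = list(union[1:-1])

    # --- MEE: pairwise witness + no isoform containing both exons
    mee_exons: set[Interval] = set()
    for i, x in enumerate(internal):
        for y in internal[i + 1 :]:
            if _overlaps(x, y):
                continue
            has_x = _contains_exon(isoform, x)
            has_y = _contains_exon(isoform, y)
            if has_x == has_y:
                continue
            mine, theirs = (x, y) if has_x else (y, x)
            witness = next(
                (
                    o
                    for o in others
                    if _contains_exon(o, theirs) and not _contains_exon(o, mine)
                ),
                None,
            )
            if witness is None:
                continue
            if any(
                _contains_exon(t, x) and _contains_exon(t, y) for t in gene_isoforms
            ):
                continue
            events.add(SpliceEventLabel("MEE", x + y, partner=witness.id))
            mee_exons.update((x, y))

    # --- SES / MES: runs of absent internal pre-mRNA exons between
    # retained exons (MEE exons excluded)
    span = (isoform.start, isoform.end)
    absent_run: list[Interval] = []

    def flush_run() -> None:
        run = [e for e in absent_run if e not in mee_exons]
        if len(run) == 1:
            events.add(SpliceEventLabel("SES", run[0]))
        elif len(run) >= 2:
            coords = tuple(x for e in run for x in e)
            events.add(SpliceEventLabel("MES", coords))

    for ux in internal:
        if not _overlaps(ux, span):
            # outside the isoform's span: not between two retained exons
            continue
        if _contains_exon(isoform, ux):
            flush_run()
            absent_run = []
        else:
            absent_run.append(ux)
    # any remaining run lies inside the span, hence between two retained
    # exons (the span limits guarantee flanking isoform exons)
    flush_run()

    # --- IR: an isoform exon strictly covering another isoform's intron
    for ex in isoform.exons:
        for o in others:
            for s, e in o.introns:
                if ex[0] < s and e < ex[1]:
                    events.add(SpliceEventLabel("IR", (s, e)))

    # --- A5 / A3: one intron boundary shared, the other shifted, with
    # overlapping flanking exons (so plain exon skipping does not qualify)
    def exon_ending_at(t: TranscriptModel, pos: int) -> Interval | None:
        return next((ex for ex in t.exons if ex[1] == pos), None)

    def exon_starting_at(t: TranscriptModel, pos: int) -> Interval | None:
        return next((ex for ex in t.exons if ex[0] == pos), None)

    for s1, e1 in isoform.introns:
        for o in others:
            for s2, e2 in o.introns:
                if s1 == s2 and e1 != e2:
                    a = exon_starting_at(isoform, e1)
                    b = exon_starting_at(o, e2)
                    if a and b and _overlaps(a, b):
                        typ = "A3" if isoform.strand == "+" else "A5"
                        events.add(SpliceEventLabel(typ, (min(e1, e2), max(e1, e2))))
                elif e1 == e2 and s1 != s2:
                    a = exon_ending_at(isoform, s1)
                    b = exon_ending_at(o, s2)
                    if a and b and _overlaps(a, b):
                        typ = "A5" if isoform.strand == "+" else "A3"
                        events.add(SpliceEventLabel(typ, (min(s1, s2), max(s1, s2))))

    # --- ATSS / ATTS: outer boundary away from every other isoform's
    if all(abs(isoform.tss - o.tss) > end_tol for o in others):
        events.add(SpliceEventLabel("ATSS", (isoform.tss,)))
    if all(abs(isoform.tts - o.tts) > end_tol for o in others):
        events.add(SpliceEventLabel("ATTS", (isoform.tts,)))

    return events


def annotate_gene(
    gene_isoforms: list[TranscriptModel], end_tol: int = 50
) -> dict[str, set[SpliceEventLabel]]:
    return {
        t.id: annotate_events(t, gene_isoforms, end_tol) for t in gene_isoforms
    }


def events_table(events_by_isoform: dict[str, set[SpliceEventLabel]],
                 gene_of: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for iso, evs in sorted(events_by_isoform.items()):
        for ev in sorted(evs, key=lambda e: (e.type, e.coords)):
            rows.append(
                {
                    "isoform_id": iso,
                    "gene_id": (gene_of or {}).get(iso, ""),
                    "event_type": ev.type,
                    "coords": ",".join(map(str, ev.coords)),
                    "partner": ev.partner or "",
                }
            )
    return pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "event_type", "coords", "partner"]
    )


def select_switch_pairs(usage: pd.DataFrame) -> list[tuple[str, str]]:
    """For each gene with a significant usage change, pair the most
    upregulated (max dIF) with the most downregulated (min dIF) isoform."""
    pairs = []
    for gid, sub in usage.groupby("gene_id"):
        if not sub["significant"].any():
            continue
        up = sub.loc[sub["dIF"].idxmax(), "isoform_id"]
        down = sub.loc[sub["dIF"].idxmin(), "isoform_id"]
        if up != down:
            pairs.append((up, down))
    return pairs


def gain_loss_summary(
    pairs: list[tuple[str, str]],
    events_by_isoform: dict[str, set[SpliceEventLabel]],
) -> pd.DataFrame:
    """Events gained (present in the up-isoform only) and lost (down-only)
    per type, with fractions over the number of isoform pairs."""
    gained = {t: 0 for t in EVENT_VOCAB}
    lost = {t: 0 for t in EVENT_VOCAB}
    for up, down in pairs:
        up_types = {e.type for e in events_by_isoform.get(up, set())}
        down_types = {e.type for e in events_by_isoform.get(down, set())}
        for t in up_types - down_types:
            gained[t] += 1
        for t in down_types - up_types:
            lost[t] += 1
    n = max(len(pairs), 1)
    return pd.DataFrame(
        {
            "event_type": list(EVENT_VOCAB),
            "gained": [gained[t] for t in EVENT_VOCAB],
            "lost": [lost[t] for t in EVENT_VOCAB],
            "gained_frac": [gained[t] / n for t in EVENT_VOCAB],
            "lost_frac": [lost[t] / n for t in EVENT_VOCAB],
        }
    )
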