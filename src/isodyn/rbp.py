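"""Positional RBP analysis around cassette exons.

Eight sequence segments are cut around each skipping event (50 bp of the
flanking exon ends and target exon ends, 250 bp of each intron end);
consensus-motif coverage is summarized in a 50-bp sliding window as a
percent score, included/excluded event sets are compared with the
unregulated background position-by-position by rank-sum test (region call
at min-p < 0.001), and CLIP peak density is compared with Fisher's exact
test (region call at min-p < 0.05).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import IUPAC, revcomp
from .models import Interval, SkippingEvent

# (name, feature, side, kind): side refers to transcript orientation
SEGMENT_DEFS = (
    ("upExon3p", "upstream_exon", "3p", "exon"),
    ("upIntron5p", "upstream_intron", "5p", "intron"),
    ("upIntron3p", "upstream_intron", "3p", "intron"),
    ("target5p", "target_exon", "5p", "exon"),
    ("target3p", "target_exon", "3p", "exon"),
    ("dnIntron5p", "downstream_intron", "5p", "intron"),
    ("dnIntron3p", "downstream_intron", "3p", "intron"),
    ("dnExon5p", "downstream_exon", "5p", "exon"),
)
SEGMENT_NAMES = tuple(d[0] for d in SEGMENT_DEFS)


@dataclass(frozen=True)
class Segment:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str | None = None


@dataclass
class SegmentSet:
    event_id: str
    segments: dict[str, Segment] = field(default_factory=dict)


def _feature_interval(event: SkippingEvent, feature: str) -> Interval:
    return {
        "upstream_exon": event.upstream_exon,
        "upstream_intron": event.upstream_intron,
        "target_exon": event.target_exon,
        "downstream_intron": event.downstream_intron,
        "downstream_exon": event.downstream_exon,
    }[feature]


def _clip_side(iv: Interval, strand: str, side: str, k: int) -> Interval:
    """First k bases of the 5' or 3' side of a feature, transcript strand."""
    s, e = iv
    want_genomic_left = (strand == "+") == (side == "5p")
    if want_genomic_left:
        return (s, min(e, s + k))
    return (max(s, e - k), e)


def segment_coordinates(
    event: SkippingEvent, exon_offset: int = 50, intron_offset: int = 250
) -> dict[str, tuple[str, int, int, str]]:
    """Genomic coordinates of the eight segments (clipped to feature
    length); segments of a short intron may overlap."""
    out = {}
    for name, feature, side, kind in SEGMENT_DEFS:
        k = exon_offset if kind == "exon" else intron_offset
        s, e = _clip_side(_feature_interval(event, feature), event.strand, side, k)
        out[name] = (event.chrom, s, e, event.strand)
    return out


def extract_segments(
    event: SkippingEvent,
    genome: dict[str, str],
    exon_offset: int = 50,
    intron_offset: int = 250,
) -> SegmentSet:
    """Cut the eight segments; sequences are transcript-strand oriented so
    position 0 is always the 5'-most base of the segment."""
    coords = segment_coordinates(event, exon_offset, intron_offset)
    ss = SegmentSet(event_id=event.id)
    for name, (chrom, s, e, strand) in coords.items():
        seq = genome[chrom][s:e].upper()
        if strand == "-":
            seq = revcomp(seq)
        ss.segments[name] = Segment(name, chrom, s, e, strand, seq)
    return ss


# ---------------------------------------------------------------------------
# Motif scanning


def iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_motif(sequence: str, motif: str) -> np.ndarray:
    """0/1 coverage mask: positions inside at least one (possibly
    overlapping) match of the IUPAC motif."""
    seq = sequence.upper().replace("U", "T")
    mask = np.zeros(len(seq), dtype=np.int8)
    pattern = re.compile(f"(?=({iupac_regex(motif)}))")
    for m in pattern.finditer(seq):
        mask[m.start() : m.start() + len(m.group(1))] = 1
    return mask


def window_scores(mask: np.ndarray, window: int = 50) -> np.ndarray:
    """Percent of covered bases in the window centered at each position,
    using only the bases actually available near the edges."""
    n = len(mask)
    half = window // 2
    csum = np.concatenate([[0], np.cumsum(mask)])
    pos = np.arange(n)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + (window - half), n)
    covered = csum[hi] - csum[lo]
    return 100.0 * covered / (hi - lo)


def motif_score_matrix(
    segment_sets: list[SegmentSet], segment: str, motif: str, window: int = 50
) -> np.ndarray:
    """Events x positions matrix of window scores for one segment (NaN
    where an event's clipped segment is shorter)."""
    if not segment_sets:
        raise ValueError("empty event set")
    lengths = [len(ss.segments[segment].sequence or "") for ss in segment_sets]
    L = max(lengths)
    out = np.full((len(segment_sets), L), np.nan)
    for i, ss in enumerate(segment_sets):
        seq = ss.segments[segment].sequence or ""
        if seq:
            out[i, : len(seq)] = window_scores(scan_motif(seq, motif), window)
    return out


def motif_score_profile(
    segment_sets: list[SegmentSet], segment: str, motif: str, window: int = 50
) -> np.ndarray:
    """Per-position mean window score over events."""
    return np.nanmean(motif_score_matrix(segment_sets, segment, motif, window), axis=0)


# ---------------------------------------------------------------------------
# Positional tests


@dataclass
class MotifProfile:
    rbp: str
    motif: str
    profiles: dict[str, dict[str, np.ndarray]]       # segment -> set -> mean profile
    pvalues: dict[str, dict[str, np.ndarray]]        # segment -> comparison -> per-pos p
    region_min_p: dict[str, dict[str, float]]        # segment -> comparison -> min p
    enriched: dict[str, dict[str, bool]]


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _ranksum_p_columns(reg: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Per-column two-sided rank-sum p-values (constant columns get 1)."""
    L = min(reg.shape[1], bg.shape[1])
    reg, bg = reg[:, :L], bg[:, :L]
    if np.isnan(reg).any() or np.isnan(bg).any():
        return np.array([_ranksum_p(reg[:, j], bg[:, j]) for j in range(L)])
    ps = stats.mannwhitneyu(reg, bg, alternative="two-sided", axis=0).pvalue
    both = np.vstack([reg, bg])
    constant = np.ptp(both, axis=0) == 0
    ps = np.where(constant | ~np.isfinite(ps), 1.0, ps)
    return ps


def positional_motif_test(
    included: list[SegmentSet],
    excluded: list[SegmentSet],
    background: list[SegmentSet],
    motif: str,
    rbp: str = "RBP",
    window: int = 50,
    alpha: float = 0.001,
) -> MotifProfile:
    """Rank-sum comparison of per-event window scores, regulated set vs
    background, at every position of every segment; a segment is flagged
    enriched when its minimum p-value drops below ``alpha``."""
    profiles, pvalues, minp, enriched = {}, {}, {}, {}
    for seg in SEGMENT_NAMES:
        bg = motif_score_matrix(background, seg, motif, window)
        profiles[seg] = {"background": np.nanmean(bg, axis=0)}
        pvalues[seg], minp[seg], enriched[seg] = {}, {}, {}
        for name, evset in (("included", included), ("excluded", excluded)):
            if not evset:
                continue
            reg = motif_score_matrix(evset, seg, motif, window)
            profiles[seg][name] = np.nanmean(reg, axis=0)
            ps = _ranksum_p_columns(reg, bg)
            pvalues[seg][name] = ps
            minp[seg][name] = float(ps.min()) if len(ps) else 1.0
            enriched[seg][name] = minp[seg][name] < alpha
    return MotifProfile(rbp, motif, profiles, pvalues, minp, enriched)


# ---------------------------------------------------------------------------
# CLIP peak density


@dataclass
class PeakDensityProfile:
    rbp: str
    density: dict[str, dict[str, np.ndarray]]
    pvalues: dict[str, dict[str, np.ndarray]]
    region_min_p: dict[str, dict[str, float]]
    enriched: dict[str, dict[str, bool]]


def _peak_mask(ss: SegmentSet, segment: str, peaks: list) -> np.ndarray:
    seg = ss.segments[segment]
    n = seg.end - seg.start
    mask = np.zeros(n, dtype=np.int8)
    for chrom, ps, pe, *_rest in peaks:
        if chrom != seg.chrom:
            continue
        lo, hi = max(ps, seg.start), min(pe, seg.end)
        if lo < hi:
            mask[lo - seg.start : hi - seg.start] = 1
    if seg.strand == "-":
        mask = mask[::-1]
    return mask


def peak_mask_matrix(
    segment_sets: list[SegmentSet], segment: str, peaks: list
) -> np.ndarray:
    if not segment_sets:
        raise ValueError("empty event set")
    L = max(ss.segments[segment].end - ss.segments[segment].start for ss in segment_sets)
    out = np.full((len(segment_sets), L), np.nan)
    for i, ss in enumerate(segment_sets):
        m = _peak_mask(ss, segment, peaks)
        out[i, : len(m)] = m
    return out


@lru_cache(maxsize=100_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_position_p(reg: np.ndarray, bg: np.ndarray) -> float:
    """Fisher 2x2 on has-site/has-not at one position."""
    reg = reg[~np.isnan(reg)]
    bg = bg[~np.isnan(bg)]
    a, b = int(reg.sum()), len(reg) - int(reg.sum())
    c, d = int(bg.sum()), len(bg) - int(bg.sum())
    return _fisher_cached(a, b, c, d)


def peak_density_test(
    included: list[SegmentSet],
    excluded: list[SegmentSet],
    background: list[SegmentSet],
    peaks: list,
    rbp: str = "RBP",
    alpha: float = 0.05,
) -> PeakDensityProfile:
    """Per-position fraction of events with a binding site, compared with
    the background by Fisher's exact test; region call at min-p < alpha."""
    density, pvalues, minp, enriched = {}, {}, {}, {}
    for seg in SEGMENT_NAMES:
        bg = peak_mask_matrix(background, seg, peaks)
        density[seg] = {"background": np.nanmean(bg, axis=0)}
        pvalues[seg], minp[seg], enriched[seg] = {}, {}, {}
        for name, evset in (("included", included), ("excluded", excluded)):
            if not evset:
                continue
            reg = peak_mask_matrix(evset, seg, peaks)
            density[seg][name] = np.nanmean(reg, axis=0)
            L = min(reg.shape[1], bg.shape[1])
            ps = np.array([fisher_position_p(reg[:, j], bg[:, j]) for j in range(L)])
            pvalues[seg][name] = ps
            minp[seg][name] = float(ps.min()) if len(ps) else 1.0
            enriched[seg][name] = minp[seg][name] < alpha
    return PeakDensityProfile(rbp, density, pvalues, minp, enriched)


# ---------------------------------------------------------------------------
# Summary


def rbp_summary(
    motif_profiles: dict[tuple[str, str], MotifProfile],
    peak_profiles: dict[tuple[str, str], PeakDensityProfile] | None = None,
    motif_alpha: float = 0.001,
    peak_alpha: float = 0.05,
) -> pd.DataFrame:
    """Long table over (RBP, comparison, segment, regulated set): motif
    min-p, peak min-p and the co-occurrence flag (both enriched in the
    same region)."""
    peak_profiles = peak_profiles or {}
    rows = []
    for (rbp, comparison), mp in sorted(motif_profiles.items()):
        pp = peak_profiles.get((rbp, comparison))
        for seg in SEGMENT_NAMES:
            for name in ("included", "excluded"):
                if name not in mp.region_min_p[seg]:
                    continue
                motif_p = mp.region_min_p[seg][name]
                peak_p = (
                    pp.region_min_p[seg].get(name, np.nan) if pp is not None else np.nan
                )
                rows.append(
                    {
                        "rbp": rbp,
                        "comparison": comparison,
                        "segment": seg,
                        "set": name,
                        "motif_min_p": motif_p,
                        "peak_min_p": peak_p,
                        "motif_enriched": motif_p < motif_alpha,
                        "peak_enriched": bool(peak_p < peak_alpha)
                        if not np.isnan(peak_p)
                        else False,
                        "co_occurrence": motif_p < motif_alpha
                        and not np.isnan(peak_p)
                        and peak_p < peak_alpha,
                    }
                )
    return pd.DataFrame(rows)
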