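"""Synthetic multi-omics generator with planted ground truth.

Everything the pipeline consumes can be produced here: a reference
annotation whose genes carry planted alternative transcription/splicing
events, long reads with planted artifact classes (truncation, oligo-dT
mispriming into A-rich genomic tracts, RT template switching, fusions),
a day 0..5 triplicate count design with planted isoform-usage switches,
cassette-exon junction counts around planted inclusion levels, RBP motif
occurrences written into defined segments, and isoform-resolved peptide
tables with intensity-dependent (MNAR) missingness.

A fixed seed makes every output bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CANONICAL_INTRON_DINUCS, junction_dinucleotides
from .io import IUPAC, revcomp
from .models import (
    Annotation,
    ExpressionMatrix,
    GeneModel,
    Interval,
    LongRead,
    SkippingEvent,
    TranscriptModel,
    make_design,
)

EVENT_TYPES = ("SES", "MES", "MEE", "IR", "A5", "A3", "ATSS", "ATTS")


@dataclass
class SimulationConfig:
    """Knobs of the study-shaped simulation.

    Defaults mirror the study design: a 6-point differentiation time
    course (days 0-5) with 3 replicates, and usage switches of dIF 0.4
    planted in a fraction of multi-isoform genes.
    """

    seed: int = 0
    n_genes: int = 24
    isoforms_per_gene: tuple[int, int] = (2, 2)
    n_days: int = 6
    replicates_per_day: int = 3
    artifact_rates: dict = field(
        default_factory=lambda: {
            "mispriming": 0.0,
            "template_switch": 0.0,
            "truncation": 0.0,
            "fusion": 0.0,
        }
    )
    switch_fraction: float = 0.3
    switch_dif: float = 0.4
    motif_plant: dict = field(
        default_factory=lambda: {
            "motif": "TTTTT",
            "segment": "dnIntron5p",
            "fraction": 0.0,
            "copies": 3,
        }
    )
    peptide_missingness: float = 0.1
    event_types: tuple[str, ...] = EVENT_TYPES
    internal_jitter: int = 0
    end_jitter: int = 0
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        for name, rate in self.artifact_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate {name}={rate} outside [0, 1]")
        if sum(self.artifact_rates.values()) > 1.0 + 1e-12:
            raise ValueError("artifact rates sum to more than 1")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction outside [0, 1]")
        if not 0.0 <= self.peptide_missingness <= 1.0:
            raise ValueError("peptide_missingness outside [0, 1]")
        if self.n_days < 2:
            raise ValueError("need at least 2 days")
        if self.replicates_per_day < 2:
            raise ValueError("need at least 2 replicates per day")
        lo, hi = self.isoforms_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid isoforms_per_gene range")
        unknown = set(self.event_types) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")


@dataclass
class Reference:
    """Bundled reference outputs: annotation, genome and truth tracks."""

    annotation: Annotation
    genome: dict[str, str]
    cage_peaks: list[tuple[str, int, int, str, str]]
    polya_sites: list[tuple[str, int, int, str, str]]
    traps: dict[str, dict]
    planted_events: dict[str, str]
    config: SimulationConfig


class GenerationError(ValueError):
    """Raised when a requested gene geometry is impossible."""


# ---------------------------------------------------------------------------
# Reference generation


def _transcript_exons(exons: tuple[Interval, ...], strand: str) -> list[Interval]:
    """Exons in transcript (5'->3') order."""
    return list(exons) if strand == "+" else list(reversed(exons))


def _genomic_exons(exons: list[Interval], strand: str) -> tuple[Interval, ...]:
    ex = tuple(sorted(exons))
    for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
        if s2 < e1:
            raise GenerationError(f"exon overlap within one isoform: {ex}")
    return ex


def _build_gene(
    rng: np.random.Generator,
    gid: str,
    chrom: str,
    strand: str,
    cursor: int,
    event_type: str,
    n_isoforms: int,
) -> tuple[GeneModel, int]:
    """Lay out one gene left-to-right from ``cursor`` and plant one
    alternative event between the canonical isoform and isoform 2."""
    n_exons = int(rng.integers(6, 8))
    exon_lens = [400] + [int(rng.integers(90, 151)) for _ in range(n_exons - 2)] + [400]
    intron_lens = [int(rng.integers(520, 801)) for _ in range(n_exons - 1)]

    mee_extra: Interval | None = None
    pos = cursor
    slots: list[Interval] = []
    for i, L in enumerate(exon_lens):
        slots.append((pos, pos + L))
        pos += L
        if i < n_exons - 1:
            pos += intron_lens[i]
    gene_end = pos

    # transcript-orientation view of the genomic slots
    t_slots = _transcript_exons(tuple(slots), strand)
    target = 2  # internal exon index (transcript orientation) used by most plants

    canonical = list(t_slots)
    variant: list[Interval] | None = None

    if n_isoforms >= 2:
        if event_type == "SES":
            variant = canonical[:target] + canonical[target + 1 :]
        elif event_type == "MES":
            variant = canonical[:target] + canonical[target + 2 :]
        elif event_type == "IR":
            a, b = canonical[target], canonical[target + 1]
            lo = min(a[0], b[0])
            hi = max(a[1], b[1])
            variant = canonical[:target] + [(lo, hi)] + canonical[target + 2 :]
        elif event_type == "A5":
            # shift the donor of the intron after `target` 30 nt into the exon
            s, e = canonical[target]
            variant = list(canonical)
            variant[target] = (s, e - 30) if strand == "+" else (s + 30, e)
        elif event_type == "A3":
            s, e = canonical[target + 1]
            variant = list(canonical)
            variant[target + 1] = (s + 30, e) if strand == "+" else (s, e - 30)
        elif event_type == "ATSS":
            s, e = canonical[0]
            variant = list(canonical)
            variant[0] = (s + 300, e) if strand == "+" else (s, e - 300)
        elif event_type == "ATTS":
            s, e = canonical[-1]
            variant = list(canonical)
            variant[-1] = (s, e - 300) if strand == "+" else (s + 300, e)
        elif event_type == "MEE":
            # replace exon `target` (X) by a fresh slot Y in isoform 2;
            # Y sits inside the downstream intron of X
            s, e = canonical[target]
            if strand == "+":
                y = (e + 180, e + 180 + 120)
            else:
                y = (s - 180 - 120, s - 180)
            mee_extra = y
            variant = canonical[:target] + [y] + canonical[target + 1 :]
        else:  # pragma: no cover
            raise GenerationError(f"unknown event type {event_type}")

    isoforms = [
        TranscriptModel(
            id=f"{gid}.1",
            chrom=chrom,
            strand=strand,
            exons=_genomic_exons(canonical, strand),
            gene_id=gid,
        )
    ]
    if variant is not None:
        isoforms.append(
            TranscriptModel(
                id=f"{gid}.2",
                chrom=chrom,
                strand=strand,
                exons=_genomic_exons(variant, strand),
                gene_id=gid,
            )
        )
    # extra isoforms: additional single-exon skips at other internal exons
    extra_idx = 3
    while len(isoforms) < n_isoforms and extra_idx < n_exons - 1:
        alt = canonical[:extra_idx] + canonical[extra_idx + 1 :]
        isoforms.append(
            TranscriptModel(
                id=f"{gid}.{len(isoforms) + 1}",
                chrom=chrom,
                strand=strand,
                exons=_genomic_exons(alt, strand),
                gene_id=gid,
            )
        )
        extra_idx += 1

    gene = GeneModel(id=gid, chrom=chrom, strand=strand, isoforms=tuple(isoforms))
    if mee_extra is not None:
        gene_end = max(gene_end, mee_extra[1])
    return gene, gene_end


def _plant(seq: list[str], pos: int, s: str) -> None:
    seq[pos : pos + len(s)] = list(s)


def _sanitize_window(rng: np.random.Generator, seq: list[str], start: int, end: int) -> None:
    """Rewrite [start, end) with low-A content so it cannot look like a
    mispriming tract."""
    start = max(start, 0)
    end = min(end, len(seq))
    bases = rng.choice(list("ACGT"), size=end - start, p=[0.1, 0.3, 0.3, 0.3])
    seq[start:end] = list(bases)


def generate_reference(config: SimulationConfig) -> Reference:
    """Build the annotation, genome, CAGE/polyA tracks and artifact traps.

    Gene structures instantiate the planted event types in rotation; the
    genome carries canonical GT-AG dinucleotides at every annotated
    junction, an AATAAA motif just upstream of every transcript 3' end,
    and (when mispriming is simulated) a 70%-A 20-nt tract a short
    distance downstream of an internal donor exon end.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genes: dict[str, GeneModel] = {}
    planted: dict[str, str] = {}
    cursor = 1000
    lo, hi = config.isoforms_per_gene
    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        ev = config.event_types[i % len(config.event_types)]
        n_iso = int(rng.integers(lo, hi + 1))
        gene, gene_end = _build_gene(rng, gid, chrom, strand, cursor, ev, n_iso)
        genes[gid] = gene
        planted[gid] = ev if len(gene.isoforms) >= 2 else "none"
        cursor = gene_end + 2000

    seq = list(rng.choice(list("ACGT"), size=cursor + 1000))
    annotation = Annotation(genes=genes)

    # mispriming traps: 20-nt 70%-A tract 3-40 nt downstream (transcript
    # orientation) of the canonical isoform's second exon
    traps: dict[str, dict] = {}
    want_traps = config.artifact_rates.get("mispriming", 0.0) > 0
    for gid, gene in genes.items():
        canonical = gene.isoforms[0]
        t_ex = _transcript_exons(canonical.exons, gene.strand)
        exon = t_ex[1]
        d = int(rng.integers(3, 41))
        if gene.strand == "+":
            tract = (exon[1] + d, exon[1] + d + 20)
        else:
            tract = (exon[0] - d - 20, exon[0] - d)
        if want_traps:
            # exactly 70% A so the tract always clears the 60% rule
            bases = list("A" * 14) + [str(b) for b in rng.choice(list("CGT"), size=6)]
            rng.shuffle(bases)
            tract_seq = "".join(bases)
            if gene.strand == "-":
                tract_seq = revcomp(tract_seq)
            _plant(seq, tract[0], tract_seq)
            traps[gid] = {"exon": exon, "tract": tract, "exon_t_index": 1}

    # canonical dinucleotides at every annotated junction
    for gene in genes.values():
        for t in gene.isoforms:
            for s, e in t.introns:
                if gene.strand == "+":
                    _plant(seq, s, "GT")
                    _plant(seq, e - 2, "AG")
                else:
                    _plant(seq, s, "CT")
                    _plant(seq, e - 2, "AC")

    # polyA motif ~20 nt upstream of each TTS; de-A-rich the 20 nt
    # downstream of each TTS so real ends never look misprimed
    cage, polya = [], []
    for gene in genes.values():
        for t in gene.isoforms:
            if gene.strand == "+":
                _plant(seq, t.tts - 26, "AATAAA")
                _sanitize_window(rng, seq, t.tts, t.tts + 20)
            else:
                _plant(seq, t.tts + 20, revcomp("AATAAA"))
                _sanitize_window(rng, seq, t.tts - 20, t.tts)
            cage.append((chrom, max(t.tss - 10, 0), t.tss + 10, f"cage_{t.id}", t.strand))
            polya.append((chrom, max(t.tts - 10, 0), t.tts + 10, f"pa_{t.id}", t.strand))

    return Reference(
        annotation=annotation,
        genome={chrom: "".join(seq)},
        cage_peaks=cage,
        polya_sites=polya,
        traps=traps,
        planted_events=planted,
        config=config,
    )


# ---------------------------------------------------------------------------
# Long reads


def _template_switch_variant(
    model: TranscriptModel, genome: dict[str, str], annotated_donors: set[tuple[str, int]]
) -> tuple[Interval, ...]:
    """Shift one donor into its intron until the junction is non-canonical
    and the new donor site is unannotated."""
    introns = model.introns
    j = len(introns) // 2
    s, e = introns[j]
    # shift beyond the default collapse tolerance so switch reads form
    # their own clusters instead of folding into the clean isoform
    for d in range(8, 60):
        if model.strand == "+":
            new_intron = (s + d, e)
            donor_pos = s + d
        else:
            new_intron = (s, e - d)
            donor_pos = e - d
        if new_intron[1] - new_intron[0] < 30:
            break
        dinucs = junction_dinucleotides(genome, model.chrom, model.strand, new_intron)
        if dinucs in CANONICAL_INTRON_DINUCS:
            continue
        if (model.strand, donor_pos) in annotated_donors:
            continue
        exons = list(model.exons)
        if model.strand == "+":
            exons[j] = (exons[j][0], s + d)
        else:
            exons[j + 1] = (e - d, exons[j + 1][1])
        return tuple(exons)
    raise GenerationError(f"no template-switch variant found for {model.id}")


def _mispriming_variant(model: TranscriptModel, trap: dict) -> tuple[Interval, ...]:
    t_ex = _transcript_exons(model.exons, model.strand)
    k = trap["exon_t_index"]
    kept = t_ex[: k + 1]
    t0, t1 = trap["tract"]
    if model.strand == "+":
        kept[-1] = (kept[-1][0], t0)
    else:
        kept[-1] = (t1, kept[-1][1])
    return tuple(sorted(kept))


def _truncation_variant(model: TranscriptModel) -> tuple[Interval, ...]:
    if len(model.exons) < 3:
        raise GenerationError("cannot truncate a transcript with < 3 exons")
    return model.exons[1:] if model.strand == "+" else model.exons[:-1]


def _fusion_partner_map(annotation: Annotation) -> dict[str, str]:
    out = {}
    by_strand: dict[tuple[str, str], list[GeneModel]] = {}
    for g in annotation.genes.values():
        by_strand.setdefault((g.chrom, g.strand), []).append(g)
    for key, gs in by_strand.items():
        gs = sorted(gs, key=lambda g: g.start)
        if len(gs) < 2:
            continue
        for i, g in enumerate(gs):
            out[g.id] = gs[(i + 1) % len(gs)].id
    return out


def simulate_long_reads(
    reference: Reference,
    n_reads: int,
    artifact_rates: dict[str, float] | None = None,
    seed: int = 0,
    abundances: dict[str, float] | None = None,
    internal_jitter: int = 0,
    end_jitter: int = 0,
) -> list[LongRead]:
    """Draw reads from isoforms with planted artifact classes.

    Artifact variants are deterministic per isoform so that artifact
    reads form collapsible clusters, as RT artifacts do in real libraries
    (the same trap or switch site is hit repeatedly).
    """
    config = reference.config
    rates = dict(artifact_rates if artifact_rates is not None else config.artifact_rates)
    if any(not 0 <= r <= 1 for r in rates.values()) or sum(rates.values()) > 1 + 1e-12:
        raise ValueError("artifact rates must be in [0,1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    annotation = reference.annotation
    transcripts = sorted(annotation.transcripts)
    if abundances is not None:
        if any(v < 0 for v in abundances.values()):
            raise ValueError("abundances must be nonnegative")
        weights = np.array([abundances.get(t, 0.0) for t in transcripts], dtype=float)
    else:
        weights = np.ones(len(transcripts))
    weights = weights / weights.sum()

    labels = ["mispriming", "template_switch", "truncation", "fusion"]
    probs = [rates.get(k, 0.0) for k in labels]
    probs.append(1.0 - sum(probs))
    labels.append("clean")

    annotated_donors = {
        (t.strand, d) for t in annotation.transcripts.values() for d in t.donors()
    }
    partner = _fusion_partner_map(annotation)
    ts_cache: dict[str, tuple[Interval, ...]] = {}

    iso_idx = rng.choice(len(transcripts), size=n_reads, p=weights)
    lab_idx = rng.choice(len(labels), size=n_reads, p=np.array(probs) / sum(probs))

    reads: list[LongRead] = []
    for i in range(n_reads):
        tid = transcripts[iso_idx[i]]
        model = annotation.transcripts[tid]
        label = labels[lab_idx[i]]
        gene = model.gene_id
        if label == "mispriming":
            trap = reference.traps.get(gene)
            if trap is None:
                raise GenerationError(
                    f"mispriming requested but no trap planted for {gene}; "
                    "set a positive mispriming rate before generate_reference"
                )
            exons = _mispriming_variant(model, trap)
        elif label == "template_switch":
            if tid not in ts_cache:
                ts_cache[tid] = _template_switch_variant(
                    model, reference.genome, annotated_donors
                )
            exons = ts_cache[tid]
        elif label == "truncation":
            exons = _truncation_variant(model)
        elif label == "fusion":
            other = annotation.genes[partner[gene]].isoforms[0]
            exons = tuple(sorted(model.exons + other.exons))
        else:
            exons = model.exons

        exons = [list(e) for e in exons]
        if internal_jitter > 0:
            for k in range(len(exons)):
                if k > 0:
                    exons[k][0] += int(rng.integers(-internal_jitter, internal_jitter + 1))
                if k < len(exons) - 1:
                    exons[k][1] += int(rng.integers(-internal_jitter, internal_jitter + 1))
        if end_jitter > 0:
            exons[0][0] += int(rng.integers(-end_jitter, end_jitter + 1))
            exons[-1][1] += int(rng.integers(-end_jitter, end_jitter + 1))
        fixed = []
        prev_end = None
        for s, e in exons:
            if prev_end is not None:
                s = max(s, prev_end + 5)
            e = max(e, s + 5)
            fixed.append((s, e))
            prev_end = e
        reads.append(
            LongRead(
                id=f"read_{i:06d}",
                chrom=model.chrom,
                strand=model.strand,
                exons=tuple(fixed),
                source_isoform=tid,
                truth_label=label,
            )
        )
    return reads


def junction_support_table(
    annotation: Annotation, seed: int = 0, mean_support: float = 60.0
) -> pd.DataFrame:
    """Short-read support for every annotated junction (and nothing else)."""
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    for t in annotation.transcripts.values():
        for s, e in t.introns:
            key = (t.chrom, s, e, t.strand)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "chrom": t.chrom,
                    "start": s,
                    "end": e,
                    "strand": t.strand,
                    "reads": int(rng.poisson(mean_support)) + 10,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "reads"])


# ---------------------------------------------------------------------------
# Counts


def make_switch_plan(
    annotation: Annotation,
    switch_fraction: float,
    switch_dif: float,
    n_days: int,
    seed: int = 0,
) -> dict[str, dict]:
    """Pick genes whose isoform usage flips by ``switch_dif`` between the
    first and last day (linear in between)."""
    rng = np.random.default_rng(seed)
    eligible = sorted(g.id for g in annotation.genes.values() if len(g.isoforms) >= 2)
    k = int(round(switch_fraction * len(eligible)))
    chosen = sorted(rng.permutation(eligible)[:k].tolist())
    plan = {}
    for gid in chosen:
        iso = [t.id for t in annotation.genes[gid].isoforms]
        plan[gid] = {
            "iso_down": iso[0],
            "iso_up": iso[1],
            "dif": switch_dif,
            "day_from": 0,
            "day_to": n_days - 1,
        }
    return plan


def _isoform_fractions(
    gene: GeneModel, plan: dict | None, day: int, n_days: int, rng: np.random.Generator,
    base: dict[str, np.ndarray],
) -> np.ndarray:
    iso = [t.id for t in gene.isoforms]
    k = len(iso)
    if gene.id not in base:
        if plan is None:
            f = rng.dirichlet(np.full(k, 5.0))
        else:
            rest = 0.1 * (k - 2)
            f = np.full(k, 0.1)
            f[0] = (1 - rest) / 2 + plan["dif"] / 2
            f[1] = (1 - rest) / 2 - plan["dif"] / 2
        base[gene.id] = f
    f = base[gene.id].copy()
    if plan is not None:
        t0, t1 = plan["day_from"], plan["day_to"]
        frac = min(max((day - t0) / (t1 - t0), 0.0), 1.0)
        shift = plan["dif"] * frac
        f[0] -= shift
        f[1] += shift
    return f


def simulate_counts(
    annotation: Annotation,
    n_days: int = 6,
    replicates: int = 3,
    switch_plan: dict[str, dict] | None = None,
    seed: int = 0,
    dispersion: float = 0.05,
    mean_log: float = np.log(300.0),
    libsize_range: tuple[float, float] = (0.8, 1.25),
) -> ExpressionMatrix:
    """Negative-binomial isoform counts over the time-course design.

    Variance model is mu + dispersion * mu^2 (gamma-Poisson); at
    dispersion == 0 the noise-free limit round(mu) is emitted.
    """
    switch_plan = switch_plan or {}
    rng = np.random.default_rng(seed)
    design = make_design(n_days, replicates)
    samples = list(design.index)
    if libsize_range[0] == libsize_range[1]:
        lib = np.full(len(samples), libsize_range[0])
    else:
        lib = rng.uniform(libsize_range[0], libsize_range[1], size=len(samples))
    gene_mean = {
        gid: float(np.exp(rng.normal(mean_log, 0.7)))
        for gid in sorted(annotation.genes)
    }
    base_fracs: dict[str, np.ndarray] = {}
    rows = {}
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        plan = switch_plan.get(gid)
        iso_ids = [t.id for t in gene.isoforms]
        lengths = np.array([t.length for t in gene.isoforms], dtype=float)
        mat = np.zeros((len(iso_ids), len(samples)))
        for si, sample in enumerate(samples):
            day = int(design.loc[sample, "day"])
            f = _isoform_fractions(gene, plan, day, n_days, rng, base_fracs)
            # fractions are isoform fractions on the TPM scale: expected
            # counts are proportional to fraction x length
            w = f * lengths
            mu = gene_mean[gid] * (w / w.sum()) * lib[si]
            if dispersion == 0:
                mat[:, si] = np.round(mu)
            else:
                lam = rng.gamma(1.0 / dispersion, mu * dispersion)
                mat[:, si] = rng.poisson(lam)
        for ii, tid in enumerate(iso_ids):
            rows[tid] = mat[ii]
    data = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(data=data, design=design, kind="counts")


# ---------------------------------------------------------------------------
# Junction counts


def simulate_junction_counts(
    event_ids: list[str],
    psi_by_day: pd.DataFrame,
    depth: int = 100,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial junction counts around planted inclusion levels.

    ``psi_by_day``: events x days matrix of true Ψ.  Each replicate gets
    two inclusion-junction counts ~ Binomial(depth, Ψ) and one skipping
    count ~ Binomial(depth, 1-Ψ).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for eid in event_ids:
        for day in psi_by_day.columns:
            psi = float(psi_by_day.loc[eid, day])
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "event_id": eid,
                        "day": int(day),
                        "replicate": rep,
                        "inc1": int(rng.binomial(depth, psi)),
                        "inc2": int(rng.binomial(depth, psi)),
                        "skip": int(rng.binomial(depth, 1.0 - psi)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standalone cassette events (for positional RBP analyses)


def make_cassette_events(
    n_events: int,
    seed: int = 0,
    exon_len: int = 120,
    intron_len: int = 700,
    chrom: str = "chrS",
    strand_mix: bool = True,
) -> tuple[dict[str, str], list[SkippingEvent]]:
    """Self-contained cassette-exon events on their own chromosome, spaced
    so that all eight segments are full length and non-overlapping."""
    rng = np.random.default_rng(seed)
    events = []
    pos = 100
    seq_len = n_events * (3 * exon_len + 2 * intron_len + 500) + 1000
    genome = {chrom: "".join(rng.choice(list("ACGT"), size=seq_len))}
    for i in range(n_events):
        e1 = (pos, pos + exon_len)
        t = (e1[1] + intron_len, e1[1] + intron_len + exon_len)
        e2 = (t[1] + intron_len, t[1] + intron_len + exon_len)
        strand = "+" if (not strand_mix or rng.random() < 0.5) else "-"
        up, dn = (e1, e2) if strand == "+" else (e2, e1)
        events.append(
            SkippingEvent(
                id=f"EV{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                upstream_exon=up,
                target_exon=t,
                downstream_exon=dn,
            )
        )
        pos = e2[1] + 500
    return genome, events


def make_psi_plan(
    event_ids: list[str],
    n_days: int,
    included: list[str] | None = None,
    excluded: list[str] | None = None,
    base_psi: float = 0.5,
    delta: float = 0.3,
) -> pd.DataFrame:
    """True Ψ per event per day: regulated events move linearly by
    ±delta from day 0 to the last day, background stays flat."""
    included = set(included or [])
    excluded = set(excluded or [])
    t = np.linspace(0.0, 1.0, n_days)
    rows = {}
    for eid in event_ids:
        if eid in included:
            rows[eid] = np.clip(base_psi + delta * t, 0.0, 1.0)
        elif eid in excluded:
            rows[eid] = np.clip(base_psi - delta * t, 0.0, 1.0)
        else:
            rows[eid] = np.full(n_days, base_psi)
    return pd.DataFrame(rows, index=range(n_days)).T


# ---------------------------------------------------------------------------
# Motif planting


def instantiate_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[ch.upper()])) for ch in motif)


def plant_motifs(
    genome: dict[str, str],
    events: list[SkippingEvent],
    motif: str,
    segment: str,
    fraction: float,
    seed: int = 0,
    copies: int = 3,
    exon_offset: int = 50,
    intron_offset: int = 250,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write concrete motif instances into the named segment of a random
    fraction of the events; returns the modified genome and a plant log."""
    from .rbp import segment_coordinates

    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(events)))
    chosen_idx = set(rng.permutation(len(events))[:n_plant].tolist())
    new_genome = {c: list(s) for c, s in genome.items()}
    log_rows = []
    for i, ev in enumerate(events):
        if i not in chosen_idx:
            continue
        coords = segment_coordinates(ev, exon_offset, intron_offset)
        chrom, s, e, strand = coords[segment]
        for _ in range(copies):
            inst = instantiate_iupac(motif, rng)
            if e - s < len(inst):
                continue
            pos = int(rng.integers(s, e - len(inst) + 1))
            written = inst if strand == "+" else revcomp(inst)
            _plant(new_genome[chrom], pos, written)
            log_rows.append(
                {"event_id": ev.id, "chrom": chrom, "pos": pos, "motif": inst}
            )
    return (
        {c: "".join(s) for c, s in new_genome.items()},
        pd.DataFrame(log_rows, columns=["event_id", "chrom", "pos", "motif"]),
    )


def plant_clip_peaks(
    events: list[SkippingEvent],
    segment: str,
    fraction: float,
    seed: int = 0,
    peak_width: int = 30,
    exon_offset: int = 50,
    intron_offset: int = 250,
) -> tuple[list[tuple[str, int, int, str, str]], pd.DataFrame]:
    """CLIP-style peak intervals inside the named segment of a random
    fraction of events."""
    from .rbp import segment_coordinates

    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(events)))
    chosen_idx = set(rng.permutation(len(events))[:n_plant].tolist())
    peaks, rows = [], []
    for i, ev in enumerate(events):
        if i not in chosen_idx:
            continue
        chrom, s, e, strand = segment_coordinates(ev, exon_offset, intron_offset)[segment]
        if e - s <= peak_width:
            p0 = s
        else:
            p0 = int(rng.integers(s, e - peak_width))
        peaks.append((chrom, p0, p0 + peak_width, f"peak_{ev.id}", strand))
        rows.append({"event_id": ev.id, "chrom": chrom, "start": p0, "end": p0 + peak_width})
    return peaks, pd.DataFrame(rows, columns=["event_id", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Peptides


AA = "ACDEFGHILMNPQSTVWY"  # K/R added explicitly as cleavage points


def _random_block(rng: np.random.Generator, lo: int = 8, hi: int = 20) -> str:
    n = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(AA), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_protein_isoforms(
    n_genes: int, seed: int = 0, blocks_common: int = 4, blocks_variable: int = 2
) -> tuple[dict[str, str], dict[str, str]]:
    """Per gene, two protein isoforms sharing N- and C-terminal blocks and
    differing in an internal variable region.

    Returns (isoform -> sequence, isoform -> gene).
    """
    rng = np.random.default_rng(seed)
    seqs, gene_of = {}, {}
    for i in range(n_genes):
        gid = f"P{i + 1:04d}"
        nter = "".join(_random_block(rng) for _ in range(blocks_common))
        cter = "".join(_random_block(rng) for _ in range(blocks_common))
        var_a = "".join(_random_block(rng) for _ in range(blocks_variable))
        var_b = "".join(_random_block(rng) for _ in range(blocks_variable))
        for tag, var in (("a", var_a), ("b", var_b)):
            iso = f"{gid}-{tag}"
            seqs[iso] = nter + var + cter
            gene_of[iso] = gid
    return seqs, gene_of


def tryptic_peptides(seq: str, min_len: int = 7, max_len: int = 30) -> list[str]:
    """Cleave after K/R except before P; keep peptides of 7-30 residues."""
    peptides = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 >= len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return [p for p in peptides if min_len <= len(p) <= max_len]


def default_abundance_plan(
    gene_of: dict[str, str],
    n_days: int = 6,
    switch_log2fc: float = 1.5,
    flat_log2fc: float = -0.2,
    switch_genes: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-isoform log2 abundance trajectories: in switch genes the 'b'
    isoform climbs by ``switch_log2fc`` while 'a' drifts by ``flat_log2fc``;
    elsewhere both stay flat."""
    genes = sorted(set(gene_of.values()))
    if switch_genes is None:
        switch_genes = genes[: max(1, len(genes) // 2)]
    t = np.linspace(0.0, 1.0, n_days)
    plan = {}
    for iso, gid in gene_of.items():
        if gid in switch_genes:
            slope = switch_log2fc if iso.endswith("b") else flat_log2fc
        else:
            slope = 0.0
        plan[iso] = slope * t
    return plan


def simulate_peptides(
    protein_seqs: dict[str, str],
    gene_of: dict[str, str],
    abundance_plan: dict[str, np.ndarray],
    n_days: int = 6,
    replicates: int = 3,
    missingness: float = 0.1,
    seed: int = 0,
    n_fractions: int = 2,
    base_log2: float = 23.0,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Peptide x (fraction, sample) intensity table with MNAR missingness.

    Tryptic peptides are enumerated per isoform; a peptide occurring in
    more than one isoform is listed with all matches.  Intensities are
    log-normal around the isoform's planted trajectory; missingness
    probability decreases with intensity rank (missing-not-at-random),
    with overall rate ``missingness``.
    """
    rng = np.random.default_rng(seed)
    design = make_design(n_days, replicates)
    samples = list(design.index)

    pep_matches: dict[str, list[str]] = {}
    for iso in sorted(protein_seqs):
        for pep in tryptic_peptides(protein_seqs[iso]):
            pep_matches.setdefault(pep, []).append(iso)

    rows = []
    for pep in sorted(pep_matches):
        matches = pep_matches[pep]
        pep_base = base_log2 + rng.normal(0, 1.0)
        frac_split = rng.dirichlet(np.full(n_fractions, 3.0))
        for fi in range(n_fractions):
            row = {
                "peptide": pep,
                "matched_isoforms": ";".join(sorted(set(matches))),
                "fraction": fi + 1,
            }
            for sample in samples:
                day = int(design.loc[sample, "day"])
                level = float(
                    np.mean([abundance_plan[m][day] for m in matches])
                )
                log2_int = pep_base + level + np.log2(frac_split[fi]) + rng.normal(0, noise_sd)
                row[sample] = 2.0 ** log2_int
            rows.append(row)
    df = pd.DataFrame(rows)

    if missingness > 0 and len(df):
        vals = df[samples].to_numpy()
        order = np.argsort(np.argsort(vals, axis=None))
        q = order.reshape(vals.shape) / vals.size  # ascending intensity rank
        p_miss = np.clip(2.0 * missingness * (1.0 - q), 0.0, 1.0)
        mask = rng.random(vals.shape) < p_miss
        vals[mask] = np.nan
        df[samples] = vals
    return df
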