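"""Collapse, classification, artifact flags and curation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodyn.catalog import (
    classify_isoform,
    collapse_reads,
    curate,
    detect_mispriming,
    end_support,
    junction_canonicality,
    quantify_isoforms,
)
from isodyn.models import (
    Annotation,
    GeneModel,
    IsoformRecord,
    LongRead,
    TranscriptModel,
)
from oracles import classify_oracle, random_annotation, random_query_model


def _read(i, exons, strand="+", chrom="chr1"):
    return LongRead(id=f"r{i}", chrom=chrom, strand=strand, exons=tuple(exons))


# ---------------------------------------------------------------------------
# Collapse


def test_three_identical_reads_make_one_isoform():
    exons = ((100, 200), (300, 400))
    recs = collapse_reads([_read(i, exons) for i in range(3)])
    assert len(recs) == 1
    assert recs[0].read_support == 3
    assert recs[0].model.exons == exons


def test_two_reads_fall_below_min_cluster():
    exons = ((100, 200), (300, 400))
    assert collapse_reads([_read(i, exons) for i in range(2)]) == []


def test_boundary_tolerance_splits_clusters():
    """6 nt at an internal boundary splits; 4 nt merges."""
    base = ((100, 200), (300, 400))
    far = ((100, 206), (300, 400))
    near = ((100, 204), (300, 400))
    reads = [_read(i, base) for i in range(3)] + [_read(i + 3, far) for i in range(3)]
    assert len(collapse_reads(reads)) == 2
    reads = [_read(i, base) for i in range(3)] + [_read(i + 3, near) for i in range(3)]
    assert len(collapse_reads(reads)) == 1


def test_collapse_representative_is_median():
    reads = [
        _read(0, ((100, 200), (300, 400))),
        _read(1, ((100, 202), (300, 400))),
        _read(2, ((100, 204), (300, 400))),
    ]
    recs = collapse_reads(reads)
    assert recs[0].model.exons == ((100, 202), (300, 400))


def test_mixed_strand_reads_never_merge():
    exons = ((100, 200), (300, 400))
    reads = [_read(i, exons) for i in range(3)] + [
        _read(i + 3, exons, strand="-") for i in range(3)
    ]
    recs = collapse_reads(reads)
    assert len(recs) == 2
    assert {r.model.strand for r in recs} == {"+", "-"}


# ---------------------------------------------------------------------------
# Classification


@pytest.fixture(scope="module")
def toy_annotation():
    # G1: 6-junction transcript + a skip variant; G2 far away, same strand
    t1 = TranscriptModel(
        "T1", "chr1", "+",
        tuple((1000 + 500 * i, 1100 + 500 * i) for i in range(7)),
        gene_id="G1",
    )
    t2 = TranscriptModel(
        "T2", "chr1", "+",
        tuple((20000 + 500 * i, 20100 + 500 * i) for i in range(4)),
        gene_id="G2",
    )
    return Annotation(
        genes={
            "G1": GeneModel("G1", "chr1", "+", (t1,)),
            "G2": GeneModel("G2", "chr1", "+", (t2,)),
        }
    )


def test_fsm_full_junction_match(toy_annotation):
    t1 = toy_annotation.transcripts["T1"]
    model = TranscriptModel("q", "chr1", "+", t1.exons)
    assert classify_isoform(model, toy_annotation) == ("FSM", ("T1",))


def test_ism_contiguous_subchain(toy_annotation):
    t1 = toy_annotation.transcripts["T1"]
    model = TranscriptModel("q", "chr1", "+", t1.exons[2:6])
    cls, matched = classify_isoform(model, toy_annotation)
    assert cls == "ISM" and matched == ("T1",)


def test_nic_novel_combination_vs_nnc_novel_site(toy_annotation):
    t1 = toy_annotation.transcripts["T1"]
    # join exon1's donor to exon3's acceptor: both sites annotated, the
    # combination is not
    exons = (t1.exons[0], *t1.exons[2:])
    skip = TranscriptModel("q", "chr1", "+", exons)
    # dropping exon 2 creates junction (e1_end, e3_start): both sites are
    # annotated but the chain matches no reference
    assert classify_isoform(skip, toy_annotation)[0] == "NIC"
    # shift the donor 8 nt off any annotated site -> NNC
    shifted = (t1.exons[0][0], t1.exons[0][1] - 8)
    nnc = TranscriptModel("q2", "chr1", "+", (shifted, *t1.exons[2:]))
    assert classify_isoform(nnc, toy_annotation)[0] == "NNC"


def test_fusion_spans_two_loci(toy_annotation):
    t1 = toy_annotation.transcripts["T1"]
    t2 = toy_annotation.transcripts["T2"]
    model = TranscriptModel("q", "chr1", "+", t1.exons + t2.exons)
    cls, matched = classify_isoform(model, toy_annotation)
    assert cls == "fusion"
    assert set(matched) == {"G1", "G2"}


def test_mono_exon_rules(toy_annotation):
    mono_ref = TranscriptModel("M1", "chr1", "+", ((50000, 51000),), gene_id="G3")
    ann = Annotation(
        genes={
            **toy_annotation.genes,
            "G3": GeneModel("G3", "chr1", "+", (mono_ref,)),
        }
    )
    inside = TranscriptModel("q", "chr1", "+", ((50100, 50900),))
    assert classify_isoform(inside, ann)[0] == "FSM"
    outside = TranscriptModel("q", "chr1", "+", ((52000, 52500),))
    assert classify_isoform(outside, ann)[0] == "NNC"


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_classification_matches_bruteforce_oracle(seed):
    """Random queries against random annotations agree with the
    enumeration oracle, and exactly one class is assigned."""
    rng = np.random.default_rng(seed)
    ann = random_annotation(rng)
    for _ in range(5):
        q = random_query_model(rng, ann)
        cls, _ = classify_isoform(q, ann)
        assert cls in {"FSM", "ISM", "NIC", "NNC", "fusion"}
        assert cls == classify_oracle(q, ann)


# ---------------------------------------------------------------------------
# Mispriming / canonicality / end support


def _genome_with(downstream, upstream="C" * 60, exonic="G" * 200):
    return {"chr1": upstream + exonic + downstream + "C" * 60}


def test_mispriming_threshold_plus_strand():
    model = TranscriptModel("q", "chr1", "+", ((60, 260),))
    g13 = _genome_with("A" * 13 + "C" * 7)   # 65% A
    g11 = _genome_with("A" * 11 + "C" * 9)   # 55% A
    assert detect_mispriming(model, g13) is True
    assert detect_mispriming(model, g11) is False


def test_mispriming_minus_strand_uses_upstream_revcomp():
    # minus-strand transcript 3' end at genomic start; genomic window
    # upstream holds 13 T -> 13 A after reverse complement
    genome = {"chr1": "C" * 40 + "T" * 13 + "G" * 7 + "G" * 200}
    model = TranscriptModel("q", "chr1", "-", ((60, 260),))
    assert detect_mispriming(model, genome) is True


def test_junction_canonicality_both_strands():
    #         exon   GT...AG   exon
    genome = {"chr1": "G" * 100 + "GT" + "C" * 96 + "AG" + "G" * 100}
    plus = TranscriptModel("q", "chr1", "+", ((50, 100), (200, 250)))
    assert junction_canonicality(plus, genome) == (True,)
    # CT..AC genomically is GT..AG on the minus strand
    genome_minus = {"chr1": "G" * 100 + "CT" + "C" * 96 + "AC" + "G" * 100}
    minus = TranscriptModel("q", "chr1", "-", ((50, 100), (200, 250)))
    assert junction_canonicality(minus, genome_minus) == (True,)
    genome_bad = {"chr1": "G" * 100 + "GG" + "C" * 96 + "AG" + "G" * 100}
    assert junction_canonicality(plus, genome_bad) == (False,)


def test_end_support_windows_and_motif():
    genome = {"chr1": "C" * 240 + "AATAAA" + "C" * 14 + "C" * 300}
    model = TranscriptModel("q", "chr1", "+", ((100, 260),))
    cage = [("chr1", 95, 105, "p1", "+")]
    polya = [("chr1", 250, 270, "a1", "+")]
    tss, tts, pa = end_support(model, cage, polya, genome)
    assert (tss, tts, pa) == (True, True, True)
    # no tracks loaded -> unsupported
    tss, tts, pa = end_support(model, [], [], genome)
    assert (tss, tts) == (False, False)


# ---------------------------------------------------------------------------
# Curation


def _record(cls, canonical=(True,), support=(0,), mispriming=False,
            template_switch=False, ends=(True, True, True)):
    model = TranscriptModel("q", "chr1", "+", ((100, 200), (300, 400)))
    rec = IsoformRecord(
        model=model, read_support=5,
        isoform_class=cls,
        mispriming=mispriming, template_switch=template_switch,
        junction_canonical=canonical,
        tss_supported=ends[0], tts_supported=ends[1], polya_motif_found=ends[2],
    )
    support_map = {
        ("chr1", 200, 300, "+"): support[0],
    }
    return rec, support_map


def test_nnc_junction_support_boundary():
    rec, sup = _record("NNC", canonical=(False,), support=(12,))
    assert curate([rec], sup)[0].retained is True
    rec, sup = _record("NNC", canonical=(False,), support=(9,))
    assert curate([rec], sup)[0].retained is False


def test_fsm_mispriming_always_removed():
    rec, sup = _record("FSM", mispriming=True)
    assert curate([rec], sup)[0].retained is False


def test_fsm_requires_all_end_evidence():
    for ends in [(False, True, True), (True, False, True), (True, True, False)]:
        rec, sup = _record("FSM", ends=ends)
        assert curate([rec], sup)[0].retained is False
    rec, sup = _record("FSM")
    assert curate([rec], sup)[0].retained is True


def test_curation_monotone_in_junction_support():
    """Raising junction support never flips retained -> removed."""
    for base in range(0, 25, 4):
        rec_lo, sup = _record("NNC", canonical=(False,), support=(base,))
        rec_hi, sup_hi = _record("NNC", canonical=(False,), support=(base + 5,))
        lo = curate([rec_lo], sup)[0].retained
        hi = curate([rec_hi], sup_hi)[0].retained
        assert hi >= lo


def test_curate_requires_computed_flags():
    model = TranscriptModel("q", "chr1", "+", ((100, 200), (300, 400)))
    rec = IsoformRecord(model=model, read_support=3)
    with pytest.raises(ValueError):
        curate([rec], {})


# ---------------------------------------------------------------------------
# Quantification


def test_tpm_normalization_single_isoform():
    model = TranscriptModel("I1", "chr1", "+", ((0, 1000),))
    rec = IsoformRecord(model=model, read_support=10)
    reads = [_read(i, ((0, 1000),)) for i in range(10)]
    df = quantify_isoforms(reads, [rec])
    assert df.loc["I1", "count"] == 10
    assert df.loc["I1", "tpm"] == pytest.approx(1e6)


def test_tpm_equal_lengths_split():
    m1 = TranscriptModel("I1", "chr1", "+", ((0, 500), (1000, 1500)))
    m2 = TranscriptModel("I2", "chr1", "+", ((0, 500), (2000, 2500)))
    reads = [_read(i, m1.exons) for i in range(30)] + [
        _read(100 + i, m2.exons) for i in range(70)
    ]
    df = quantify_isoforms(reads, [IsoformRecord(m1, 30), IsoformRecord(m2, 70)])
    assert df.loc["I1", "tpm"] == pytest.approx(3e5)
    assert df.loc["I2", "tpm"] == pytest.approx(7e5)


def test_read_prefers_longest_compatible_on_tie():
    """A read matching an FSM and its ISM truncation equally well goes to
    the longer isoform."""
    fsm = TranscriptModel("A_full", "chr1", "+", ((0, 100), (200, 300), (400, 500)))
    ism = TranscriptModel("B_trunc", "chr1", "+", ((200, 300), (400, 500)))
    read = _read(0, ((200, 300), (400, 500)))
    df = quantify_isoforms([read], [IsoformRecord(fsm, 3), IsoformRecord(ism, 3)])
    # equal shared junction count (1 each) is impossible here: read shares
    # 1 junction with both; the FSM is longer so it wins
    assert df.loc["A_full", "count"] == 1
    assert df.loc["B_trunc", "count"] == 0


# ---------------------------------------------------------------------------
# Pipeline-level invariants


def test_zero_artifact_catalog_is_all_retained_fsm(clean_reference):
    from isodyn.catalog import build_catalog
    from isodyn.synthetic import junction_support_table, simulate_long_reads

    reads = simulate_long_reads(clean_reference, 600, seed=4)
    recs = build_catalog(
        reads,
        clean_reference.annotation,
        clean_reference.genome,
        clean_reference.cage_peaks,
        clean_reference.polya_sites,
        junction_support_table(clean_reference.annotation, seed=5),
    )
    assert recs
    assert all(r.isoform_class in ("FSM", "ISM") for r in recs)
    assert all(r.retained for r in recs)
    # set equality of junction chains with the generating annotation
    catalog_chains = {r.model.introns for r in recs}
    truth_chains = {
        t.introns for t in clean_reference.annotation.transcripts.values()
    }
    assert catalog_chains <= truth_chains
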