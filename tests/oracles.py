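"""Independent brute-force oracles used to check the implementation.

Each oracle is written as plain enumeration/direct arithmetic, separate
from the library code paths it validates.
"""

from __future__ import annotations

import numpy as np


def classify_oracle(model, annotation, end_tol=50):
    """Transcript classification by exhaustive enumeration: all reference
    chains, all their contiguous sub-chains, and the full donor/acceptor
    site sets are materialized before comparison."""
    refs = [
        t
        for gene in annotation.genes.values()
        for t in gene.isoforms
        if t.chrom == model.chrom and t.strand == model.strand
    ]
    if len(model.exons) == 1:
        for t in refs:
            if len(t.exons) == 1:
                if t.start - end_tol <= model.start and model.end <= t.end + end_tol:
                    return "FSM"
        return "NNC"

    chain = tuple(model.introns)

    full_chains = {t.id: tuple(t.introns) for t in refs if len(t.exons) > 1}
    if any(c == chain for c in full_chains.values()):
        return "FSM"

    subchains = set()
    for c in full_chains.values():
        for i in range(len(c)):
            for j in range(i + 1, len(c) + 1):
                if (j - i) < len(c):
                    subchains.add(c[i:j])
    if chain in subchains:
        return "ISM"

    gene_junctions = {}
    for t in refs:
        gid = t.gene_id or t.id
        gene_junctions.setdefault(gid, set()).update(t.introns)
    hit_genes = [g for g, js in gene_junctions.items() if js & set(chain)]
    for i, a in enumerate(hit_genes):
        for b in hit_genes[i + 1 :]:
            ga, gb = annotation.genes.get(a), annotation.genes.get(b)
            if ga is None or gb is None:
                continue
            if ga.end <= gb.start or gb.end <= ga.start:
                return "fusion"

    donors = set()
    acceptors = set()
    for t in refs:
        for s, e in t.introns:
            if t.strand == "+":
                donors.add(s)
                acceptors.add(e)
            else:
                donors.add(e)
                acceptors.add(s)
    model_donors = []
    model_acceptors = []
    for s, e in chain:
        if model.strand == "+":
            model_donors.append(s)
            model_acceptors.append(e)
        else:
            model_donors.append(e)
            model_acceptors.append(s)
    if all(d in donors for d in model_donors) and all(
        a in acceptors for a in model_acceptors
    ):
        return "NIC"
    return "NNC"


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values by the textbook
    procedure."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        adj[idx] = val
        prev = val
    return adj


def merge_intervals_oracle(intervals):
    """Interval union by scanning a boolean number line."""
    if not intervals:
        return []
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    line = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        line[s - lo : e - lo] = True
    merged = []
    i = 0
    while i < len(line):
        if line[i]:
            j = i
            while j < len(line) and line[j]:
                j += 1
            merged.append((i + lo, j + lo))
            i = j
        else:
            i += 1
    return merged


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def motif_mask_oracle(sequence, motif):
    """Coverage mask by checking the motif at every offset, base by base."""
    seq = sequence.upper().replace("U", "T")
    motif = motif.upper()
    k = len(motif)
    mask = np.zeros(len(seq), dtype=np.int8)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(k)):
            mask[i : i + k] = 1
    return mask


def size_factors_oracle(counts):
    """Median-of-ratios size factors computed row-by-row with explicit
    loops."""
    mat = np.asarray(counts, dtype=float)
    n_feat, n_samp = mat.shape
    keep = [i for i in range(n_feat) if all(mat[i, j] > 0 for j in range(n_samp))]
    geo = [float(np.prod(mat[i]) ** (1.0 / n_samp)) for i in keep]
    sfs = []
    for j in range(n_samp):
        ratios = sorted(mat[i, j] / g for i, g in zip(keep, geo))
        mid = len(ratios) // 2
        if len(ratios) % 2:
            sfs.append(ratios[mid])
        else:
            sfs.append(0.5 * (ratios[mid - 1] + ratios[mid]))
    return np.array(sfs)


def nmd_oracle(exon_lengths, orf_end, min_distance=50):
    """NMD sensitivity from exon lengths (5'->3') and the transcript
    coordinate just past the stop codon."""
    if len(exon_lengths) < 2:
        return "insensitive"
    last_junction = sum(exon_lengths[:-1])
    return (
        "NMD-sensitive"
        if last_junction - orf_end >= min_distance
        else "insensitive"
    )


def random_annotation(rng, n_genes=5, max_exons=8, chrom="chrR"):
    """Random multi-isoform gene models for oracle comparisons."""
    from isodyn.models import Annotation, GeneModel, TranscriptModel

    genes = {}
    cursor = 100
    for g in range(n_genes):
        gid = f"R{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, max_exons + 1))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(50, 200))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 400))
        isoforms = [
            TranscriptModel(
                id=f"{gid}.1", chrom=chrom, strand=strand,
                exons=tuple(exons), gene_id=gid,
            )
        ]
        if n_exons >= 4 and rng.random() < 0.7:
            drop = int(rng.integers(1, n_exons - 1))
            alt = tuple(e for k, e in enumerate(exons) if k != drop)
            isoforms.append(
                TranscriptModel(
                    id=f"{gid}.2", chrom=chrom, strand=strand,
                    exons=alt, gene_id=gid,
                )
            )
        genes[gid] = GeneModel(id=gid, chrom=chrom, strand=strand,
                               isoforms=tuple(isoforms))
        cursor = pos + 1500
    return Annotation(genes=genes)


def random_query_model(rng, annotation, chrom="chrR"):
    """Random query chains derived from the annotation by dropping exons,
    shifting sites, recombining isoforms or joining two genes."""
    from isodyn.models import TranscriptModel

    gene_ids = sorted(annotation.genes)
    gid = gene_ids[int(rng.integers(len(gene_ids)))]
    gene = annotation.genes[gid]
    t = gene.isoforms[int(rng.integers(len(gene.isoforms)))]
    exons = [list(e) for e in t.exons]
    mode = rng.choice(["exact", "sub", "shift", "drop", "fuse", "ends"])
    if mode == "sub" and len(exons) > 2:
        i = int(rng.integers(0, len(exons) - 1))
        j = int(rng.integers(i + 2, len(exons) + 1))
        exons = exons[i:j]
    elif mode == "shift" and len(exons) > 1:
        k = int(rng.integers(len(exons)))
        side = int(rng.integers(2))
        delta = int(rng.integers(7, 25)) * (1 if rng.random() < 0.5 else -1)
        # only internal boundaries change the junction chain
        if side == 0 and k > 0:
            exons[k][0] += delta
        elif k < len(exons) - 1:
            exons[k][1] += delta
    elif mode == "drop" and len(exons) > 2:
        k = int(rng.integers(1, len(exons) - 1))
        exons = exons[:k] + exons[k + 1 :]
    elif mode == "fuse":
        others = [
            g for g in annotation.genes.values()
            if g.id != gid and g.strand == t.strand
        ]
        if others:
            o = others[int(rng.integers(len(others)))].isoforms[0]
            exons = sorted([list(e) for e in t.exons] + [list(e) for e in o.exons])
    elif mode == "ends":
        exons[0][0] += int(rng.integers(-40, 40))
        exons[-1][1] += int(rng.integers(-40, 40))
    fixed = []
    prev = None
    for s, e in exons:
        if prev is not None and s <= prev:
            s = prev + 10
        e = max(e, s + 20)
        fixed.append((s, e))
        prev = e
    return TranscriptModel(id="q", chrom=chrom, strand=t.strand, exons=tuple(fixed))
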