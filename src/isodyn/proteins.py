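"""Protein-level pipeline: presence filtering, left-censored (MNAR)
imputation, differential enrichment, unique-peptide isoform LFQ,
trend-difference calls, NMD prediction and lagged RNA-protein
correlation.

Matrices are protein (or protein-isoform) x sample log2 LFQ intensities
with NaN for missing values; the design is the standard day/replicate
table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import _welch, bh_adjust
from .models import TranscriptModel


# ---------------------------------------------------------------------------
# Presence + imputation


def presence_filter(matrix: pd.DataFrame, design: pd.DataFrame, min_present: int = 2) -> pd.DataFrame:
    """Keep proteins observed in at least ``min_present`` replicates of at
    least one condition (day)."""
    keep = pd.Series(False, index=matrix.index)
    for day in sorted(design["day"].unique()):
        samples = design.index[design["day"] == day]
        keep |= matrix[samples].notna().sum(axis=1) >= min_present
    return matrix.loc[keep]


def impute_mnar(
    matrix: pd.DataFrame, shift: float = 1.8, scale: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Left-censored imputation for missing-not-at-random intensities.

    Per sample, missing cells are drawn from a Gaussian centred
    ``shift`` standard deviations below that sample's observed mean with
    standard deviation ``scale`` times the observed one.  Observed
    values are never touched.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        missing = vals.isna()
        if not missing.any():
            continue
        observed = vals.dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, scale * sd, size=int(missing.sum()))
        out.loc[missing, col] = draws
    return out


# ---------------------------------------------------------------------------
# Differential enrichment


def differential_protein(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    day_a: int,
    day_b: int,
    alpha: float = 0.1,
    lfc_threshold: float = 0.32,
) -> pd.DataFrame:
    """log2FC (mean difference of log2 intensities), Welch t, BH.

    Significant iff padj < 0.1 and |log2FC| > 0.32 (a 25% change).
    """
    sa = list(design.index[design["day"] == day_a])
    sb = list(design.index[design["day"] == day_b])
    A = matrix[sa].to_numpy(dtype=float)
    B = matrix[sb].to_numpy(dtype=float)
    log2fc = np.nanmean(B, axis=1) - np.nanmean(A, axis=1)
    pvals = np.array(
        [
            _welch(A[i][~np.isnan(A[i])], B[i][~np.isnan(B[i])])
            if (~np.isnan(A[i])).sum() >= 2 and (~np.isnan(B[i])).sum() >= 2
            else np.nan
            for i in range(A.shape[0])
        ]
    )
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "protein_id": matrix.index,
            "log2FC": log2fc,
            "p": pvals,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(log2fc) > lfc_threshold),
        }
    ).set_index("protein_id")


# ---------------------------------------------------------------------------
# Peptide -> isoform LFQ


def assign_peptides(
    peptides: pd.DataFrame, samples: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Isoform LFQ from unique peptides only.

    ``peptides``: one row per (peptide, fraction) with a
    ``matched_isoforms`` column (';'-separated) and per-sample intensity
    columns.  Peptides matching more than one isoform are discarded;
    each isoform's LFQ per sample is the sum over its unique peptides of
    the per-fraction intensities.  Isoforms listed only on shared
    peptides are returned as unquantifiable.
    """
    all_isoforms = sorted(
        {iso for m in peptides["matched_isoforms"] for iso in str(m).split(";")}
    )
    unique_rows = peptides[~peptides["matched_isoforms"].astype(str).str.contains(";")]
    lfq = (
        unique_rows.groupby("matched_isoforms")[samples].sum(min_count=1)
        if len(unique_rows)
        else pd.DataFrame(columns=samples)
    )
    lfq.index.name = "isoform_id"
    unquantifiable = [i for i in all_isoforms if i not in lfq.index]
    return lfq, unquantifiable


def normalize_to_max(lfq: pd.DataFrame) -> pd.DataFrame:
    """Scale each isoform's intensities to a maximum of 1 across samples."""
    return lfq.div(lfq.max(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Trend differences


def trend_differences(
    lfq: pd.DataFrame,
    gene_of: dict[str, str],
    design: pd.DataFrame,
    comparisons: list[tuple[int, int]],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Pairwise isoform trend calls.

    For each pair of quantified isoforms of a gene and each day-pair,
    Δ = |log2FC_A - log2FC_B| on per-day mean intensities
    (observed-only, pairwise complete); trend_change iff any Δ >=
    ``threshold``.  log2FCs are invariant to the per-isoform max
    normalization used for display.
    """

    def day_mean(iso: str, day: int) -> float:
        samples = design.index[design["day"] == day]
        return float(np.nanmean(lfq.loc[iso, samples].to_numpy(dtype=float)))

    rows = []
    genes: dict[str, list[str]] = {}
    for iso in lfq.index:
        gid = gene_of.get(iso)
        if gid is not None:
            genes.setdefault(gid, []).append(iso)
    for gid in sorted(genes):
        isoforms = sorted(genes[gid])
        for i, a in enumerate(isoforms):
            for b in isoforms[i + 1 :]:
                deltas = {}
                for da, db in comparisons:
                    fa = np.log2(day_mean(a, db)) - np.log2(day_mean(a, da))
                    fb = np.log2(day_mean(b, db)) - np.log2(day_mean(b, da))
                    if np.isfinite(fa) and np.isfinite(fb):
                        deltas[(da, db)] = abs(fa - fb)
                if not deltas:
                    continue
                max_cmp = max(deltas, key=deltas.get)
                rows.append(
                    {
                        "gene_id": gid,
                        "isoform_a": a,
                        "isoform_b": b,
                        "max_delta": deltas[max_cmp],
                        "max_comparison": f"d{max_cmp[0]}-d{max_cmp[1]}",
                        "trend_change": deltas[max_cmp] >= threshold,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "isoform_a", "isoform_b",
            "max_delta", "max_comparison", "trend_change",
        ],
    )


# ---------------------------------------------------------------------------
# NMD


def longest_orf(sequence: str) -> tuple[int, int] | None:
    """Longest ATG-initiated open reading frame with an in-frame stop.

    Returns (start, end) transcript coordinates, end exclusive of the
    stop codon's last base + 1 (i.e., slice covering ATG..stop).
    """
    seq = sequence.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in stops:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best


def transcript_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    from .io import revcomp

    g = genome[model.chrom]
    seq = "".join(g[s:e] for s, e in model.exons)
    return seq if model.strand == "+" else revcomp(seq)


def last_junction_position(model: TranscriptModel) -> int | None:
    """Transcript coordinate of the last exon-exon junction (the first
    base of the 3'-most exon), or None for mono-exon transcripts."""
    if len(model.exons) < 2:
        return None
    exon_lengths = [e - s for s, e in model.exons]
    if model.strand == "-":
        exon_lengths = exon_lengths[::-1]
    return int(np.sum(exon_lengths[:-1]))


def predict_nmd(
    model: TranscriptModel,
    orf: tuple[int, int] | None,
    min_distance: int = 50,
) -> str:
    """'NMD-sensitive' when the stop codon ends at least ``min_distance``
    nt upstream of the last exon-exon junction, else 'insensitive'.

    ``orf`` is (start, end) in transcript coordinates with ``end`` just
    past the stop codon; mono-exon transcripts are never sensitive.
    """
    junction = last_junction_position(model)
    if junction is None or orf is None:
        return "insensitive"
    stop_end = orf[1]
    return "NMD-sensitive" if junction - stop_end >= min_distance else "insensitive"


# ---------------------------------------------------------------------------
# RNA-protein correlation


def rna_protein_correlation(
    rna_log2fc: pd.DataFrame,
    protein_log2fc: pd.DataFrame,
    rna_significant: pd.DataFrame | None = None,
    protein_significant: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman ρ of RNA vs protein log2FCs for every pair of day-pair
    comparisons (columns of the two tables), on the genes significant in
    at least one comparison when restriction tables are given.

    Column labels are comparison names such as ``d0-d1``; rows are
    feature ids shared between the two tables.
    """
    common = set(rna_log2fc.index) & set(protein_log2fc.index)
    if rna_significant is not None or protein_significant is not None:
        hits: set = set()
        for table in (rna_significant, protein_significant):
            if table is None:
                continue
            any_sig = table.any(axis=1)
            hits |= set(any_sig.index[any_sig])
        common &= hits
    features = sorted(common)
    rows = []
    for rc in rna_log2fc.columns:
        for pc in protein_log2fc.columns:
            x = rna_log2fc.loc[features, rc].to_numpy(dtype=float)
            y = protein_log2fc.loc[features, pc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                rho = float(stats.spearmanr(x[ok], y[ok]).statistic)
            else:
                rho = np.nan
            rows.append(
                {"rna_comparison": rc, "protein_comparison": pc, "rho": rho, "n": int(ok.sum())}
            )
    return pd.DataFrame(rows)
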