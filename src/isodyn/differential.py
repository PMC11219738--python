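"""Time-course differential analyses.

Three layers, all using the printed decision thresholds:

* differential gene (or transcript) expression — RLE-normalized counts,
  Welch t-test on log2(n+1), significant at BH-adjusted p < 0.05 and
  |log2FC| > 0.59 (a 50% change);
* differential transcript usage — isoform fraction IF per sample, dIF
  between days, Welch t on logit IF, significant at padj < 0.05 and
  |dIF| >= 0.1;
* cassette-exon inclusion — junction-count Ψ with the 2:1 inclusion/
  skipping junction correction, rank-sum test, and the regulated-event
  partition (included ΔΨ > 0.05 & FDR < 0.05, excluded ΔΨ < -0.05 &
  FDR < 0.05, background FDR > 0.5, otherwise unassigned).

The negative-binomial Wald/LRT machinery of the reference tools is
deliberately replaced by these simpler location tests: the decision
rules, filters and effect thresholds are what this package reproduces,
and all calibration is simulation-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Normalization


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Relative-log-expression (median-of-ratios) size factors.

    Features with a zero count in any sample are excluded from the
    median; normalized counts are counts divided by the size factor.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in all samples")
    log_geo = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_geo[:, None]
    size_factors = pd.Series(
        np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor"
    )
    return size_factors, counts / size_factors


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized relative abundance scaled to 1e6 per sample."""
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


# ---------------------------------------------------------------------------
# Differential expression


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    res = stats.ttest_ind(b, a, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def dge(
    normalized: ExpressionMatrix,
    day_a: int,
    day_b: int,
    lfc_threshold: float = 0.59,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature log2FC (with pseudocount), Welch p on log2(n+1), BH.

    Significant iff padj < ``alpha`` and |log2FC| > ``lfc_threshold``.
    """
    sa = normalized.samples_for_day(day_a)
    sb = normalized.samples_for_day(day_b)
    if not sa or not sb:
        raise ValueError(f"no samples for one of days {day_a}, {day_b}")
    A = normalized.data[sa].to_numpy(dtype=float)
    B = normalized.data[sb].to_numpy(dtype=float)
    log2fc = np.log2(B.mean(axis=1) + pseudocount) - np.log2(A.mean(axis=1) + pseudocount)
    la, lb = np.log2(A + 1), np.log2(B + 1)
    pvals = np.array([_welch(la[i], lb[i]) for i in range(la.shape[0])])
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "feature_id": normalized.data.index,
            "log2FC": log2fc,
            "p": pvals,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(log2fc) > lfc_threshold),
        }
    ).set_index("feature_id")


# ---------------------------------------------------------------------------
# Transcript usage


def compute_usage(
    tpm: ExpressionMatrix,
    gene_of: dict[str, str],
    min_gene_tpm: float = 1.0,
    min_isoforms: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-replicate isoform fractions for genes passing the expression
    filters: mean gene TPM > ``min_gene_tpm`` at every day and at least
    ``min_isoforms`` isoforms detected."""
    genes = pd.Series({i: gene_of[i] for i in tpm.data.index}, name="gene_id")
    gene_tpm = tpm.data.groupby(genes).sum()
    keep = set(gene_tpm.index)
    for day in tpm.days:
        day_mean = gene_tpm[tpm.samples_for_day(day)].mean(axis=1)
        keep &= set(day_mean.index[day_mean > min_gene_tpm])
    n_iso = genes.groupby(genes).size()
    keep &= set(n_iso.index[n_iso >= min_isoforms])

    iso_keep = genes.index[genes.isin(keep)]
    sub = tpm.data.loc[iso_keep]
    denom = gene_tpm.loc[genes.loc[iso_keep]].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        iff = pd.DataFrame(
            np.where(denom > 0, sub.to_numpy() / denom, np.nan),
            index=sub.index,
            columns=sub.columns,
        )
    return iff, genes.loc[iso_keep]


def dtu_test(
    if_table: pd.DataFrame,
    gene_of: pd.Series,
    design: pd.DataFrame,
    day_a: int,
    day_b: int,
    alpha: float = 0.05,
    min_dif: float = 0.1,
    clamp: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Isoform usage change between two days.

    dIF = mean IF(day_b) - mean IF(day_a); p from a Welch t-test on
    logit-transformed IF; significant iff padj < ``alpha`` and
    |dIF| >= ``min_dif``.
    """
    sa = list(design.index[design["day"] == day_a])
    sb = list(design.index[design["day"] == day_b])
    A = if_table[sa].to_numpy(dtype=float)
    B = if_table[sb].to_numpy(dtype=float)
    dif = np.nanmean(B, axis=1) - np.nanmean(A, axis=1)
    logit = lambda x: np.log(x / (1 - x))
    la = logit(np.clip(A, *clamp))
    lb = logit(np.clip(B, *clamp))
    pvals = np.array([_welch(la[i], lb[i]) for i in range(la.shape[0])])
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "isoform_id": if_table.index,
            "gene_id": gene_of.reindex(if_table.index).to_numpy(),
            "IF_a": np.nanmean(A, axis=1),
            "IF_b": np.nanmean(B, axis=1),
            "dIF": dif,
            "p": pvals,
            "padj": padj,
        }
    )
    out["significant"] = (out["padj"] < alpha) & (out["dIF"].abs() >= min_dif)
    return out


# ---------------------------------------------------------------------------
# Junction-count Ψ and the regulated-event partition


def psi_from_counts(inc1: float, inc2: float, skip: float) -> float:
    """Ψ with the 2:1 junction-count correction: two inclusion junctions
    support one included exon, one junction supports skipping."""
    inc = (inc1 + inc2) / 2.0
    denom = inc + skip
    if denom == 0:
        return np.nan
    return inc / denom


def psi_and_classify(
    junctions: pd.DataFrame,
    day_a: int,
    day_b: int,
    delta_bound: float = 0.05,
    fdr_sig: float = 0.05,
    fdr_background: float = 0.5,
    min_informative: int = 2,
) -> pd.DataFrame:
    """Per-event ΔΨ, rank-sum FDR and the four-way regulation partition.

    ``junctions`` is long-format with columns event_id, day, replicate,
    inc1, inc2, skip.  Replicates with no informative reads are dropped;
    events with fewer than ``min_informative`` informative replicates in
    either group are dropped.
    """
    rows = []
    for eid, sub in junctions.groupby("event_id"):
        psis = {}
        for day in (day_a, day_b):
            vals = [
                psi_from_counts(r.inc1, r.inc2, r.skip)
                for r in sub[sub["day"] == day].itertuples(index=False)
            ]
            psis[day] = [v for v in vals if not np.isnan(v)]
        if len(psis[day_a]) < min_informative or len(psis[day_b]) < min_informative:
            continue
        a, b = np.array(psis[day_a]), np.array(psis[day_b])
        dpsi = b.mean() - a.mean()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(b, a, alternative="two-sided").pvalue)
        rows.append(
            {
                "event_id": eid,
                "psi_a": a.mean(),
                "psi_b": b.mean(),
                "delta_psi": dpsi,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(
            columns=["event_id", "psi_a", "psi_b", "delta_psi", "p", "fdr", "regulation"]
        )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["regulation"] = classify_regulation(
        out["delta_psi"].to_numpy(), out["fdr"].to_numpy(),
        delta_bound, fdr_sig, fdr_background,
    )
    return out


def classify_regulation(
    delta_psi: np.ndarray,
    fdr: np.ndarray,
    delta_bound: float = 0.05,
    fdr_sig: float = 0.05,
    fdr_background: float = 0.5,
) -> np.ndarray:
    """included / excluded / background / unassigned, exactly one each."""
    out = np.full(len(delta_psi), "unassigned", dtype=object)
    out[(delta_psi > delta_bound) & (fdr < fdr_sig)] = "included"
    out[(delta_psi < -delta_bound) & (fdr < fdr_sig)] = "excluded"
    out[(fdr > fdr_background)] = "background"
    return out


def consecutive_day_pairs(days: list[int]) -> list[tuple[int, int]]:
    days = sorted(days)
    return list(zip(days, days[1:]))
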