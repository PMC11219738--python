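"""Presence filtering, MNAR imputation, differential proteins, isoform
LFQ, trend calls, NMD and RNA-protein correlation."""

import numpy as np
import pandas as pd
import pytest

from isodyn import proteins as prot
from isodyn.models import TranscriptModel, make_design
from oracles import nmd_oracle


def _design(n_days=3, reps=3):
    return make_design(n_days, reps)


# ---------------------------------------------------------------------------
# Presence filter


def test_presence_two_of_three_in_one_condition_kept():
    design = _design()
    row = {s: np.nan for s in design.index}
    row["d0_r1"], row["d0_r2"] = 20.0, 21.0  # 2/3 on day 0 only
    mat = pd.DataFrame([row], index=["P1"])
    assert list(prot.presence_filter(mat, design).index) == ["P1"]


def test_presence_one_per_condition_dropped():
    design = _design()
    row = {s: np.nan for s in design.index}
    for day in range(3):
        row[f"d{day}_r1"] = 20.0  # only 1/3 everywhere
    mat = pd.DataFrame([row], index=["P1"])
    assert prot.presence_filter(mat, design).empty


def test_presence_fully_observed_kept():
    design = _design()
    mat = pd.DataFrame(
        np.full((2, len(design)), 20.0), index=["P1", "P2"], columns=design.index
    )
    assert len(prot.presence_filter(mat, design)) == 2


# ---------------------------------------------------------------------------
# Imputation


def test_impute_preserves_observed_values():
    design = _design()
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(
        rng.normal(25, 2, size=(50, len(design))), columns=design.index
    )
    holes = mat.copy()
    holes.iloc[:10, 0] = np.nan
    imp = prot.impute_mnar(holes, seed=1)
    observed = ~holes.isna()
    assert np.allclose(imp.to_numpy()[observed.to_numpy()],
                       holes.to_numpy()[observed.to_numpy()])
    assert not imp.isna().any().any()


def test_impute_is_deterministic_per_seed():
    design = _design()
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(
        rng.normal(25, 2, size=(30, len(design))), columns=design.index
    )
    mat.iloc[:15, 2] = np.nan
    a = prot.impute_mnar(mat, seed=7)
    b = prot.impute_mnar(mat, seed=7)
    c = prot.impute_mnar(mat, seed=8)
    assert a.equals(b)
    assert not a.equals(c)


def test_impute_left_shifted_distribution():
    """10,000 imputed draws: mean within 3 SE of mean - 1.8 sd; sd within
    5% of 0.3 sd."""
    design = _design(2, 2)
    rng = np.random.default_rng(3)
    col = rng.normal(24, 2, size=20_000)
    mat = pd.DataFrame({s: col.copy() for s in design.index})
    mat.iloc[:10_000, 0] = np.nan
    observed = mat["d0_r1"].dropna()
    mu, sd = observed.mean(), observed.std(ddof=1)
    imp = prot.impute_mnar(mat, seed=4)
    draws = imp.loc[mat["d0_r1"].isna(), "d0_r1"]
    se = 0.3 * sd / np.sqrt(len(draws))
    assert abs(draws.mean() - (mu - 1.8 * sd)) < 3 * se
    assert abs(draws.std(ddof=1) - 0.3 * sd) / (0.3 * sd) < 0.05


# ---------------------------------------------------------------------------
# Differential proteins


def test_protein_lfc_threshold_excludes_032():
    """log2FC 0.30 never passes, whatever the p-value."""
    design = _design(2, 3)
    rng = np.random.default_rng(5)
    base = rng.normal(24, 0.001, size=(30, 3))
    mat = pd.DataFrame(
        np.hstack([base, base + 0.30]), columns=design.index
    )
    res = prot.differential_protein(mat, design, 0, 1)
    assert (res["padj"] < 0.1).all()
    assert not res["significant"].any()


def test_protein_identical_groups_null():
    design = _design(2, 3)
    mat = pd.DataFrame(
        np.full((10, 6), 24.0), columns=design.index
    )
    res = prot.differential_protein(mat, design, 0, 1)
    assert not res["significant"].any()


def test_protein_power_on_planted_twofold():
    """Planted 2-fold (log2FC=1) proteins at sd 0.2, 3 vs 3: detected in
    >= 80% of simulations."""
    design = _design(2, 3)
    rng = np.random.default_rng(6)
    hits = total = 0
    for _ in range(60):
        a = rng.normal(24, 0.2, size=(30, 3))
        b = rng.normal(24, 0.2, size=(30, 3))
        b[:10] += 1.0
        mat = pd.DataFrame(np.hstack([a, b]), columns=design.index)
        res = prot.differential_protein(mat, design, 0, 1)
        hits += res["significant"].to_numpy()[:10].sum()
        total += 10
    assert hits / total >= 0.8


# ---------------------------------------------------------------------------
# Peptide assignment


def _pep_table(rows, samples):
    return pd.DataFrame(rows, columns=["peptide", "matched_isoforms", "fraction", *samples])


def test_shared_peptides_contribute_to_neither():
    samples = ["s1"]
    df = _pep_table(
        [
            ("AAAAAAK", "isoA;isoB", 1, 100.0),
            ("CCCCCCK", "isoA", 1, 50.0),
        ],
        samples,
    )
    lfq, unquant = prot.assign_peptides(df, samples)
    assert list(lfq.index) == ["isoA"]
    assert lfq.loc["isoA", "s1"] == 50.0
    assert unquant == ["isoB"]


def test_fraction_intensities_are_summed():
    samples = ["s1"]
    df = _pep_table(
        [
            ("AAAAAAK", "isoA", 1, 100.0),
            ("AAAAAAK", "isoA", 2, 50.0),
        ],
        samples,
    )
    lfq, _ = prot.assign_peptides(df, samples)
    assert lfq.loc["isoA", "s1"] == 150.0


def test_twin_isoforms_are_unquantifiable():
    samples = ["s1"]
    df = _pep_table([("AAAAAAK", "twinA;twinB", 1, 100.0)], samples)
    lfq, unquant = prot.assign_peptides(df, samples)
    assert lfq.empty
    assert set(unquant) == {"twinA", "twinB"}


def test_moving_peptide_to_shared_never_raises_lfq():
    samples = ["s1"]
    before = _pep_table(
        [("AAAAAAK", "isoA", 1, 100.0), ("CCCCCCK", "isoA", 1, 40.0)], samples
    )
    after = _pep_table(
        [("AAAAAAK", "isoA;isoB", 1, 100.0), ("CCCCCCK", "isoA", 1, 40.0)], samples
    )
    lfq_before, _ = prot.assign_peptides(before, samples)
    lfq_after, _ = prot.assign_peptides(after, samples)
    assert lfq_after.loc["isoA", "s1"] <= lfq_before.loc["isoA", "s1"]


# ---------------------------------------------------------------------------
# Trend differences


def test_trend_delta_above_one_is_called():
    design = _design(2, 2)
    # isoform a: 2^24 -> 2^25.2 (log2FC +1.2); b: 2^24 -> 2^23.7 (-0.3)
    lfq = pd.DataFrame(
        {
            "d0_r1": [2**24.0, 2**24.0],
            "d0_r2": [2**24.0, 2**24.0],
            "d1_r1": [2**25.2, 2**23.7],
            "d1_r2": [2**25.2, 2**23.7],
        },
        index=["g-a", "g-b"],
    )
    res = prot.trend_differences(lfq, {"g-a": "g", "g-b": "g"}, design, [(0, 1)])
    assert len(res) == 1
    assert res.iloc[0]["max_delta"] == pytest.approx(1.5, abs=1e-6)
    assert bool(res.iloc[0]["trend_change"])


def test_trend_equal_trajectories_no_call():
    design = _design(2, 2)
    lfq = pd.DataFrame(
        {
            "d0_r1": [100.0, 200.0],
            "d0_r2": [100.0, 200.0],
            "d1_r1": [400.0, 800.0],
            "d1_r2": [400.0, 800.0],
        },
        index=["g-a", "g-b"],
    )
    res = prot.trend_differences(lfq, {"g-a": "g", "g-b": "g"}, design, [(0, 1)])
    assert res.iloc[0]["max_delta"] == pytest.approx(0.0, abs=1e-9)
    assert not res.iloc[0]["trend_change"]


def test_trend_invariant_to_max_normalization():
    design = _design(2, 2)
    rng = np.random.default_rng(8)
    lfq = pd.DataFrame(
        rng.lognormal(17, 1, size=(2, 4)),
        index=["g-a", "g-b"],
        columns=design.index,
    )
    res_raw = prot.trend_differences(lfq, {"g-a": "g", "g-b": "g"}, design, [(0, 1)])
    res_norm = prot.trend_differences(
        prot.normalize_to_max(lfq), {"g-a": "g", "g-b": "g"}, design, [(0, 1)]
    )
    assert res_raw.iloc[0]["max_delta"] == pytest.approx(
        res_norm.iloc[0]["max_delta"]
    )


# ---------------------------------------------------------------------------
# NMD


def test_nmd_rule_examples():
    m = TranscriptModel("t", "chr1", "+", ((0, 200), (300, 500), (600, 800)))
    # last junction at transcript position 400
    assert prot.predict_nmd(m, (0, 340)) == "NMD-sensitive"   # 60 upstream
    assert prot.predict_nmd(m, (0, 350)) == "NMD-sensitive"   # exactly 50
    assert prot.predict_nmd(m, (0, 351)) == "insensitive"     # 49
    assert prot.predict_nmd(m, (0, 450)) == "insensitive"     # stop in last exon
    mono = TranscriptModel("m", "chr1", "+", ((0, 900),))
    assert prot.predict_nmd(mono, (0, 100)) == "insensitive"


def test_nmd_matches_coordinate_oracle_on_random_structures():
    rng = np.random.default_rng(9)
    for _ in range(1000):
        n_exons = int(rng.integers(1, 8))
        lengths = rng.integers(30, 400, size=n_exons)
        exons = []
        pos = 0
        for L in lengths:
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(rng.integers(100, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        m = TranscriptModel("t", "chr1", strand, tuple(exons))
        total = int(lengths.sum())
        orf_end = int(rng.integers(3, total + 1))
        t_lengths = list(lengths) if strand == "+" else list(lengths[::-1])
        assert prot.predict_nmd(m, (0, orf_end)) == nmd_oracle(t_lengths, orf_end)


def test_longest_orf_finds_atg_to_stop():
    seq = "CC" + "ATG" + "AAA" * 5 + "TAA" + "GG"
    start, end = prot.longest_orf(seq)
    assert seq[start : start + 3] == "ATG"
    assert seq[end - 3 : end] == "TAA"
    assert prot.longest_orf("CCCCCC") is None


# ---------------------------------------------------------------------------
# RNA-protein correlation


def test_correlation_identity_at_lag_zero():
    rng = np.random.default_rng(10)
    fc = pd.DataFrame(
        {"d0-d1": rng.normal(size=100)}, index=[f"g{i}" for i in range(100)]
    )
    res = prot.rna_protein_correlation(fc, fc)
    assert res.iloc[0]["rho"] == pytest.approx(1.0)


def test_correlation_null_is_small():
    rng = np.random.default_rng(11)
    ok = 0
    for _ in range(20):
        idx = [f"g{i}" for i in range(200)]
        r = pd.DataFrame({"d0-d1": rng.normal(size=200)}, index=idx)
        p = pd.DataFrame({"d0-d1": rng.normal(size=200)}, index=idx)
        rho = prot.rna_protein_correlation(r, p).iloc[0]["rho"]
        ok += abs(rho) < 0.2
    assert ok >= 19


def test_correlation_recovers_planted_lag():
    """Protein changes shifted one day after RNA: the argmax correlation
    sits on the lagged comparison."""
    rng = np.random.default_rng(12)
    idx = [f"g{i}" for i in range(150)]
    base = {f"d{k}-d{k+1}": rng.normal(size=150) for k in range(3)}
    rna = pd.DataFrame(base, index=idx)
    protein = pd.DataFrame(
        {
            "d1-d2": base["d0-d1"] + rng.normal(0, 0.3, 150),
            "d2-d3": base["d1-d2"] + rng.normal(0, 0.3, 150),
        },
        index=idx,
    )
    res = prot.rna_protein_correlation(rna, protein)
    best = res.loc[res["rho"].idxmax()]
    assert (best["rna_comparison"], best["protein_comparison"]) in {
        ("d0-d1", "d1-d2"),
        ("d1-d2", "d2-d3"),
    }


def test_correlation_restriction_to_significant_features():
    idx = [f"g{i}" for i in range(10)]
    rng = np.random.default_rng(13)
    r = pd.DataFrame({"c": rng.normal(size=10)}, index=idx)
    p = pd.DataFrame({"c": rng.normal(size=10)}, index=idx)
    sig = pd.DataFrame({"c": [True] * 4 + [False] * 6}, index=idx)
    res = prot.rna_protein_correlation(r, p, rna_significant=sig)
    assert res.iloc[0]["n"] == 4
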