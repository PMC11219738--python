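"""End-to-end orchestration: write a full synthetic study to disk and run
the downstream stages on the files, mirroring shell usage."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import catalog as cat
from . import differential as diff
from . import io as iio
from . import synthetic as syn
from .models import ExpressionMatrix, make_design


def simulate_to_dir(config: syn.SimulationConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input under ``outdir`` (one-line-header
    TSVs, GTF, FASTA, BED) plus ground-truth tables under ``truth/``."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    ref = syn.generate_reference(config)

    n_reads = max(60 * config.n_genes, 500)
    reads = syn.simulate_long_reads(
        ref,
        n_reads=n_reads,
        seed=config.seed + 1,
        internal_jitter=config.internal_jitter,
        end_jitter=config.end_jitter,
    )
    switch_plan = syn.make_switch_plan(
        ref.annotation, config.switch_fraction, config.switch_dif,
        config.n_days, seed=config.seed + 2,
    )
    counts = syn.simulate_counts(
        ref.annotation,
        n_days=config.n_days,
        replicates=config.replicates_per_day,
        switch_plan=switch_plan,
        seed=config.seed + 3,
        dispersion=config.dispersion,
    )
    junc_support = syn.junction_support_table(ref.annotation, seed=config.seed + 4)

    genome = ref.genome
    ev_genome, events = syn.make_cassette_events(60, seed=config.seed + 5)
    genome = {**genome, **ev_genome}
    included = [e.id for e in events[:15]]
    excluded = [e.id for e in events[15:30]]
    psi_plan = syn.make_psi_plan(
        [e.id for e in events], config.n_days, included, excluded
    )
    junctions = syn.simulate_junction_counts(
        [e.id for e in events], psi_plan,
        replicates=config.replicates_per_day, seed=config.seed + 6,
    )
    plant = config.motif_plant
    if plant.get("fraction", 0) > 0:
        inc_events = [e for e in events if e.id in set(included)]
        genome, plant_log = syn.plant_motifs(
            genome, inc_events, plant["motif"], plant["segment"],
            plant["fraction"], seed=config.seed + 7,
            copies=plant.get("copies", 3),
        )
    else:
        plant_log = pd.DataFrame(columns=["event_id", "chrom", "pos", "motif"])
    peaks, peak_log = syn.plant_clip_peaks(
        [e for e in events if e.id in set(included)], "dnIntron5p", 1.0,
        seed=config.seed + 8,
    )

    seqs, gene_of = syn.generate_protein_isoforms(
        max(config.n_genes // 2, 4), seed=config.seed + 9
    )
    plan = syn.default_abundance_plan(gene_of, config.n_days)
    peptides = syn.simulate_peptides(
        seqs, gene_of, plan,
        n_days=config.n_days, replicates=config.replicates_per_day,
        missingness=config.peptide_missingness, seed=config.seed + 10,
    )

    iio.write_gtf(ref.annotation, outdir / "reference.gtf")
    iio.write_fasta(genome, outdir / "genome.fa")
    iio.write_reads(reads, outdir / "reads.bed12.tsv")
    counts.data.rename_axis("isoform_id").to_csv(outdir / "counts_isoform.tsv", sep="\t")
    counts.design.to_csv(outdir / "design.tsv", sep="\t")
    junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    junc_support.to_csv(outdir / "junction_support.tsv", sep="\t", index=False)
    iio.write_bed(ref.cage_peaks, outdir / "cage.bed")
    iio.write_bed(ref.polya_sites, outdir / "polya.bed")
    iio.write_bed(peaks, outdir / "clip_peaks.bed")
    pd.DataFrame(
        [
            {"rbp_name": "HuR", "iupac_motif": "UUUUU"},
            {"rbp_name": "RBFOX2", "iupac_motif": "UGCAUG"},
            {"rbp_name": "QKI", "iupac_motif": "ACUAAY"},
            {"rbp_name": "PTBP1", "iupac_motif": "YUCUCU"},
        ]
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)

    events_df = pd.DataFrame(
        [
            {
                "event_id": e.id, "chrom": e.chrom, "strand": e.strand,
                "up_start": e.upstream_exon[0], "up_end": e.upstream_exon[1],
                "target_start": e.target_exon[0], "target_end": e.target_exon[1],
                "dn_start": e.downstream_exon[0], "dn_end": e.downstream_exon[1],
            }
            for e in events
        ]
    )
    events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)

    truth = outdir / "truth"
    pd.DataFrame(
        [{"read_id": r.id, "source_isoform": r.source_isoform, "label": r.truth_label}
         for r in reads]
    ).to_csv(truth / "read_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "event_type": t} for g, t in sorted(ref.planted_events.items())]
    ).to_csv(truth / "planted_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": g, **{k: str(v) for k, v in p.items()}}
            for g, p in sorted(switch_plan.items())
        ]
    ).to_csv(truth / "switch_plan.tsv", sep="\t", index=False)
    psi_plan.rename_axis("event_id").to_csv(truth / "psi_plan.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "event_id": e.id,
                "regulation": "included" if e.id in set(included)
                else "excluded" if e.id in set(excluded)
                else "background",
            }
            for e in events
        ]
    ).to_csv(truth / "regulation.tsv", sep="\t", index=False)
    plant_log.to_csv(truth / "motif_plants.tsv", sep="\t", index=False)
    peak_log.to_csv(truth / "clip_plants.tsv", sep="\t", index=False)

    return {
        "reference": ref,
        "genome": genome,
        "reads": reads,
        "counts": counts,
        "junctions": junctions,
        "junction_support": junc_support,
        "events": events,
        "included": included,
        "excluded": excluded,
        "peptides": peptides,
        "protein_gene_of": gene_of,
        "switch_plan": switch_plan,
    }


def run_catalog_stage(sim: dict, **kwargs) -> list:
    ref = sim["reference"]
    return cat.build_catalog(
        sim["reads"], ref.annotation, sim["genome"],
        ref.cage_peaks, ref.polya_sites, sim["junction_support"], **kwargs,
    )


def run_differential_stage(sim: dict) -> dict:
    counts: ExpressionMatrix = sim["counts"]
    ref = sim["reference"]
    _, norm = diff.rle_normalize(counts.data)
    norm_mat = ExpressionMatrix(data=norm, design=counts.design, kind="normalized")
    lengths = pd.Series(
        {t.id: t.length for t in ref.annotation.transcripts.values()}
    )
    tpm = ExpressionMatrix(
        data=diff.tpm_from_counts(counts.data, lengths),
        design=counts.design,
        kind="tpm",
    )
    gene_of = {t.id: t.gene_id for t in ref.annotation.transcripts.values()}
    if_table, genes = diff.compute_usage(tpm, gene_of)
    days = counts.days
    pairs = diff.consecutive_day_pairs(days)
    out = {"pairs": pairs, "dge": {}, "dtu": {}, "psi": {}}
    for a, b in pairs:
        out["dge"][(a, b)] = diff.dge(norm_mat, a, b)
        out["dtu"][(a, b)] = diff.dtu_test(if_table, genes, counts.design, a, b)
        out["psi"][(a, b)] = diff.psi_and_classify(sim["junctions"], a, b)
    return out
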