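# isodyn

Transcript isoforms — alternative starts, splice variants, alternative
polyadenylation — shift massively during processes such as neuronal
differentiation, and the shifts propagate (with a lag, and only partly)
to the proteome. `isodyn` is a desk-scale, fully testable implementation
of the analysis stack used for such multi-omics time courses:

1. **Long-read isoform cataloging** — collapse nanopore-style exon
   chains into isoform models, classify them against a reference
   annotation into **FSM / ISM / NIC / NNC / fusion**, and curate the
   catalog with artifact filters (oligo-dT mispriming into A-rich
   genomic tracts, reverse-transcriptase template switching,
   CAGE/polyA-site end support).
2. **Event annotation** — compare each isoform with its gene's
   hypothetical pre-mRNA (exon union) and call the eight event types
   ATSS, ATTS, A5, A3, SES, MES, MEE, IR; summarize event gains/losses
   between differentially used isoforms.
3. **Differential analyses over a 6-day design** — RLE (median-of-ratios)
   normalization; differential expression at padj < 0.05 and
   |log2FC| > 0.59; differential transcript usage via isoform fractions
   (IF = isoform TPM / gene TPM) at padj < 0.05 and |dIF| ≥ 0.1; and
   junction-count cassette-exon inclusion
   Ψ = ((I₁+I₂)/2) / ((I₁+I₂)/2 + S) with the regulated-event partition
   (included: ΔΨ > 0.05 & FDR < 0.05; excluded: ΔΨ < −0.05 & FDR < 0.05;
   background: FDR > 0.5).
4. **Positional RBP maps** — eight sequence segments around each cassette
   exon (50 bp of flanking/target exon ends, 250 bp of intron ends),
   motif scores as percent coverage in a 50-bp sliding window, per-position
   rank-sum tests of regulated vs background events (region call at
   min-p < 0.001), and CLIP-peak density with Fisher's exact test
   (region call at p < 0.05), plus motif/peak co-occurrence flags.
5. **Protein isoforms** — presence filtering (≥2 of 3 replicates in one
   condition), left-censored MNAR imputation (shift 1.8 σ, scale 0.3 σ),
   differential enrichment at padj < 0.1 and |log2FC| > 0.32,
   unique-peptide isoform LFQ, **trend differences**
   (|log2FC_A − log2FC_B| ≥ 1 between isoforms of one gene), the 50-nt
   NMD rule, and lagged RNA–protein Spearman correlation.

A first-class synthetic-data generator (`isodyn.synthetic`) produces
every input the pipeline consumes — annotation, genome, reads with
planted artifact classes, count matrices with planted usage switches,
junction counts around planted Ψ, motif/peak plants, peptide tables with
intensity-dependent missingness — with complete ground truth, so every
stage is testable without downloads.

## Worked example

```python
import pandas as pd
from isodyn.synthetic import (SimulationConfig, generate_reference,
                              simulate_long_reads, junction_support_table,
                              make_switch_plan, simulate_counts)
from isodyn.catalog import build_catalog, catalog_table
from isodyn import differential as d
from isodyn.models import ExpressionMatrix

cfg = SimulationConfig(seed=1, n_genes=24,
                       artifact_rates={"mispriming": 0.15,
                                       "template_switch": 0.15},
                       switch_fraction=0.4)
ref = generate_reference(cfg)
reads = simulate_long_reads(ref, 2000, seed=2)
records = build_catalog(reads, ref.annotation, ref.genome,
                        ref.cage_peaks, ref.polya_sites,
                        junction_support_table(ref.annotation, seed=3))
print(catalog_table(records).groupby(["class", "retained"]).size())
```

```
class  retained
FSM    True        48
ISM    False       27
NNC    False       43
```

All 48 clean full-splice-match isoforms survive curation; the 27 ISM
records (misprimed 3′ ends, unsupported 5′ ends) and 43 NNC records
(template-switch junctions, neither canonical nor short-read-supported)
are removed. Continuing with usage analysis between day 0 and day 5:

```python
plan = make_switch_plan(ref.annotation, 0.4, 0.4, 6, seed=4)
counts = simulate_counts(ref.annotation, switch_plan=plan, seed=5)
lengths = pd.Series({t.id: t.length for t in ref.annotation.transcripts.values()})
tpm = ExpressionMatrix(d.tpm_from_counts(counts.data, lengths),
                       counts.design, "tpm")
gene_of = {t.id: t.gene_id for t in ref.annotation.transcripts.values()}
if_table, genes = d.compute_usage(tpm, gene_of)
res = d.dtu_test(if_table, genes, counts.design, 0, 5)
print(res[res.significant].sort_values("dIF", ascending=False)
         [["isoform_id", "gene_id", "dIF", "padj"]].head(4).round(4))
```

```
isoform_id gene_id    dIF   padj
   G0021.2   G0021 0.5438 0.0304
   G0014.2   G0014 0.4573 0.0267
   G0008.2   G0008 0.4559 0.0037
   G0011.2   G0011 0.4300 0.0304
```

The generator planted a dIF = 0.4 usage switch in 10 of 24 genes between
day 0 and day 5; at 3 replicates the test recovers 9 of the 10 (each
recovered dIF within sampling noise of 0.4) with no false positives.

A command-line interface mirrors the library
(`isodyn simulate / catalog / events / diff / rbpmap / protein`); run
`isodyn --help` for the file-level contracts.

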