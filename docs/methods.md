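# Methods

This note documents the models, decision rules, numerical choices and
limitations of `isodyn`, stage by stage. Coordinates are 0-based
half-open internally; GTF output is 1-based inclusive and BED stays
0-based half-open. The genome alphabet is A/C/G/T (no N handling).

## Isoform cataloging

**Collapse.** Reads sharing chromosome, strand and exon count are merged
greedily when every internal exon boundary agrees within `internal_tol`
(default 5 nt) and both transcript ends agree within `end_tol` (50 nt);
the cluster representative takes the per-boundary median, and clusters
with fewer than `min_cluster` (3) reads are discarded. These defaults
are the standard nanopore transcript-clustering parameters
(`-c 3 -d 5 -e 50`). Greedy assignment with a running median makes the
result order-dependent in principle; in practice clusters are separated
by far more than the tolerance and the unit tests include a brute-force
comparison on small read sets.

**Classification.** The unit of identity is the splice-junction chain
(the ordered intron intervals). A model is **FSM** when its chain equals
a reference transcript's chain; **ISM** when it is a contiguous proper
sub-chain; **fusion** when its junctions match references of two or more
non-overlapping gene loci; **NIC** when every donor and acceptor site is
annotated but the chain matches no reference; otherwise **NNC**.
Checks run in that order, so a fusion (which may use only annotated
sites) is never mislabelled NIC. Mono-exon models are FSM when contained
in a mono-exon reference within `end_tol`, else NNC — junction-based
classes are undefined without junctions, and an unannotated standalone
exon is best treated as novel-not-in-catalog.

**Artifact flags.** A transcript is flagged as a potential oligo-dT
mispriming product when the 20-nt genomic window immediately 3′ of its
end (sense strand) is ≥ 60% adenine. The 60% rule is the standard
threshold; the 20-nt window is the smallest span in which 60% is
meaningful and is the convention for this artifact class. A junction is
canonical when its intron-terminal dinucleotides (transcript strand) are
GT..AG, GC..AG or AT..AC; any non-canonical junction sets the
template-switch flag.

**End support.** The 5′ end must fall within 50 nt of a CAGE peak, the
3′ end within 50 nt of a polyA-site cluster, and a polyA motif (default
AATAAA/ATTAAA, configurable) must occur within 50 nt upstream of the 3′
end on the transcript strand. The window sizes are this package's
choices; upstream placement of the motif search follows polyadenylation
biology (the hexamer precedes the cleavage site).

**Curation.** FSM/ISM records are retained only with no mispriming
flag, no template-switch junction, and all three end supports. NIC /
NNC / fusion records are retained when not misprimed and every junction
is canonical or carries short-read support ≥ 10. The short-read support
rule doubles as the operative template-switch test for novel classes:
a switch junction is non-canonical and, being an RT artifact, has no
genuine short-read coverage. Curation is monotone in junction support by
construction.

**Quantification.** Each read is assigned to the single best-matching
catalog isoform: most shared junctions (each within `internal_tol`),
ties to the longest isoform, remaining ties to the smallest id. This
deterministic rule replaces EM-based multi-mapping resolution; synthetic
reads are unambiguous by construction, and the tie-break keeps
truncation-derived reads with their full-length parent.
TPM_i = (c_i / ℓ_i) / Σ_j (c_j / ℓ_j) × 10⁶ with ℓ the summed exon
length.

## Event annotation

The gene's hypothetical pre-mRNA is the union of all exon intervals
across its isoforms (merged where overlapping). Per isoform:

- **SES / MES** — maximal runs of absent internal pre-mRNA exons lying
  between retained exons; run length 1 is SES, ≥ 2 is MES.
- **IR** — an isoform exon strictly covering another isoform's intron.
- **A5 / A3** — two introns sharing one boundary and differing at the
  other, with overlapping flanking exons at the shifted side (the exon
  overlap requirement keeps plain exon skipping from masquerading as an
  alternative splice site). Naming is in transcript orientation: A5 is
  the donor side.
- **ATSS / ATTS** — the outer 5′/3′ boundary differs by more than 50 nt
  from every other isoform's corresponding boundary. The 50-nt tolerance
  matches the collapse end tolerance, so closely spaced alternative ends
  are not called.
- **MEE** — a pair of non-overlapping internal exons of which the
  isoform holds exactly one, a partner isoform holds exactly the other,
  and no isoform holds both. The pairwise-witness reading was chosen
  over demanding exclusivity across all isoform pairs; the "no isoform
  holds both" guard prevents two independent skipping variants from
  being read as MEE. Exons consumed by an MEE call are excluded from
  SES/MES runs, otherwise every MEE would also surface as skipping.

An isoform may carry several labels; none take priority. Gain/loss
summaries pair each significant DTU gene's most-upregulated (max dIF)
and most-downregulated (min dIF) isoforms and report per-type set
differences of their event labels.

## Differential analyses

**Normalization.** RLE size factors: per sample, the median over
features of count / geometric-mean-across-samples, excluding features
with a zero anywhere. Cross-checked in the tests against both a looped
oracle and pyDESeq2's implementation.

**Tests.** The reference tools' negative-binomial Wald and LRT machinery
is deliberately replaced by Welch t-tests — on log2(normalized + 1) for
expression, on logit-clamped isoform fractions (clamp [0.01, 0.99]) for
usage — with Benjamini–Hochberg correction. What this package reproduces
is the decision rules and thresholds; all validation is
calibration/recovery based on simulations. Two consequences are worth
stating plainly:

- the per-gene Welch test shares no dispersion information across genes,
  so its power at 3 replicates is measurably below a moderated NB test
  (≈ 0.69 vs > 0.9 for 4-fold changes at dispersion 0.05 in the test
  suite's own simulation);
- groups that are exactly constant and equal return p = 1; constant but
  different groups (zero variance) also fall back to p = 1 rather than
  claiming infinite evidence — this occurs only in degenerate noise-free
  fixtures.

**Thresholds** (all as printed): expression padj < 0.05 and
|log2FC| > 0.59 (≥ 50% change; a pseudocount of 1 stabilizes the
ratio); usage padj < 0.05 and |dIF| ≥ 0.1; proteins padj < 0.1 and
|log2FC| > 0.32 (≥ 25% change). Transcript-level differential
expression is the same machinery applied to the isoform count matrix.
The usage filter keeps genes with mean TPM > 1 at every day and ≥ 2
detected isoforms. Per gene and sample, IF sums to 1 and per-gene dIF
sums to 0 (asserted invariants).

**Cassette-exon inclusion.** Per replicate
Ψ = ((I₁+I₂)/2) / ((I₁+I₂)/2 + S): two junctions support inclusion and
one supports skipping, hence the 2:1 correction. Replicates with no
informative reads are dropped; events need ≥ 2 informative replicates
per group. The group comparison is a two-sided rank-sum test
(exact when group sizes permit, normal approximation with tie
correction otherwise — scipy's policy), BH-corrected. The partition is
exactly: included ΔΨ > 0.05 & FDR < 0.05; excluded ΔΨ < −0.05 &
FDR < 0.05; background FDR > 0.5; otherwise unassigned. Note the exact
two-sided rank-sum at 3 vs 3 replicates has minimum p = 0.1, so
regulated calls require ≥ 4–5 replicates or an externally supplied
regulation table; the test suite exercises calling power at 5
replicates and the partition itself on constructed fixtures.

## Positional RBP maps

Eight segments per cassette event, in transcript orientation: the last
50 bp of the upstream exon, first/last 250 bp of the upstream intron,
first/last 50 bp of the target exon, first/last 250 bp of the
downstream intron, first 50 bp of the downstream exon. Segments are
clipped to feature length, so the two segments of a < 500 nt intron
overlap. Sequences are reverse-complemented on minus-strand events so
position 0 is always a segment's 5′-most base.

Motif scores: IUPAC consensus matches (overlapping matches included;
U ≡ T) give a 0/1 coverage mask; the per-position score is the percent
of covered bases in a 50-bp window centered there, using the available
bases near segment edges as the denominator (the edge convention is
this package's choice). Per position, the regulated and background
event-score distributions are compared with a two-sided rank-sum test
(two-sided because directionality is not assumed; the flag is
configurable); a region is enriched when its minimum p across positions
is < 0.001. CLIP peak density is the fraction of events with a peak
covering the position; per-position 2×2 Fisher exact tests against the
background give a region call at min-p < 0.05. Co-occurrence requires
both calls in the same region. PWMs and peak calling are out of scope;
motifs are consensus strings only.

## Protein isoforms

Presence filter: ≥ 2 observed replicates in at least one condition.
MNAR imputation: per sample, missing cells are drawn from
N(μ − 1.8 σ, (0.3 σ)²) with μ, σ the observed mean and standard
deviation of that sample — the standard left-censored model for
intensities below detection. Observed values are never modified.

Isoform LFQ uses unique peptides exclusively; per-fraction intensities
are summed into one value per isoform and sample, and isoforms with no
unique peptide are reported unquantifiable. Trend differences compare
isoforms of one gene via Δ = |log2FC_A − log2FC_B| per day pair — fold
changes are comparable where absolute intensities are not — with a
trend change called at Δ ≥ 1. Fold changes are computed on
observed-only per-day means (pairwise complete); whether to impute
first is configurable, and log2FCs are invariant to the per-isoform
max-normalization used for display.

NMD: a transcript is NMD-sensitive when its ORF's stop codon ends at
least 50 nt upstream of the last exon–exon junction (boundary value 50
is sensitive); mono-exon transcripts are never sensitive. ORFs are the
longest ATG-initiated reading frame with an in-frame stop — a
deliberate stand-in for dedicated coding-potential predictors.

RNA–protein coupling: Spearman ρ of log2 fold changes joined on feature
id, for every pair of day-pair comparisons including lagged ones,
optionally restricted to features significant in at least one
comparison.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design — six days, three replicates —
and plants: all eight event types (in rotation across genes); artifact
reads (5′ truncations; mispriming reads ending at a 20-nt, exactly-70%-A
tract placed 3–40 nt downstream of an internal donor exon end — chosen
to be detectable by the 60% rule; template-switch reads with one donor
shifted 8+ nt to a non-canonical, unannotated site; fusion reads joining
two same-strand genes); usage switches of dIF 0.4 (default) moving
linearly from day 0 to day 5 between two isoforms centered around a
0.7/0.3 split; binomial junction counts around planted Ψ; motif and
CLIP-peak plants in named segments of included events; and two protein
isoforms per gene sharing terminal blocks with a variable middle,
digested by the standard tryptic rule (cleave after K/R, not before P,
7–30 aa retained).

Distributional choices are stand-ins, not inferences about any real
dataset: counts are gamma-Poisson with variance μ + αμ² (α = 0.05
default; α = 0 gives the deterministic rounded-mean limit), library
size factors are uniform on [0.8, 1.25], peptide intensities are
log-normal, and peptide missingness is rank-based with probability
2 m (1 − q) at intensity quantile q (mean rate m, concentrated in low
intensities). Artifact variants are deterministic per isoform so that
artifact reads form collapsible clusters, as repeated RT artifacts do.
Genomes are uniform random with planted canonical dinucleotides, polyA
motifs ~20 nt upstream of each 3′ end, and de-A-enriched windows
downstream of true ends so genuine transcripts never look misprimed.

Consequences for interpretation: passing tests show the decision rules,
filters and estimators behave as specified under controlled conditions
with known truth. They do not show robustness to features the generator
lacks — base-level sequencing error, quality scores, degraded RNA,
ambiguous multi-mapping reads, correlated replicates, batch effects, or
isoform-specific peptide detectability.

## Numerical details

- Random draws all flow through `numpy.random.default_rng` seeded
  explicitly; fixed seeds give bit-identical outputs.
- BH adjustment uses statsmodels' `fdr_bh`, verified against a step-up
  oracle.
- Rank-sum positional tests are vectorized across positions; constant
  columns are assigned p = 1. Fisher 2×2 results are memoized on the
  table counts (peak masks are blocky, so few distinct tables occur).
- Degenerate inputs: empty event sets raise; Ψ with zero informative
  reads is NaN and dropped; genes with zero TPM give NaN fractions;
  quantification with no junction match leaves a read unassigned.
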