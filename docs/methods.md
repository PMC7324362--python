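# Methods

This note documents the models implemented in `metaribo`, the conventions
and tunables that matter, what the synthetic-community generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## ORF calling

ORFs are predicted by an explicit six-frame scan rather than a trained gene
model. In each frame, every in-frame stop codon closes the ORF that begins
at the *outermost* upstream in-frame start codon (ATG, GTG, or TTG) with no
intervening stop — the maximal-ORF convention. Without a start-scoring
model this is the only reproducible choice, and the simulator plants genes
whose true start is unambiguous (an in-frame stop sits immediately
upstream). ORFs shorter than `min_orf_nt` (default 15 bp) are dropped.
Partial ORFs at contig edges are not reported.

Protein length counts the initiator Met and excludes the stop codon; the
smORF window (default 5–50 aa) applies to this count. The window's
phrasing "including start and stop codons" is ambiguous about whether the
stop contributes an amino acid; a stop codon is not an amino acid, so the
count above is used and both bounds are configurable. Translation follows
the bacterial code (table 11) with any permitted initiator rendered as Met.

## Mapping and the perfect-unique filter

Because downstream analyses only consume alignments that are perfect
(0 mismatches) and unique (exactly one genomic location), the mapper's full
semantics are exact substring matching: seed on the read's first k-mer
(default k = 21), verify the complete read on both strands, and record
every 0-mismatch location. `n_hits` is carried on each record so uniqueness
filtering is a pure, idempotent predicate. Reads shorter than k are dropped
with a logged count. Externally produced SAM (with mandatory NM tags) can
be filtered identically; `n_hits` is then the number of equal-best records
per read, or the NH tag when present.

## Signal diagnostics

Footprint signal is assigned to the 5′ end of each alignment — the leftmost
base on the + strand, rightmost on the − strand — with **no P-site
offset**: offsetting is a calibration with no defined ground truth here,
and raw 5′-end signal already carries the start/stop and frame structure
being tested.

* **Metagene profile**: per gene with ≥ `min_reads_metagene` (default 10)
  in-ORF 5′ ends, the window of ±`metagene_flank_nt` (default 50) around
  the start (or the first nucleotide of the stop codon) is extracted in the
  gene's reading direction, normalized to sum 1, and averaged over genes.
  Per-gene normalization makes the profile invariant to any single gene's
  coverage scale.
* **Start enrichment**: mean metagene signal over offsets [0, 12) divided
  by the mean over the remaining downstream window. A zero body mean
  returns +inf with a warning.
* **Triplet periodicity**: in-ORF 5′ ends are classified by (offset from
  start) mod 3; Pearson's χ² against (⅓,⅓,⅓) with 2 df. Zero in-ORF signal
  returns counts (0,0,0) and p = 1.

## Quantification

A read is counted for a feature when its 5′ end lies within the feature
span; RNA and footprint assays additionally require strand agreement, while
metagenomic coverage is unstranded. A 5′ end inside two same-strand
overlapping features counts for both (multi-coverage semantics). 5′-end
containment, rather than any-overlap, keeps counting consistent with the
signal track and avoids boundary double-counting. Library size is the
number of retained unique-perfect alignments in the sample, not the number
of feature-assigned reads. The translation call is strictly RPKM > 10.
Translational efficiency is the RPKM ratio footprints/mRNA, undefined (NaN)
at zero mRNA — a stated convention; nothing downstream depends on it.
Pearson correlations of abundance vectors are computed on log10 values with
a pseudocount of half the smallest positive value; distribution differences
use the two-sample Kolmogorov–Smirnov test, and differences between two
dependent overlapping correlations use Zou's (2007) 95% confidence interval
on r12 − r13.

## Protein families

Database-style pairwise hits use Smith–Waterman local alignment (BLOSUM62,
gap open 11 / extend 1) with Karlin–Altschul statistics (λ = 0.267,
K = 0.041, the standard gapped BLOSUM62 parameters) and search space
len(query) × len(subject) × N_subjects. Identity is identical residues over
local-alignment columns (internal gaps count, end gaps do not exist in a
local alignment).

Greedy clustering processes sequences longest-first (ties by id); each
sequence joins the qualifying cluster of highest identity (best-match, the
`-g 1` behaviour) or founds a new one. Qualification against a
representative requires identity ≥ c, candidate/representative length
ratio ≥ `cluster_length_diff_cutoff` (the `-s` mirror, default 0.95), and
alignment coverage of the representative ≥ `cluster_long_coverage` (the
`-aL` mirror, default 0.95). Clustering qualification deliberately uses an
**end-to-end global alignment** (end gaps penalized) rather than the local
model: local alignment clips terminal mismatches, which spuriously fails
the coverage rule for equal-length homologs at 80–90% identity, whereas
banded-global scoring — what identity-clustering tools actually compute —
keeps them end-to-end.

Homolog assignment to reference families keeps the best-e-value hit with
e ≤ 0.05 whose **alignment length** is within 90–110% of the query protein
length ("length of the hit" is read as alignment length; a switch to
subject length is a one-line change). A family is flagged as synthesized
when at least one linked smORF passes the translation call; the flag is
monotone under added evidence. Unique-DNA collapse is exact string
deduplication of member nucleotide sequences. Domain enrichment between a
population and a subset is the upper-tail hypergeometric probability.

## Differential testing

Counts are normalized with median-of-ratios size factors (reference:
per-gene geometric mean over columns, genes with any zero excluded). Each
gene is tested by a likelihood-ratio χ² between nested NB GLMs (log link,
log size factors as offsets): condition effect per assay, or the
`samplegroup:type` interaction — the translational-regulation effect
controlling for transcription. log₂FC is the fitted coefficient / ln 2.

Dispersion is estimated per gene by method-of-moments on normalized counts
pooled within design cells, then **shrunk 50/50 toward the across-gene mean
estimate** and floored at 1e-8. The moderation matters: with 3 replicates
per cell the raw gene-wise estimate is noisy and its negative excursions
floor to zero, which makes the plug-in LRT anti-conservative (≈7% raw
p < 0.05 under a simulated global null); equal-weight shrinkage restores
calibration (≈4–5% across seeds) while keeping genuinely high-dispersion
genes conservative. Genes with all-zero counts are excluded before testing;
non-converging fits get p = NaN and drop out of the FDR denominator.

Multiple testing is Benjamini–Hochberg step-up (the convention behind
"FDR"); a gene is called when |log₂FC| is strictly above 1 and FDR strictly
below 0.05. The test suite verifies, beyond unit behaviour: sign
equivariance under group relabeling, BH dominance/monotonicity, null
calibration of the raw p-value fraction, and recovery of planted
interaction effects. Real duplicate-only designs (2 replicates per cell)
fit but have documented low power; the simulator's default is 3 replicates.

## Taxonomy, neighborhoods, localization

Reads take the taxon of the gene containing their 5′ end (strand rule as in
counting); reads in no gene, or in genes without labels, are unclassified
and tallied. When a 5′ end falls in two same-strand overlapping genes of
different taxa the gene with the closer start codon wins, and the ambiguity
count is logged — no external rule exists for this corner. Abundance tables
are fractions of classified reads; taxa strictly below 3% merge into
"Other". Neighborhoods are measured in gene-rank distance (1..10 by
default) along the start-sorted gene order of a contig, strand-blind.
Family localization is "secreted"/"transmembrane" when ≥ 80% of members
carry the per-protein flag (inclusive at exactly 80%); both labels can
co-occur. Per-protein secretion/transmembrane flags, domain-hit tables, and
comparative-genomics support flags are inputs from external predictors, not
computed here.

## The synthetic community

`simulate_community` packs planted genes (start codon, stop codon, no
internal in-frame stop, in-frame stop immediately upstream) into random
multi-taxon genomes, non-overlapping, with 20–100 nt spacers. Planted smORF
families diverge from a random ancestor; `aa_divergence` is the expected
*pairwise* divergence between members (each member mutates at the per-site
rate r solving (1−r)² + r²/19 = 1 − d), so a 30%-divergence family has
~70% pairwise identity. Optionally a family's members share DNA among a
fixed number of nucleotide variants, for unique-DNA collapse testing.

`simulate_abundances` draws transcription levels lognormal(μ, σ) (default
σ = 1, a realistic spread of community expression) and translational
efficiencies lognormal(0, 0.5); decoy genes get efficiency exactly 0.
Regulated subsets receive planted log₂ shifts between two conditions:
transcriptional regulation shifts mRNA and footprints together,
translational regulation shifts footprints only, "both" adds independent
shifts.

`simulate_reads` draws exact-substring reads (fixed length, quality "I")
from per-position weights: metagenomic uniform over both strands; RNA
uniform over gene spans ∝ transcription; footprint 5′ ends ∝ transcription
× efficiency, frame-weighted (default 0.6/0.2/0.2), with multiplicative
start-window (default 10× over 12 nt) and stop-window (5× over 12 nt)
peaks and an optional genome-wide background. Peak magnitudes are
calibration choices — no quantitative ground truth exists for them — and
the background defaults to 0: the generator idealizes footprints as
ORF-derived, and at desk-scale depth even single stray reads exceed
RPKM 10 on a short decoy, a regime the threshold was never designed for
(real libraries are orders of magnitude deeper). Position counts are
multinomial given the total, i.e. per-position Poisson conditioned on the
library size, so read accounting is exact. Genome and read streams take
separate seeds.

`simulate_counts` skips the read level for differential testing: per gene
and library, Poisson counts with lognormal replicate noise (default
σ = 0.15) and lognormal library-depth jitter (σ = 0.10), scaled so the
condition-1 mean is `mean_depth`.

**What the generator does not emulate** — sequencing errors and quality
variation (the perfect-match filter makes errors pure read loss), indels,
footprint-length heterogeneity, P-site geometry, rRNA/structured-RNA
contamination, overlapping genes on the same strand, operon structure, and
GC/codon bias. Passing tests therefore certify the *computations* — filter
semantics, counting conventions, statistical calibration, recovery of
planted structure — not robustness to these real-data artifacts.

## Problem sizes and determinism

Validation runs at desk scale, chosen so the full suite and the acceptance
script each complete in minutes: ORF/mapper oracles on 100 × 1 kb contigs
and 10 kb × 1k reads; signal-shape recovery at 50k footprints over 40
genes; translation evidence at 200k footprints over 100 translated + 100
decoy smORFs; clustering on 25-sequence planted family sets; differential
calibration and power at 2000 genes × 6–12 libraries with 50 planted
effects. The power scenario uses abundance spread σ = 0.5 so genes sit
near the stated mean depth of 50 counts; at σ = 1 a third of planted genes
fall below ~12 counts, where no count-based test retains power — the
remaining recovery shortfall is depth-limited, not methodological. All
randomness flows from explicit seeds; pipeline runs with the same config
and seed are byte-identical, verified by digest in the run report.

## Known limitations

* The exact-match mapper is the filter's semantics, not a general aligner:
  no mismatches, indels, clipping, or pairing.
* e-values use Karlin–Altschul statistics with fixed gapped BLOSUM62
  parameters; at very short lengths (< ~10 aa) they are approximate, which
  is acceptable because the homolog filter also demands 90–110% length
  coverage.
* The NB test is not a DESeq2 re-implementation: no dispersion trend
  fitting, no LFC shrinkage, no Cook's outlier handling. Its operating
  characteristics are instead verified directly by simulation.
* Greedy clustering is O(n × clusters) alignments; it is meant for
  thousands of smORFs, not the hundreds of thousands a word-indexed tool
  handles.
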