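# Methods

This note documents the models, conventions and numerical choices behind
`salifrag`, and what the synthetic-data tests do and do not establish about
real data.

## Fragment model and filtering

A fragment is one sequenced cfDNA molecule, represented as a 0-based
half-open genomic interval (BED convention; SAM/BAM 1-based positions are
converted on ingest). For properly paired alignments the fragment is the
template span counted once at the leftmost mate; for unpaired (merged)
reads it is the aligned reference span, on the assumption that read merging
upstream reconstructed the whole molecule. Duplicates are assumed removed
upstream (UMI-based dedup); no deduplication is performed here.

Default filters: mapping quality ≥ 20, length in [20, 400] bp, chromosomes
restricted to chr1–22, chrX, chrY, chrM. These are conventional cfDNA
choices, not values with special meaning, and are fully configurable.
Records with invalid coordinates, disallowed chromosomes, or ends beyond
the chromosome length (when a chrom.sizes table is supplied) are rejected
and tallied by reason rather than silently dropped.

Size histograms are tallied at 1-bp resolution on the configured length
range, with the y-axis in percent of reads; the denominator is the number
of fragments inside the range, so the histogram always sums to 100%.

## Jagged peak-valley index

The index quantifies the ruggedness of the size profile as the mean drop
from each detected peak to the first valley at a larger fragment length,
J = (1/n) Σ (Pᵢ − Vᵢ), in % reads units. J = 0 is returned when no pair
exists: a featureless histogram has no jaggedness.

Detection is a delta-gated alternating extremum search with a lookahead
window (defaults lookahead = 1, delta = 10⁻⁴). The scan alternates between
hunting a maximum and a minimum; a candidate is confirmed when the series
moves more than `delta` past it and no better candidate appears within the
next `lookahead` grid points. Three boundary conventions are fixed
deliberately:

* the first confirmed extremum is always a peak (an initial descent makes
  the first point a peak; an initial minimum is never reported);
* a valley still pending when the series ends is emitted, so the last
  interior peak always acquires its right-hand valley — without this flush
  a profile ending in a monotone descent would lose its final, often
  largest, peak/valley pair;
* a pending trailing peak is not emitted and therefore never enters the
  index (it has no valley to its right).

At delta = 0 on series with distinct values this reduces exactly to
neighbour comparison (every interior strict local extremum, plus the
boundary rules above), which is how the detector is certified in the tests
against an independent brute-force oracle. The detector runs on the
histogram exactly as built; no smoothing is applied.

## Binned fragmentomics

Chromosomes are tiled contiguously from 0 with fixed-size bins (default
1 Mb), the last bin per chromosome truncated; per-bin analyses are
restricted to autosomes. On GRCh38 chr1–22 (chromosome lengths vendored as
a plain-text chrom.sizes) this yields exactly 2887 bins. Fragments are
assigned to the single bin containing their midpoint ⌊(start+end)/2⌋ —
midpoint assignment avoids the boundary bias of leftmost-base assignment
for long fragments. Per-bin coverage is the bin's share of counted
fragments in percent (read counts, not base coverage).

The fragmentomic score is #(length < t) / #(length ≥ t) with t = 100 bp; a
fragment of exactly 100 bp counts as long so the two classes partition all
fragments. Bins with no long fragments carry an undefined (NaN) score and
are masked from downstream tests. The mitochondrial fraction is
100 · chrM / (chrM + autosomal + sex-chromosomal) fragments, i.e. the chrM
share of all human-mapped fragments.

## End motifs and G-quadruplex

Each fragment contributes two 4-mers: the reference bases at its left end
on the forward strand and the reverse complement of the bases at its right
end — the 5′ motifs of both strands of the duplex, pooled into one
256-word profile. Motifs are read from the reference at the aligned
boundaries rather than from read bases: this is robust to sequencing error,
lets fragment TSVs omit sequence, and confines ambiguity to reference Ns
(non-ACGT motifs are discarded and tallied; counted + discarded always
equals twice the attempted fragments). Entropy is Shannon's H in bits
(0–8 for 4-mers); any other log base is a monotone rescale.

G-quadruplex prevalence is the percentage of fragments whose sequence
matches G{min_run,}(N{1,max_loop}G{min_run,}){n_runs−1} with defaults
min_run = 3, max_loop = 7, n_runs = 4 (the common quadparser pattern).
Both strands are scanned by default; the reverse-strand match is evaluated
as the equivalent C-run pattern on the forward sequence, which makes the
statistic exactly strand-symmetric.

## Element annotation and coverage profiles

Peak calls are consumed in ENCODE narrowPeak form; a summit offset of −1
falls back to the peak midpoint. Each peak is assigned one category at its
summit with precedence promoter > 5utr > exon > intron > intergenic
(categories absent from the precedence list are appended after it).
Genome fractions per category are computed by resolving overlaps with the
same precedence; uncovered bases count as intergenic, so fractions sum
to 1. Observed/expected enrichment is (category share of peaks)/(category
share of genome); consequently the genome-share-weighted mean of O/E over
covered categories is exactly 1.

Relative coverage profiles accumulate per-base fragment coverage in
±2 kb windows (configurable) centred on element midpoints, orient
minus-strand elements 5′→3′, average across elements, and divide by the
window-wide mean — a flat profile is identically 1.

## Microbiome

Classifier output is consumed as a taxa × sample count table with
greengenes-style lineage strings; a host row (rank `host`, the reads that
re-aligned to the host inside the microbial database) is excluded from all
microbial denominators. Rank aggregation sums counts over the label at the
requested rank, pooling unlabelled taxa into `unclassified`, and conserves
per-sample microbial totals. Alpha diversity is Shannon's H in nats
(ecology convention). Read-level classification itself is out of scope;
the package treats classifier counts as given.

## Cohort statistics

Single features use Welch's unequal-variance t with Satterthwaite degrees
of freedom and two-sided p. Degenerate zero-variance comparisons return
t = 0, p = 1 when means agree (no evidence) and |t| = ∞, p = 0 otherwise.

Multi-feature scans control FDR with the two-stage step-up procedure of
Benjamini, Krieger and Yekutieli at Q = 0.05: stage 1 is a linear (BH)
step-up at q′ = Q/(1+Q); with r₁ rejections, m₀ = m − r₁ estimates the
true nulls and stage 2 reruns the step-up at q′·m/m₀ (zero rejections stop
the procedure; m rejections reject everything). Per-feature q-values are
reported on a scale where q ≤ Q reproduces the stage-2 mask, so
volcano-style outputs (mean difference vs q) can be drawn directly.

AUC is the Mann–Whitney U statistic divided by n₁·n₀ with ties counted
half — invariant under any strictly monotone transform of scores. PCA
integration centres features, scales them to unit variance and decomposes
by full SVD (no log transform: the inputs are already comparable scores);
zero-variance features are dropped with a log entry, components are capped
at min(samples, features), and group separation is tested by Welch t on
PC1 scores. The companion heatmap ordering uses average-linkage
hierarchical clustering on correlation distance and reports the dendrogram
leaf order.

## Synthetic cohorts

The generator plants, on a toy genome (by default two 3-Mb contigs plus a
16,569-bp chrM, GC 0.42, with G4 islands inserted at ~40/Mb), exactly the
signals the analyses target:

* **Lengths** follow a two-component mixture on the 20–400 bp grid: a short
  component N(60, 15) multiplied by the comb term
  max(0, 1 + a·cos(2πL/10)) and renormalised, plus a mononucleosomal
  component N(167, 15) with weight m. The truncated-cosine comb is a
  deliberately simple model of the ~10-bp periodicity — its analytic mass
  is computable, which the tests exploit; it is a caricature of the real
  phenomenon, not a nuclease model.
* **Placement** draws a bin from a telomere-weighted multinomial (terminal
  bins of each contig up-weighted 3×) and a uniform position within it;
  a `mito_fraction` share of fragments lands uniformly on chrM; a
  `motif_bias_strength` share starts at reference positions bearing
  favoured 4-mers (GG-prefixed by default), planting the end-motif signal.
* **Microbial mixtures** are Dirichlet-multinomial over ten oral genera
  (overdispersion 0.02, i.e. Dirichlet precision 50), with an even
  composition for the noncancer-like group and a skewed one for the
  cancer-like group.

The default group templates encode the contrasts the analyses are built to
recover: comb amplitude 0.8 vs 0.1, mononucleosomal weight 0.05 vs 0.30,
mitochondrial fraction 0.02 vs 0.08, motif bias 0.15 vs 0.35, even vs
skewed microbiota; 50,000 fragments per sample. Per-sample parameters are
the templates under multiplicative lognormal jitter (σ = 0.15, clipped to
valid ranges). All outputs are deterministic functions of the seed, to the
byte for file outputs.

**What the generator does not emulate:** GC and mappability bias, copy
number, sequencing error, jagged single-strand overhangs, realistic
chromatin-driven positioning, or any coupling between features beyond the
planted parameters. G-quadruplex prevalence in particular is not an
independent dial — it responds to the planted G-rich end bias — so
simulations certify the G4 scanner's correctness, not any
disease-direction claim. Passing the recovery tests shows the estimators
detect their planted signals at realistic effect sizes and n = 10/group;
it does not validate the biological effect sizes themselves.

## Problem sizes and numerical conventions

Recovery checks run 20 independent cohorts of 10 vs 10 samples at 50,000
fragments each; null FDR control uses 200 cohorts of 1,000 features;
oracle equivalence checks use 1,000 random instances each. Histogram and
coverage normalisations are exact to 1e-9 relative tolerance. Ratios with
empty denominators (fragment score with no long fragments, O/E for a
zero-share category) are NaN and masked, never 0. Ties in AUC are handled
by average ranks; equal-valued histogram plateaus yield the first position
of the plateau as the extremum (stable left-to-right scan).

## Known limitations

* End motifs require a reference; read-sequence-derived motifs are not
  implemented (fragment TSVs carrying a `sequence` column are used only by
  the G4 scanner when no reference is given).
* Per-bin coverage uses read counts, not base coverage.
* The annotation module approximates HOMER-style assignment with a
  user-supplied BED and a fixed precedence; it does not reproduce HOMER's
  own element definitions.
* The pipeline assumes two groups; multi-group designs are out of scope.
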