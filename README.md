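# salifrag

Fragmentomic analysis of salivary cell-free DNA (cfDNA) for two-group
biomarker studies, with a synthetic-cohort generator so the whole stack is
testable without sequencing data.

Saliva carries a cfDNA population unlike plasma: a dominant sub-100-bp
component whose size histogram shows a rugged comb of peaks at ~10-bp
spacing, an optional mononucleosomal (~167 bp) shoulder, a measurable
mitochondrial load, and a large microbial read fraction. `salifrag`
consumes aligned, deduplicated fragments (coordinate-sorted BAM/SAM or a
plain fragment TSV) and computes, per sample and per cohort, the features
that discriminate such profiles.

## What it computes

* **Jagged peak-valley index.** Peaks and valleys of the % reads size
  histogram are located with a delta-gated alternating extremum search
  (lookahead = 1, delta = 10⁻⁴ by default); the index is the mean drop from
  each peak to the first valley to its right:

  *J* = (1/*n*) Σᵢ (*P*ᵢ − *V*ᵢ)

  where *P*ᵢ, *V*ᵢ are % reads at peak *i* and at the matched valley.
* **Binned fragmentomics.** Contiguous 1-Mb tiling of chr1–22 (2887 bins on
  GRCh38), per-bin coverage % and the fragmentomic score
  *S* = #(length < 100 bp) / #(length ≥ 100 bp), globally and per bin, plus
  the mitochondrial percentage of human-mapped fragments.
* **End motifs.** The 4 reference bases at each fragment 5′ end (both ends,
  256-word vocabulary), profile frequencies and Shannon entropy
  *H* = −Σ *f*ₘ log₂ *f*ₘ (bits), and G-quadruplex prevalence
  (G₃₊N₁₋₇ × 4, both strands).
* **Element profiles.** Peaks-per-read from narrowPeak calls,
  observed/expected peak enrichment over a category-labelled annotation BED
  (summit-based, promoter > 5utr > exon > intron > intergenic precedence),
  and mean-1-normalised fragment coverage around element centres.
* **Microbiome.** Taxa-table rank aggregation, relative abundances,
  human/microbial/unmapped read partition, Shannon alpha diversity (nats).
* **Cohort statistics.** Welch t tests, multi-feature scans with the
  two-stage Benjamini–Krieger–Yekutieli FDR step-up at Q = 0.05, ROC/AUC via
  the Mann–Whitney identity, and PCA integration (unit-variance scaling +
  SVD) with a PC1 group-separation test.
* **Synthetic cohorts.** A generator that plants all of the above —
  comb amplitude, mononucleosomal weight, mitochondrial fraction, telomeric
  placement bias, G-rich end-motif bias, Dirichlet-multinomial microbial
  mixtures — with per-sample lognormal jitter and a recorded truth file.

## Worked example

```python
import salifrag as sf

cohort = sf.simulate_cohort(n_per_group=10, seed=1)   # 10 vs 10 samples
fm = cohort.feature_matrix

scan = sf.feature_scan(fm, q=0.05)
pca = sf.pca_integrate(fm, n_components=20)
pc1 = pca.scores["PC1"]
t, df, p = sf.welch_t(pc1[fm.groups == "noncancer"], pc1[fm.groups == "cancer"])
print(scan.n_significant, len(scan.table))
print(round(pca.variance_explained[0], 1), f"{p:.2e}")
```

prints

```
25 25
80.3 1.62e-16
```

— all 25 extracted features (jaggedness, fragment scores, per-bin coverage,
end-motif entropy, G-quad prevalence, mitochondrial %, microbial features)
separate the two planted groups after two-stage FDR, and PC1, carrying
80.3% of the scaled variance, splits the groups at Welch p ≈ 10⁻¹⁶. The
scripts in `examples/` walk through each capability the same way; a thin
CLI (`salifrag histogram|jaggedness|fragscore|bins|endmotif|gquad|mito|
peaks|microbiome|scan|integrate|simulate|run`) wraps the library for shell
use, including a YAML-configured end-to-end pipeline (`salifrag run`).

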