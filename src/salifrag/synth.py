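"""Synthetic two-group salivary cfDNA cohorts with known planted structure.

The generator emulates the statistical signatures the analysis stack is
built to detect, on a toy reference genome, so every stage can be exercised
and validated without sequencing data:

* a sub-100-bp fragment population (normal around ~60 bp) carrying a 10-bp
  periodic comb, modelled as a truncated cosine modulation of the short
  length distribution — ``(1 + a·cos(2π·L/10))`` clipped at zero and
  renormalised, with comb amplitude ``a`` the planted jaggedness dial;
* an optional mononucleosomal component (normal around 167 bp) whose weight
  moves the short/long fragment score;
* per-bin placement bias (terminal bins of each contig up-weighted, mimicking
  telomeric enrichment) on 1-Mb bins of the toy genome;
* a mitochondrial fragment fraction placed on a toy chrM contig;
* biased 4-mer end composition, planted by starting a configurable share of
  fragments at reference positions bearing favoured 4-mers;
* group-structured microbial mixtures drawn Dirichlet-multinomially.

Group templates default to a "noncancer-like" profile (strong comb, little
mononucleosomal DNA, low mitochondrial load, even microbiota) versus a
"cancer-like" profile (weak comb, pronounced ~167 bp component, higher
mitochondrial load, skewed microbiota), the direction of every contrast the
analyses are designed to pick up. Per-sample biological variability is
introduced by multiplicative lognormal jitter of the planted parameters.
All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import GenomeBins, make_bins
from .endmotif import DictReference, motif_vocabulary
from .features import extract_sample_features
from .fragments import FragmentSet
from .microbiome import TaxaTable
from .stats import FeatureMatrix

LENGTH_GRID = np.arange(20, 401)

#: favoured left-end 4-mers for the planted end-motif bias (G-run starts,
#: echoing the guanine-dominated ends of salivary cfDNA)
G_RICH_MOTIFS = tuple(m for m in motif_vocabulary(4) if m.startswith("GG"))


@dataclass
class SampleParams:
    """Planted per-sample generative parameters."""

    n_fragments: int = 50_000
    short_mode: float = 60.0      # centre of the sub-100-bp component (bp)
    short_sd: float = 15.0        # its spread (bp)
    mono_weight: float = 0.05     # proportion of the ~167 bp component
    mono_sd: float = 15.0
    comb_amplitude: float = 0.8   # a in (1 + a·cos(2πL/10)), clipped at 0
    mito_fraction: float = 0.02   # proportion of fragments on chrM
    telomere_bias: float = 3.0    # weight multiplier for terminal bins
    motif_bias_strength: float = 0.15   # share of fragments started at favoured 4-mers
    favored_motifs: tuple[str, ...] = G_RICH_MOTIFS
    taxa_composition: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        for name in ("mono_weight", "mito_fraction", "motif_bias_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.comb_amplitude <= 1.0:
            raise ValueError("comb_amplitude must lie in [0, 1]")
        if self.taxa_composition is not None:
            total = sum(self.taxa_composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("taxa_composition must sum to 1")


def length_pmf(params: SampleParams, grid: np.ndarray = LENGTH_GRID) -> np.ndarray:
    """Analytic fragment-length distribution on the integer grid.

    Mixture of the comb-modulated short component and the mononucleosomal
    component, truncated to the grid and renormalised. Exposed so tests can
    compare empirical mass against the exact mixture.
    """
    short = sps.norm.pdf(grid, params.short_mode, params.short_sd)
    comb = np.clip(1.0 + params.comb_amplitude * np.cos(2 * np.pi * grid / 10.0), 0.0, None)
    short = short * comb
    short /= short.sum()
    mono = sps.norm.pdf(grid, 167.0, params.mono_sd)
    mono /= mono.sum()
    return (1.0 - params.mono_weight) * short + params.mono_weight * mono


# -- toy reference -----------------------------------------------------------

_G4_ISLAND = "GGGATGGGTAGGGTTGGG"


def make_toy_reference(seed: int = 0, n_contigs: int = 2,
                       contig_len: int = 3_000_000, gc: float = 0.42,
                       g4_per_mb: int = 40, mito_len: int = 16_569) -> DictReference:
    """Random toy genome: ``n_contigs`` autosome-like contigs plus a chrM.

    G-quadruplex islands are planted at random positions (``g4_per_mb`` per
    megabase) so G4 scanning has genuine targets.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs: dict[str, str] = {}
    specs = [(f"chr{i + 1}", contig_len) for i in range(n_contigs)] + [("chrM", mito_len)]
    island = np.frombuffer(_G4_ISLAND.encode(), dtype=np.uint8)
    for name, length in specs:
        arr = rng.choice(bases, size=length, p=p)
        if name != "chrM":
            n_islands = int(g4_per_mb * length / 1e6)
            pos = rng.integers(0, length - len(island), size=n_islands)
            for s in pos:
                arr[s:s + len(island)] = island
        contigs[name] = arr.tobytes().decode("ascii")
    return DictReference(contigs)


def _favored_positions(reference: DictReference, motifs: tuple[str, ...],
                       margin: int = 450) -> dict[str, np.ndarray]:
    """Per-contig start positions whose forward 4-mer is a favoured motif."""
    from .endmotif import _ENCODE

    motif_set = set(motifs)
    k = len(next(iter(motif_set)))
    out: dict[str, np.ndarray] = {}
    for chrom, seq in reference.contigs.items():
        if chrom == "chrM":
            continue
        codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        idx = np.zeros(len(seq) - k + 1, dtype=np.int64)
        bad = np.zeros(len(seq) - k + 1, dtype=bool)
        for i in range(k):
            b = codes[i: len(seq) - k + 1 + i]
            bad |= b == 255
            idx = idx * 4 + np.where(b == 255, 0, b)
        vocab = motif_vocabulary(k)
        wanted = np.zeros(4 ** k, dtype=bool)
        for m in motif_set:
            wanted[vocab.index(m)] = True
        hits = np.flatnonzero(wanted[idx] & ~bad)
        out[chrom] = hits[hits < len(seq) - margin]
    return out


def simulate_fragments(params: SampleParams, reference: DictReference,
                       bins: GenomeBins | None = None,
                       sample_id: str = "sample",
                       _favored: dict[str, np.ndarray] | None = None) -> FragmentSet:
    """Draw one sample's fragments from the planted generative model.

    Lengths come from :func:`length_pmf`; placement mixes the telomere-
    weighted bin multinomial, the favoured-motif start positions, and the
    chrM compartment. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sizes = {c: len(s) for c, s in reference.contigs.items()}
    auto_sizes = {c: n for c, n in sizes.items() if c != "chrM"}
    if bins is None:
        bins = make_bins(auto_sizes, bin_size=1_000_000, chroms=list(auto_sizes))

    n = params.n_fragments
    lengths = rng.choice(LENGTH_GRID, size=n, p=length_pmf(params))

    # compartment assignment: chrM vs nuclear, then motif-biased vs bin-placed
    on_mito = rng.random(n) < params.mito_fraction
    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)

    idx_m = np.flatnonzero(on_mito)
    if idx_m.size:
        mito_len = sizes.get("chrM")
        if mito_len is None:
            raise ValueError("reference has no chrM contig but mito_fraction > 0")
        chroms[idx_m] = "chrM"
        span = np.maximum(mito_len - lengths[idx_m], 1)
        starts[idx_m] = (rng.random(idx_m.size) * span).astype(np.int64)

    idx_n = np.flatnonzero(~on_mito)
    if idx_n.size:
        favored = _favored if _favored is not None else (
            _favored_positions(reference, params.favored_motifs)
            if params.motif_bias_strength > 0 else {})
        biased = rng.random(idx_n.size) < params.motif_bias_strength
        pool_chroms = [c for c in favored if favored[c].size]
        if not pool_chroms:
            biased[:] = False
        ib = idx_n[biased]
        if ib.size:
            pool_sizes = np.array([favored[c].size for c in pool_chroms], dtype=float)
            pick = rng.choice(len(pool_chroms), size=ib.size, p=pool_sizes / pool_sizes.sum())
            for ci, chrom in enumerate(pool_chroms):
                sel = ib[pick == ci]
                chroms[sel] = chrom
                starts[sel] = rng.choice(favored[chrom], size=sel.size)
        iu = idx_n[~biased]
        if iu.size:
            bdf = bins.df
            weights = np.ones(len(bdf))
            for _, g in bdf.groupby("chrom", sort=False):
                weights[g.index[0]] = params.telomere_bias
                weights[g.index[-1]] = params.telomere_bias
            weights *= (bdf["end"] - bdf["start"]).to_numpy()
            weights /= weights.sum()
            chosen = rng.choice(len(bdf), size=iu.size, p=weights)
            bstart = bdf["start"].to_numpy()[chosen]
            bend = bdf["end"].to_numpy()[chosen]
            chroms[iu] = bdf["chrom"].to_numpy()[chosen]
            pos = bstart + (rng.random(iu.size) * (bend - bstart)).astype(np.int64)
            limit = np.array([sizes[c] for c in chroms[iu]])
            starts[iu] = np.minimum(pos, limit - lengths[iu])

    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return FragmentSet.from_arrays(chrom=chroms, start=starts, end=starts + lengths,
                                   strand=strand, mapq=np.full(n, 60),
                                   sample_id=sample_id)


# -- microbiome --------------------------------------------------------------

ORAL_TAXA: dict[str, str] = {
    "Streptococcus": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus",
    "Granulicatella": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Carnobacteriaceae;g__Granulicatella",
    "Gemella": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__Gemellaceae;g__Gemella",
    "Veillonella": "k__Bacteria;p__Firmicutes;c__Negativicutes;o__Veillonellales;f__Veillonellaceae;g__Veillonella",
    "Haemophilus": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;f__Pasteurellaceae;g__Haemophilus",
    "Neisseria": "k__Bacteria;p__Proteobacteria;c__Betaproteobacteria;o__Neisseriales;f__Neisseriaceae;g__Neisseria",
    "Prevotella": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella",
    "Porphyromonas": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Porphyromonadaceae;g__Porphyromonas",
    "Fusobacterium": "k__Bacteria;p__Fusobacteria;c__Fusobacteriia;o__Fusobacteriales;f__Fusobacteriaceae;g__Fusobacterium",
    "Rothia": "k__Bacteria;p__Actinobacteria;c__Actinomycetia;o__Micrococcales;f__Micrococcaceae;g__Rothia",
}

#: even, diverse oral community (noncancer-like)
NONCANCER_TAXA = {"Streptococcus": 0.20, "Granulicatella": 0.05, "Gemella": 0.05,
                  "Veillonella": 0.12, "Haemophilus": 0.12, "Neisseria": 0.12,
                  "Prevotella": 0.12, "Porphyromonas": 0.07, "Fusobacterium": 0.07,
                  "Rothia": 0.08}
#: skewed community with depressed diversity (cancer-like)
CANCER_TAXA = {"Streptococcus": 0.50, "Granulicatella": 0.02, "Gemella": 0.02,
               "Veillonella": 0.06, "Haemophilus": 0.04, "Neisseria": 0.04,
               "Prevotella": 0.20, "Porphyromonas": 0.04, "Fusobacterium": 0.06,
               "Rothia": 0.02}


def simulate_taxa(n_samples: int, composition: dict[str, float],
                  depth: int = 100_000, overdispersion: float = 0.02,
                  seed: int = 0, sample_ids: list[str] | None = None,
                  lineages: dict[str, str] | None = None) -> TaxaTable:
    """Dirichlet-multinomial taxa counts for ``n_samples`` samples.

    ``overdispersion`` is the Dirichlet scale 1/alpha0 relative to the
    composition: 0 degenerates to a plain multinomial, larger values add
    between-sample compositional noise.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    lineages = lineages or ORAL_TAXA
    taxa = list(composition)
    probs = np.array([composition[t] for t in taxa], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(seed)
    ids = sample_ids or [f"s{i + 1}" for i in range(n_samples)]
    data = {}
    for sid in ids:
        p = rng.dirichlet(probs / overdispersion) if overdispersion > 0 else probs
        data[sid] = rng.multinomial(depth, p)
    df = pd.DataFrame({"taxon_id": taxa,
                       "lineage": [lineages.get(t, f"g__{t}") for t in taxa],
                       "rank": "species",
                       **{sid: data[sid] for sid in ids}})
    return TaxaTable(df)


# -- cohorts -----------------------------------------------------------------

NONCANCER_TEMPLATE = SampleParams(comb_amplitude=0.8, mono_weight=0.05,
                                  mito_fraction=0.02, motif_bias_strength=0.15,
                                  taxa_composition=NONCANCER_TAXA)
CANCER_TEMPLATE = SampleParams(comb_amplitude=0.1, mono_weight=0.30,
                               mito_fraction=0.08, motif_bias_strength=0.35,
                               taxa_composition=CANCER_TAXA)


@dataclass
class CohortResult:
    """A simulated cohort with its planted truth and extracted features."""

    feature_matrix: FeatureMatrix
    truth: dict
    reference: DictReference
    bins: GenomeBins
    taxa: TaxaTable | None = None
    fragment_files: dict[str, Path] = field(default_factory=dict)


def _jitter(rng: np.random.Generator, value: float, sigma: float,
            lo: float = 0.0, hi: float = 1.0) -> float:
    return float(np.clip(value * rng.lognormal(0.0, sigma), lo, hi))


def simulate_cohort(n_per_group: int = 10,
                    group_params: tuple[SampleParams, SampleParams] | None = None,
                    seed: int = 0, jitter_sigma: float = 0.15,
                    out_dir: str | Path | None = None,
                    with_taxa: bool = True, taxa_depth: int = 100_000,
                    reference: DictReference | None = None) -> CohortResult:
    """Simulate a two-group cohort and run the full feature extraction.

    Per-sample parameters are the group templates under multiplicative
    lognormal jitter (sigma ``jitter_sigma``, clipped to valid ranges). The
    planted truth is recorded for every sample. With ``out_dir``, fragment
    TSVs, the toy reference FASTA, chrom.sizes, the taxa table, the feature
    matrix and the truth JSON are written; outputs are byte-identical for
    identical seeds.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    g1, g2 = group_params or (NONCANCER_TEMPLATE, CANCER_TEMPLATE)
    g1.validate(), g2.validate()
    master = np.random.default_rng(seed)
    reference = reference or make_toy_reference(seed=int(master.integers(2 ** 31)))
    auto_sizes = {c: len(s) for c, s in reference.contigs.items() if c != "chrM"}
    bins = make_bins(auto_sizes, bin_size=1_000_000, chroms=list(auto_sizes))
    favored = _favored_positions(reference, g1.favored_motifs)

    rows: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    truth: dict = {"seed": seed, "jitter_sigma": jitter_sigma,
                   "templates": {"noncancer": dataclasses.asdict(g1) | {"favored_motifs": list(g1.favored_motifs)},
                                 "cancer": dataclasses.asdict(g2) | {"favored_motifs": list(g2.favored_motifs)}},
                   "samples": {}}
    fragment_files: dict[str, Path] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "fragments").mkdir(parents=True, exist_ok=True)

    sample_specs = [("noncancer", g1, f"nc{i + 1}") for i in range(n_per_group)] + \
                   [("cancer", g2, f"gc{i + 1}") for i in range(n_per_group)]
    for group, template, sid in sample_specs:
        srng = np.random.default_rng(int(master.integers(2 ** 31)))
        params = dataclasses.replace(
            template,
            comb_amplitude=_jitter(srng, template.comb_amplitude, jitter_sigma),
            mono_weight=_jitter(srng, template.mono_weight, jitter_sigma),
            mito_fraction=_jitter(srng, template.mito_fraction, jitter_sigma),
            seed=int(srng.integers(2 ** 31)),
        )
        fragset = simulate_fragments(params, reference, bins=bins, sample_id=sid,
                                     _favored=favored)
        rows[sid] = extract_sample_features(fragset, bins=bins, reference=reference)
        groups[sid] = group
        truth["samples"][sid] = {"group": group,
                                 "comb_amplitude": params.comb_amplitude,
                                 "mono_weight": params.mono_weight,
                                 "mito_fraction": params.mito_fraction,
                                 "seed": params.seed}
        if out_path is not None:
            f = out_path / "fragments" / f"{sid}.tsv"
            fragset.to_tsv(f)
            fragment_files[sid] = f

    taxa = None
    if with_taxa:
        taxa_seed = int(master.integers(2 ** 31))
        ids = list(rows)
        nc_ids = [s for s in ids if groups[s] == "noncancer"]
        gc_ids = [s for s in ids if groups[s] == "cancer"]
        t1 = simulate_taxa(len(nc_ids), g1.taxa_composition or NONCANCER_TAXA,
                           depth=taxa_depth, seed=taxa_seed, sample_ids=nc_ids)
        t2 = simulate_taxa(len(gc_ids), g2.taxa_composition or CANCER_TAXA,
                           depth=taxa_depth, seed=taxa_seed + 1, sample_ids=gc_ids)
        merged = t1.df.merge(t2.df[["taxon_id", *gc_ids]], on="taxon_id", how="outer")
        merged[[*nc_ids, *gc_ids]] = merged[[*nc_ids, *gc_ids]].fillna(0).astype(int)
        taxa = TaxaTable(merged)
        from .microbiome import aggregate_rank, alpha_diversity, relative_abundance

        for sid in ids:
            rows[sid]["alpha_diversity"] = alpha_diversity(taxa.counts(sid))
        cls_tab = aggregate_rank(taxa, "class")
        rel = relative_abundance(cls_tab)
        for row in rel.itertuples(index=False):
            for sid in ids:
                rows[sid][f"class_{row.taxon_id}"] = getattr(row, sid)

    values = pd.DataFrame.from_dict(rows, orient="index")
    fm = FeatureMatrix(values=values, groups=pd.Series(groups))
    if out_path is not None:
        reference.to_fasta(out_path / "reference.fa")
        with open(out_path / "toy.chrom.sizes", "w") as fh:
            for c, s in reference.contigs.items():
                fh.write(f"{c}\t{len(s)}\n")
        if taxa is not None:
            taxa.to_tsv(out_path / "taxa.tsv")
        fm.to_tsv(out_path / "features.tsv")
        with open(out_path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return CohortResult(feature_matrix=fm, truth=truth, reference=reference,
                        bins=bins, taxa=taxa, fragment_files=fragment_files)
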