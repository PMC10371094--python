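"""End-to-end cohort pipeline: fragments in, feature matrix / scan / PCA out.

The pipeline runs, per sample: fragment loading -> size histogram and
jaggedness -> 1-Mb binning with coverage and fragment scores -> end motifs
and G-quadruplex (when a reference is configured) -> microbiome features
(when a taxa table is configured); then cohort-level: the per-feature Welch
t + BKY FDR scan and PCA integration. Optional stages whose inputs are
absent are skipped with a warning rather than aborting. All stage outputs
are pure functions of (inputs, parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binning import make_bins
from .endmotif import GQuadParams
from .features import extract_sample_features
from .fragments import FilterConfig, load_fragments
from .genome import read_chrom_sizes
from .jaggedness import PeakDetectParams
from .microbiome import TaxaTable, aggregate_rank, alpha_diversity, relative_abundance
from .stats import FeatureMatrix, feature_scan, pca_integrate, welch_t

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (loadable from YAML)."""

    samples: list[dict]                 # [{id, fragments, group}, ...]
    chrom_sizes: str
    out_dir: str
    reference: str | None = None
    taxa: str | None = None
    bin_size: int = 1_000_000
    threshold: int = 100
    min_len: int = 20
    max_len: int = 400
    min_mapq: int = 20
    k: int = 4
    lookahead: int = 1
    delta: float = 1e-4
    q: float = 0.05
    n_components: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        for s in self.samples:
            missing = {"id", "fragments", "group"} - set(s)
            if missing:
                raise ValueError(f"sample entry missing {sorted(missing)}: {s}")
            if not Path(s["fragments"]).exists():
                raise FileNotFoundError(s["fragments"])
        for attr in ("chrom_sizes", "reference", "taxa"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of written outputs.

    On stage failure the run aborts with the stage name and cause; outputs
    written so far are retained next to a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "outputs": {},
                      "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                                     if k != "samples"}}
    stage = "setup"
    try:
        sizes = read_chrom_sizes(config.chrom_sizes)
        bins = make_bins(sizes, bin_size=config.bin_size)
        filters = FilterConfig(min_mapq=config.min_mapq, min_len=config.min_len,
                               max_len=config.max_len)
        detect = PeakDetectParams(lookahead=config.lookahead, delta=config.delta)

        reference = config.reference
        if reference is None:
            logger.warning("no reference configured; skipping end-motif and G-quad stages")

        stage = "per-sample features"
        rows: dict[str, dict] = {}
        groups: dict[str, str] = {}
        for s in config.samples:
            fragset = load_fragments(s["fragments"], filters=filters,
                                     chrom_sizes=sizes, sample_id=s["id"])
            rows[s["id"]] = extract_sample_features(
                fragset, bins=bins, reference=reference, min_len=config.min_len,
                max_len=config.max_len, threshold=config.threshold, detect=detect,
                gquad=GQuadParams(), k=config.k)
            groups[s["id"]] = s["group"]

        stage = "microbiome"
        if config.taxa is not None:
            taxa = TaxaTable.from_tsv(config.taxa)
            cls_tab = aggregate_rank(taxa, "class")
            rel = relative_abundance(cls_tab)
            for sid in rows:
                if sid in taxa.sample_ids:
                    rows[sid]["alpha_diversity"] = alpha_diversity(taxa.counts(sid))
                    for row in rel.itertuples(index=False):
                        rows[sid][f"class_{row.taxon_id}"] = getattr(row, sid)
        else:
            logger.warning("no taxa table configured; skipping microbiome stage")

        stage = "feature matrix"
        fm = FeatureMatrix(values=pd.DataFrame.from_dict(rows, orient="index"),
                           groups=pd.Series(groups))
        fm.to_tsv(out / "features.tsv")
        manifest["outputs"]["features"] = "features.tsv"

        stage = "scan"
        scan = feature_scan(fm, q=config.q)
        scan.to_tsv(out / "scan.tsv")
        manifest["outputs"]["scan"] = "scan.tsv"
        manifest["n_significant_features"] = scan.n_significant

        stage = "pca"
        pca = pca_integrate(fm, n_components=config.n_components)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index_label="feature")
        pd.DataFrame({"component": pca.scores.columns,
                      "variance_explained_pct": pca.variance_explained}) \
            .to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        manifest["outputs"]["pca"] = ["pca_scores.tsv", "pca_loadings.tsv",
                                      "pca_variance.tsv"]
        g1, g2 = fm.split("jagged_index")  # groups, reused for PC1
        pc1 = pca.scores["PC1"]
        t, df, p = welch_t(pc1.loc[g1.index], pc1.loc[g2.index])
        manifest["pc1_welch"] = {"t": t, "df": df, "p": p}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
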