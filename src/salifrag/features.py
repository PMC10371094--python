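"""Per-sample feature extraction: one row of the cohort feature matrix.

Collects the scalar fragmentomic features (jaggedness index, global
fragment score, mitochondrial %, end-motif entropy, G-quadruplex
prevalence) and the per-bin features (coverage % and binned fragment
score) for a single sample.
"""

from __future__ import annotations

import numpy as np

from .binning import GenomeBins, assign_to_bins, fragment_score, mitochondrial_fraction
from .endmotif import GQuadParams, extract_end_motifs, gquad_prevalence, shannon_entropy
from .fragments import FragmentSet, build_size_histogram
from .jaggedness import PeakDetectParams, jagged_index_from_histogram


def extract_sample_features(fragset: FragmentSet, bins: GenomeBins | None = None,
                            reference=None, *, min_len: int = 20, max_len: int = 400,
                            threshold: int = 100,
                            detect: PeakDetectParams | None = None,
                            gquad: GQuadParams | None = None,
                            k: int = 4) -> dict[str, float]:
    """Compute the per-sample feature vector as a flat name -> value dict.

    Per-bin features are named ``cov_<chrom>_<start>`` and
    ``fs_<chrom>_<start>``; bins with an undefined fragment score carry NaN
    and are masked downstream.
    """
    feats: dict[str, float] = {}
    hist = build_size_histogram(fragset, min_len=min_len, max_len=max_len)
    feats["jagged_index"] = jagged_index_from_histogram(hist, detect or PeakDetectParams())
    feats["fragment_score"] = fragment_score(fragset, threshold=threshold)
    try:
        feats["mito_pct"] = mitochondrial_fraction(fragset)
    except ValueError:
        feats["mito_pct"] = np.nan

    if bins is not None:
        bt = assign_to_bins(fragset, bins, threshold=threshold)
        for row in bt.df.itertuples(index=False):
            key = f"{row.chrom}_{row.start}"
            feats[f"cov_{key}"] = row.coverage_pct
            feats[f"fs_{key}"] = row.frag_score

    if reference is not None:
        profile = extract_end_motifs(fragset, reference, k=k)
        feats["motif_entropy_bits"] = (shannon_entropy(profile)
                                       if profile.counts.sum() > 0 else np.nan)
        feats["gquad_pct"] = gquad_prevalence(fragset, reference, gquad or GQuadParams())
    return feats
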