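"""Genome binning and binned fragmentomics.

Chromosomes are tiled with contiguous fixed-size bins (1 Mb by default,
the final bin per chromosome truncated at the chromosome end). Each
autosomal fragment is assigned to exactly one bin by its midpoint, and per
bin we track short/long fragment counts (length < threshold vs >=
threshold, threshold 100 bp by default), the bin's share of all counted
fragments (coverage %), and the short/long ratio (the binned fragmentomic
score). A fragment of exactly the threshold length counts as long, so the
two classes partition all fragments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import AUTOSOMES, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass
class GenomeBins:
    """Contiguous fixed-size tiling of a chromosome set."""

    df: pd.DataFrame  # columns: chrom, start, end, bin_id
    bin_size: int

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass
class BinTable:
    """Per-bin fragment counts and scores.

    ``frag_score`` is NaN for bins with no long fragments (undefined ratio);
    such bins are excluded from downstream per-bin tests.
    """

    df: pd.DataFrame  # chrom, start, end, bin_id, n_short, n_long, n_total,
    #                   coverage_pct, frag_score
    threshold: int
    n_skipped: int = 0  # fragments outside the binned chromosome set

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def make_bins(chrom_sizes: dict[str, int], bin_size: int = 1_000_000,
              chroms: list[str] | None = None) -> GenomeBins:
    """Tile chromosomes into fixed-size bins (default: the 22 autosomes at 1 Mb).

    Bins are 0-based half-open and contiguous from 0; the final bin per
    chromosome may be shorter than ``bin_size``. Requesting a chromosome
    absent from ``chrom_sizes`` raises ``KeyError``.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sizes = {normalize_chrom(c): n for c, n in chrom_sizes.items()}
    if chroms is None:
        selected = [c for c in sizes if c in AUTOSOMES]
    else:
        selected = [normalize_chrom(c) for c in chroms]
        missing = [c for c in selected if c not in sizes]
        if missing:
            raise KeyError(f"chromosomes not in chrom.sizes: {missing}")
    rows = []
    bin_id = 0
    for chrom in selected:
        length = sizes[chrom]
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length), bin_id))
            bin_id += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])
    return GenomeBins(df=df, bin_size=bin_size)


def assign_to_bins(fragset: FragmentSet, bins: GenomeBins,
                   threshold: int = 100) -> BinTable:
    """Count fragments per bin by midpoint and classify short vs long.

    The midpoint is ``floor((start + end) / 2)``. Fragments on chromosomes
    outside the bin set are skipped and tallied in ``n_skipped``.
    """
    out = bins.df.copy()
    nbins = len(out)
    n_short = np.zeros(nbins, dtype=np.int64)
    n_long = np.zeros(nbins, dtype=np.int64)
    n_skipped = 0

    frag = fragset.df
    starts_by_chrom = {c: g for c, g in out.groupby("chrom", sort=False)}
    for chrom, g in frag.groupby("chrom", sort=False, observed=True):
        if chrom not in starts_by_chrom:
            n_skipped += len(g)
            continue
        cbins = starts_by_chrom[chrom]
        mid = ((g["start"].to_numpy() + g["end"].to_numpy()) // 2)
        idx = np.searchsorted(cbins["start"].to_numpy(), mid, side="right") - 1
        chrom_end = cbins["end"].to_numpy()[-1]
        ok = (idx >= 0) & (mid < chrom_end)
        n_skipped += int((~ok).sum())
        idx = idx[ok]
        short = (g["end"].to_numpy() - g["start"].to_numpy())[ok] < threshold
        gids = cbins["bin_id"].to_numpy()[idx]
        n_short += np.bincount(gids[short], minlength=nbins)
        n_long += np.bincount(gids[~short], minlength=nbins)

    n_total = n_short + n_long
    total = n_total.sum()
    out["n_short"] = n_short
    out["n_long"] = n_long
    out["n_total"] = n_total
    if total == 0:
        logger.warning("no fragments fell inside the bin set; coverage undefined")
        out["coverage_pct"] = np.nan
    else:
        out["coverage_pct"] = 100.0 * n_total / total
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["frag_score"] = np.where(n_long > 0, n_short / np.maximum(n_long, 1), np.nan)
    return BinTable(df=out, threshold=threshold, n_skipped=n_skipped)


def fragment_score(data: FragmentSet | np.ndarray, threshold: int = 100) -> float:
    """Global fragmentomic score: count(length < threshold) / count(length >= threshold).

    Accepts a :class:`FragmentSet` or a raw length array. Returns NaN when no
    long fragments exist (undefined ratio).
    """
    lengths = data.lengths if isinstance(data, FragmentSet) else np.asarray(data)
    n_short = int((lengths < threshold).sum())
    n_long = int((lengths >= threshold).sum())
    if n_long == 0:
        return float("nan")
    return n_short / n_long


def mitochondrial_fraction(fragset: FragmentSet) -> float:
    """Percent of human-mapped fragments on the mitochondrial genome.

    Denominator is all human-mapped fragments (autosomes + sex chromosomes +
    chrM); raises when the sample has no human-mapped fragments.
    """
    c = fragset.counts_by_compartment
    n_mito = c.get("mitochondrial", 0)
    n_human = n_mito + c.get("autosomal", 0) + c.get("sexchrom", 0)
    if n_human == 0:
        raise ValueError("no human-mapped fragments; mitochondrial fraction undefined")
    return 100.0 * n_mito / n_human
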