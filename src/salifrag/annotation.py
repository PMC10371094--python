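"""Genomic-element annotation of peak calls and coverage profiles.

Consumes externally called peaks (ENCODE narrowPeak) and a category-labelled
element BED (promoter / 5utr / exon / intron / ...). Peaks are assigned one
category at their summit using a precedence order (promoter > 5utr > exon >
intron > intergenic); bases covered by no element count as intergenic.
Observed/expected enrichment compares each category's share of peaks with
its share of the genome. Relative coverage profiles average per-base
fragment coverage in windows centred on element midpoints and normalise by
the window-wide mean, so a flat profile equals 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .fragments import FragmentSet
from .genome import normalize_chrom

DEFAULT_PRECEDENCE = ("promoter", "5utr", "exon", "intron", "intergenic")

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signal", "pvalue", "qvalue", "summit_offset"]


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 is the summit offset from ``start``; -1 means undefined, in
    which case the peak midpoint is used as the summit. A ``summit`` column
    with the absolute summit coordinate is added.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     dtype={"chrom": str}, comment="#")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    bad = (df["summit_offset"] >= 0) & (df["summit_offset"] >= df["end"] - df["start"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} peaks have summit offsets outside the peak")
    df["summit"] = np.where(df["summit_offset"] >= 0,
                            df["start"] + df["summit_offset"],
                            (df["start"] + df["end"]) // 2)
    return df


class ElementAnnotation:
    """Category-labelled genomic intervals with a precedence order.

    Built from a BED whose 4th column is the category label (optionally
    followed by name and strand columns). Overlaps are resolved by
    precedence, both for point queries and for genome-fraction computation.
    """

    def __init__(self, df: pd.DataFrame,
                 precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> None:
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if "strand" not in df.columns:
            df["strand"] = "."
        extra = [c for c in pd.unique(df["category"]) if c not in precedence]
        self.precedence = tuple(precedence) + tuple(extra)
        self._rank = {c: i for i, c in enumerate(self.precedence)}
        self.df = df
        self._trees: dict[str, IntervalTree] = {}
        for chrom, g in df.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), c) for s, e, c in zip(g["start"], g["end"], g["category"]))

    @classmethod
    def from_bed(cls, path: str | Path,
                 precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> "ElementAnnotation":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          dtype={0: str}, na_filter=False)
        if raw.shape[1] < 4:
            raise ValueError("annotation BED needs chrom, start, end, category columns")
        names = ["chrom", "start", "end", "category", "name", "strand"]
        df = raw.iloc[:, : min(6, raw.shape[1])]
        df.columns = names[: df.shape[1]]
        return cls(df, precedence=precedence)

    def category_at(self, chrom: str, pos: int) -> str:
        """Highest-precedence category covering ``pos``; intergenic if none."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return "intergenic"
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return "intergenic"
        return min(hits, key=lambda c: self._rank.get(c, len(self._rank)))

    def elements(self, category: str) -> pd.DataFrame:
        return self.df[self.df["category"] == category]

    def genome_fractions(self, chrom_sizes: dict[str, int]) -> pd.Series:
        """Per-category fraction of the genome, overlap-resolved by precedence.

        Bases covered by no element are assigned to ``intergenic``; fractions
        sum to 1 over the supplied chromosome set.
        """
        sizes = {normalize_chrom(c): n for c, n in chrom_sizes.items()}
        total = sum(sizes.values())
        covered: dict[str, int] = {c: 0 for c in self.precedence}
        covered.setdefault("intergenic", 0)
        for chrom, length in sizes.items():
            g = self.df[(self.df["chrom"] == chrom) & (self.df["start"] < length)]
            events = sorted(set([0, length])
                            | set(np.minimum(g["start"], length))
                            | set(np.minimum(g["end"], length)))
            starts = g["start"].to_numpy()
            ends = np.minimum(g["end"].to_numpy(), length)
            cats = g["category"].to_numpy()
            for lo, hi in zip(events[:-1], events[1:]):
                active = cats[(starts <= lo) & (ends >= hi)]
                if active.size:
                    best = min(active, key=lambda c: self._rank.get(c, len(self._rank)))
                else:
                    best = "intergenic"
                covered[best] = covered.get(best, 0) + (hi - lo)
        return pd.Series(covered, dtype=float) / total


def peaks_per_read(peaks: pd.DataFrame, fragset: FragmentSet) -> dict[str, float]:
    """Ratio of peak count to fragment count (also scaled per million fragments)."""
    n_frag = len(fragset)
    if n_frag == 0:
        raise ValueError("peaks-per-read is undefined for zero fragments")
    ratio = len(peaks) / n_frag
    return {"ratio": ratio, "per_million_fragments": ratio * 1e6}


def categorize_peaks(peaks: pd.DataFrame, annotation: ElementAnnotation,
                     chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Assign each peak a category at its summit and compute O/E enrichment.

    observed/expected = (category share of peaks) / (category share of genome).
    Returns one row per category with ``n_peaks``, ``peak_share``,
    ``genome_share`` and ``obs_over_exp``.
    """
    summits = peaks["summit"] if "summit" in peaks.columns else (peaks["start"] + peaks["end"]) // 2
    cats = [annotation.category_at(c, int(p)) for c, p in zip(peaks["chrom"], summits)]
    genome_share = annotation.genome_fractions(chrom_sizes)
    counts = pd.Series(cats).value_counts()
    out = pd.DataFrame({"category": genome_share.index})
    out["n_peaks"] = out["category"].map(counts).fillna(0).astype(int)
    out["peak_share"] = out["n_peaks"] / max(len(peaks), 1)
    out["genome_share"] = out["category"].map(genome_share)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["obs_over_exp"] = np.where(out["genome_share"] > 0,
                                       out["peak_share"] / out["genome_share"], np.nan)
    return out


def relative_coverage_profile(fragset: FragmentSet, elements: pd.DataFrame,
                              window: int = 2000) -> pd.DataFrame:
    """Mean fragment coverage around element centres, normalised to mean 1.

    For every element, per-base coverage is accumulated over a +/-``window``
    bp window centred on the element midpoint (reversed for minus-strand
    elements so profiles are 5'->3' oriented), averaged across elements and
    divided by the window-wide mean. Returns ``offset`` (bp from centre) and
    ``relative_coverage`` columns.
    """
    if len(elements) == 0:
        raise ValueError("no elements supplied for the coverage profile")
    width = 2 * window + 1
    total = np.zeros(width)
    frag = fragset.df
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in frag.groupby("chrom", sort=False, observed=True)}
    for row in elements.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        center = (int(row.start) + int(row.end)) // 2
        lo, hi = center - window, center + window + 1
        prof = np.zeros(width + 1)
        if chrom in by_chrom:
            starts, ends = by_chrom[chrom]
            i0 = np.searchsorted(starts, hi, side="left")
            s, e = starts[:i0], ends[:i0]
            keep = e > lo
            s, e = s[keep], e[keep]
            np.add.at(prof, np.clip(s - lo, 0, width), 1)
            np.add.at(prof, np.clip(e - lo, 0, width), -1)
        curve = np.cumsum(prof[:-1])
        strand = getattr(row, "strand", ".")
        if strand == "-":
            curve = curve[::-1]
        total += curve
    mean_curve = total / len(elements)
    grand_mean = mean_curve.mean()
    if grand_mean == 0:
        raise ValueError("no fragment coverage inside any element window")
    return pd.DataFrame({"offset": np.arange(-window, window + 1),
                         "relative_coverage": mean_curve / grand_mean})
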