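"""Aligned cfDNA fragment ingestion, filtering, and fragment-length histograms.

A *fragment* is the genomic interval covered by one sequenced cfDNA molecule.
For paired-end alignments the fragment is the reference span of the proper
pair (leftmost start to rightmost end); for merged/single-end reads it is the
aligned reference span, since read merging upstream reconstructs the whole
molecule. Duplicate removal is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .genome import CANONICAL_CHROMS, compartment_of, normalize_chrom

logger = logging.getLogger(__name__)

COMPARTMENTS = ("autosomal", "sexchrom", "mitochondrial", "unplaced")

_TSV_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "sequence"]


@dataclass(frozen=True)
class Fragment:
    """One aligned cfDNA fragment (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    mapq: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FilterConfig:
    """Fragment-level filters applied on ingest.

    The defaults (mapq >= 20, 20-400 bp, canonical human chromosomes) are
    conventional for cfDNA work and fully configurable.
    """

    min_mapq: int = 20
    min_len: int = 20
    max_len: int = 400
    chroms: tuple[str, ...] | None = None  # None -> canonical chr1-22, X, Y, M

    def allowed_chroms(self, chrom_sizes: dict[str, int] | None) -> set[str]:
        allowed = set(self.chroms) if self.chroms is not None else set(CANONICAL_CHROMS)
        if chrom_sizes is not None:
            allowed &= {normalize_chrom(c) for c in chrom_sizes}
        return allowed


class FragmentSet:
    """A per-sample collection of fragments, stored columnarly.

    Fragments are kept sorted by (chrom, start). Compartment counts
    (autosomal / sexchrom / mitochondrial / unplaced) always sum to the
    total fragment count.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "sample",
                 rejects: dict[str, int] | None = None) -> None:
        df = df.copy()
        for col in ("strand", "mapq", "sequence"):
            if col not in df.columns:
                df[col] = "." if col == "strand" else pd.NA
        df = df[_TSV_COLUMNS]
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df = df.astype({"start": np.int64, "end": np.int64})
        if len(df) and not (df["end"] > df["start"]).all():
            raise ValueError("all fragments must satisfy end > start")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.sample_id = sample_id
        self.rejects: dict[str, int] = dict(rejects or {})
        self.counts_by_compartment: dict[str, int] = {c: 0 for c in COMPARTMENTS}
        if len(df):
            comp = df["chrom"].map(compartment_of)
            self.counts_by_compartment.update(comp.value_counts().to_dict())

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Fragment]:
        for row in self.df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end), row.strand,
                           None if pd.isna(row.mapq) else int(row.mapq),
                           None if pd.isna(row.sequence) else str(row.sequence))

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def subset(self, compartment: str) -> "FragmentSet":
        mask = self.df["chrom"].map(compartment_of) == compartment
        return FragmentSet(self.df[mask], sample_id=self.sample_id)

    @classmethod
    def from_fragments(cls, fragments: list[Fragment], sample_id: str = "sample") -> "FragmentSet":
        df = pd.DataFrame(
            [(f.chrom, f.start, f.end, f.strand, f.mapq, f.sequence) for f in fragments],
            columns=_TSV_COLUMNS,
        )
        return cls(df, sample_id=sample_id)

    @classmethod
    def from_arrays(cls, chrom, start, end, strand=None, mapq=None, sequence=None,
                    sample_id: str = "sample") -> "FragmentSet":
        df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
        if strand is not None:
            df["strand"] = strand
        if mapq is not None:
            df["mapq"] = mapq
        if sequence is not None:
            df["sequence"] = sequence
        return cls(df, sample_id=sample_id)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["mapq"] = out["mapq"].astype("Int64")
        out.to_csv(path, sep="\t", index=False, na_rep="")


@dataclass
class SizeHistogram:
    """Fragment-length histogram at 1-bp resolution, in percent of reads.

    ``percent_reads`` sums to 100 over the configured length range; fragments
    outside the range are excluded from the denominator.
    """

    lengths: np.ndarray
    percent_reads: np.ndarray
    n_fragments: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.percent_reads = np.asarray(self.percent_reads, dtype=float)
        if self.lengths.shape != self.percent_reads.shape:
            raise ValueError("lengths and percent_reads must have equal shape")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"length": self.lengths, "percent_reads": self.percent_reads}) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SizeHistogram":
        df = pd.read_csv(path, sep="\t")
        return cls(df["length"].to_numpy(), df["percent_reads"].to_numpy())


def build_size_histogram(fragset: FragmentSet, min_len: int = 20,
                         max_len: int = 400) -> SizeHistogram:
    """Tally fragment lengths on the 1-bp grid [min_len, max_len].

    The y-axis is the percentage of reads at each length; normalisation uses
    the number of fragments whose length falls inside the range.
    """
    if len(fragset) == 0:
        raise ValueError("cannot build a size histogram from an empty fragment set")
    lengths = fragset.lengths
    inside = lengths[(lengths >= min_len) & (lengths <= max_len)]
    if inside.size == 0:
        raise ValueError("no fragments inside the requested length range")
    grid = np.arange(min_len, max_len + 1)
    counts = np.bincount(inside - min_len, minlength=grid.size)[: grid.size]
    percent = 100.0 * counts / inside.size
    return SizeHistogram(grid, percent, n_fragments=int(inside.size))


def _filter_frame(df: pd.DataFrame, filters: FilterConfig,
                  chrom_sizes: dict[str, int] | None,
                  rejects: Counter) -> pd.DataFrame:
    """Apply filters to a raw fragment frame, tallying rejected records."""
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)

    bad_coord = df["end"] <= df["start"]
    rejects["invalid_coordinates"] += int(bad_coord.sum())
    df = df[~bad_coord]

    allowed = filters.allowed_chroms(chrom_sizes)
    off_chrom = ~df["chrom"].isin(allowed)
    if off_chrom.any():
        rejects["chromosome_not_allowed"] += int(off_chrom.sum())
        df = df[~off_chrom]

    if chrom_sizes is not None:
        sizes = {normalize_chrom(c): n for c, n in chrom_sizes.items()}
        limit = df["chrom"].map(sizes)
        oob = df["end"] > limit
        if oob.any():
            rejects["outside_chromosome"] += int(oob.sum())
            logger.warning("rejected %d fragments beyond chromosome ends", oob.sum())
            df = df[~oob]

    length = df["end"] - df["start"]
    in_range = (length >= filters.min_len) & (length <= filters.max_len)
    rejects["length_out_of_range"] += int((~in_range).sum())
    df = df[in_range]

    if "mapq" in df.columns and df["mapq"].notna().any():
        ok = df["mapq"].isna() | (df["mapq"] >= filters.min_mapq)
        rejects["low_mapq"] += int((~ok).sum())
        df = df[ok]
    return df


def _fragments_from_alignment(path: str | Path, rejects: Counter) -> pd.DataFrame:
    """Build a raw fragment frame from a SAM/BAM of aligned, deduplicated reads.

    Proper pairs yield one fragment per pair (template span, counted at the
    leftmost mate); unpaired or merged reads yield their aligned span.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    rows: list[tuple] = []
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                rejects["unmapped_or_nonprimary"] += 1
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    rejects["not_proper_pair"] += 1
                    continue
                # count each pair once, at the leftmost mate
                if read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start = read.reference_start
                end = read.reference_end
            strand = "-" if read.is_reverse else "+"
            rows.append((read.reference_name, start, end, strand,
                         read.mapping_quality, None))
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def load_fragments(path: str | Path, format: str = "auto",
                   filters: FilterConfig | None = None,
                   chrom_sizes: dict[str, int] | None = None,
                   sample_id: str | None = None) -> FragmentSet:
    """Load fragments from a fragment TSV or an aligned SAM/BAM file.

    Parameters
    ----------
    path
        Fragment TSV (``chrom start end strand [mapq] [sequence]`` with
        header) or a SAM/BAM of aligned, deduplicated reads.
    format
        ``tsv``, ``bam`` (also covers SAM), or ``auto`` (by file extension).
    filters
        Fragment filters; defaults to :class:`FilterConfig`.
    chrom_sizes
        Optional chromosome-length table used to validate coordinates and
        restrict the chromosome set. Records on unknown chromosomes or
        beyond chromosome ends are rejected and tallied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    filters = filters or FilterConfig()
    if format == "auto":
        format = "bam" if path.suffix.lower() in (".bam", ".sam", ".cram") else "tsv"

    rejects: Counter = Counter()
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"fragment TSV missing columns: {sorted(missing)}")
    elif format == "bam":
        df = _fragments_from_alignment(path, rejects)
    else:
        raise ValueError(f"unknown fragment format: {format!r}")

    df = _filter_frame(df, filters, chrom_sizes, rejects)
    name = sample_id if sample_id is not None else path.stem
    return FragmentSet(df, sample_id=name, rejects=dict(rejects))
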