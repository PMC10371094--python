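"""Fragment end-motif profiling and G-quadruplex scanning.

cfDNA fragment ends carry nuclease cleavage signatures: the first k
nucleotides (k = 4 here, a 256-word vocabulary) at each 5' end. Motifs are
read from the reference genome at the aligned fragment boundaries, so each
duplex fragment contributes two motifs — the k bases at its left end on the
forward strand, and the reverse complement of the k bases at its right end
(the 5' motif of the complementary strand). Reading from the reference
rather than from read bases makes the profile robust to sequencing error
and lets fragment tables omit sequence entirely; ambiguity then arises only
from reference Ns, and motifs containing non-ACGT characters are discarded
and tallied.

Profile randomness is summarised by Shannon entropy in bits (0 to 8 for
4-mers). G-quadruplex prevalence is the percentage of fragments whose
sequence matches a G4 sequence motif — by default four runs of >= 3 G
separated by 1-7 nt loops, scanned on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import revcomp


def motif_vocabulary(k: int = 4) -> list[str]:
    """All 4**k DNA k-mers in lexicographic order (256 words for k = 4)."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


class DictReference:
    """In-memory reference: mapping of contig name to sequence string."""

    def __init__(self, contigs: dict[str, str]) -> None:
        self.contigs = {c: s.upper() for c, s in contigs.items()}

    def references(self) -> list[str]:
        return list(self.contigs)

    def get_reference_length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.contigs[chrom][start:end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def open_reference(ref) -> object:
    """Coerce a path / dict / accessor into an object with ``fetch``."""
    if isinstance(ref, (str, Path)):
        import pysam

        return pysam.FastaFile(str(ref))
    if isinstance(ref, dict):
        return DictReference(ref)
    if not hasattr(ref, "fetch"):
        raise TypeError("reference must expose fetch(chrom, start, end)")
    return ref


@dataclass
class MotifProfile:
    """Counts and frequencies over the k-mer end-motif vocabulary."""

    counts: pd.Series  # indexed by the full vocabulary, integer counts
    n_discarded: int = 0
    n_skipped_fragments: int = 0

    @property
    def k(self) -> int:
        return len(self.counts.index[0])

    @property
    def freqs(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("motif profile has no counted motifs")
        return self.counts / total

    @property
    def entropy_bits(self) -> float:
        return shannon_entropy(self)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"motif": self.counts.index, "count": self.counts.values})
        df["freq"] = df["count"] / max(df["count"].sum(), 1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_counts(cls, counts: dict[str, int] | pd.Series, k: int = 4) -> "MotifProfile":
        full = pd.Series(0, index=motif_vocabulary(k), dtype=np.int64)
        s = pd.Series(counts, dtype=np.int64)
        unknown = s.index.difference(full.index)
        if len(unknown):
            raise ValueError(f"motifs outside the {{A,C,G,T}}^{k} vocabulary: {list(unknown)[:5]}")
        full.loc[s.index] = s.values
        return cls(counts=full)


# base encoding for the vectorised fast path: A=0 C=1 G=2 T=3, other=255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _end_motif_codes(seq_codes: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                     k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised motif codes for left (forward) and right (revcomp) fragment ends.

    Returns integer codes in [0, 4**k); invalid motifs (containing a
    non-ACGT base) are coded as -1.
    """
    n = starts.size
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    left_bad = np.zeros(n, dtype=bool)
    right_bad = np.zeros(n, dtype=bool)
    for i in range(k):
        lb = seq_codes[starts + i]
        left_bad |= lb == 255
        left = left * 4 + np.where(lb == 255, 0, lb)
        # right-end motif read 3'->5' on the forward strand, complemented:
        # position end-1-i contributes complement(base) at motif position i
        rb = seq_codes[ends - 1 - i]
        right_bad |= rb == 255
        right = right * 4 + np.where(rb == 255, 0, 3 - rb)
    left[left_bad] = -1
    right[right_bad] = -1
    return left, right


def extract_end_motifs(fragset: FragmentSet, reference, k: int = 4) -> MotifProfile:
    """Build the pooled end-motif profile of a fragment set against a reference.

    Each fragment contributes its two 5' end motifs. Fragments shorter than
    ``k`` or extending past the reference are skipped and tallied in
    ``n_skipped_fragments``; motifs with non-ACGT characters are discarded
    and tallied in ``n_discarded``.
    """
    ref = open_reference(reference)
    vocab = motif_vocabulary(k)
    counts = np.zeros(len(vocab), dtype=np.int64)
    n_discarded = 0
    n_skipped = 0

    for chrom, g in fragset.df.groupby("chrom", sort=False, observed=True):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if isinstance(ref, DictReference):
            contig = ref.contigs.get(chrom)
            if contig is None:
                n_skipped += len(g)
                continue
            clen = len(contig)
            ok = (ends - starts >= k) & (starts >= 0) & (ends <= clen)
            n_skipped += int((~ok).sum())
            if not ok.any():
                continue
            codes = _ENCODE[np.frombuffer(contig.encode("ascii"), dtype=np.uint8)]
            left, right = _end_motif_codes(codes, starts[ok], ends[ok], k)
            for arr in (left, right):
                bad = arr < 0
                n_discarded += int(bad.sum())
                counts += np.bincount(arr[~bad], minlength=len(vocab))
        else:
            try:
                clen = ref.get_reference_length(chrom)
            except (KeyError, ValueError):
                n_skipped += len(g)
                continue
            for s, e in zip(starts, ends):
                if e - s < k or s < 0 or e > clen:
                    n_skipped += 1
                    continue
                for motif in (ref.fetch(chrom, s, s + k).upper(),
                              revcomp(ref.fetch(chrom, e - k, e).upper())):
                    idx = _motif_index(motif, k)
                    if idx < 0:
                        n_discarded += 1
                    else:
                        counts[idx] += 1

    series = pd.Series(counts, index=vocab)
    return MotifProfile(counts=series, n_discarded=n_discarded,
                        n_skipped_fragments=n_skipped)


def _motif_index(motif: str, k: int) -> int:
    idx = 0
    for ch in motif:
        b = _ENCODE[ord(ch)] if ord(ch) < 256 else 255
        if b == 255:
            return -1
        idx = idx * 4 + int(b)
    return idx


def shannon_entropy(profile: MotifProfile) -> float:
    """Shannon entropy of the motif frequency profile, in bits."""
    f = profile.freqs.to_numpy(dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class GQuadParams:
    """G-quadruplex sequence-motif definition: ``n_runs`` runs of at least
    ``min_run`` guanines separated by loops of 1..``max_loop`` nt."""

    min_run: int = 3
    max_loop: int = 7
    n_runs: int = 4
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_run < 2 or self.max_loop < 1 or self.n_runs < 4:
            raise ValueError("invalid G-quadruplex parameters")

    @property
    def regex(self) -> re.Pattern:
        g = f"G{{{self.min_run},}}"
        loop = f"[ACGT]{{1,{self.max_loop}}}"
        return re.compile(f"{g}(?:{loop}{g}){{{self.n_runs - 1}}}")


def gquad_prevalence(fragset: FragmentSet, reference=None,
                     params: GQuadParams | None = None) -> float:
    """Percent of fragments whose sequence contains >= 1 G-quadruplex motif.

    Sequences are fetched from ``reference`` when given, otherwise taken from
    the fragment table's ``sequence`` column. With ``scan_both_strands`` a
    fragment is positive if either strand matches (the reverse complement is
    scanned via the equivalent C-run pattern on the forward sequence).
    """
    params = params or GQuadParams()
    pattern = params.regex
    c_pattern = re.compile(
        f"C{{{params.min_run},}}(?:[ACGT]{{1,{params.max_loop}}}C{{{params.min_run},}})"
        f"{{{params.n_runs - 1}}}")

    ref = open_reference(reference) if reference is not None else None
    n_scanned = 0
    n_positive = 0
    for chrom, g in fragset.df.groupby("chrom", sort=False, observed=True):
        if ref is not None:
            try:
                clen = (len(ref.contigs[chrom]) if isinstance(ref, DictReference)
                        else ref.get_reference_length(chrom))
            except (KeyError, ValueError):
                continue
            seqs = (ref.fetch(chrom, s, e).upper()
                    for s, e in zip(g["start"], g["end"]) if e <= clen)
        else:
            seqs = (str(s).upper() for s in g["sequence"] if not pd.isna(s))
        for seq in seqs:
            n_scanned += 1
            hit = pattern.search(seq) is not None
            if not hit and params.scan_both_strands:
                hit = c_pattern.search(seq) is not None
            n_positive += hit
    if n_scanned == 0:
        return 0.0
    return 100.0 * n_positive / n_scanned
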