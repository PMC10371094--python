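"""Genome bookkeeping: chromosome naming, compartments, chrom.sizes tables.

Coordinates are 0-based half-open (BED convention) everywhere in this
package; 1-based sources (SAM/BAM positions) are converted on ingest.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("chrX", "chrY")
MITO_CHROMS: tuple[str, ...] = ("chrM", "chrMT")

#: canonical human chromosome set used by the default fragment filters
CANONICAL_CHROMS: tuple[str, ...] = AUTOSOMES + SEX_CHROMS + ("chrM",)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize_chrom(chrom: str) -> str:
    """Map Ensembl-style names (``1``, ``MT``) onto UCSC-style (``chr1``, ``chrM``)."""
    c = chrom.strip()
    if c.startswith("chr"):
        return "chrM" if c == "chrMT" else c
    if c == "MT":
        return "chrM"
    return f"chr{c}"


def compartment_of(chrom: str) -> str:
    """Classify a chromosome as autosomal / sexchrom / mitochondrial / unplaced."""
    c = normalize_chrom(chrom)
    if c in AUTOSOMES:
        return "autosomal"
    if c in SEX_CHROMS:
        return "sexchrom"
    if c in MITO_CHROMS:
        return "mitochondrial"
    return "unplaced"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps case, maps other chars to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed chrom.sizes line: {line!r}")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"empty chrom.sizes file: {path}")
    return sizes


def grch38_chrom_sizes() -> dict[str, int]:
    """Chromosome lengths for GRCh38 chr1-22, chrX, chrY, chrM (vendored table)."""
    ref = importlib.resources.files("salifrag") / "data" / "GRCh38.chrom.sizes"
    sizes: dict[str, int] = {}
    for line in ref.read_text().splitlines():
        if line.strip():
            chrom, length = line.split("\t")
            sizes[chrom] = int(length)
    return sizes
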