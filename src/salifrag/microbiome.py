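"""Microbial read accounting from classifier abundance tables.

Salivary cfDNA contains a sizeable microbial component. Reads are aligned
sequentially upstream (human first, then a microbial database); reads that
re-align to the host inside the microbial database are recorded as a host
row and excluded from all microbial denominators. This module consumes the
resulting taxa x sample count table, aggregates it at a chosen taxonomic
rank, and computes relative abundances and Shannon alpha diversity
(natural log, the ecology convention).

Taxa TSV layout: ``taxon_id  lineage  rank  sample1 ... sampleN`` where
lineage uses greengenes-style prefixes (``k__...;p__...;c__...;o__...;
f__...;g__...;s__...``). A row with rank ``host`` marks host-aligned reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RANK_PREFIX = {"kingdom": "k__", "phylum": "p__", "class": "c__", "order": "o__",
               "family": "f__", "genus": "g__", "species": "s__"}


@dataclass
class TaxaTable:
    """Taxa x sample read counts with lineage metadata.

    ``df`` holds columns ``taxon_id``, ``lineage``, ``rank`` followed by one
    numeric column per sample. Host rows (rank == 'host') are excluded from
    microbial totals.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"taxon_id", "lineage", "rank"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"taxa table missing columns: {sorted(missing)}")
        if (self.df[self.sample_ids] < 0).any().any():
            raise ValueError("taxa counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("taxon_id", "lineage", "rank")]

    @property
    def microbial(self) -> pd.DataFrame:
        return self.df[self.df["rank"] != "host"]

    def microbial_totals(self) -> pd.Series:
        return self.microbial[self.sample_ids].sum()

    def counts(self, sample: str, include_host: bool = False) -> pd.Series:
        df = self.df if include_host else self.microbial
        return df.set_index("taxon_id")[sample]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxaTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _rank_label(lineage: str, rank: str) -> str:
    prefix = RANK_PREFIX[rank]
    for field in str(lineage).split(";"):
        field = field.strip()
        if field.startswith(prefix) and len(field) > len(prefix):
            return field[len(prefix):]
    return "unclassified"


def aggregate_rank(table: TaxaTable, rank: str) -> TaxaTable:
    """Sum microbial counts over taxa sharing a label at ``rank``.

    Taxa whose lineage carries no label at that rank are pooled into
    ``unclassified``. Host rows are dropped. Total microbial counts per
    sample are conserved.
    """
    if rank not in RANK_PREFIX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {list(RANK_PREFIX)}")
    mic = table.microbial.copy()
    samples = table.sample_ids
    if mic.empty:
        return TaxaTable(pd.DataFrame(columns=["taxon_id", "lineage", "rank", *samples]))
    mic["_label"] = [_rank_label(lin, rank) for lin in mic["lineage"]]
    grouped = mic.groupby("_label", sort=True)[samples].sum().reset_index()
    out = pd.DataFrame({"taxon_id": grouped["_label"],
                        "lineage": [f"{RANK_PREFIX[rank]}{x}" for x in grouped["_label"]],
                        "rank": rank})
    out[samples] = grouped[samples]
    return TaxaTable(out)


def relative_abundance(table: TaxaTable) -> pd.DataFrame:
    """Microbial counts normalised to per-sample proportions."""
    mic = table.microbial.copy()
    samples = table.sample_ids
    totals = mic[samples].sum()
    mic[samples] = mic[samples] / totals.replace(0, np.nan)
    return mic


def alpha_diversity(counts: pd.Series | np.ndarray, index: str = "shannon") -> float:
    """Within-sample Shannon diversity, H = -sum p_i ln p_i (nats)."""
    if index != "shannon":
        raise ValueError(f"unsupported diversity index: {index!r}")
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("alpha diversity undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def microbial_read_percent(human_mapped: int, microbial_mapped: int,
                           total: int) -> dict[str, float]:
    """Partition total reads into human / microbial / unmapped percentages."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if human_mapped + microbial_mapped > total:
        raise ValueError("human + microbial reads exceed the total")
    human_pct = 100.0 * human_mapped / total
    microbial_pct = 100.0 * microbial_mapped / total
    return {"human_pct": human_pct, "microbial_pct": microbial_pct,
            "unmapped_pct": 100.0 - human_pct - microbial_pct}
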