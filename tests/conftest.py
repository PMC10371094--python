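"""Shared fixtures and independent reference oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import salifrag as sf


# -- independent oracles ------------------------------------------------------

def brute_force_extrema(y: np.ndarray) -> tuple[list[int], list[int]]:
    """Neighbour-comparison reference for the peak/valley detector at delta=0.

    Interior points larger than both neighbours are peaks, smaller than both
    are valleys; the boundary behaviour mirrors the alternating detector
    contract: a first point above its neighbour is a peak (the scan opens
    hunting a maximum), and when the last labelled extremum is a peak the
    final point is flushed as its right-hand valley. Assumes distinct values.
    """
    n = len(y)
    extrema: list[tuple[int, str]] = []
    if y[0] > y[1]:
        extrema.append((0, "peak"))
    for i in range(1, n - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            extrema.append((i, "peak"))
        elif y[i] < y[i - 1] and y[i] < y[i + 1]:
            extrema.append((i, "valley"))
    if extrema and extrema[-1][1] == "peak":
        extrema.append((n - 1, "valley"))
    peaks = [i for i, kind in extrema if kind == "peak"]
    valleys = [i for i, kind in extrema if kind == "valley"]
    return peaks, valleys


def bky_oracle(pvalues, q: float = 0.05) -> np.ndarray:
    """Step-by-step execution of the two-stage adaptive step-up procedure.

    Literal transcription of the published algorithm, independent of the
    package's vectorised implementation.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size

    def step_up(level: float) -> np.ndarray:
        order = np.argsort(p, kind="mergesort")
        sorted_p = p[order]
        below = [i for i in range(m) if sorted_p[i] <= (i + 1) / m * level]
        k = (max(below) + 1) if below else 0
        mask = np.zeros(m, dtype=bool)
        mask[order[:k]] = True
        return mask

    q_prime = q / (1.0 + q)
    stage1 = step_up(q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return step_up(q_prime * m / m0)


# -- fixtures -----------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_reference() -> sf.DictReference:
    """Small random genome (2 x 1.2 Mb contigs + chrM) shared across tests."""
    return sf.make_toy_reference(seed=11, n_contigs=2, contig_len=1_200_000)


@pytest.fixture(scope="session")
def toy_chrom_sizes(toy_reference) -> dict[str, int]:
    return {c: len(s) for c, s in toy_reference.contigs.items()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_fragset(chroms, starts, lengths, sample_id="t", **kwargs) -> sf.FragmentSet:
    starts = np.asarray(starts)
    return sf.FragmentSet.from_arrays(chrom=chroms, start=starts,
                                      end=starts + np.asarray(lengths),
                                      sample_id=sample_id, **kwargs)


def fragset_with_lengths(lengths, chrom="chr1", start=1000) -> sf.FragmentSet:
    """A fragment set with prescribed lengths, all at the same locus."""
    lengths = np.asarray(lengths)
    return make_fragset([chrom] * len(lengths), np.full(len(lengths), start), lengths)
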