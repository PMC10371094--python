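"""Peak/valley detection on fragment-size histograms and the jagged
peak-valley index.

Salivary cfDNA size profiles show a comb of local maxima at roughly 10-bp
spacing below 100 bp. The jagged peak-valley index quantifies this
ruggedness as the mean height drop from each detected peak to the first
valley on its right:

    J = (1/n) * sum_i (P_i - V_i)

where P_i is the % reads at peak i and V_i the % reads at the nearest
valley with a larger fragment length. A featureless profile gives J = 0.

Detection uses a delta-gated alternating extremum search with a lookahead
window: the series is scanned left to right, alternating between hunting a
maximum and a minimum; a candidate maximum is confirmed once the series
drops more than ``delta`` below it and no higher value occurs within the
next ``lookahead`` points (symmetrically for minima). The first confirmed
extremum is always a peak. A valley still pending when the series ends is
emitted, so every interior peak acquires its right-hand valley; a trailing
peak with no valley to its right is left unpaired and does not enter the
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import SizeHistogram


@dataclass
class PeakDetectParams:
    """Detector settings: ``lookahead`` in grid points, ``delta`` in % reads."""

    lookahead: int = 1
    delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.lookahead < 1:
            raise ValueError("lookahead must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class PeakValleySet:
    """Detected extrema and the peak/right-valley pairs used by the index."""

    peaks: list[tuple[float, float]] = field(default_factory=list)
    valleys: list[tuple[float, float]] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[float, float]]:
        """(P_i, V_i) pairs: each peak matched to the first valley to its right."""
        out: list[tuple[float, float]] = []
        vx = [x for x, _ in self.valleys]
        vy = [y for _, y in self.valleys]
        j = 0
        for px, py in self.peaks:
            while j < len(vx) and vx[j] <= px:
                j += 1
            if j == len(vx):
                break  # trailing peak with no right-hand valley: dropped
            out.append((py, vy[j]))
        return out


def detect_peaks_valleys(hist: SizeHistogram | tuple, params: PeakDetectParams | None = None
                         ) -> PeakValleySet:
    """Locate alternating peaks and valleys in a size histogram.

    Accepts a :class:`SizeHistogram` or an ``(x, y)`` pair of arrays. Raises
    on series shorter than 3 points; a series with no extrema returns an
    empty :class:`PeakValleySet`.
    """
    params = params or PeakDetectParams()
    if isinstance(hist, SizeHistogram):
        x, y = hist.lengths, hist.percent_reads
    else:
        x, y = hist
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("peak detection needs at least 3 histogram points")

    peaks: list[tuple[float, float]] = []
    valleys: list[tuple[float, float]] = []
    mx, mn = -np.inf, np.inf
    mx_pos = mn_pos = 0
    look_for_max = True

    for i in range(n):
        yi = y[i]
        if yi > mx:
            mx, mx_pos = yi, i
        if yi < mn:
            mn, mn_pos = yi, i
        window_hi = min(i + params.lookahead, n)
        if look_for_max:
            if yi < mx - params.delta and np.isfinite(mx):
                if y[i:window_hi].max(initial=-np.inf) < mx:
                    peaks.append((x[mx_pos], mx))
                    mn, mn_pos = yi, i
                    look_for_max = False
        else:
            if yi > mn + params.delta:
                if y[i:window_hi].min(initial=np.inf) > mn:
                    valleys.append((x[mn_pos], mn))
                    mx, mx_pos = yi, i
                    look_for_max = True

    # flush the pending valley so the last interior peak gets its right-hand
    # partner; a pending peak stays unreported (it has no valley to pair with)
    if not look_for_max and peaks and mn_pos > 0:
        last_peak_x = peaks[-1][0]
        if x[mn_pos] > last_peak_x:
            valleys.append((x[mn_pos], mn))

    return PeakValleySet(peaks=peaks, valleys=valleys)


def jagged_index(pvs: PeakValleySet) -> float:
    """Mean peak-minus-right-valley difference; 0.0 when there are no pairs."""
    pairs = pvs.pairs
    if not pairs:
        return 0.0
    return float(sum(p - v for p, v in pairs) / len(pairs))


def jagged_index_from_histogram(hist: SizeHistogram,
                                params: PeakDetectParams | None = None) -> float:
    """Convenience wrapper: detect extrema on ``hist`` and return the index."""
    return jagged_index(detect_peaks_valleys(hist, params))
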