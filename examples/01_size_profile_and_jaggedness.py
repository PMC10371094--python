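"""Fragment-size profile and the jagged peak-valley index.

Simulates one salivary-cfDNA-like sample with a strong 10-bp comb and one
with a weak comb plus a mononucleosomal (~167 bp) shoulder, builds the
% reads size histograms, and scores their jaggedness.
"""

import salifrag as sf

ref = sf.make_toy_reference(seed=0)
for label, params in [
    ("noncancer-like", sf.SampleParams(comb_amplitude=0.8, mono_weight=0.05, seed=1)),
    ("cancer-like", sf.SampleParams(comb_amplitude=0.1, mono_weight=0.30, seed=2)),
]:
    fragset = sf.simulate_fragments(params, ref)
    hist = sf.build_size_histogram(fragset, min_len=20, max_len=400)
    pvs = sf.detect_peaks_valleys(hist, sf.PeakDetectParams(lookahead=1, delta=1e-4))
    print(f"{label}: {len(fragset)} fragments, {len(pvs.pairs)} peak/valley pairs, "
          f"jagged index = {sf.jagged_index(pvs):.3f}")

# The jagged index is the mean height drop (in % reads) from each histogram
# peak to the first valley on its right: a rugged, comb-like profile scores
# high, a smooth profile scores near zero.
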