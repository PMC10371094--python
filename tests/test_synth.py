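"""Synthetic-cohort generator: determinism, planted-effect recovery, taxa."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

import salifrag as sf


class TestSimulateFragments:
    def test_deterministic_given_seed(self, toy_reference):
        p = sf.SampleParams(n_fragments=5000, seed=42)
        a = sf.simulate_fragments(p, toy_reference)
        b = sf.simulate_fragments(p, toy_reference)
        assert a.df.equals(b.df)

    def test_invalid_params_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            sf.simulate_fragments(sf.SampleParams(n_fragments=0), toy_reference)
        with pytest.raises(ValueError):
            sf.SampleParams(mono_weight=1.5).validate()

    def test_mono_mass_matches_mixture_cdf(self, toy_reference):
        p = sf.SampleParams(n_fragments=50_000, mono_weight=0.3, seed=9)
        fs = sf.simulate_fragments(p, toy_reference)
        pmf = sf.length_pmf(p)
        grid = np.arange(20, 401)
        band = (grid >= 150) & (grid <= 185)
        expected = pmf[band].sum()
        observed = ((fs.lengths >= 150) & (fs.lengths <= 185)).mean()
        se = np.sqrt(expected * (1 - expected) / 50_000)
        assert abs(observed - expected) < 3 * se

    def test_comb_amplitude_drives_jaggedness(self, toy_reference):
        high, low = [], []
        for seed in range(6):
            for amp, acc in ((0.8, high), (0.1, low)):
                fs = sf.simulate_fragments(
                    sf.SampleParams(n_fragments=50_000, comb_amplitude=amp, seed=seed),
                    toy_reference)
                hist = sf.build_size_histogram(fs)
                acc.append(sf.jagged_index_from_histogram(hist))
        assert np.mean(high) > np.mean(low)
        assert all(h > l for h, l in zip(high, low))

    def test_no_comb_has_no_lag10_autocorrelation_excess(self, toy_reference):
        fs = sf.simulate_fragments(
            sf.SampleParams(n_fragments=100_000, comb_amplitude=0.0, mono_weight=0.0,
                            seed=3), toy_reference)
        hist = sf.build_size_histogram(fs)
        y = hist.percent_reads - hist.percent_reads.mean()

        def lag_corr(lag):
            return float(np.corrcoef(y[:-lag], y[lag:])[0, 1])

        assert abs(lag_corr(10)) < max(abs(lag_corr(9)), abs(lag_corr(11))) + 0.05

    def test_motif_bias_enriches_favored_left_ends(self, toy_reference):
        biased = sf.simulate_fragments(
            sf.SampleParams(n_fragments=20_000, motif_bias_strength=0.5, seed=4),
            toy_reference)
        unbiased = sf.simulate_fragments(
            sf.SampleParams(n_fragments=20_000, motif_bias_strength=0.0, seed=4),
            toy_reference)
        def gg_share(fs):
            prof = sf.extract_end_motifs(fs, toy_reference)
            f = prof.freqs
            return sum(f[m] for m in f.index if m.startswith("GG"))
        assert gg_share(biased) > gg_share(unbiased) + 0.1

    def test_telomere_bias_loads_terminal_bins(self, toy_reference, toy_chrom_sizes):
        auto = {c: n for c, n in toy_chrom_sizes.items() if c != "chrM"}
        bins = sf.make_bins(auto, bin_size=400_000, chroms=list(auto))
        fs = sf.simulate_fragments(
            sf.SampleParams(n_fragments=50_000, telomere_bias=5.0, mito_fraction=0.0,
                            motif_bias_strength=0.0, seed=8), toy_reference, bins=bins)
        table = sf.assign_to_bins(fs, bins).df
        terminal = table.groupby("chrom")["n_total"].agg(["first", "last"]).sum(axis=1)
        interior = table.groupby("chrom")["n_total"].sum() - terminal
        # 2 terminal vs 1 interior bin per 1.2 Mb contig at 5x weight
        assert (terminal > 2 * interior).all()


class TestSimulateTaxa:
    def test_uniform_composition_diversity_limit(self):
        comp = {f"t{i}": 0.125 for i in range(8)}
        table = sf.simulate_taxa(4, comp, depth=200_000, overdispersion=0.0, seed=1)
        for s in table.sample_ids:
            assert sf.alpha_diversity(table.counts(s)) == pytest.approx(np.log(8), abs=0.01)

    def test_zero_overdispersion_matches_multinomial_variance(self):
        comp = {"a": 0.5, "b": 0.3, "c": 0.2}
        table = sf.simulate_taxa(300, comp, depth=1000, overdispersion=0.0, seed=2)
        counts = table.df[table.sample_ids].to_numpy()
        for i, p in enumerate([0.5, 0.3, 0.2]):
            var_ratio = counts[i].var(ddof=1) / (1000 * p * (1 - p))
            # (n-1) s^2 / sigma^2 ~ chi^2_{n-1}
            stat = 299 * var_ratio
            assert sps.chi2.cdf(stat, 299) > 1e-4
            assert sps.chi2.sf(stat, 299) > 1e-4

    def test_overdispersion_inflates_variance(self):
        comp = {"a": 0.5, "b": 0.5}
        tight = sf.simulate_taxa(200, comp, depth=1000, overdispersion=0.0, seed=3)
        loose = sf.simulate_taxa(200, comp, depth=1000, overdispersion=0.1, seed=3)
        v0 = tight.df[tight.sample_ids].to_numpy()[0].var()
        v1 = loose.df[loose.sample_ids].to_numpy()[0].var()
        assert v1 > 3 * v0

    def test_planted_genus_difference_detected(self):
        # contrast magnitude mirrors the default templates' dominant-genus shift
        base = dict(sf.NONCANCER_TAXA)
        shifted = dict(base)
        shifted["Prevotella"] = 0.30
        norm = sum(shifted.values())
        shifted = {k: v / norm for k, v in shifted.items()}
        flagged = 0
        reps = 25
        for rep in range(reps):
            t1 = sf.simulate_taxa(10, base, depth=100_000, seed=1000 + rep,
                                  sample_ids=[f"a{i}" for i in range(10)])
            t2 = sf.simulate_taxa(10, shifted, depth=100_000, seed=5000 + rep,
                                  sample_ids=[f"b{i}" for i in range(10)])
            merged = t1.df.merge(t2.df[["taxon_id", *t2.sample_ids]], on="taxon_id")
            table = sf.TaxaTable(merged)
            rel = sf.relative_abundance(table).set_index("taxon_id")[table.sample_ids]
            import pandas as pd
            fm = sf.FeatureMatrix(values=rel.T,
                                  groups=pd.Series(["a"] * 10 + ["b"] * 10,
                                                   index=rel.columns))
            scan = sf.feature_scan(fm).table.set_index("feature")
            flagged += bool(scan.loc["Prevotella", "rejected"])
        assert flagged / reps > 0.8

    def test_invalid_depth_and_composition(self):
        with pytest.raises(ValueError):
            sf.simulate_taxa(2, {"a": 1.0}, depth=0)
        with pytest.raises(ValueError):
            sf.simulate_taxa(2, {"a": 0.5, "b": 0.2}, depth=10)


class TestSimulateCohort:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        small = sf.SampleParams(n_fragments=3000)
        kwargs = dict(n_per_group=2, group_params=(small, small), seed=77,
                      taxa_depth=5000)
        sf.simulate_cohort(out_dir=tmp_path / "a", **kwargs)
        sf.simulate_cohort(out_dir=tmp_path / "b", **kwargs)
        files = ["features.tsv", "truth.json", "taxa.tsv", "toy.chrom.sizes",
                 "reference.fa", "fragments/nc1.tsv", "fragments/gc2.tsv"]
        for f in files:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f

    def test_truth_records_every_sample(self):
        small = sf.SampleParams(n_fragments=2000)
        result = sf.simulate_cohort(n_per_group=3, group_params=(small, small),
                                    seed=5, with_taxa=False)
        assert set(result.truth["samples"]) == set(result.feature_matrix.values.index)
        assert len(result.truth["samples"]) == 6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sf.simulate_cohort(n_per_group=1)

    def test_null_cohort_scan_controls_false_rejections(self):
        shares = []
        small = sf.SampleParams(n_fragments=4000)
        for seed in range(5):
            result = sf.simulate_cohort(n_per_group=4, group_params=(small, small),
                                        seed=seed, with_taxa=False)
            scan = sf.feature_scan(result.feature_matrix)
            shares.append(scan.n_significant / max(len(scan.table), 1))
        assert np.mean(shares) <= 0.05 + 0.05
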