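"""Simulator tests: panels, zone pedigrees, read counts, determinism."""

import numpy as np
import pytest
from scipy.stats import binomtest

import contactzone as cz
from contactzone.simulate import (OUTCROSSER, SELFER, _meiosis, panel_site_map,
                                  simulate_panels)


class TestPanels:
    def test_zero_divergence_gives_identical_frequencies(self):
        cfg = cz.SimConfig(n_sites=300, panel_divergence=0.0, fixed_diff_fraction=0.0)
        panels = simulate_panels(cfg)
        assert np.array_equal(panels.df["ac_out"], panels.df["ac_self"])

    def test_row_count_matches_requested_sites(self):
        # the study-scale panel: 113786 SNPs
        cfg = cz.SimConfig(n_sites=113786)
        assert len(simulate_panels(cfg)) == 113786

    def test_balding_nichols_matches_reimplementation(self):
        cfg = cz.SimConfig(n_sites=10_000, panel_divergence=0.4,
                           fixed_diff_fraction=0.0, seed=5)
        panels = simulate_panels(cfg)
        f_out = panels.df["ac_out"] / panels.df["an_out"]
        f_self = panels.df["ac_self"] / panels.df["an_self"]
        # independent draw-by-draw re-simulation with the same seed
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, 10_000)
        F = 0.4
        a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
        g_out = rng.beta(a, b)
        g_self = rng.beta(a, b)
        assert np.allclose(f_out, g_out)
        assert np.isclose(np.abs(f_out - f_self).mean(),
                          np.abs(g_out - g_self).mean())

    def test_sites_spaced_at_least_200bp(self):
        cfg = cz.SimConfig(n_sites=500)
        df = simulate_panels(cfg).df
        for _, sub in df.groupby("chrom"):
            assert np.diff(np.sort(sub["pos"])).min() >= 200

    def test_invalid_divergence_raises(self):
        with pytest.raises(ValueError):
            simulate_panels(cz.SimConfig(panel_divergence=1.5))


class TestZone:
    def test_no_pulse_gives_zero_admixture(self):
        cfg = cz.SimConfig(n_sites=100, n_outcrosser=10, n_selfer=8,
                           pulse_fraction=0.0, generations_since_pulse=3, seed=1)
        panels = simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        assert (truth.true_alpha == 0).all()

    def test_f1_cohort_is_fully_heterozygous(self):
        cfg = cz.SimConfig(n_sites=100, n_outcrosser=5, n_selfer=0,
                           pedigree_class="F1", seed=2)
        panels = simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        assert (truth.true_ancestry == 1).all()
        assert np.allclose(truth.true_alpha, 0.5)

    def test_bc1_cohort_mean_alpha_near_quarter(self):
        cfg = cz.SimConfig(n_sites=500, n_outcrosser=200, n_selfer=0,
                           pedigree_class="BC1", seed=3)
        panels = simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        # independent tally: alpha recomputed from the haplotype tracts
        selfer_copies = truth.ancestry_hap.sum(axis=1)
        tally = selfer_copies.mean(axis=1) / 2.0
        assert np.allclose(tally, truth.true_alpha)
        se = truth.true_alpha.std(ddof=1) / np.sqrt(200)
        assert abs(truth.true_alpha.mean() - 0.25) < 4 * se + 1e-3

    def test_chloroplast_follows_maternal_line(self):
        cfg = cz.SimConfig(n_sites=60, n_outcrosser=12, n_selfer=10,
                           generations_since_pulse=6, seed=7)
        panels = simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        anc = truth.sample_index.copy()
        for mothers, _fathers in truth.pedigree[::-1]:
            anc = mothers[anc]
        assert np.array_equal(truth.chloroplast_origin,
                              truth.founder_chloroplast[anc])

    def test_selfing_halves_heterozygosity_per_generation(self):
        # core inheritance machinery: selfing an F1 line halves the fraction
        # of heterozygous-ancestry sites each generation in expectation
        # many chromosomes: enough independent segments that the genome-wide
        # heterozygous fraction concentrates around its expectation
        cfg = cz.SimConfig(n_sites=2000, n_chromosomes=10, map_length=1.0)
        panels = simulate_panels(cfg)
        chrom, morgan = panel_site_map(panels)
        rng = np.random.default_rng(11)
        het_frac = []
        reps = 40
        for _ in range(reps):
            ind = np.stack([np.zeros(2000, np.int8), np.ones(2000, np.int8)])
            fracs = []
            for _gen in range(3):
                ind = np.stack([
                    _meiosis(ind, chrom, morgan, cfg.map_length, rng),
                    _meiosis(ind, chrom, morgan, cfg.map_length, rng),
                ])
                fracs.append((ind[0] != ind[1]).mean())
            het_frac.append(fracs)
        mean = np.array(het_frac).mean(axis=0)
        assert np.allclose(mean, [0.5, 0.25, 0.125], atol=0.04)

    def test_missing_taxon_raises_in_forward_mode(self):
        cfg = cz.SimConfig(n_sites=50, n_outcrosser=5, n_selfer=0)
        panels = simulate_panels(cfg)
        with pytest.raises(ValueError):
            cz.simulate_zone(cfg, panels)

    def test_phenotypes_separate_taxa(self):
        cfg = cz.SimConfig(n_sites=50, n_outcrosser=30, n_selfer=30,
                           pulse_fraction=0.0, generations_since_pulse=2, seed=9)
        panels = simulate_panels(cfg)
        records, _ = cz.simulate_zone(cfg, panels)
        import pandas as pd
        df = pd.DataFrame([r.__dict__ for r in records])
        for trait in ("petal_size", "herkogamy", "protandry"):
            gap = df.groupby("taxon")[trait].mean()
            sd = df.groupby("taxon")[trait].std().mean()
            assert abs(gap["outcrosser"] - gap["selfer"]) > 4 * sd
        assert (df.loc[df.taxon == "outcrosser", "flower_color"] == "pink").all()
        assert (df.loc[df.taxon == "selfer", "flower_color"] == "white").any()


@pytest.fixture(scope="module")
def small_sim():
    cfg = cz.SimConfig(n_sites=500, n_outcrosser=40, n_selfer=30,
                       generations_since_pulse=4, seed=13)
    panels = simulate_panels(cfg)
    _, truth = cz.simulate_zone(cfg, panels)
    reads = cz.simulate_reads(truth, panels, cfg)
    return cfg, panels, truth, reads


class TestReads:
    def test_zero_depth_recorded_not_dropped(self, small_sim):
        _, _, _, reads = small_sim
        zero = reads.depth == 0
        assert zero.any()
        assert (reads.ref[zero] == 0).all() and (reads.alt[zero] == 0).all()

    def test_error_free_homozygote_yields_pure_reads(self):
        # truly fixed alt in the selfer panel, error-free reads, HH truth:
        # every read carries the alt allele
        import pandas as pd
        cfg = cz.SimConfig(n_sites=200, n_outcrosser=1, n_selfer=0,
                           error_rate=0.0, depth_mean=5.0, seed=15)
        panels = simulate_panels(cfg)
        df = panels.df.copy()
        df["ac_out"] = 0.0
        df["ac_self"] = df["an_self"]
        panels = cz.SnpPanelTable(df)
        truth = cz.SimTruth(
            ancestry_hap=np.ones((1, 2, 200), np.int8),  # all selfer-derived
            taxon=np.array([0]),  # labelled outcrosser -> HH relative to label
            true_alpha=np.array([1.0]),
            pedigree_class=["old-admixed"],
            chloroplast_origin=np.array([1]),
        )
        reads = cz.simulate_reads(truth, panels, cfg)
        assert (reads.ref == 0).all()
        assert reads.alt.sum() == reads.depth.sum() > 0

    def test_het_site_alt_fraction_is_binomial_half(self):
        # many draws at a heterozygous genotype: alt fraction ~ Binomial(n, 0.5)
        cfg = cz.SimConfig(n_sites=100, n_outcrosser=50, n_selfer=0,
                           pedigree_class="F1", depth_mean=10.0,
                           panel_divergence=0.5, fixed_diff_fraction=1.0,
                           error_rate=0.01, seed=17)
        panels = simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        reads = cz.simulate_reads(truth, panels, cfg)
        n_alt = int(reads.alt.sum())
        n_tot = int(reads.depth.sum())
        ci = binomtest(n_alt, n_tot, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_mean_depth_within_two_percent(self, small_sim):
        cfg, _, _, reads = small_sim
        assert reads.depth.size >= 1e4
        assert abs(reads.depth.mean() - cfg.depth_mean) / cfg.depth_mean < 0.02

    def test_mismatched_site_index_raises(self, small_sim):
        cfg, panels, truth, _ = small_sim
        short = cz.SnpPanelTable(panels.df.iloc[:-1].copy())
        with pytest.raises(ValueError):
            cz.simulate_reads(truth, short, cfg)


def test_same_seed_reproduces_identical_output():
    cfg = cz.SimConfig(n_sites=120, n_outcrosser=8, n_selfer=6,
                       generations_since_pulse=3, seed=23)
    outs = []
    for _ in range(2):
        panels = simulate_panels(cfg)
        records, truth = cz.simulate_zone(cfg, panels)
        reads = cz.simulate_reads(truth, panels, cfg)
        outs.append((panels.df, truth.ancestry_hap, reads.ref, reads.alt,
                     [r.__dict__ for r in records]))
    assert outs[0][0].equals(outs[1][0])
    for a, b in zip(outs[0][1:4], outs[1][1:4]):
        assert np.array_equal(a, b)
    assert outs[0][4] == outs[1][4]
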