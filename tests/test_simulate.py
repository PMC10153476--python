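"""Generator distributional checks against closed-form expectations."""

import dataclasses

import numpy as np
import pytest

import admixscan as ax


def small_config(**kwargs):
    base = dict(n_chromosomes=1, n_snps_per_chrom=500, n_mesolithic=10,
                n_neolithic=10, n_admixed=25, seed=42)
    base.update(kwargs)
    return ax.SimulationConfig(**base)


class TestSourceFrequencies:
    def test_no_drift_limit_recovers_ancestral(self):
        cfg = small_config(f_mes=1e-9, f_neo=1e-9, n_snps_per_chrom=2000)
        src = ax.simulate_source_frequencies(cfg)
        assert np.max(np.abs(src.p_mes - src.p_ancestral)) < 1e-3
        assert np.max(np.abs(src.p_neo - src.p_ancestral)) < 1e-3

    def test_mean_matches_ancestral_mean(self):
        cfg = small_config(n_snps_per_chrom=50_000, f_mes=0.1, f_neo=0.1)
        src = ax.simulate_source_frequencies(cfg)
        # E[p_src] = p0; Var(p_src) = F p0 (1-p0) <= F/4
        se = np.sqrt((src.p_ancestral.var() + 0.1 / 4) / 50_000)
        assert abs(src.p_mes.mean() - src.p_ancestral.mean()) < 3 * se

    def test_drift_variance_formula(self):
        cfg = small_config(n_snps_per_chrom=50_000, f_mes=0.1,
                           ancestral_freq_range=(0.5, 0.5))
        src = ax.simulate_source_frequencies(cfg)
        expected = 0.1 * 0.5 * 0.5
        assert src.p_mes.var() == pytest.approx(expected, rel=0.10)

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="f_mes"):
            small_config(f_mes=1.5)


class TestTractProcess:
    def test_mean_ancestry_near_alpha(self):
        cfg = small_config(n_admixed=100, n_snps_per_chrom=1000,
                           chrom_length_bp=50_000_000,
                           chrom_length_morgans=0.5)
        res = ax.simulate_cohort(cfg)
        # conservative: per-haplotype genome fractions are independent
        se = np.sqrt(0.3 * 0.7 / 200)
        assert abs(res.truth.true_mesolithic_fraction.mean() - 0.3) < 3 * se

    def test_observed_switch_rate(self):
        # expected observed switches over 1 morgan: 2 t alpha (1-alpha) = 14.7
        cfg = small_config(n_admixed=250, n_snps_per_chrom=2000,
                           chrom_length_morgans=1.0)
        res = ax.simulate_cohort(cfg)
        st = res.truth.haplotype_states
        switches = (st[1:] != st[:-1]).sum(axis=0).mean()
        assert switches == pytest.approx(2 * 35 * 0.3 * 0.7, rel=0.05)

    def test_null_shift_leaves_local_ancestry_at_alpha(self):
        locus = ax.SelectedLocus("1", 25_000_000, 0.0)
        cfg = small_config(n_admixed=300, n_snps_per_chrom=1000,
                           chrom_length_bp=50_000_000,
                           chrom_length_morgans=0.5, selected_loci=(locus,))
        res = ax.simulate_cohort(cfg)
        snps = res.truth.snps
        focal = int(np.argmin(np.abs(snps.position_bp - 25_000_000)))
        frac = res.truth.true_mesolithic_fraction[focal]
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 600)

    def test_positive_shift_raises_local_ancestry(self):
        locus = ax.SelectedLocus("1", 25_000_000, 0.2)
        cfg = small_config(n_admixed=300, n_snps_per_chrom=1000,
                           chrom_length_bp=50_000_000,
                           chrom_length_morgans=0.5, selected_loci=(locus,))
        res = ax.simulate_cohort(cfg)
        focal = int(np.argmin(np.abs(res.truth.snps.position_bp - 25_000_000)))
        frac = res.truth.true_mesolithic_fraction[focal]
        assert abs(frac - 0.5) < 3 * np.sqrt(0.5 * 0.5 / 600)

    def test_locus_outside_snps_rejected(self):
        locus = ax.SelectedLocus("7", 1_000, 0.1)
        cfg = small_config(selected_loci=(locus,))
        with pytest.raises(ValueError, match="outside simulated SNPs"):
            ax.simulate_cohort(cfg)

    def test_tracts_tile_chromosome_and_match_fractions(self):
        cfg = small_config(n_admixed=20)
        res = ax.simulate_cohort(cfg)
        tracts = res.truth.tracts
        for hap, grp in tracts.groupby("haplotype"):
            grp = grp.sort_values("start_bp")
            assert grp["start_bp"].iloc[0] == 1
            assert grp["end_bp"].iloc[-1] == cfg.chrom_length_bp
            assert np.all(grp["start_bp"].to_numpy()[1:]
                          == grp["end_bp"].to_numpy()[:-1] + 1)
        recomputed = res.truth.fraction_from_tracts()
        assert np.allclose(recomputed, res.truth.true_mesolithic_fraction)


class TestPseudohaploidization:
    def test_full_missingness(self):
        rng = np.random.default_rng(0)
        h = rng.random((50, 5)) < 0.5
        calls, _ = ax.pseudohaploidize(h, h, miss_rate=1.0, rng=rng)
        assert np.all(calls == 9)

    def test_no_missingness_haploid_truth_is_deterministic(self):
        rng = np.random.default_rng(0)
        h = rng.random((50, 5)) < 0.5
        calls, _ = ax.pseudohaploidize(h, h, miss_rate=0.0, rng=rng)
        assert np.array_equal(calls == 2, h)

    def test_single_allele_sampling_is_unbiased(self):
        rng = np.random.default_rng(5)
        p = 0.37
        h1 = rng.random((50_000, 4)) < p
        h2 = rng.random((50_000, 4)) < p
        calls, _ = ax.pseudohaploidize(h1, h2, miss_rate=0.2, rng=rng)
        obs = calls != 9
        freq = (calls == 2).sum() / obs.sum()
        se = np.sqrt(p * (1 - p) / obs.sum())
        assert abs(freq - p) < 3 * se

    def test_read_count_mode_consistency(self):
        rng = np.random.default_rng(6)
        h1 = rng.random((2_000, 10)) < 0.4
        h2 = rng.random((2_000, 10)) < 0.4
        calls, counts = ax.pseudohaploidize(h1, h2, miss_rate=0.0, rng=rng,
                                            mode="read_counts", mean_depth=2.0)
        ref_reads, alt_reads = counts
        assert np.all((calls == 9) == (ref_reads + alt_reads == 0))
        assert np.all(alt_reads[calls == 2] >= 1)


class TestReproducibility:
    def test_same_seed_is_byte_identical(self):
        cfg = small_config()
        a = ax.simulate_cohort(cfg)
        b = ax.simulate_cohort(dataclasses.replace(cfg))
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert np.array_equal(a.truth.haplotype_states,
                              b.truth.haplotype_states)
        assert np.array_equal(a.source.p_mes, b.source.p_mes)

    def test_different_seed_differs(self):
        a = ax.simulate_cohort(small_config(seed=1))
        b = ax.simulate_cohort(small_config(seed=2))
        assert not np.array_equal(a.genotypes.calls, b.genotypes.calls)


class TestTraitAssociations:
    def test_zero_hits_empty_table(self):
        src = ax.simulate_source_frequencies(small_config())
        table = ax.simulate_trait_associations(
            src, 0, np.random.default_rng(0))
        assert len(table) == 0

    def test_null_trait_uncorrelated_with_true_lad(self):
        # over replicates, w = beta*(p_neo - p_mes) is uncorrelated with the
        # realized true local-ancestry deviation at the hit SNPs
        rs = []
        for seed in range(50):
            cfg = small_config(seed=seed, n_admixed=60, n_chromosomes=2,
                               chrom_length_bp=50_000_000,
                               chrom_length_morgans=0.5)
            res = ax.simulate_cohort(cfg)
            src = res.source
            rng = np.random.default_rng(1000 + seed)
            table = ax.simulate_trait_associations(src, 12, rng,
                                                   min_gap_bp=3_000_000)
            idx = {s: i for i, s in enumerate(src.snps.snp_id)}
            hit_idx = np.array([idx[s] for s in table["snp"]])
            w = table["beta"].to_numpy() * (src.p_neo[hit_idx]
                                            - src.p_mes[hit_idx])
            lad = res.truth.true_mesolithic_fraction[hit_idx] - 0.3
            rs.append(np.corrcoef(w, lad)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_sub_threshold_pvalues_all_pruned_away(self):
        src = ax.simulate_source_frequencies(small_config())
        rng = np.random.default_rng(2)
        table = ax.simulate_trait_associations(src, 10, rng,
                                               log10p_range=(-4.0, -4.0))
        assert len(ax.prune_associations(table, p_threshold=1e-8)) == 0

    def test_off_panel_fraction(self):
        src = ax.simulate_source_frequencies(small_config())
        rng = np.random.default_rng(3)
        table = ax.simulate_trait_associations(src, 20, rng,
                                               frac_on_panel=0.0,
                                               min_gap_bp=1_000_000)
        on_panel = set(map(int, src.snps.position_bp))
        assert not any(int(p) in on_panel for p in table["position_bp"])
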