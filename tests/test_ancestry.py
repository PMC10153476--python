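"""Local-ancestry HMM: construction limits, decoding oracles, LAD track."""

import numpy as np
import pandas as pd
import pytest

import admixscan as ax
from admixscan.ancestry import _loglik_backward, enumerate_posteriors
from admixscan.nullfit import NullSample

from conftest import make_snps


def uniform_hmm(n=20, alpha=0.3, p_mes=None, p_neo=None, mode="diploid",
                spacing_morgans=0.01):
    snps = make_snps(np.arange(1, n + 1) * 100_000,
                     gpos=np.arange(n) * spacing_morgans)
    if p_mes is None:
        p_mes = np.full(n, 0.8)
    if p_neo is None:
        p_neo = np.full(n, 0.2)
    return ax.build_hmm(alpha=alpha, snps=snps, panel_freqs=(p_mes, p_neo),
                        mode=mode)


def random_hmm(rng, n, mode="diploid"):
    snps = make_snps(np.arange(1, n + 1) * 50_000,
                     gpos=np.sort(rng.uniform(0, 0.3, n)))
    return ax.build_hmm(alpha=rng.uniform(0.1, 0.9),
                        t_generations=rng.uniform(1, 80), snps=snps,
                        panel_freqs=(rng.uniform(0.05, 0.95, n),
                                     rng.uniform(0.05, 0.95, n)),
                        mode=mode)


class TestHmmConstruction:
    def test_transition_rows_are_stochastic(self):
        rng = np.random.default_rng(1)
        hmm = random_hmm(rng, 50)
        assert np.abs(hmm.trans.sum(axis=2) - 1.0).max() < 1e-12
        assert hmm.prior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_distance_gives_identity(self):
        snps = make_snps([100, 101, 200], gpos=[0.0, 0.0, 0.01])
        hmm = ax.build_hmm(alpha=0.3, snps=snps,
                           panel_freqs=(np.full(3, 0.5), np.full(3, 0.4)))
        assert np.allclose(hmm.trans[0], np.eye(3))

    def test_large_distance_reaches_stationary(self):
        snps = make_snps([100, 200], gpos=[0.0, 50.0])
        hmm = ax.build_hmm(alpha=0.3, snps=snps,
                           panel_freqs=(np.full(2, 0.6), np.full(2, 0.4)))
        stationary = np.array([0.49, 0.42, 0.09])   # k = 0, 1, 2 Mes copies
        assert np.allclose(hmm.trans[0], np.tile(stationary, (3, 1)),
                           atol=1e-12)

    def test_chromosome_boundary_restarts_the_chain(self):
        chroms = np.array(["1", "2"], dtype=object)
        snps = make_snps([100, 100], chromosome=chroms, gpos=[0.001, 0.001])
        hmm = ax.build_hmm(alpha=0.3, snps=snps,
                           panel_freqs=(np.full(2, 0.6), np.full(2, 0.4)))
        assert np.allclose(hmm.trans[0], np.tile(hmm.prior, (3, 1)))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            uniform_hmm(alpha=1.2)

    def test_degenerate_genetic_map_rejected(self):
        snps = make_snps([1, 2, 3], gpos=[0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            ax.build_hmm(snps=snps, panel_freqs=(np.full(3, .5), np.full(3, .4)))


class TestPosteriorDecoding:
    def test_single_site_bayes_by_hand(self):
        # prior (0.49, 0.42, 0.09), alt observed, p_mes=1, p_neo=0:
        # weights (0, 0.21, 0.09) -> dosage 0.39/0.30 = 1.3
        snps = make_snps([100], gpos=[0.001])
        hmm = ax.build_hmm(alpha=0.3, snps=snps,
                           panel_freqs=(np.array([1.0]), np.array([0.0])))
        track = ax.posterior_dosage(hmm, np.array([[2]]))
        assert track.dosage[0, 0] == pytest.approx(1.3, abs=1e-12)

    def test_uninformative_panels_return_prior_dosage(self):
        n = 30
        hmm = uniform_hmm(n, p_mes=np.full(n, 0.5), p_neo=np.full(n, 0.5))
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 2, 9], size=(n, 4)).astype(np.int8)
        track = ax.posterior_dosage(hmm, calls)
        assert np.allclose(track.dosage, 0.6, atol=1e-12)

    def test_all_missing_individual_decodes_to_prior(self):
        hmm = uniform_hmm(25)
        track = ax.posterior_dosage(hmm, np.full((25, 1), 9, dtype=np.int8))
        assert np.allclose(track.dosage, 2 * 0.3, atol=1e-12)

    @pytest.mark.parametrize("mode,n_sites", [("diploid", 6), ("haploid", 5)])
    def test_forward_backward_matches_path_enumeration(self, mode, n_sites):
        rng = np.random.default_rng(42 if mode == "diploid" else 43)
        for _ in range(25):
            hmm = random_hmm(rng, n_sites, mode=mode)
            calls = rng.choice([0, 2, 9], size=n_sites)
            track = ax.posterior_dosage(hmm, calls[:, None],
                                        return_posteriors=True)
            exact = enumerate_posteriors(hmm, calls)
            assert np.abs(track.posteriors[:, 0, :] - exact).max() < 1e-10

    def test_forward_and_backward_logliks_agree(self):
        rng = np.random.default_rng(3)
        hmm = random_hmm(rng, 200)
        calls = rng.choice([0, 2, 9], size=(200, 8)).astype(np.int8)
        track = ax.posterior_dosage(hmm, calls)
        assert np.abs(track.loglik
                      - _loglik_backward(hmm, calls)).max() < 1e-8

    def test_posteriors_sum_to_one_everywhere(self):
        rng = np.random.default_rng(4)
        hmm = random_hmm(rng, 300)
        calls = rng.choice([0, 2, 9], size=(300, 5)).astype(np.int8)
        track = ax.posterior_dosage(hmm, calls, return_posteriors=True)
        assert np.abs(track.posteriors.sum(axis=2) - 1.0).max() < 1e-10

    def test_read_count_emissions_match_pseudohaploid_single_read(self):
        n = 40
        hmm = uniform_hmm(n)
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 2], size=(n, 3)).astype(np.int8)
        alt = (calls == 2).astype(np.int64)
        ref = 1 - alt
        a = ax.posterior_dosage(hmm, calls)
        b = ax.posterior_dosage(hmm, ref_reads=ref, alt_reads=alt)
        assert np.allclose(a.dosage, b.dosage, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        hmm = uniform_hmm(10)
        with pytest.raises(ValueError, match="sites"):
            ax.posterior_dosage(hmm, np.zeros((9, 2), dtype=np.int8))


class TestCohortLad:
    def test_constant_cohort_has_zero_lad_and_z(self):
        n = 120
        hmm = uniform_hmm(n, p_mes=np.full(n, 0.5), p_neo=np.full(n, 0.5))
        calls = np.zeros((n, 6), dtype=np.int8)
        track = ax.posterior_dosage(hmm, calls)
        lad = ax.cohort_lad(track, hmm.snps, window_snps=51,
                            min_gap_bp=1_000_000)
        assert np.allclose(lad.windows["lad"], 0.0)
        assert np.allclose(lad.windows["z"], 0.0)

    def test_cohort_mean_is_average_of_individuals(self):
        track = ax.PosteriorTrack(
            dosage=np.array([[0.4, 0.8]] * 60), loglik=np.zeros(2), ploidy=2)
        snps = make_snps(np.arange(1, 61) * 200_000,
                         gpos=np.arange(60) * 1e-3)
        lad = ax.cohort_lad(track, snps, window_snps=5, min_gap_bp=1_000_000)
        assert np.allclose(lad.windows["mean_fraction"], 0.3)

    def test_empty_cohort_rejected(self):
        track = ax.PosteriorTrack(dosage=np.zeros((60, 0)),
                                  loglik=np.zeros(0), ploidy=2)
        snps = make_snps(np.arange(1, 61) * 200_000)
        with pytest.raises(ValueError, match="empty cohort"):
            ax.cohort_lad(track, snps, window_snps=5)


def toy_lad_track(centers_mb, lads, null_values, chromosome="1"):
    windows = pd.DataFrame({
        "chromosome": [chromosome] * len(centers_mb),
        "center_bp": (np.asarray(centers_mb) * 1e6).astype(np.int64),
        "mean_fraction": 0.3 + np.asarray(lads),
        "lad": np.asarray(lads, float),
        "z": np.zeros(len(centers_mb)),
        "n_snps": 51,
    })
    null = NullSample(pd.DataFrame({
        "chromosome": [chromosome] * len(null_values),
        "center_bp": (np.arange(len(null_values)) * 5e6 + 1e6).astype(np.int64),
        "value": 0.3 + np.asarray(null_values),
    }), 5_000_000)
    return ax.LADTrack(windows, null, n_individuals=10)


class TestRegionAverage:
    def test_mean_over_covered_windows(self, neutral_lad):
        lad = neutral_lad
        sub = lad.windows[(lad.windows["chromosome"] == "1")].iloc[100:103]
        start, end = int(sub["center_bp"].min()), int(sub["center_bp"].max())
        mean, z = ax.region_average(lad, "1", start, end)
        assert mean == pytest.approx(sub["lad"].mean())
        assert np.isfinite(z)

    def test_two_window_hand_mean(self):
        lad = toy_lad_track([1, 2, 10, 20, 30, 40],
                            [0.1, 0.3, 0.0, 0.02, -0.02, 0.01],
                            np.linspace(-0.03, 0.03, 8))
        mean, _ = ax.region_average(lad, "1", 500_000, 2_500_000)
        assert mean == pytest.approx(0.2)

    def test_empty_overlap_rejected(self, neutral_lad):
        with pytest.raises(ValueError, match="no window centers"):
            ax.region_average(neutral_lad, "1", 1, 2)

    def test_neutral_regions_are_not_outliers(self, neutral_lad):
        # region means under neutrality should rarely exceed |Z| = 2
        zs = []
        for chrom in ("2", "3", "4", "5", "6"):
            for start in (20_000_000, 60_000_000):
                _, z = ax.region_average(neutral_lad, chrom, start,
                                         start + 5_000_000)
                zs.append(abs(z))
        assert np.mean(np.array(zs) < 2.0) >= 0.8


class TestReferenceProbe:
    def test_uninformative_panels_give_prior(self):
        n = 40
        hmm = uniform_hmm(n, p_mes=np.full(n, 0.5), p_neo=np.full(n, 0.5),
                          mode="haploid")
        probe = ax.reference_bias_probe(hmm, np.zeros(n, dtype=np.int8))
        assert np.allclose(probe.track.dosage, 0.3, atol=1e-12)
        assert probe.fraction_mesolithic_confident == 0.0

    def test_requires_haploid_mode(self):
        hmm = uniform_hmm(10, mode="diploid")
        with pytest.raises(ValueError, match="haploid"):
            ax.reference_bias_probe(hmm, np.zeros(10, dtype=np.int8))

    def test_known_segment_recovery(self):
        # synthetic "reference": first half Mesolithic alleles, second half
        # Neolithic, with near-fixed panel differences
        n = 400
        rng = np.random.default_rng(9)
        p_mes = np.full(n, 0.95)
        p_neo = np.full(n, 0.05)
        hmm = uniform_hmm(n, p_mes=p_mes, p_neo=p_neo, mode="haploid",
                          spacing_morgans=0.001)
        alleles = np.where(np.arange(n) < n // 2,
                           rng.random(n) < p_mes,
                           rng.random(n) < p_neo)
        probe = ax.reference_bias_probe(
            hmm, np.where(alleles, 2, 0).astype(np.int8))
        p_mes_post = probe.track.posteriors[:, 0, 1]
        correct = np.where(np.arange(n) < n // 2, p_mes_post > 0.9,
                           p_mes_post < 0.1)
        assert correct.mean() >= 0.95
        assert 0.3 < probe.fraction_mesolithic_confident < 0.7
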