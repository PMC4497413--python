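"""Correlation distributions, the association test, lags, enrichment."""
import itertools

import numpy as np
import pytest
from scipy import stats as sps

import featurespeed as fs
from featurespeed.profiles import STATISTIC_WINDOW, WindowSpec
from featurespeed.stats import CorrelationDistribution


class TestPearson:
    def test_self_correlation(self):
        assert fs.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversal(self):
        assert fs.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # covariance 1.0, sds sqrt(1.25) each -> r = 0.8
        assert fs.pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(fs.DegeneratePairError):
            fs.pearson([1, 1, 1], [1, 2, 3])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            fs.pearson([1, np.nan, 3], [1, 2, 3])

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert fs.pearson(x, y) == pytest.approx(sps.pearsonr(x, y).statistic,
                                                     abs=1e-12)


def _matrix_from(data):
    data = np.asarray(data, dtype=float)
    return fs.ProfileMatrix(data, [("p", i + 1) for i in range(len(data))],
                            WindowSpec(0, data.shape[1] - 1))


class TestObservedDistribution:
    def test_identical_windows_all_correlate_perfectly(self):
        m = _matrix_from([[1, 2, 3]] * 3)
        dist = fs.observed_distribution(m)
        np.testing.assert_allclose(dist.values, [1, 1, 1])

    def test_pair_combinatorics(self):
        rng = np.random.default_rng(0)
        m = _matrix_from(rng.normal(size=(5, 7)))
        assert fs.observed_distribution(m).n_pairs == 10

    def test_incomplete_windows_excluded(self):
        data = np.random.default_rng(1).normal(size=(4, 6))
        data[0, 2] = np.nan
        dist = fs.observed_distribution(_matrix_from(data))
        assert dist.n_windows == 3 and dist.n_pairs == 3

    def test_matches_exhaustive_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(10, 12))
        dist = fs.observed_distribution(_matrix_from(data))
        expected = sorted(
            sps.pearsonr(data[i], data[j]).statistic
            for i, j in itertools.combinations(range(10), 2)
        )
        np.testing.assert_allclose(sorted(dist.values), expected, atol=1e-12)

    def test_constant_windows_dropped_and_counted(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 5))
        data[1] = 3.14  # constant row: every pair through it is degenerate
        dist = fs.observed_distribution(_matrix_from(data))
        assert dist.n_degenerate_dropped == 3
        assert dist.n_pairs == 3

    def test_subsampling_is_seeded_and_capped(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(30, 6))
        a = fs.observed_distribution(_matrix_from(data), max_windows=10, seed=5)
        b = fs.observed_distribution(_matrix_from(data), max_windows=10, seed=5)
        c = fs.observed_distribution(_matrix_from(data), max_windows=10, seed=6)
        assert a.n_windows == 10 and a.n_pairs == 45
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_fewer_than_two_complete_windows_raise(self):
        data = np.full((3, 5), np.nan)
        data[0] = 1.0
        with pytest.raises(fs.InsufficientDataError):
            fs.observed_distribution(_matrix_from(data))


class TestBackgroundDistribution:
    def test_pair_combinatorics(self, small_dataset):
        dist = fs.background_distribution(small_dataset, "occupancy", 31,
                                          n_vectors=40, seed=0)
        assert dist.n_windows == 40
        assert dist.n_pairs + dist.n_degenerate_dropped == 40 * 39 // 2

    def test_single_eligible_segment_gives_perfect_correlations(self,
                                                                record_factory):
        cds = "ATGGCTTAA"
        rec = record_factory(cds, {"x": [1.0, 4.0, 2.0, 6.0, 3.0, 5.0,
                                         2.0, 1.0, 4.0]})
        ds = fs.Dataset(transcripts={"t1": rec})
        # window as long as the transcript: every draw is the same
        # (non-constant) segment, so every pair correlates perfectly
        dist = fs.background_distribution(ds, "x", 9, n_vectors=5, seed=0)
        assert dist.n_pairs == 10
        np.testing.assert_allclose(dist.values, np.ones(10))
        with pytest.raises(fs.InsufficientDataError):
            fs.background_distribution(ds, "x", 10, n_vectors=5, seed=0)

    def test_segments_avoid_missing_values(self, small_dataset):
        tid = sorted(small_dataset.transcripts)[0]
        small_dataset.transcripts[tid].tracks["occupancy"][100] = np.nan
        starts = fs.stats.eligible_starts(small_dataset, "occupancy", 21)
        assert all(not (off <= 100 <= off + 20) for t, off in starts if t == tid)

    def test_null_background_and_observed_agree(self):
        """With no planted signal the two distributions share their mean."""
        cfg = fs.SimConfig(n_genes=20, cds_length_range=(600, 600),
                           feature_specs=[fs.FeatureSpec("f", 40, (5, 15))],
                           seed=99)
        ds = fs.generate_dataset(cfg)
        m = fs.build_profile_matrix(ds, "f", "structure", STATISTIC_WINDOW)
        obs = fs.observed_distribution(m, seed=1)
        bg = fs.background_distribution(ds, "structure", 101,
                                        n_vectors=1000, seed=2)
        # Monte-Carlo agreement: both means are near 0 on a [-1, 1] scale
        assert abs(obs.mean() - bg.mean()) < 0.05


def _dist(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return CorrelationDistribution(values=values, n_windows=n,
                                   n_pairs=n, n_degenerate_dropped=0)


class TestAssociationTest:
    def test_identical_distributions_give_symmetric_null(self):
        d = _dist(np.random.default_rng(0).uniform(-1, 1, 50))
        res = fs.association_test(d, d)
        assert res.t_statistic == 0.0
        assert res.p_value == 0.5

    def test_strong_shift_matches_closed_form(self):
        rng = np.random.default_rng(8)
        obs = rng.normal(0.5, 0.1, 1000)
        bg = rng.normal(0.0, 0.1, 1000)
        res = fs.association_test(_dist(obs), _dist(bg))
        assert res.p_value < 1e-10
        # Welch t from the sample moments
        t_expected = (obs.mean() - bg.mean()) / np.sqrt(
            obs.var(ddof=1) / 1000 + bg.var(ddof=1) / 1000)
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-10)

    def test_one_sidedness(self):
        rng = np.random.default_rng(9)
        low = rng.normal(-0.3, 0.1, 200)
        high = rng.normal(0.0, 0.1, 200)
        assert fs.association_test(_dist(low), _dist(high)).p_value > 0.5

    def test_pooled_variance_option(self):
        rng = np.random.default_rng(10)
        obs, bg = rng.normal(0.2, 0.1, 50), rng.normal(0.0, 0.3, 500)
        welch = fs.association_test(_dist(obs), _dist(bg))
        student = fs.association_test(_dist(obs), _dist(bg), equal_var=True)
        assert welch.p_value != student.p_value

    def test_affine_track_rescaling_leaves_p_invariant(self):
        """Pearson is affine-invariant, so the whole test is too."""
        cfg = fs.SimConfig(n_genes=10, cds_length_range=(450, 450),
                           feature_specs=[fs.FeatureSpec("f", 20, (5, 15))],
                           seed=17)
        results = []
        for scale, shift in [(1.0, 0.0), (37.5, -12.0)]:
            ds = fs.generate_dataset(cfg)
            for r in ds.transcripts.values():
                r.tracks["occupancy"] = scale * r.tracks["occupancy"] + shift
            m = fs.build_profile_matrix(ds, "f", "occupancy", STATISTIC_WINDOW)
            obs = fs.observed_distribution(m, seed=3)
            bg = fs.background_distribution(ds, "occupancy", 101,
                                            n_vectors=200, seed=4)
            results.append(fs.association_test(obs, bg).p_value)
        assert results[0] == pytest.approx(results[1], abs=1e-9)

    def test_tiny_distributions_raise(self):
        with pytest.raises(fs.InsufficientDataError):
            fs.association_test(_dist([0.1]), _dist([0.0, 0.1]))


class TestCrossCorrelation:
    def test_identity_has_zero_lag(self):
        a = np.sin(np.linspace(0, 6, 80))
        res = fs.cross_correlation(a, a.copy(), max_lag=10)
        assert res.best_lag == 0
        assert res.r_at_best == pytest.approx(1.0)

    def test_planted_shift_of_seven(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=120)
        a = base[:100]
        b = np.roll(base, 7)[:100]  # b[i] = a[i - 7]
        res = fs.cross_correlation(a, b, max_lag=15)
        assert res.best_lag == 7
        assert res.r_at_best == pytest.approx(1.0)

    def test_exhaustive_lag_scan_recovers_every_shift(self):
        rng = np.random.default_rng(22)
        base = rng.normal(size=140)
        for k in range(-10, 11):
            a = base[20:120]
            b = np.roll(base, k)[20:120]
            res = fs.cross_correlation(a, b, max_lag=15)
            assert res.best_lag == k, f"shift {k} not recovered"

    def test_tie_breaks_toward_smaller_then_negative_lag(self):
        a = np.tile([1.0, 2.0], 30)  # period 2: r = 1 at every even lag
        res = fs.cross_correlation(a, a.copy(), max_lag=6)
        assert res.best_lag == 0
        b = np.roll(a, 1)  # equally good at odd lags -1 and +1
        res = fs.cross_correlation(a, b, max_lag=6)
        assert res.best_lag == -1

    def test_overlap_too_short_raises(self):
        with pytest.raises(fs.InsufficientDataError):
            fs.cross_correlation(np.arange(10.0), np.arange(10.0), max_lag=8)


class TestPositiveResidueEnrichment:
    def _dataset_with_protein(self, protein, features):
        from featurespeed.types import SENSE_CODONS

        aa_to_codon = {}
        from Bio.Seq import Seq
        for codon in SENSE_CODONS:
            aa_to_codon.setdefault(str(Seq(codon).translate()), codon)
        cds = "".join(aa_to_codon[c] for c in protein) + "TAA"
        rec = fs.TranscriptRecord("t1", cds, protein, {})
        return fs.Dataset(transcripts={"t1": rec}, features=features)

    def test_poly_basic_feature_is_enriched(self):
        protein = "M" + "A" * 60 + "KRKRKRKRKR" + "A" * 60
        ds = self._dataset_with_protein(
            protein, [fs.FeatureInstance("t1", "f", 62, 71)])
        res = fs.positive_residue_enrichment(ds, "f", window_res=(5, 9))
        assert res.ratio > 1
        assert res.p_value < 0.05

    def test_uniform_windows_are_null(self):
        rng = np.random.default_rng(30)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        protein = "M" + "".join(rng.choice(list(aas), size=400))
        features = [fs.FeatureInstance("t1", "f", int(s), int(s) + 2)
                    for s in rng.integers(40, 360, size=12)]
        ds = self._dataset_with_protein(protein, sorted(
            set(features), key=lambda f: f.start_res))
        res = fs.positive_residue_enrichment(ds, "f")
        assert 0.5 < res.ratio < 1.5
        assert res.p_value > 0.01

    def test_no_positive_residues_is_an_error(self):
        ds = self._dataset_with_protein(
            "M" + "A" * 50, [fs.FeatureInstance("t1", "f", 10, 12)])
        with pytest.raises(ValueError):
            fs.positive_residue_enrichment(ds, "f")
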