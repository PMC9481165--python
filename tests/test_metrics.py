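import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from corticonet.errors import EstimationError, InvalidInputError
from corticonet.metrics import (
    best_noise_ceiling,
    circular_selectivity,
    js_distance,
    lifetime_sparseness,
    mds_layout_and_diversity,
    noise_ceiling,
    similarity_matrix,
    split_half_reliability,
    ssm,
)
from corticonet.synthdata import ResponseGenSpec, gen_responses


class TestSimilarityMatrix:
    def test_identical_rows(self):
        R = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 5.0, 1.0]])
        S = similarity_matrix(R)
        assert S.matrix[0, 1] == pytest.approx(1.0)

    def test_reversed_rows(self):
        S = similarity_matrix(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        assert S.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_pairwise_pearson(self, rng):
        R = rng.normal(size=(4, 3))
        S = similarity_matrix(R).matrix
        for i in range(4):
            for j in range(4):
                expected = stats.pearsonr(R[i], R[j]).statistic
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_flagged(self):
        R = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        S = similarity_matrix(R)
        assert S.excluded == (0,)
        assert np.isnan(S.matrix[0, 1])
        assert np.isfinite(S.matrix[1, 2])


class TestSSM:
    def test_self_similarity(self, rng):
        A = similarity_matrix(rng.normal(size=(6, 5)))
        assert ssm(A, A) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        A = similarity_matrix(rng.normal(size=(6, 5))).matrix
        B = np.tanh(3.0 * A)  # strictly monotone elementwise
        np.fill_diagonal(B, 1.0)
        assert ssm(A, B) == pytest.approx(1.0)

    def test_matches_exhaustive_rank_oracle(self, rng):
        A = similarity_matrix(rng.normal(size=(5, 4))).matrix
        B = similarity_matrix(rng.normal(size=(5, 4))).matrix
        iu = np.triu_indices(5, k=1)
        ra = stats.rankdata(A[iu])
        rb = stats.rankdata(B[iu])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert ssm(A, B) == pytest.approx(oracle, abs=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            ssm(np.eye(3), np.eye(4))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounded(self, seed):
        rng = np.random.default_rng(seed)
        A = similarity_matrix(rng.normal(size=(5, 6))).matrix
        B = similarity_matrix(rng.normal(size=(5, 6))).matrix
        assert -1.0 <= ssm(A, B) <= 1.0


class TestSplitHalfReliability:
    def test_noiseless_is_one(self, rng):
        signal = rng.normal(size=(20, 7))
        T = np.repeat(signal[:, :, None], 10, axis=2)
        rel = split_half_reliability(T, seed=0)
        assert np.allclose(rel, 1.0)

    def test_pure_noise_centers_at_zero(self):
        T = gen_responses(
            ResponseGenSpec(n_images=118, n_neurons=200, n_trials=50,
                            signal_var=0.0, noise_var=1.0, seed=5)
        )
        rel = split_half_reliability(T, seed=0)
        se = rel.std() / np.sqrt(len(rel))
        assert abs(np.nanmean(rel)) < 3 * se + 1e-3

    def test_closed_form_attenuation_over_seeds(self):
        # expected reliability sigma_s^2 / (sigma_s^2 + sigma_n^2 / 25)
        for sv, nv in [(1.0, 25.0), (1.0, 8.0)]:
            expected = sv / (sv + nv / 25)
            means = []
            for seed in range(20):
                T = gen_responses(
                    ResponseGenSpec(n_images=118, n_neurons=30, n_trials=50,
                                    signal_var=sv, noise_var=nv, seed=seed)
                )
                means.append(np.nanmean(split_half_reliability(T, seed=seed)))
            assert np.mean(means) == pytest.approx(expected, abs=0.05)

    def test_constant_neuron_recorded_missing(self, rng):
        T = rng.normal(size=(10, 3, 6))
        T[:, 1, :] = 4.2
        rel = split_half_reliability(T, seed=0)
        assert np.isnan(rel[1])
        assert np.isfinite(rel[[0, 2]]).all()

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            split_half_reliability(rng.normal(size=(5, 3, 1)))


class TestNoiseCeiling:
    def test_noiseless_gives_one_at_any_threshold(self, rng):
        signal = rng.normal(size=(15, 8))
        T = np.repeat(signal[:, :, None], 10, axis=2)
        for th in (-1.0, 0.0, 0.9):
            mean, sd = noise_ceiling(T, threshold=th, seed=0)
            assert mean == pytest.approx(1.0)
            assert sd == pytest.approx(0.0, abs=1e-12)

    def test_threshold_above_max_reliability_fails(self, rng):
        T = rng.normal(size=(10, 5, 8))
        with pytest.raises(EstimationError):
            noise_ceiling(T, threshold=1.5, seed=0)

    def test_mixed_population_peaks_at_positive_threshold(self):
        # half the neurons reliable, half pure noise: thresholding helps
        rng = np.random.default_rng(7)
        n, t = 60, 50
        good = rng.normal(size=(n, 20))[:, :, None] + 0.4 * rng.normal(
            size=(n, 20, t)
        )
        bad = 2.0 * rng.normal(size=(n, 40, t))
        T = np.concatenate([good, bad], axis=1)
        lo, _ = noise_ceiling(T, threshold=-1.0, seed=0)
        hi, _ = noise_ceiling(T, threshold=0.5, seed=0)
        assert hi > lo
        th, ceiling = best_noise_ceiling(T, np.array([-1.0, 0.0, 0.5]), seed=0)
        assert th > 0.0
        assert ceiling == pytest.approx(hi, abs=1e-9)

    def test_homogeneous_population_flat_in_threshold(self):
        T = gen_responses(
            ResponseGenSpec(n_images=60, n_neurons=40, n_trials=50,
                            signal_var=1.0, noise_var=2.0, seed=3)
        )
        unthresh, sd = noise_ceiling(T, threshold=-1.0, seed=0)
        _, best = best_noise_ceiling(T, np.array([-1.0, 0.2, 0.4]), seed=0)
        assert abs(best - unthresh) <= max(2 * sd, 0.02)

    def test_ceiling_never_exceeds_one(self):
        for seed in range(5):
            T = gen_responses(
                ResponseGenSpec(n_images=20, n_neurons=15, n_trials=20,
                                signal_var=1.0, noise_var=0.5, seed=seed)
            )
            mean, _ = noise_ceiling(T, threshold=-1.0, seed=seed)
            assert mean <= 1.0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            best_noise_ceiling(rng.normal(size=(10, 5, 8)), np.array([]))


class TestLifetimeSparseness:
    def test_one_hot(self):
        r = np.zeros(10)
        r[3] = 1.0
        assert lifetime_sparseness(r) == pytest.approx(1.0)

    def test_uniform(self):
        assert lifetime_sparseness(np.full(8, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        got = lifetime_sparseness(np.array([2.0, 1.0, 1.0, 0.0]))
        assert got == pytest.approx((1 - (1 / 4) * (16 / 6)) / (3 / 4))
        assert got == pytest.approx(4.0 / 9.0)

    def test_all_zero_is_missing(self):
        assert np.isnan(lifetime_sparseness(np.zeros(5)))

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        r = np.array([0.5, 2.0, 0.0, 1.0])
        assert lifetime_sparseness(scale * r) == pytest.approx(
            lifetime_sparseness(r)
        )

    def test_single_condition_rejected(self):
        with pytest.raises(InvalidInputError):
            lifetime_sparseness(np.array([1.0]))


class TestCircularSelectivity:
    def test_single_direction(self):
        r = np.array([0.0, 3.0, 0.0])
        th = np.deg2rad([0, 45, 90])
        assert circular_selectivity(r, th) == pytest.approx(1.0)

    def test_uniform_four_directions_cancels(self):
        r = np.ones(4)
        th = np.deg2rad([0, 45, 90, 135])
        assert circular_selectivity(r, th) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        r = np.array([2.0, 1.0])
        th = np.deg2rad([0, 90])
        assert circular_selectivity(r, th) == pytest.approx(1.0 / 3.0)

    def test_zero_total_is_missing(self):
        assert np.isnan(circular_selectivity(np.zeros(3), np.zeros(3)))

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        r = np.array([1.0, 0.5, 2.0])
        th = np.deg2rad([0, 60, 120])
        assert circular_selectivity(scale * r, th) == pytest.approx(
            circular_selectivity(r, th)
        )


class TestJSDistance:
    def test_identical_samples(self, rng):
        x = rng.normal(size=500)
        assert js_distance(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_max_out(self):
        a = np.zeros(100)
        b = np.ones(100) * 10
        assert js_distance(a, b, bins=4) == pytest.approx(1.0)

    def test_hand_computed_three_bin_histograms(self):
        # p = (1/2, 1/2, 0), q = (0, 1/2, 1/2) on shared bins
        a = np.array([0.0, 1.0])
        b = np.array([1.0, 2.0])
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([0.0, 0.5, 0.5])
        m = (p + q) / 2
        kl = lambda u, v: sum(
            ui * np.log2(ui / vi) for ui, vi in zip(u, v) if ui > 0
        )
        expected = np.sqrt((kl(p, m) + kl(q, m)) / 2)
        got = js_distance(a, b, bins=3, range_=(0.0, 2.0000001))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            js_distance(np.array([]), np.array([1.0]))


class TestMDSDiversity:
    def test_identical_layers_give_zero(self):
        S = np.ones((5, 5))
        _, diversity = mds_layout_and_diversity(S, seed=0)
        assert diversity == pytest.approx(0.0, abs=1e-6)

    def test_collinear_configuration_gives_near_zero(self):
        # four layers on a perfect line in SSM space
        x = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(x[:, None] - x[None, :]) / 10.0
        S = 1.0 - D
        _, diversity = mds_layout_and_diversity(S, seed=0)
        coords, _ = mds_layout_and_diversity(S, seed=0)
        sv = np.linalg.svd(coords - coords.mean(0), compute_uv=False)
        assert sv[1] < 0.05 * sv[0]

    def test_distance_scaling_scales_diversity_quadratically(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        D /= D.max() * 2
        _, d1 = mds_layout_and_diversity(1.0 - D, seed=1)
        alpha = 0.5
        _, d2 = mds_layout_and_diversity(1.0 - alpha * D, seed=1)
        assert d2 / d1 == pytest.approx(alpha**2, rel=0.05)

    def test_too_few_layers_rejected(self):
        with pytest.raises(EstimationError):
            mds_layout_and_diversity(np.eye(2), seed=0)
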