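"""Analysis metrics and the spike-count readout."""

import numpy as np
import pytest

from convallis.core_sim import poisson_spike_trains
from convallis.metrics import (
    CountMatrix,
    cv_isi,
    evaluate_readout,
    f_statistic,
    pairwise_correlation,
    subthreshold_skewness,
    train_readout,
    tuning_index,
)


class TestSkewness:
    def test_gaussian_sample_near_zero(self, rng):
        v = rng.normal(-60, 3, 1_000_000)
        assert abs(subthreshold_skewness(v, [])) < 0.05

    def test_exponential_sample_near_two(self, rng):
        v = -75 + rng.exponential(3.0, 1_000_000)
        assert subthreshold_skewness(v, []) == pytest.approx(2.0, abs=0.05)

    def test_rest_dominated_mixture_positively_skewed(self, rng):
        n = 200_000
        v = np.where(rng.random(n) < 0.95,
                     rng.normal(-70, 1, n), rng.normal(-52, 1, n))
        assert subthreshold_skewness(v, []) > 1.0

    def test_spike_shape_excised(self):
        v = np.full(30_000, -70.0)
        v[10_000:10_020] = 20.0  # a spike shape at t=1000 ms
        v[:10_000] += np.sin(np.arange(10_000)) * 2
        v[10_100:] += np.sin(np.arange(19_900)) * 2
        s_with = subthreshold_skewness(v, [1000.0], dt=0.1)
        assert abs(s_with) < 0.1  # the +20 mV excursion is gone

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            subthreshold_skewness(np.full(1000, -70.0), [])


class TestTuning:
    def test_uniform_rates_zero(self):
        assert tuning_index(np.full(16, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_single_position_one(self):
        r = np.zeros(16)
        r[4] = 7.0
        assert tuning_index(r) == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        r = np.zeros(16)
        r[2] = r[10] = 5.0
        assert tuning_index(r) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tuning_index(np.zeros(8))


class TestFStatistic:
    def test_hand_computed_example(self):
        counts = np.array([1.0, 3.0, 3.0, 5.0])
        labels = np.array(["a", "a", "b", "b"])
        assert f_statistic(counts, labels) == pytest.approx(2.0)

    def test_equal_class_means_zero(self):
        counts = np.array([1.0, 3.0, 1.0, 3.0])
        labels = np.array([0, 0, 1, 1])
        assert f_statistic(counts, labels) == pytest.approx(0.0)

    def test_tuned_neuron_beats_permutation_null(self, rng):
        labels = np.repeat(np.arange(4), 10)
        counts = rng.poisson(3 + 4 * (labels == 2), size=40).astype(float)
        f_obs = f_statistic(counts, labels)
        null = []
        for _ in range(1000):
            null.append(f_statistic(counts, rng.permutation(labels)))
        assert f_obs > np.percentile(null, 95)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            f_statistic([1.0, 2.0], [0, 0])  # single class
        with pytest.raises(ValueError):
            f_statistic([1.0, 1.0, 2.0, 2.0], [0, 0, 1, 1])  # zero within-var


class TestCvIsi:
    def test_regular_train_zero(self):
        assert cv_isi(np.arange(0, 1000, 10.0)) == pytest.approx(0.0)

    def test_poisson_train_near_one(self):
        t = poisson_spike_trains(np.full((1, 2000), 5.0), 1000.0, seed=4).trains[0]
        assert len(t) > 5000
        assert cv_isi(t) == pytest.approx(1.0, abs=0.05)

    def test_two_isi_sample_convention(self):
        # ISIs [1, 3]: sample s.d. (n-1) over mean = sqrt(2)/2
        assert cv_isi([0.0, 1.0, 4.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            cv_isi([1.0, 2.0])


class TestPairwiseCorrelation:
    def test_independent_trains_near_zero(self):
        trains = [
            poisson_spike_trains(np.full((1, 100), 5.0), 1000.0, seed=s).trains[0]
            for s in range(40)
        ]
        c = pairwise_correlation(trains, duration=100_000.0, n_pairs=400, seed=0)
        assert abs(c) < 0.01

    def test_duplicated_train_fully_correlated(self):
        t = poisson_spike_trains(np.full((1, 50), 8.0), 1000.0, seed=1).trains[0]
        # only two neurons: every sampled pair is (0, 1)
        c = pairwise_correlation([t, t.copy()], duration=50_000.0, n_pairs=10,
                                 seed=0)
        assert c == pytest.approx(1.0)

    def test_common_input_thinning_increases_correlation(self, rng):
        mother = poisson_spike_trains(
            np.full((1, 200), 40.0), 1000.0, seed=2
        ).trains[0]

        def thinned(p, n=30):
            return [mother[rng.random(len(mother)) < p] for _ in range(n)]

        c_lo = pairwise_correlation(thinned(0.2), 200_000.0, n_pairs=200, seed=0)
        c_hi = pairwise_correlation(thinned(0.8), 200_000.0, n_pairs=200, seed=0)
        assert 0 < c_lo < c_hi


class TestReadout:
    def test_separable_toy_problem_zero_training_error(self, rng):
        n = 60
        labels = rng.integers(0, 2, n)
        counts = np.stack([10.0 * labels + rng.normal(0, 0.1, n),
                           5.0 - 3.0 * labels + rng.normal(0, 0.1, n)], axis=1)
        A = CountMatrix(np.abs(counts), labels)
        model = train_readout(A)
        assert evaluate_readout(model, A) == 0.0

    def test_shuffled_labels_near_chance(self, rng):
        n_class, n = 5, 400
        counts = rng.poisson(5.0, size=(n, 30)).astype(float)
        labels = rng.integers(0, n_class, n)
        A_train = CountMatrix(counts[:300], labels[:300])
        A_test = CountMatrix(counts[300:], rng.integers(0, n_class, 100))
        err = evaluate_readout(train_readout(A_train), A_test)
        assert err == pytest.approx(1 - 1 / n_class, abs=0.12)

    def test_ridge_alternative_close_to_margin_model(self, rng):
        # qualitative robustness of the readout to the exact linear learner
        from sklearn.linear_model import RidgeClassifier

        n_class, n_neuron = 4, 25
        labels = np.repeat(np.arange(n_class), 60)
        centers = rng.normal(5, 2, (n_class, n_neuron)).clip(0.5)
        counts = rng.poisson(centers[labels]).astype(float)
        A_train = CountMatrix(counts[::2], labels[::2])
        A_test = CountMatrix(counts[1::2], labels[1::2])
        err_svm = evaluate_readout(train_readout(A_train), A_test)
        ridge = RidgeClassifier(alpha=1.0).fit(A_train.counts, A_train.labels)
        err_ridge = float(np.mean(ridge.predict(A_test.counts) != A_test.labels))
        assert abs(err_svm - err_ridge) <= 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_readout(CountMatrix(np.ones((5, 3)), np.zeros(5)))
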