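"""Triplet labeling, permutation test, KL divergence, reconstructions,
triplet averages and the motor control analysis."""

import numpy as np
import pandas as pd
import pytest

from koopstream.datatypes import (LABEL_CODES, NEUTRAL, ONE_STREAM,
                                  TWO_STREAM, KoopstreamError,
                                  PerceptTimeline, TripletLabels)
from koopstream.stats import (compare_similarities, kl_divergence_percepts,
                              label_triplets, label_triplets_control,
                              median_ci_bootstrap, motor_control_analysis,
                              n_neutral_triplets, permutation_test_phi_star,
                              profile_similarity, reconstruction_r2,
                              triplet_average)

_ONE = LABEL_CODES[ONE_STREAM]
_TWO = LABEL_CODES[TWO_STREAM]
_NEU = LABEL_CODES[NEUTRAL]


def timeline(switches, first=ONE_STREAM, rt=0.65, duration=60.0):
    seq = [first]
    for _ in switches:
        seq.append(TWO_STREAM if seq[-1] == ONE_STREAM else ONE_STREAM)
    return PerceptTimeline(switch_times=np.asarray(switches, float),
                           percept_sequence=seq, reaction_time=rt,
                           block_duration=duration)


def simple_labels(codes, rt=0.65, td=0.6):
    return TripletLabels(labels=np.asarray(codes, int), triplet_duration=td,
                         n_neutral=n_neutral_triplets(rt, td),
                         reaction_time=rt)


class TestLabelTriplets:
    @pytest.mark.parametrize("rt, expected", [(0.65, 2), (3.22, 6),
                                              (0.36, 1), (1.24, 3)])
    def test_neutral_count_rule(self, rt, expected):
        assert n_neutral_triplets(rt) == expected

    def test_neutral_zone_precedes_each_press(self):
        tl = timeline([12.0], rt=0.65)
        labels = label_triplets(tl)
        press = tl.button_times[0]
        j = int(press // 0.6)
        assert np.all(labels.labels[j - 2:j] == _NEU)
        assert labels.labels[j - 3] == _ONE   # percept before the switch

    def test_no_presses_all_initial_percept(self):
        tl = timeline([], first=TWO_STREAM, duration=12.0)
        labels = label_triplets(tl)
        assert np.all(labels.labels == _TWO)
        assert labels.n_triplets == 20

    def test_labels_follow_percept_in_force_at_onset(self):
        tl = timeline([6.0, 18.0], duration=30.0)
        labels = label_triplets(tl)
        assert labels.labels[0] == _ONE
        assert labels.labels[15] == _TWO   # onset 9.0 s, after 1st switch
        assert labels.labels[-1] == _ONE


class TestControlLabelsAndHelpers:
    def test_control_neutral_spans_change_to_press(self):
        tl = timeline([12.0], rt=0.65, duration=30.0)
        # stimulus change at 11.35 s drives the switch; press at 12.65 s
        labels = label_triplets_control(tl, stimulus_changes=[11.35])
        lo = int(11.35 // 0.6)
        hi = int(tl.button_times[0] // 0.6)
        assert np.all(labels.labels[lo:hi + 1] == LABEL_CODES[NEUTRAL])
        assert labels.labels[lo - 1] != LABEL_CODES[NEUTRAL]

    def test_bootstrap_ci_covers_true_median(self, rng):
        values = rng.normal(5.0, 1.0, size=200)
        med, lo, hi = median_ci_bootstrap(values, n_boot=2000, seed=1)
        assert lo < med < hi
        assert lo < 5.0 < hi
        width = hi - lo
        assert 0.05 < width < 1.0  # sane scale for n=200

    def test_one_sided_rank_sum_direction(self, rng):
        high = rng.normal(0.99, 0.005, 30)
        low = rng.normal(0.90, 0.02, 30)
        _, p_correct = compare_similarities(high, low, "greater")
        _, p_wrong = compare_similarities(low, high, "greater")
        assert p_correct < 0.001
        assert p_wrong > 0.5


class TestPermutationTest:
    def _phi_and_labels(self, rng, n_triplets=100, effect=0.0):
        td, rate = 0.6, 200.0
        times = np.arange(int(n_triplets * td * rate)) / rate
        tl = timeline([12.0, 30.0, 45.3], rt=0.65,
                      duration=n_triplets * td)
        labels = label_triplets(tl)
        phi = rng.normal(size=len(times))
        phi += effect * (labels.sample_labels(times) == _TWO)
        return phi, times, labels

    def test_p_value_formula_extremes(self, rng):
        phi, times, labels = self._phi_and_labels(rng, effect=50.0)
        out = permutation_test_phi_star(phi, times, labels, n_perm=200,
                                        seed=0)
        assert out["m"] == 0
        assert out["p"] == pytest.approx(1 / 201)

    def test_reported_formula_cases(self):
        # p = (m+1)/(n+1): m=0 at n=10,000 gives p < 1e-4; m=52 gives the
        # printed 0.0053
        assert (0 + 1) / (10_000 + 1) < 1.0e-4
        assert (52 + 1) / (10_000 + 1) == pytest.approx(0.0053, abs=5e-5)

    def test_null_respects_switch_count_and_is_roughly_uniform(self):
        # label-independent phi_star: p-values should be uniform; check the
        # rejection fraction at alpha=0.05 stays inside the binomial band
        n_seeds, n_perm = 50, 199
        rejections = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            phi, times, labels = self._phi_and_labels(rng, effect=0.0)
            out = permutation_test_phi_star(phi, times, labels,
                                            n_perm=n_perm, seed=seed)
            rejections += out["p"] < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds <= 0.05 + band + 1e-9

    def test_single_percept_rejected(self, rng):
        labels = simple_labels([_ONE] * 50)
        times = np.arange(50 * 120) / 200.0
        with pytest.raises(KoopstreamError):
            permutation_test_phi_star(rng.normal(size=len(times)), times,
                                      labels, n_perm=10, seed=0)


class TestKlDivergence:
    def _setup(self, rng, mu_one, mu_two, n=30_000):
        td, rate = 0.6, 200.0
        n_trip = int(np.ceil(n / (td * rate)))
        codes = np.tile([_ONE, _TWO], n_trip // 2 + 1)[:n_trip]
        labels = simple_labels(codes)
        times = np.arange(n) / rate
        side = labels.sample_labels(times)
        phi = np.where(side == _TWO, rng.normal(mu_two, 1.0, n),
                       rng.normal(mu_one, 1.0, n))
        return phi, times, labels

    def test_identical_distributions_near_zero(self, rng):
        phi, times, labels = self._setup(rng, 0.0, 0.0)
        assert kl_divergence_percepts(phi, times, labels) < 0.02

    def test_monotone_in_separation(self, rng):
        phi_far, t, lab = self._setup(rng, -3.0, 3.0)
        kl_far = kl_divergence_percepts(phi_far, t, lab)
        rng2 = np.random.default_rng(1)
        phi_near, t2, lab2 = self._setup(rng2, -0.3, 0.3)
        kl_near = kl_divergence_percepts(phi_near, t2, lab2)
        assert kl_far > kl_near > 0

    def test_against_analytic_gaussian_kl(self, rng):
        # KL(N(d,1) || N(0,1)) = d^2/2; the histogram estimate with many
        # samples should land within ~10%
        d = 1.0
        phi, times, labels = self._setup(rng, 0.0, d, n=120_000)
        kl = kl_divergence_percepts(phi, times, labels, n_bins=50)
        assert kl == pytest.approx(d ** 2 / 2, rel=0.12)


class TestProfiles:
    def test_periodic_series_profile_equals_period_with_zero_sem(self):
        rate, td = 200.0, 0.6
        times = np.arange(int(20 * td * rate)) / rate
        series = np.sin(2 * np.pi * times / td)
        labels = simple_labels([_ONE] * 20)
        mean, sem = triplet_average(series, times, labels, ONE_STREAM, rate)
        assert len(mean) == 120
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, series[:120], atol=1e-12)

    def test_sem_matches_sampling_theory(self, rng):
        rate, td, n_ep = 200.0, 0.6, 400
        times = np.arange(int(n_ep * td * rate)) / rate
        series = rng.normal(size=len(times))
        labels = simple_labels([_TWO] * n_ep)
        _, sem = triplet_average(series, times, labels, TWO_STREAM, rate)
        assert np.median(sem) == pytest.approx(1 / np.sqrt(n_ep), rel=0.2)

    def test_too_few_epochs_rejected(self):
        rate = 200.0
        times = np.arange(120) / rate
        labels = simple_labels([_ONE])
        with pytest.raises(KoopstreamError):
            triplet_average(np.ones(120), times, labels, ONE_STREAM, rate)

    def test_pearson_and_r2_closed_forms(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert profile_similarity(a, 2 * a) == pytest.approx(1.0)
        assert profile_similarity(a, -a) == pytest.approx(-1.0)
        b = np.array([1.0, 2.0, 3.0, 5.0])
        # brute-force Pearson formula
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert profile_similarity(a, b) == pytest.approx(expected)
        assert reconstruction_r2(a, a) == pytest.approx(1.0)
        with pytest.raises(KoopstreamError):
            profile_similarity(a, np.ones(4))


class TestMotorControl:
    def _matches(self, rng, n_each=20, shift=0.0):
        rows = []
        t = 10.0
        for i in range(2 * n_each):
            rows.append(dict(outcome="bp" if i % 2 else "pb",
                             predicted_time=t,
                             direction="one_to_two"))
            t += 3.0
        return pd.DataFrame(rows)

    def test_null_calibrated(self, rng):
        rate = 200.0
        rejections = 0
        n_runs = 30
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            times = np.arange(int(150 * rate)) / rate
            phi = r.normal(size=len(times))
            res = motor_control_analysis(phi, times, self._matches(r), rate)
            p = res["one_to_two"]
            rejections += (p["p_pc1"] < 0.05) or (p["p_pc2"] < 0.05)
        assert rejections / n_runs <= 0.35   # ~2 tests at alpha 0.05

    def test_constant_offset_removed_by_zscoring(self, rng):
        rate = 200.0
        times = np.arange(int(150 * rate)) / rate
        phi = rng.normal(size=len(times))
        matches = self._matches(rng)
        base = motor_control_analysis(phi, times, matches, rate)
        # add a large constant to every pb segment: z-scoring removes it
        phi2 = phi.copy()
        for _, row in matches[matches.outcome == "pb"].iterrows():
            k = int(round(row["predicted_time"] * rate))
            phi2[k - 240:k] += 100.0
        shifted = motor_control_analysis(phi2, times, matches, rate)
        assert shifted["one_to_two"]["p_pc1"] == pytest.approx(
            base["one_to_two"]["p_pc1"], abs=1e-9)

    def test_shape_difference_detected(self, rng):
        rate = 200.0
        times = np.arange(int(400 * rate)) / rate
        phi = rng.normal(size=len(times))
        matches = self._matches(rng, n_each=60)
        phi2 = phi.copy()
        ramp = np.linspace(-3, 3, 240)
        for _, row in matches[matches.outcome == "pb"].iterrows():
            k = int(round(row["predicted_time"] * rate))
            phi2[k - 240:k] += ramp
        res = motor_control_analysis(phi2, times, matches, rate)
        p = res["one_to_two"]
        assert min(p["p_pc1"], p["p_pc2"]) < 0.01
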