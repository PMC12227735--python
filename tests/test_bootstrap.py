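"""ISI-shuffle null construction, percentile rule, and classification logic."""

from itertools import permutations

import numpy as np
import pytest

from vtaephys import (
    Classification,
    NeuronSimSpec,
    SpikeTrain,
    ValidationError,
    build_null_distribution,
    classify_drug_response,
    classify_response,
    contrast_drug_vs_saline,
    first_significant_dose,
    holm_correction,
    percentile_of,
    shuffle_isis,
    simulate_neuron,
)
from vtaephys.rates import baseline_mean_rate, compute_rate_trace


class TestShuffleIsis:
    def test_regular_train_invariant_under_shuffle(self, rng):
        times = np.arange(0.0, 10.0, 0.5)
        assert np.allclose(shuffle_isis(times, rng), times)

    def test_isi_multiset_count_and_span_conserved(self, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0.0, 60.0, rng.integers(4, 40)))
            surr = shuffle_isis(times, rng)
            assert surr.size == times.size
            assert surr[0] == times[0]
            assert np.isclose(surr[-1], times[-1])
            assert np.allclose(np.sort(np.diff(surr)), np.sort(np.diff(times)))

    def test_too_few_spikes_rejected(self, rng):
        with pytest.raises(ValidationError, match="insufficient baseline"):
            shuffle_isis(np.array([1.0, 2.0]), rng)

    def test_permutations_uniform_over_orderings(self, rng):
        # 4 spikes, 3 distinct ISIs -> 3! = 6 equally likely surrogate orders
        times = np.array([0.0, 1.0, 3.0, 6.0])
        n = 12000
        seen = {}
        for _ in range(n):
            key = tuple(np.round(np.diff(shuffle_isis(times, rng)), 6))
            seen[key] = seen.get(key, 0) + 1
        assert set(seen) == set(permutations((1.0, 2.0, 3.0)))
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for count in seen.values():
            assert abs(count / n - 1 / 6) < 3 * se


class TestNullDistribution:
    def test_regular_baseline_gives_degenerate_null(self, regular_train):
        null = build_null_distribution(
            regular_train.spike_times, n_windows=9, rng=np.random.default_rng(0)
        )
        assert np.allclose(null.values, null.values[0])

    def test_fixed_seed_reproducible(self, stationary_train):
        bs = stationary_train.between(0.0, 300.0)
        a = build_null_distribution(bs, n_windows=10, rng=np.random.default_rng(3))
        b = build_null_distribution(bs, n_windows=10, rng=np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)

    def test_matches_naive_second_implementation(self, stationary_train):
        """Vectorized null vs a naive per-shuffle rate-trace oracle (different
        RNG stream), compared through their means within 3 MC SE."""
        bs = stationary_train.between(0.0, 300.0)
        mu = baseline_mean_rate(bs, (0.0, 300.0))
        fast = build_null_distribution(
            bs, n_windows=10, n_shuffles=400, rng=np.random.default_rng(11),
            baseline_mean_hz=mu,
        )
        oracle_rng = np.random.default_rng(999)  # independent stream
        vals = []
        for _ in range(400):
            surr = shuffle_isis(bs, oracle_rng)
            trace = compute_rate_trace(surr, (surr[0], surr[-1]))
            pct = 100.0 * (trace.rates[:10] - mu) / mu
            vmax, vmin = pct.max(), pct.min()
            vals.append(vmax if abs(vmax) >= abs(vmin) else vmin)
        vals = np.asarray(vals)
        se = np.sqrt(fast.values.var() / 400 + vals.var() / 400)
        assert abs(fast.values.mean() - vals.mean()) < 3 * se

    def test_short_baseline_rejected(self):
        times = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        with pytest.raises(ValidationError, match="too short"):
            build_null_distribution(times, n_windows=10)


class TestPercentileRule:
    def test_observation_above_all_nulls(self):
        assert percentile_of(50.0, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_degenerate_null_midrank(self):
        assert percentile_of(5.0, np.full(100, 5.0)) == 0.5

    def test_counting_oracle(self):
        assert percentile_of(5.0, np.array([-10.0, 0.0, 10.0, 20.0])) == 0.5
        assert percentile_of(10.0, np.array([-10.0, 0.0, 10.0, 20.0])) == pytest.approx(
            (2 + 0.5) / 4
        )


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "delta_f,percentile,label,conflict",
        [
            (8.0, 0.50, "nonresponsive", False),
            (35.0, 0.96, "activated", False),  # Nic+ rule
            (-40.0, 0.02, "inhibited", False),  # Nic- rule
            (35.0, 0.95, "activated", False),  # boundary inclusive
            (-12.0, 0.97, "nonresponsive", True),  # tail/sign conflict
            (12.0, 0.01, "nonresponsive", True),
            (0.0, 0.99, "nonresponsive", True),
        ],
    )
    def test_percentile_and_sign_rules(self, delta_f, percentile, label, conflict):
        cls = classify_response(delta_f, percentile)
        assert cls.label == label
        assert cls.conflict_flag == conflict

    def test_polarity_property(self):
        assert classify_response(30.0, 0.99).polarity == 1
        assert classify_response(-30.0, 0.01).polarity == -1
        assert classify_response(5.0, 0.5).polarity == 0


class TestEndToEndClassification:
    def test_activated_neuron_recovered(self):
        spec = NeuronSimSpec(modulation_amplitude_pct=60.0)
        train = simulate_neuron(
            spec, epoch=(0, 480), injection_times=(300.0,),
            rng=np.random.default_rng(21), neuron_id="act",
        )
        cls, prof, null = classify_drug_response(
            train, 300.0, rng=np.random.default_rng(22)
        )
        assert cls.label == "activated"
        assert prof.delta_f_pct > 30.0
        assert null.n_shuffles == 1000

    def test_identical_seed_identical_classification(self, stationary_train):
        out = [
            classify_drug_response(
                stationary_train, 300.0, rng=np.random.default_rng(5)
            )[0]
            for _ in range(2)
        ]
        assert out[0] == out[1]

    def test_monotone_power_in_modulation_amplitude(self):
        """Correct-classification rate is nondecreasing in |Δf| (common
        random numbers across amplitude levels)."""
        amplitudes = [0.0, 15.0, 30.0, 60.0]
        n = 30
        rates = []
        for m in amplitudes:
            correct = 0
            for i in range(n):
                train = simulate_neuron(
                    NeuronSimSpec(modulation_amplitude_pct=m),
                    epoch=(0, 480), injection_times=(300.0,),
                    rng=np.random.default_rng(1000 + i),  # common across levels
                    neuron_id=f"n{i}",
                )
                cls, _, _ = classify_drug_response(
                    train, 300.0, n_shuffles=400, rng=np.random.default_rng(2000 + i)
                )
                if m == 0:
                    correct += not cls.responsive
                else:
                    correct += cls.label == "activated"
            rates.append(correct / n)
        power = rates[1:]
        assert all(b >= a - 1e-9 for a, b in zip(power, power[1:]))
        assert power[-1] >= 0.95

    def test_baseline_before_epoch_rejected(self):
        train = SpikeTrain("x", np.arange(10.0, 400.0, 0.3), 10.0, 400.0)
        with pytest.raises(ValidationError, match="baseline"):
            classify_drug_response(train, 300.0)


class TestContrastAndDose:
    def test_identical_pairs_no_rejection(self):
        res = contrast_drug_vs_saline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.test == "degenerate"

    def test_constant_shift_detected_by_paired_t(self, rng):
        sal = rng.normal(0.0, 1.0, 12)
        drug = sal + 30.0 + rng.normal(0.0, 0.5, 12)
        res = contrast_drug_vs_saline(drug, sal)
        assert res.test == "paired_t" and res.p_value < 0.05
        # closed-form paired t oracle
        d = drug - sal
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.statistic == pytest.approx(t_oracle)

    def test_skewed_differences_use_wilcoxon(self, rng):
        sal = np.zeros(20)
        drug = rng.lognormal(0.0, 1.5, 20)  # heavily skewed differences
        res = contrast_drug_vs_saline(drug, sal)
        assert res.test == "wilcoxon"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            contrast_drug_vs_saline([1.0, 2.0], [0.0, 1.0])

    def test_holm_against_hand_computation(self):
        # sorted p: 0.01, 0.03, 0.04 -> adjusted 0.03, 0.06, 0.06
        reject, adjusted = holm_correction([0.01, 0.04, 0.03], alpha=0.05)
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])
        assert list(reject) == [True, False, False]

    def test_first_significant_dose_rules(self):
        nr = Classification("nonresponsive", 0.5, 1.0)
        inh = Classification("inhibited", 0.02, -35.0)
        act = Classification("activated", 0.97, 25.0)
        assert first_significant_dose([(125.0, nr), (250.0, inh)]) == "inhibited"
        assert first_significant_dose([(125.0, act), (250.0, inh)]) == "activated"
        assert first_significant_dose([(125.0, nr), (250.0, nr)]) == "unclassified"
        with pytest.raises(ValidationError):
            first_significant_dose([(250.0, nr), (125.0, inh)])
        with pytest.raises(ValidationError):
            first_significant_dose([])

    def test_first_significant_dose_on_simulated_threshold_neuron(self):
        """A neuron responding only from 250 mg/kg upward is labeled by the
        250 mg/kg polarity (here inhibition)."""
        doses, threshold = (125.0, 250.0), 250.0
        series = []
        for j, dose in enumerate(doses):
            m = -40.0 if dose >= threshold else 0.0
            train = simulate_neuron(
                NeuronSimSpec(modulation_amplitude_pct=m),
                epoch=(0, 480), injection_times=(300.0,),
                rng=np.random.default_rng(77 + j), neuron_id=f"d{j}",
            )
            cls, _, _ = classify_drug_response(
                train, 300.0, rng=np.random.default_rng(177 + j), dose=dose
            )
            series.append((dose, cls))
        assert first_significant_dose(series) == "inhibited"
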