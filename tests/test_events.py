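"""Template construction, noise estimation, matched detection, evoked peaks."""

import numpy as np
import pytest

from vtaephys import (
    CurrentTrace,
    ValidationError,
    build_template,
    detect_events,
    estimate_noise_sd,
    evoked_amplitude,
    simulate_current_trace,
)


def biexp_kernel(n, fs, tau_rise_ms=1.0, tau_decay_ms=8.0):
    u = np.arange(n) / fs
    k = np.exp(-u / (tau_decay_ms / 1000)) - np.exp(-u / (tau_rise_ms / 1000))
    return k / k.max()


@pytest.fixture
def clean_events_trace():
    """Noise-free trace with 20 identical −50 pA biexponential events."""
    stim = np.arange(0.5, 20.0, 1.0)
    trace, truth = simulate_current_trace(
        20.0, noise_sd=0.0, event_rate_hz=0.0,
        stim_times=stim, evoked_amplitude_pA=-50.0, rng=np.random.default_rng(0),
    )
    return trace, truth


class TestBuildTemplate:
    def test_identical_events_recover_kernel(self, clean_events_trace):
        trace, truth = clean_events_trace
        tmpl = build_template(trace, truth["onset_s"].to_numpy()[:15])
        fs = trace.sampling_rate
        pre = int(round(tmpl.pre_ms / 1000 * fs))
        # normalization by the signed peak makes the template positive-peaked;
        # the noise-robust peak estimate leaves a ~1% overall-scale freedom
        expected = biexp_kernel(tmpl.waveform.size - pre, fs)
        post = tmpl.waveform[pre:]
        assert np.allclose(post / post.max(), expected, atol=1e-9)
        assert abs(post.max() - 1.0) < 0.02
        assert np.allclose(tmpl.waveform[:pre], 0.0, atol=1e-9)

    def test_fourteen_examples_rejected(self, clean_events_trace):
        trace, truth = clean_events_trace
        with pytest.raises(ValidationError, match="15"):
            build_template(trace, truth["onset_s"].to_numpy()[:14])

    def test_overlapping_examples_rejected(self, clean_events_trace):
        trace, truth = clean_events_trace
        onsets = truth["onset_s"].to_numpy()[:15].copy()
        onsets[1] = onsets[0] + 0.005  # inside one template length
        with pytest.raises(ValidationError, match="overlap"):
            build_template(trace, onsets)

    def test_average_template_beats_single_snippets(self):
        """With i.i.d. noise the averaged template is closer (L2) to the
        true kernel than any individual example snippet."""
        stim = np.arange(0.5, 22.0, 1.0)
        trace, truth = simulate_current_trace(
            22.0, noise_sd=5.0, event_rate_hz=0.0,
            stim_times=stim, evoked_amplitude_pA=-40.0, rng=np.random.default_rng(3),
        )
        onsets = truth["onset_s"].to_numpy()[:20]
        tmpl = build_template(trace, onsets)
        fs = trace.sampling_rate
        pre = int(round(tmpl.pre_ms / 1000 * fs))
        n_post = tmpl.waveform.size - pre
        true_kernel = biexp_kernel(n_post, fs)
        err_template = np.linalg.norm(tmpl.waveform[pre:] - true_kernel)
        idx = np.round(onsets * fs).astype(int)
        snippet_errs = [
            np.linalg.norm(trace.samples[i : i + n_post] / -40.0 - true_kernel)
            for i in idx
        ]
        assert err_template < min(snippet_errs)


class TestNoiseEstimation:
    def test_recovers_gaussian_sigma(self):
        trace = CurrentTrace(np.random.default_rng(1).normal(0, 5.0, 100_000), 10_000.0)
        assert estimate_noise_sd(trace) == pytest.approx(5.0, rel=0.10)

    def test_constant_trace_gives_zero(self):
        assert estimate_noise_sd(CurrentTrace(np.full(5000, 7.0), 10_000.0)) == 0.0

    def test_masked_events_do_not_inflate_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5.0, 50_000)
        mask = np.zeros_like(x, dtype=bool)
        for i in range(0, 50_000, 5000):  # large rare deflections
            x[i : i + 300] -= 200.0
            mask[i : i + 300] = True
        trace = CurrentTrace(x, 10_000.0)
        assert estimate_noise_sd(trace, mask) == pytest.approx(5.0, rel=0.10)
        assert estimate_noise_sd(trace) > estimate_noise_sd(trace, mask)

    def test_fully_masked_rejected(self):
        trace = CurrentTrace(np.zeros(5000), 10_000.0)
        with pytest.raises(ValidationError):
            estimate_noise_sd(trace, np.ones(5000, dtype=bool))


class TestDetectEvents:
    @pytest.fixture
    def template(self, clean_events_trace):
        trace, truth = clean_events_trace
        return build_template(trace, truth["onset_s"].to_numpy()[:15])

    def test_pure_noise_yields_no_events(self, template):
        trace, _ = simulate_current_trace(
            10.0, noise_sd=5.0, event_rate_hz=0.0, rng=np.random.default_rng(8)
        )
        assert detect_events(trace, template, 5.0) == []

    def test_planted_five_sigma_events_all_found(self, template):
        stim = np.arange(0.5, 20.0, 0.95)
        trace, truth = simulate_current_trace(
            20.0, noise_sd=5.0, event_rate_hz=0.0,
            stim_times=stim, evoked_amplitude_pA=-25.0, rng=np.random.default_rng(6),
        )
        events = detect_events(trace, template, 5.0)
        det = np.array([e.onset_time for e in events])
        for t in truth["onset_s"]:
            assert np.any(np.abs(det - t) < 0.005)
        for e in events:
            assert abs(e.amplitude_pA - (-25.0)) < 0.2 * 25.0
            assert abs(e.amplitude_pA) >= 3 * 5.0

    def test_two_sigma_events_rejected_by_amplitude_rule(self, template):
        stim = np.arange(0.5, 20.0, 0.95)
        trace, _ = simulate_current_trace(
            20.0, noise_sd=5.0, event_rate_hz=0.0,
            stim_times=stim, evoked_amplitude_pA=-10.0, rng=np.random.default_rng(7),
        )
        assert detect_events(trace, template, 5.0) == []

    def test_amplitude_scale_equivariance(self, template):
        stim = np.arange(0.5, 10.0, 0.95)
        trace, _ = simulate_current_trace(
            10.0, noise_sd=5.0, event_rate_hz=0.0,
            stim_times=stim, evoked_amplitude_pA=-30.0, rng=np.random.default_rng(9),
        )
        c = 3.5
        scaled = CurrentTrace(c * trace.samples, trace.sampling_rate)
        ev1 = detect_events(trace, template, 5.0)
        ev2 = detect_events(scaled, template, c * 5.0)
        assert len(ev1) == len(ev2) > 0
        for a, b in zip(ev1, ev2):
            assert b.amplitude_pA == pytest.approx(c * a.amplitude_pA)
            assert b.onset_time == a.onset_time
            assert b.detection_score == pytest.approx(a.detection_score)

    def test_nonpositive_noise_sd_rejected(self, template):
        trace, _ = simulate_current_trace(5.0, rng=np.random.default_rng(5))
        with pytest.raises(ValidationError):
            detect_events(trace, template, 0.0)


class TestEvokedAmplitude:
    def test_flat_trace_zero(self):
        trace = CurrentTrace(np.zeros(10_000), 10_000.0)
        assert evoked_amplitude(trace, 0.5, (0.3, 0.45), (0.5, 0.8)) == 0.0

    def test_step_deflection_recovered(self):
        x = np.zeros(10_000)
        x[5000:] = -50.0
        trace = CurrentTrace(x, 10_000.0)
        assert evoked_amplitude(trace, 0.5, (0.3, 0.45), (0.5, 0.8)) == -50.0

    def test_biexp_peak_on_noisy_baseline(self):
        rng = np.random.default_rng(12)
        sigma, n_pre = 4.0, 2000
        x = rng.normal(0, sigma, 20_000)
        k = biexp_kernel(1200, 10_000.0)
        x[10_000 : 10_000 + 1200] += -60.0 * k
        trace = CurrentTrace(x, 10_000.0)
        est = evoked_amplitude(trace, 1.0, (0.8, 1.0), (1.0, 1.2))
        # peak-picking on noise biases |est| upward by ~the noise scale
        assert est < 0
        assert abs(est - (-60.0)) < 3 * sigma

    def test_overlapping_windows_rejected(self):
        trace = CurrentTrace(np.zeros(10_000), 10_000.0)
        with pytest.raises(ValidationError, match="overlap"):
            evoked_amplitude(trace, 0.5, (0.3, 0.6), (0.5, 0.8))
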