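import numpy as np
import pytest

from taskspike.peth import (
    NoReleaseDetected,
    classify_rs_fs,
    compute_peth,
    detect_release_onset,
    ongoing_rate,
    smooth_peth,
)
from taskspike.session import PedalTrace, SpikeTrain, TrialEvent


def _train(times):
    return SpikeTrain("n0", "CA1", np.asarray(times, float), 1.0)


class TestComputePeth:
    def test_single_spike_at_alignment(self):
        p = compute_peth(_train([10.0]), [10.0], (-0.5, 0.5), 0.02)
        hot = (p.bin_edges[:-1] <= 0) & (p.bin_edges[1:] > 0)
        assert p.rates[hot] == pytest.approx(50.0)  # 1 / (1 trial x 0.02 s)
        assert p.rates[~hot].sum() == 0

    def test_no_spikes_all_zero(self):
        p = compute_peth(_train([]), [1.0, 2.0], (-0.5, 0.5))
        assert (p.rates == 0).all()

    def test_count_conservation_random_sessions(self, rng):
        for _ in range(20):
            spikes = np.sort(rng.uniform(0, 100, rng.integers(0, 400)))
            aligns = rng.uniform(5, 95, rng.integers(1, 30))
            p = compute_peth(_train(spikes), aligns, (-0.5, 0.5), 0.02)
            pooled = sum(((spikes >= a - 0.5) & (spikes < a + 0.5)).sum() for a in aligns)
            assert (p.rates * p.bin_width).sum() * p.n_trials == pytest.approx(pooled)

    def test_homogeneous_poisson_rates(self, rng):
        n_trials, rate = 200, 10.0
        aligns = np.arange(n_trials) * 10.0 + 5.0
        spikes = np.sort(rng.uniform(0, n_trials * 10.0, int(rate * n_trials * 10)))
        p = compute_peth(_train(spikes), aligns, (-0.5, 0.5), 0.02)
        sd = np.sqrt(rate / (n_trials * 0.02))
        assert (np.abs(p.rates - rate) < 5 * sd).all()

    def test_empty_align_times_rejected(self):
        with pytest.raises(ValueError):
            compute_peth(_train([1.0]), [], (-0.5, 0.5))


class TestSmoothPeth:
    def test_single_spike_gaussian_profile(self):
        sp = smooth_peth(_train([10.0]), sigma_ms=12.5, align_times=[10.0],
                         window=(-0.5, 0.5))
        # integral equals 1 spike / trial; shape matches the kernel sd
        assert (sp.rates * sp.bin_width).sum() == pytest.approx(1.0, rel=1e-3)
        c = sp.bin_centers
        m = (sp.rates * c).sum() / sp.rates.sum()
        sd = np.sqrt((sp.rates * (c - m) ** 2).sum() / sp.rates.sum())
        assert sd == pytest.approx(0.0125, rel=0.05)

    def test_constant_rate_invariant_interior(self, rng):
        spikes = np.sort(rng.uniform(0, 1000, 20000))  # 20 Hz
        aligns = np.linspace(50, 950, 200)
        sp = smooth_peth(_train(spikes), sigma_ms=12.5, align_times=aligns,
                         window=(-2, 2))
        interior = sp.rates[200:-200]
        assert interior.mean() == pytest.approx(20.0, rel=0.05)
        assert interior.std() < 0.25 * interior.mean()

    def test_integral_preserved(self, rng):
        spikes = np.sort(rng.uniform(99.5, 100.5, 300))
        raw = compute_peth(_train(spikes), [100.0], (-1.0, 1.0), 0.001)
        sp = smooth_peth(raw, sigma_ms=12.5)
        assert (sp.rates.sum() / raw.rates.sum()) == pytest.approx(1.0, abs=1e-3)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            smooth_peth(_train([1.0]), sigma_ms=0, align_times=[1.0], window=(-1, 1))


class TestReleaseOnset:
    @staticmethod
    def _sigmoid_trace(t_release=10.0, rise=0.1, rate=1000.0):
        t = np.arange(0, 15.0, 1.0 / rate)
        pos = np.full(t.size, 10.0)
        frac = np.clip((t - t_release) / rise, 0, 1)
        s = frac * frac * (3 - 2 * frac)
        pos = 10.0 + s * 60.0
        return PedalTrace("right", t, pos, rate)

    @staticmethod
    def _trial():
        return TrialEvent(0, 8.0, 2.0, "right", True, False,
                          release_onset=10.0, released_side="right",
                          reward_onset=10.4)

    def test_noiseless_sigmoid_onset(self):
        trace = self._sigmoid_trace()
        t_on = detect_release_onset(trace, self._trial())
        # 5% excursion above the 10% baseline is crossed just after 10.0 s
        assert 10.0 <= t_on <= 10.05

    def test_flat_trace_raises(self):
        t = np.arange(0, 15.0, 0.01)
        trace = PedalTrace("right", t, np.full(t.size, 10.0), 100.0)
        with pytest.raises(NoReleaseDetected):
            detect_release_onset(trace, self._trial())

    def test_detected_precedes_30pct_crossing_on_cohort(self, behavior_320):
        _, trials, traces = behavior_320
        checked = 0
        for t in trials:
            if not t.completed:
                continue
            tr = traces[t.released_side]
            t_on = detect_release_onset(tr, t)
            i30 = np.searchsorted(tr.sample_times, t.hold_onset)
            seg = tr.positions[i30:]
            t30 = tr.sample_times[i30 + np.argmax(seg > 30.0)]
            assert t_on <= t30
            assert abs(t_on - t.release_onset) < 0.1
            checked += 1
        assert checked > 250


class TestRsFs:
    def test_bimodal_threshold_and_labels(self, rng):
        rs = rng.normal(1.0, 0.1, 200)
        fs = rng.normal(0.30, 0.05, 50)
        d = np.concatenate([rs, fs])
        truth = np.array(["RS"] * 200 + ["FS"] * 50)
        wc = classify_rs_fs(d)
        assert 0.45 < wc.threshold_ms < 0.85
        assert (wc.labels == truth).mean() >= 0.98
        assert not wc.degenerate

    def test_threshold_between_means_100_cohorts(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            d = np.concatenate([r.normal(1.0, 0.1, 80), r.normal(0.3, 0.05, 20)])
            wc = classify_rs_fs(d)
            assert 0.3 < wc.threshold_ms < 1.0

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            wc = classify_rs_fs([1.0] * 20)
        assert wc.degenerate

    def test_boundary_duration_is_rs(self):
        from taskspike.peth import label_durations

        assert label_durations([0.72], 0.72)[0] == "RS"
        assert label_durations([0.7199], 0.72)[0] == "FS"

    def test_matches_li_iterative_threshold(self, rng):
        from skimage.filters import threshold_li

        d = np.concatenate([rng.normal(1.0, 0.08, 150), rng.normal(0.3, 0.04, 50)])
        ours = classify_rs_fs(d).threshold_ms
        ref = threshold_li(d)
        # both are minimum-cross-entropy thresholds; same inter-mode gap
        assert (d[d < ours].max() < min(ours, ref)) or abs(ours - ref) < 0.15


class TestOngoingRate:
    def test_simple_rate(self):
        assert ongoing_rate(_train(np.linspace(0.1, 9.9, 30)), (0, 10)) == 3.0

    def test_empty_train(self):
        assert ongoing_rate(_train([]), (0, 10)) == 0.0

    def test_zero_length_epoch_rejected(self):
        with pytest.raises(ValueError):
            ongoing_rate(_train([1.0]), (5, 5))

    def test_simulator_baseline_recovered(self, behavior_320, rng):
        from taskspike.simulate import NeuronSpec, simulate_neuron

        _, trials, _ = behavior_320
        spec = NeuronSpec("n0", "none", "CA1", baseline_hz=3.0)
        st = simulate_neuron("none", trials, spec, seed=5, t_span=900.0)
        est = ongoing_rate(st, (0, 900.0))
        sd = np.sqrt(3.0 / 900.0)
        assert abs(est - 3.0) < 3 * sd
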