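import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import meegconnet as m
from meegconnet import connectivity as fc
from meegconnet.errors import EstimatorError, ParameterError
from conftest import lagged_sine_recording


def symmetric_zero_diag(values):
    return (np.allclose(values, values.T)
            and np.abs(np.diag(values)).max() == 0)


class TestXcorr:
    def test_identical_channels_give_one(self, rng):
        x = rng.normal(size=(1, 500, 2))
        rec = m.Recording(np.vstack([x, x]), sfreq=100,
                          channel_labels=["a", "b"])
        conn = m.xcorr_matrix(rec, max_lag=10)
        assert conn.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_pure_delay_recovered(self, rng):
        x = rng.normal(size=2000)
        y = np.roll(x, 5)
        rec = m.Recording(np.vstack([x, y]), sfreq=100,
                          channel_labels=["a", "b"])
        assert m.xcorr_matrix(rec, max_lag=10).values[0, 1] >= 0.99
        # insufficient lag range misses the alignment
        assert m.xcorr_matrix(rec, max_lag=2).values[0, 1] < 0.99

    def test_independent_noise_near_zero(self, rng):
        rec = m.Recording(rng.normal(size=(2, 10000)), sfreq=100,
                          channel_labels=["a", "b"])
        assert m.xcorr_matrix(rec, max_lag=20).values[0, 1] < 0.2

    def test_constant_channel_set_to_zero(self, rng):
        data = np.vstack([np.ones((1, 500)), rng.normal(size=(1, 500))])
        rec = m.Recording(data, sfreq=100, channel_labels=["flat", "n"])
        assert m.xcorr_matrix(rec, max_lag=5).values[0, 1] == 0.0


class TestPhaseLocking:
    def test_fixed_lag_sinusoids_lock_to_one(self):
        rec = lagged_sine_recording()
        for fn in (m.plv_static, m.mpc_matrix):
            assert fn(rec).values[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_independent_broadband_noise_low(self, rng):
        rec = m.Recording(rng.normal(size=(2, 10000)), sfreq=1000,
                          channel_labels=["a", "b"])
        from meegconnet import preprocess as pp

        band = pp.fir_bandpass(rec, 30, 45)
        assert m.plv_static(band).values[0, 1] < 0.15

    def test_mpc_equals_plv_single_trial(self, rng):
        rec = m.Recording(rng.normal(size=(3, 1000)), sfreq=250,
                          channel_labels=list("abc"))
        np.testing.assert_array_equal(
            m.plv_static(rec).values, m.mpc_matrix(rec).values
        )

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.normal(size=(3, 2000))
        rec = m.Recording(x, sfreq=250, channel_labels=list("abc"))
        scaled = m.Recording(x * np.array([[3.0], [0.1], [42.0]]), sfreq=250,
                             channel_labels=list("abc"))
        np.testing.assert_allclose(
            m.plv_static(rec).values, m.plv_static(scaled).values, atol=1e-9
        )

    def test_outputs_symmetric_zero_diagonal(self, noise_recording):
        for fn in (m.plv_static, m.mpc_matrix,
                   lambda r: m.xcorr_matrix(r, max_lag=10),
                   lambda r: m.mi_matrix(r, n_bins=8)):
            assert symmetric_zero_diag(fn(noise_recording).values)


class TestPlvIntertrial:
    def test_constant_lag_across_trials_gives_one(self):
        t = np.arange(300) / 100
        nt = 12
        rng = np.random.default_rng(0)
        trials = []
        for _ in range(nt):
            ph = rng.uniform(0, 2 * np.pi)
            trials.append(np.vstack([
                np.sin(2 * np.pi * 7 * t + ph),
                np.sin(2 * np.pi * 7 * t + ph + np.pi / 4),
            ]))
        rec = m.Recording(np.stack(trials, axis=2), sfreq=100,
                          channel_labels=["a", "b"])
        vals = m.plv_intertrial(rec)
        assert vals.shape == (300, 2, 2)
        mid = vals[30:-30, 0, 1]
        assert mid.min() > 1 - 1e-6

    def test_uniform_phase_differences_rayleigh_floor(self):
        nt = 1000
        t = np.arange(128) / 128
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2 * np.pi, nt)
        b = rng.uniform(0, 2 * np.pi, nt)
        data = np.stack([
            np.sin(2 * np.pi * 8 * t[:, None] + a),
            np.sin(2 * np.pi * 8 * t[:, None] + b),
        ])
        rec = m.Recording(data, sfreq=128, channel_labels=["a", "b"])
        assert m.plv_intertrial(rec)[10:-10, 0, 1].max() < 0.1

    def test_single_trial_directed_to_static(self, rng):
        rec = m.Recording(rng.normal(size=(2, 100, 1)), sfreq=100,
                          channel_labels=["a", "b"])
        with pytest.raises(EstimatorError, match="plv_static"):
            m.plv_intertrial(rec)


class TestMutualInformation:
    def test_identity_reaches_log2_bins(self, rng):
        x = rng.uniform(size=50000)
        rec = m.Recording(np.vstack([x, x]), sfreq=100,
                          channel_labels=["a", "b"])
        mi = m.mi_matrix(rec, n_bins=16).values[0, 1]
        assert mi == pytest.approx(4.0, rel=0.05)

    def test_independent_uniforms_near_zero(self, rng):
        rec = m.Recording(rng.uniform(size=(2, 50000)), sfreq=100,
                          channel_labels=["a", "b"])
        assert m.mi_matrix(rec, n_bins=16).values[0, 1] < 0.02

    def test_single_bin_rejected(self, noise_recording):
        with pytest.raises(ParameterError):
            m.mi_matrix(noise_recording, n_bins=1)

    def test_monotone_rescaling_keeps_mi_high(self, rng):
        x = rng.uniform(size=20000)
        rec = m.Recording(np.vstack([x, 100.0 * x]), sfreq=100,
                          channel_labels=["a", "b"])
        assert m.mi_matrix(rec, n_bins=16).values[0, 1] > 3.5


class TestSlidingWindow:
    def test_window_count_arithmetic(self, rng):
        rec = m.Recording(rng.normal(size=(3, 1000)), sfreq=250,
                          channel_labels=list("abc"))
        dyn = m.sliding_window(rec, "plv", window=250, step=250)
        assert dyn.n_windows == 4
        assert list(dyn.window_starts) == [0, 250, 500, 750]
        with pytest.raises(ParameterError):
            m.sliding_window(rec, "plv", window=2000, step=100)

    def test_stationary_coupling_stable_across_windows(self):
        rec = lagged_sine_recording(n=4000)
        dyn = m.sliding_window(rec, "plv", window=1000, step=500)
        full = m.plv_static(rec).values[0, 1]
        assert np.abs(dyn.values[:, 0, 1] - full).max() < 0.05

    def test_coupling_onset_detected(self, rng):
        n = 4000
        t = np.arange(n) / 500
        shared = np.sin(2 * np.pi * 10 * t + np.cumsum(rng.normal(0, 0.05, n)))
        other = np.sin(2 * np.pi * 10 * t + np.cumsum(rng.normal(0, 0.05, n)))
        x1 = shared + 0.3 * rng.normal(size=n)
        x2 = np.where(np.arange(n) < n // 2, other, shared) \
            + 0.3 * rng.normal(size=n)
        rec = m.Recording(np.vstack([x1, x2]), sfreq=500,
                          channel_labels=["a", "b"])
        dyn = m.sliding_window(rec, "plv", window=500, step=500)
        first, second = dyn.values[:4, 0, 1], dyn.values[4:, 0, 1]
        assert second.min() > first.max()


class TestStateSegmentation:
    @staticmethod
    def block_dynamics(rng, nw=40):
        a = np.array([[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]])
        b = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        labels = (np.arange(nw) // 10) % 2
        vals = np.stack([
            (a if l == 0 else b) + 0.0 * rng.normal() for l in labels
        ])
        vals += rng.normal(scale=0.02, size=vals.shape)
        vals = 0.5 * (vals + np.swapaxes(vals, 1, 2))
        idx = np.arange(3)
        vals[:, idx, idx] = 0.0
        return m.DynamicConnectivity(np.abs(vals), method="plv"), labels

    def test_recovers_alternating_blocks(self, rng):
        dyn, truth = self.block_dynamics(rng)
        seg = m.segment_states(dyn, k=2, seed=0)
        assert adjusted_rand_score(truth, seg.labels) > 0.95
        assert symmetric_zero_diag(seg.centroids[0])

    def test_k_one_returns_mean(self, rng):
        dyn, _ = self.block_dynamics(rng)
        seg = m.segment_states(dyn, k=1, seed=0)
        assert set(seg.labels) == {0}
        np.testing.assert_allclose(
            seg.centroids[0], dyn.values.mean(axis=0), atol=1e-9
        )

    def test_identical_windows_zero_inertia(self):
        vals = np.tile(np.array([[0, 0.5], [0.5, 0]]), (6, 1, 1))
        dyn = m.DynamicConnectivity(vals, method="plv")
        seg = m.segment_states(dyn, k=2, seed=0)
        assert seg.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_exceeding_windows_rejected(self, rng):
        dyn, _ = self.block_dynamics(rng, nw=5)
        with pytest.raises(ParameterError):
            m.segment_states(dyn, k=6, seed=0)
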