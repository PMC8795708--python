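import numpy as np
import pytest

from nirslat.preprocess import (BandpassFilter, BeerLambertTransformer,
                                MBLLParams, ODConverter, RestingPCADenoiser,
                                SplineSGCorrector, detect_motion, mbll_forward)

FS = 17.0


def _sine(freq, n=6000, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        X = np.full((200, 3, 2), 2.5)
        assert np.allclose(ODConverter().transform(X), 0.0)

    def test_tenth_of_mean_gives_od_one(self):
        X = np.ones((100, 1, 2))
        # v/mean = 0.1 with 99 unit samples: v = 9.9/99.9
        X[50, 0, 0] = 9.9 / 99.9
        od = ODConverter().transform(X)
        assert od[50, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_sample_names_location(self):
        X = np.ones((100, 2, 2))
        X[7, 1, 0] = 0.0
        with pytest.raises(ValueError, match="time index 7"):
            ODConverter().transform(X)


class TestMotionDetection:
    def test_flat_signal_has_no_segments(self):
        x = np.zeros((2000, 2))
        assert detect_motion(x, FS) == [[], []]

    def test_large_step_yields_one_covering_segment(self, rng):
        x = rng.normal(0, 0.01, (4000, 1))  # OD-scale background noise
        x[2000:, 0] += 0.10  # step of 10 channel SDs
        segs = detect_motion(x, FS)[0]
        assert len(segs) == 1
        lo, hi = segs[0]
        assert lo <= 2000 <= hi

    def test_two_distant_spikes_yield_two_segments(self, rng):
        x = rng.normal(0, 0.01, (4000, 1))
        for i in (1000, 1000 + int(30 * FS)):  # 30 s apart
            x[i:i + 4, 0] += 0.12
        segs = detect_motion(x, FS)[0]
        assert len(segs) == 2
        assert segs[0][1] < segs[1][0]


class TestSplineSG:
    def test_slow_oscillation_passes_nearly_unattenuated(self):
        x = _sine(0.05)[:, None]
        out = SplineSGCorrector(FS).transform(x)
        core = slice(500, -500)
        ratio = np.abs(out[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_injected_spike_amplitude_reduced_80_percent(self, rng):
        x = (_sine(0.05, amp=0.01) + rng.normal(0, 0.002, 6000))[:, None]
        A = 0.15
        spike = A * np.exp(-np.abs(np.arange(6000) - 3000) / (0.4 * FS))
        corrupted = x + spike[:, None]
        out = SplineSGCorrector(FS).transform(corrupted)
        clean = SplineSGCorrector(FS).transform(x)
        resid = np.abs(out - clean)[2900:3100].max()
        assert resid <= 0.2 * A

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            SplineSGCorrector(FS).transform(np.zeros((10, 1)))

    def test_frame_too_short_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            SplineSGCorrector(FS, frame_s=0.1).transform(np.zeros((500, 1)))


class TestBandpass:
    def test_dc_removed(self):
        x = np.full((6000, 1), 3.0)
        out = BandpassFilter(FS).transform(x)
        assert np.abs(out).max() < 1e-6 * 3.0

    # the 0.008 Hz pole has minute-scale edge transients: measure amplitude
    # in the interior of a long record
    def test_one_hz_attenuated_to_ten_percent(self):
        out = BandpassFilter(FS).transform(_sine(1.0, n=24000)[:, None])
        assert np.abs(out[6000:-6000]).max() <= 0.10

    def test_passband_oscillation_preserved(self):
        out = BandpassFilter(FS).transform(_sine(0.05, n=24000)[:, None])
        assert np.abs(out[6000:-6000]).max() == pytest.approx(1.0, abs=0.05)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(3000, 1)), rng.normal(size=(3000, 1))
        f = BandpassFilter(FS).transform
        assert np.allclose(f(2.0 * x - 0.5 * y), 2.0 * f(x) - 0.5 * f(y),
                           atol=1e-9)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            BandpassFilter(1.5, 0.008, 1.0).transform(np.zeros((100, 1)))


class TestBeerLambert:
    def test_zero_od_gives_zero_hemoglobin(self):
        params = MBLLParams()
        out = BeerLambertTransformer(params).transform(np.zeros((50, 2, 2)))
        assert np.allclose(out, 0.0)

    def test_hand_solved_2x2_system(self):
        # eps=[[1,2],[2,1]], dpf=1, dOD=(3,3) -> HbO*L = HbR*L = 1
        params = MBLLParams(extinction=np.array([[1.0, 2.0], [2.0, 1.0]]),
                            dpf=(1.0, 1.0))
        od = np.full((5, 1, 2), 3.0)
        out = BeerLambertTransformer(params).transform(od)
        assert np.allclose(out, 1.0)

    def test_forward_inverse_identity(self, rng):
        params = MBLLParams()
        hemo = rng.normal(0, 0.01, (400, 4, 2))
        od = mbll_forward(hemo, params)
        back = BeerLambertTransformer(params).transform(od)
        assert np.allclose(back, hemo, atol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            MBLLParams(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestRestingPCA:
    def test_zero_components_is_identity(self, rng):
        rest = rng.normal(size=(500, 6, 2))
        task = rng.normal(size=(400, 6, 2))
        den = RestingPCADenoiser(0).fit(rest)
        assert np.allclose(den.transform(task), task)

    def test_planted_rank1_global_noise_removed(self, rng):
        loading = rng.uniform(0.5, 1.5, 8)
        g_rest = np.sin(2 * np.pi * 0.1 * np.arange(3000) / FS)
        g_task = np.cos(2 * np.pi * 0.08 * np.arange(3000) / FS)
        rest = np.outer(g_rest, loading) + rng.normal(0, 0.05, (3000, 8))
        task = np.outer(g_task, loading) + rng.normal(0, 0.05, (3000, 8))
        den = RestingPCADenoiser(1).fit(rest)
        out = den.transform(task)
        for j in range(8):
            r = np.corrcoef(out[:, j], g_task)[0, 1]
            assert abs(r) < 0.1

    def test_idempotent_projection(self, rng):
        rest = rng.normal(size=(800, 5))
        task = rng.normal(size=(600, 5))
        den = RestingPCADenoiser(2).fit(rest)
        once = den.transform(task)
        assert np.allclose(den.transform(once), once, atol=1e-12)

    def test_orthogonal_signal_subspace_preserved(self, rng):
        # noise loads on channels 0-3, signal lives on channels 4-7
        g = np.sin(2 * np.pi * 0.1 * np.arange(4000) / FS)
        s = np.sin(2 * np.pi * 0.02 * np.arange(4000) / FS)
        loading = np.array([1.0, 0.8, 1.2, 0.9, 0, 0, 0, 0])
        sig_pat = np.array([0, 0, 0, 0, 1.0, 1.0, 0.5, 0.5])
        rest = np.outer(g, loading) + rng.normal(0, 0.01, (4000, 8))
        task = np.outer(g, loading) + np.outer(s, sig_pat)
        out = RestingPCADenoiser(1).fit(rest).transform(task)
        for j in (4, 5, 6, 7):
            amp_in = np.dot(task[:, j], s) / np.dot(s, s)
            amp_out = np.dot(out[:, j], s) / np.dot(s, s)
            assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_component_count_bounds(self, rng):
        rest = rng.normal(size=(100, 4))
        with pytest.raises(ValueError, match="n_components"):
            RestingPCADenoiser(4).fit(rest)
        with pytest.raises(ValueError, match="channels"):
            RestingPCADenoiser(1).fit(rest).transform(rng.normal(size=(50, 5)))

    def test_silent_resting_removes_nothing(self, rng):
        rest = np.zeros((500, 6))
        task = rng.normal(size=(300, 6))
        den = RestingPCADenoiser(2).fit(rest)
        assert np.allclose(den.transform(task), task)
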