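"""Filter bank, envelopes, AEC, Welch PSD, vectorization and segmentation."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sstats

from megfp import (
    CANONICAL_BANDS,
    BandDefinition,
    aec_connectome,
    band_by_name,
    bandpass,
    envelope,
    segment,
    vectorize,
    welch_psd,
)
from megfp.features import design_bandpass, unvectorize_connectome
from megfp.synthetic import SyntheticConfig, generate_cohort

from conftest import ALPHA, BETA, THETA

FS = 600.0


def tone(f, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * f * t)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    @pytest.mark.parametrize(
        "band,expect_pass",
        [(ALPHA, True), (BETA, False)],
        ids=["in-band-tone-passes", "out-of-band-tone-rejected"],
    )
    def test_tone_selectivity(self, band, expect_pass):
        x = tone(10.0)
        y = bandpass(x, band, FS)
        ratio = rms(y) / rms(x)
        if expect_pass:
            assert abs(ratio - 1.0) < 0.05
        else:
            assert ratio < 0.01

    def test_frequency_response_contract(self):
        # passband within +/-1 dB; >= 40 dB down one octave outside each edge
        for band in CANONICAL_BANDS[:5]:
            taps = design_bandpass(band, FS)
            w, h = sps.freqz(taps, worN=16384, fs=FS)
            gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
            margin = min(2.0, max(0.5, 0.5 * band.f_lo))
            inner = (w >= band.f_lo + margin) & (w <= band.f_hi - margin)
            assert np.all(np.abs(gain_db[inner]) < 1.0)
            below = w <= band.f_lo / 2
            above = (w >= 2 * band.f_hi) & (w <= FS / 2)
            if below.any():
                assert np.all(gain_db[below] < -40.0)
            if above.any():
                assert np.all(gain_db[above] < -40.0)

    def test_zero_input_and_length(self):
        x = np.zeros(8000)
        y = bandpass(x, ALPHA, FS)
        assert y.shape == x.shape
        assert np.allclose(y, 0.0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(8000), BandDefinition("hg", 50, 200), 300.0)

    def test_energy_partition_white_noise(self):
        # six canonical bands jointly capture the 1-150 Hz power of white noise
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(120 * FS))
        total = bandpass(x, BandDefinition("all", 1.0, 150.0), FS).var()
        parts = sum(bandpass(x, b, FS).var() for b in CANONICAL_BANDS)
        assert abs(parts / total - 1.0) < 0.15


class TestEnvelope:
    def test_pure_tone_envelope_is_amplitude(self):
        x = tone(10.0, amp=2.5)
        e = envelope(x)
        n = e.size
        trimmed = e[n // 10 : -n // 10]
        assert np.all(e >= 0)
        assert abs(trimmed.mean() - 2.5) < 0.05

    def test_tracks_slow_modulator(self):
        fs = FS
        t = np.arange(int(20 * fs)) / fs
        m = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = m * np.sin(2 * np.pi * 25.0 * t)
        e = envelope(x)
        sl = slice(int(2 * fs), int(18 * fs))
        r = np.corrcoef(e[sl], m[sl])[0, 1]
        assert r > 0.99

    def test_zero_input(self):
        assert np.allclose(envelope(np.zeros(1000)), 0.0)


class TestAEC:
    def test_identical_signals_give_unit_correlation(self, rng):
        x = rng.standard_normal(int(10 * FS))
        conn = aec_connectome(np.vstack([x, x]), ALPHA, FS)
        assert conn.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_has_small_aec(self, rng):
        ts = rng.standard_normal((2, int(300 * FS // 2))).astype(float)
        conn = aec_connectome(ts, ALPHA, 300.0)
        assert abs(conn.values[0, 1]) < 0.1

    def test_matches_bruteforce_pair_loop(self, rng):
        # vectorized path vs explicit per-pair filter -> Hilbert -> Pearson
        ts = rng.standard_normal((4, int(10 * FS)))
        conn = aec_connectome(ts, ALPHA, FS)
        for i in range(4):
            for j in range(i + 1, 4):
                ei = np.abs(sps.hilbert(bandpass(ts[i], ALPHA, FS)))
                ej = np.abs(sps.hilbert(bandpass(ts[j], ALPHA, FS)))
                r, _ = sstats.pearsonr(ei, ej)
                assert conn.values[i, j] == pytest.approx(r, abs=1e-10)

    def test_symmetric_unit_diagonal(self, rng):
        ts = rng.standard_normal((5, int(8 * FS)))
        conn = aec_connectome(ts, BETA, FS)
        assert np.allclose(conn.values, conn.values.T)
        assert np.allclose(np.diag(conn.values), 1.0)
        assert np.nanmax(np.abs(conn.values)) <= 1.0 + 1e-12

    def test_constant_envelope_flagged_not_zeroed(self, rng):
        ts = np.vstack([np.zeros(int(8 * FS)), rng.standard_normal(int(8 * FS))])
        with pytest.warns(UserWarning, match="constant envelope"):
            conn = aec_connectome(ts, ALPHA, FS)
        assert np.isnan(conn.values[0, 1])

    def test_prefiltered_equals_band_argument(self, rng):
        # one filtering code path: pre-filtering then broadband AEC == band AEC
        ts = rng.standard_normal((3, int(10 * FS)))
        pre = bandpass(ts, ALPHA, FS)
        a1 = aec_connectome(pre, None, FS).values
        a2 = aec_connectome(ts, ALPHA, FS).values
        assert np.allclose(a1, a2, atol=1e-10)


class TestWelch:
    def test_white_noise_parseval(self, rng):
        # full one-sided grid integrates to the signal variance
        x = rng.standard_normal(int(300 * 300))
        psd = welch_psd(x[None, :], 300.0, fmax=None)
        total = np.trapezoid(psd.values[0], psd.freqs)
        assert abs(total / x.var() - 1.0) < 0.1
        # and the mean level of unit-variance noise is 1/(fs/2) per Hz
        assert abs(psd.values[0].mean() * 150.0 - 1.0) < 0.1

    def test_grid_resolution_and_range(self, rng):
        x = rng.standard_normal(int(10 * FS))
        psd = welch_psd(x[None, :], FS)
        assert psd.freqs[0] == 0.0
        assert psd.freqs[-1] == pytest.approx(150.0)
        assert np.allclose(np.diff(psd.freqs), 0.5)
        assert psd.values.shape == (1, 301)
        assert np.all(psd.values >= 0)

    def test_tone_power_localized(self):
        x = tone(10.0, duration=60.0, fs=300.0)
        psd = welch_psd(x[None, :], 300.0)
        m = (psd.freqs >= 9.5) & (psd.freqs <= 10.5)
        assert psd.values[0, m].sum() / psd.values[0].sum() >= 0.95

    def test_zero_signal_zero_psd(self):
        psd = welch_psd(np.zeros((2, 2000)), 300.0)
        assert np.allclose(psd.values, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s window"):
            welch_psd(np.zeros((1, 100)), 300.0)


class TestVectorize:
    def test_connectome_vector_length_68(self, rng):
        m = rng.standard_normal((68, 68))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        from megfp.containers import Connectome

        conn = Connectome(values=m, roi_labels=[f"r{i}" for i in range(68)])
        vec, labels = vectorize(conn)
        assert vec.size == 68 * 67 // 2 == 2278
        assert len(labels) == 2278

    def test_connectome_roundtrip(self, rng):
        from megfp.containers import Connectome

        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        conn = Connectome(values=m, roi_labels=[f"r{i}" for i in range(6)])
        vec, _ = vectorize(conn)
        assert np.array_equal(unvectorize_connectome(vec, 6), m)

    def test_broadband_psd_vector_length(self, rng):
        psd = welch_psd(rng.standard_normal((68, int(4 * FS))), FS)
        vec, labels = vectorize(psd)
        assert vec.size == 68 * 301 == 20468
        band_vec, _ = vectorize(psd, ALPHA)
        n_alpha_bins = int(np.sum((psd.freqs >= 8) & (psd.freqs <= 13)))
        assert band_vec.size == 68 * n_alpha_bins

    def test_band_off_grid_rejected(self, rng):
        psd = welch_psd(rng.standard_normal((2, int(4 * FS))), FS)
        with pytest.raises(ValueError, match="no bins"):
            vectorize(psd, BandDefinition("sliver", 10.1, 10.4))


@pytest.fixture(scope="module")
def recording():
    cfg = SyntheticConfig(
        n_subjects=2, n_sessions=2, n_rois=2, fs=300.0, duration=100.0,
        bands=(THETA,), n_latents=1, seed=3,
    )
    return generate_cohort(cfg)[0]


class TestSegment:
    def test_within_halves(self, recording):
        ds = segment(recording, "within_halves")
        assert sorted(ds) == ["ses0/half1", "ses0/half2", "ses1/half1", "ses1/half2"]
        assert ds["ses0/half1"].n_times == recording.n_times // 2
        joined = np.concatenate(
            [ds["ses0/half1"].data, ds["ses0/half2"].data], axis=-1
        )
        assert np.array_equal(joined, recording.data[:, :1])

    def test_segments_30s_from_start_with_leftover(self, recording):
        ds = segment(recording, "segments_30s")
        seg = int(30 * recording.fs)
        assert sorted(k for k in ds if k.startswith("ses0")) == [
            "ses0/seg1", "ses0/seg2", "ses0/seg3",
        ]
        for d in ds.values():
            assert d.n_times == seg
        assert np.array_equal(ds["ses0/seg2"].data, recording.data[:, :1, :, seg : 2 * seg])

    def test_too_short_rejected(self, recording):
        short = recording.slice_time(0, int(89 * recording.fs))
        with pytest.raises(ValueError, match="needs >="):
            segment(short, "segments_30s")
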