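import numpy as np
import pytest

import vepforward as vf
from vepforward.preprocessing import ContinuousRecording
from vepforward.vep_derivation import (
    ComplexSpectrumSet,
    PhaseAxis,
    spectrum_from_epochs,
)


class TestEpochAverage:
    def test_noise_free_average_recovers_kernel(self):
        gt = vf.default_ground_truth(
            areas=("V1",), weights={"V1": 1.0}, noise_amplitude=0.0
        )
        rec = vf.simulate_transient(gt, n_trials=3)
        ev = vf.epoch_average(rec)
        # wedge 0, peak electrode: average equals kernel x topography
        topo = gt.topographies["V1"].values[0]
        e = int(np.argmax(np.abs(topo)))
        sel = ev.times >= 0
        t_k = ev.times[sel]
        expected = topo[e] * vf.evoked_kernel(t_k)
        got = ev.data[0, e, sel]
        assert np.abs(got - expected).max() < 1e-9

    def test_averaging_identical_epochs_is_identity(self):
        fs = 512.0
        rng = np.random.default_rng(0)
        epoch = rng.normal(size=(2, 257))
        data = np.zeros((2, 5000))
        onsets = [500, 1500, 2500]
        for s in onsets:
            data[:, s - 51 : s + 206] = epoch
        rec = ContinuousRecording(fs, data)
        ev = vf.epoch_average(rec, [("flash", s, 0) for s in onsets],
                              n_wedges=1)
        assert np.abs(ev.data[0] - epoch).max() < 1e-12

    def test_grand_average_linearity(self):
        gt = vf.default_ground_truth(
            areas=("V1",), weights={"V1": 1.0}, noise_amplitude=0.0
        )
        rec = vf.simulate_transient(gt, n_trials=2)
        ev = vf.epoch_average(rec)
        ga = vf.grand_average([ev, ev, ev])
        assert np.allclose(ga.data, ev.data)

    def test_empty_wedge_reported(self):
        rec = ContinuousRecording(512.0, np.zeros((1, 5000)))
        with pytest.raises(ValueError, match="wedge 1"):
            vf.epoch_average(rec, [("flash", 1000, 0)], n_wedges=2)


class TestC1Topography:
    def test_constant_evoked(self, layout):
        ev = vf.EvokedSet(
            np.full((16, 128, 257), 3.5),
            np.arange(-51, 206) / 512.0,
            512.0,
            np.ones(16, int),
        )
        topo = vf.c1_topography(ev, layout)
        assert np.allclose(topo.values, 3.5)

    def test_window_outside_epoch_rejected(self, layout):
        ev = vf.EvokedSet(
            np.zeros((16, 128, 10)), np.arange(10) / 512.0, 512.0,
            np.ones(16, int),
        )
        with pytest.raises(ValueError):
            vf.c1_topography(ev, layout, window_ms=(70.0, 80.0))

    def test_v1_generated_c1_matches_prediction(self, predicted):
        gt = vf.default_ground_truth(
            areas=("V1",), weights={"V1": 1.0}, noise_amplitude=0.0
        )
        rec = vf.simulate_transient(gt, n_trials=2)
        topo = vf.c1_topography(vf.epoch_average(rec), gt.layout)
        r = vf.correlate_sets(topo, gt.topographies["V1"])
        assert np.all(r.r_per_wedge > 0.99)

    def test_antisymmetric_kernel_cancels(self, layout):
        times = np.arange(-51, 206) / 512.0
        data = np.zeros((16, 128, len(times)))
        sel = (times >= 0.070) & (times <= 0.080)
        wave = np.linspace(-1, 1, sel.sum())  # odd over the window
        data[:, :, sel] = wave
        ev = vf.EvokedSet(data, times, 512.0, np.ones(16, int))
        topo = vf.c1_topography(ev, layout)
        assert np.abs(topo.values).max() < 1e-9


@pytest.fixture(scope="module")
def small_setup():
    """Orthogonal (non-overlapping) streams: pulses spaced so no two
    epochs intersect -- the regime where both methods are exact."""
    gt = vf.default_ground_truth(
        areas=("V1",), weights={"V1": 1.0}, noise_amplitude=0.0
    )
    from vepforward.stimulus_protocols import PulseStreamSet

    n_streams, n_pulses = 4, 6
    spacing = 60  # frames; 0.8 s > epoch span
    onsets = [
        np.arange(n_pulses) * spacing * n_streams + k * spacing + 10
        for k in range(n_streams)
    ]
    streams = PulseStreamSet(
        75.0, int(onsets[-1][-1] + 80), [o for o in onsets]
    )
    rec = vf.simulate_mfvep(gt, streams)
    return gt, streams, rec


class TestMfvepDeconvolve:
    def test_both_methods_recover_kernel_on_orthogonal_streams(
        self, small_setup
    ):
        gt, streams, rec = small_setup
        t_k = None
        for method in ("average", "regression"):
            ev = vf.mfvep_deconvolve(rec, streams, method=method)
            topo = gt.topographies["V1"].values[0]
            e = int(np.argmax(np.abs(topo)))
            sel = ev.times >= 0
            expected = topo[e] * vf.evoked_kernel(ev.times[sel])
            err = np.abs(ev.data[0, e, sel] - expected).max()
            assert err < 1e-6 * np.abs(expected).max()

    def test_zero_recording_gives_zero_waveforms(self, small_setup):
        gt, streams, rec = small_setup
        silent = rec.copy()
        silent.data[:] = 0.0
        for method in ("average", "regression"):
            ev = vf.mfvep_deconvolve(silent, streams, method=method)
            assert np.abs(ev.data).max() < 1e-12

    def test_degenerate_streams_rejected(self, small_setup):
        gt, streams, rec = small_setup
        from vepforward.stimulus_protocols import PulseStreamSet

        dup = PulseStreamSet(
            75.0, streams.n_frames, [streams.onsets[0], streams.onsets[0]]
        )
        bad = rec.copy()
        bad.events = [
            ("pulse", int(s), k)
            for k in range(2)
            for s in np.round(dup.onsets[k] / 75.0 * 512.0).astype(int)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            vf.mfvep_deconvolve(bad, dup, method="regression")

    def test_unknown_method_rejected(self, small_setup):
        gt, streams, rec = small_setup
        with pytest.raises(ValueError):
            vf.mfvep_deconvolve(rec, streams, method="median")


class TestSsvepSpectrum:
    def test_pure_tone_amplitude_and_phase(self):
        fs = 512.0
        t = np.arange(2048) / fs
        x = 3.0 * np.cos(2 * np.pi * 7.5 * t + 0.7)
        c = spectrum_from_epochs(x, fs, 7.5)
        assert abs(c) == pytest.approx(3.0, abs=1e-9)
        assert np.angle(c) == pytest.approx(0.7, abs=1e-9)

    def test_bin_index_arithmetic(self):
        # 7.5 Hz in a 4-s epoch is DFT bin 30
        assert 7.5 * 4.0 == 30.0
        with pytest.raises(ValueError):
            spectrum_from_epochs(np.zeros(2048), 512.0, 7.9)

    def test_antiphase_epochs_cancel(self):
        fs = 512.0
        t = np.arange(2048) / fs
        a = np.cos(2 * np.pi * 7.5 * t)
        c = spectrum_from_epochs(np.stack([a, -a]), fs, 7.5).mean()
        assert abs(c) < 1e-12

    def test_linearity(self):
        fs = 512.0
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 2048))
        cx = spectrum_from_epochs(x, fs, 7.5)
        cy = spectrum_from_epochs(y, fs, 7.5)
        cxy = spectrum_from_epochs(2 * x + 3 * y, fs, 7.5)
        assert abs(cxy - (2 * cx + 3 * cy)) < 1e-9

    def test_recording_spectrum_recovers_ground_truth(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        rec = vf.simulate_ssvep(gt, n_epochs=1)
        for f in (7.5, 18.75):
            spec = vf.ssvep_spectrum(rec, f, layout=gt.layout, wedges=gt.wedges)
            expected = sum(
                gt.ssvep_mag[a][f]
                * gt.topographies[a].values
                * np.exp(
                    1j * (gt.ssvep_phase[f] - 2 * np.pi * f
                          * gt.ssvep_lags_ms[a] / 1000.0)
                )
                for a in gt.areas
            )
            err = np.abs(spec.values - expected).max()
            assert err < 1e-9 * np.abs(expected).max()


class TestPrincipalPhaseAxis:
    def _set(self, z):
        return ComplexSpectrumSet(7.5, z)

    def test_points_on_a_line(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(16, 8)) * np.exp(1j * np.radians(30))
        ax = vf.principal_phase_axis(self._set(z), reference_wedges=[3, 12])
        assert np.degrees(ax.theta) == pytest.approx(30.0, abs=1e-9)

    def test_antiphase_clusters_share_axis(self):
        z = np.concatenate(
            [np.full(64, np.exp(1j * np.radians(30))),
             np.full(64, np.exp(1j * np.radians(210)))]
        ).reshape(16, 8)
        ax = vf.principal_phase_axis(self._set(z), reference_wedges=[3, 12])
        assert np.degrees(ax.theta) == pytest.approx(30.0, abs=1e-9)

    def test_noisy_line_recovery_within_one_degree(self):
        rng = np.random.default_rng(1)
        mag = rng.normal(size=(16, 128))
        noise = 0.1 * np.abs(mag).mean() * (
            rng.normal(size=(16, 128)) + 1j * rng.normal(size=(16, 128))
        )
        z = mag * np.exp(1j * np.radians(75)) + noise
        ax = vf.principal_phase_axis(self._set(z), reference_wedges=[3, 12])
        assert abs(np.degrees(ax.theta) - 75.0) < 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            vf.principal_phase_axis(self._set(np.zeros((16, 8), complex)))

    def test_polarity_anchored_to_reference_wedges(self, layout, wedges):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(16, 128)) * np.exp(1j * 0.3)
        spec = ComplexSpectrumSet(7.5, z, layout=layout, wedges=wedges)
        ax = vf.principal_phase_axis(spec)
        proj = vf.project_phase(spec, ax)
        refs = [w.index for w in wedges if w.upper_field and w.vm_rank == 4]
        ref_mean = proj.values[refs].mean(axis=0)
        assert ref_mean[np.argmax(np.abs(ref_mean))] < 0


class TestPhaseProjection:
    def test_energy_conservation(self, layout, wedges):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(16, 128)) + 1j * rng.normal(size=(16, 128))
        spec = ComplexSpectrumSet(7.5, z, layout=layout, wedges=wedges)
        ax = PhaseAxis(theta=1.1, polarity_sign=-1)
        p = vf.project_phase(spec, ax, "principal").values
        o = vf.project_phase(spec, ax, "orthogonal").values
        assert np.abs(p**2 + o**2 - np.abs(z) ** 2).max() < 1e-12

    def test_on_axis_coefficient(self, layout, wedges):
        z = np.zeros((16, 128), complex)
        z[0, 0] = 2.0 * np.exp(1j * 0.8)
        z[0, 1] = 1.0  # keep the set non-degenerate
        spec = ComplexSpectrumSet(7.5, z, layout=layout, wedges=wedges)
        ax = PhaseAxis(theta=0.8, polarity_sign=1)
        p = vf.project_phase(spec, ax, "principal").values
        o = vf.project_phase(spec, ax, "orthogonal").values
        assert p[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert o[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_antiphase_coefficients_opposite_sign(self, layout, wedges):
        z = np.zeros((16, 128), complex)
        z[0, 0] = np.exp(1j * 0.5)
        z[0, 1] = np.exp(1j * (0.5 + np.pi))
        spec = ComplexSpectrumSet(7.5, z, layout=layout, wedges=wedges)
        p = vf.project_phase(spec, PhaseAxis(0.5, 1)).values
        assert p[0, 0] * p[0, 1] < 0

    def test_polarity_flip_leaves_correlation_magnitude(
        self, layout, wedges, predicted
    ):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(16, 128)) * np.exp(1j * 0.3)
        spec = ComplexSpectrumSet(7.5, z, layout=layout, wedges=wedges)
        r = []
        for sign in (1, -1):
            proj = vf.project_phase(spec, PhaseAxis(0.3, sign))
            r.append(vf.correlate_sets(proj, predicted["V1"]).r_stacked)
        assert r[0] == pytest.approx(-r[1], abs=1e-12)
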