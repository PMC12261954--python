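import numpy as np
import pytest

import vepforward as vf


class TestNoiseGenerator:
    def test_zero_amplitude_is_silent(self):
        assert not vf.make_noise((4, 1000), amplitude=0.0).any()

    def test_seed_determinism(self, layout):
        a = vf.make_noise((128, 2000), seed=42, layout=layout)
        b = vf.make_noise((128, 2000), seed=42, layout=layout)
        assert np.array_equal(a, b)

    def test_layout_mismatch_rejected(self, layout):
        with pytest.raises(ValueError):
            vf.make_noise((8, 100), layout=layout)

    def test_white_uncorrelated_limit(self):
        n = vf.make_noise(
            (8, 10_000), spatial_corr_len=0.0, spectral_exponent=0.0, seed=0
        )
        c = np.corrcoef(n)
        off = c[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_spectral_exponent_shapes_spectrum(self):
        n = vf.make_noise(
            (1, 65536), spatial_corr_len=0.0, spectral_exponent=1.0, seed=1
        )[0]
        spec = np.abs(np.fft.rfft(n)) ** 2
        freqs = np.fft.rfftfreq(len(n), 1 / 512.0)
        lo = spec[(freqs > 1) & (freqs < 4)].mean()
        hi = spec[(freqs > 64) & (freqs < 256)].mean()
        assert lo > 10 * hi

    def test_amplitude_calibration(self, layout):
        n = vf.make_noise((128, 5000), amplitude=3.0, seed=2, layout=layout)
        assert n.std(axis=1).mean() == pytest.approx(3.0, rel=1e-6)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            vf.make_noise((2, 100), amplitude=-1.0)


class TestTransientSimulation:
    def test_seed_determinism(self):
        gt = vf.default_ground_truth(noise_amplitude=1.0, seed=5)
        a = vf.simulate_transient(gt, n_trials=2)
        b = vf.simulate_transient(gt, n_trials=2)
        assert np.array_equal(a.data, b.data)
        assert a.events == b.events

    def test_trial_counts_and_order_randomised(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0, seed=1)
        rec = vf.simulate_transient(gt, n_trials=3)
        wedge_seq = [w for _, _, w in rec.events]
        counts = np.bincount(wedge_seq, minlength=16)
        assert np.all(counts == 3)
        assert wedge_seq != sorted(wedge_seq)

    def test_extrastriate_kernels_delayed(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        assert gt.kernel_lags_ms == {"V1": 0.0, "V2": 35.0, "V3": 55.0}
        rec = vf.simulate_transient(
            vf.default_ground_truth(
                areas=("V1", "V2"), weights={"V1": 0.0, "V2": 1.0},
                noise_amplitude=0.0,
            ),
            n_trials=1,
        )
        ev = vf.epoch_average(rec)
        # V2-only signal peaks at 75 + 35 = 110 ms
        gav = np.abs(ev.data).max(axis=(0, 1))
        assert ev.times[np.argmax(gav)] * 1000 == pytest.approx(110.0, abs=4)


@pytest.fixture(scope="module")
def streams():
    seq = vf.generate_msequence(10, taps=(10, 3))
    return vf.pulse_streams_from_msequence(
        seq, n_streams=4, stream_lag=255, keep_every=4
    )


class TestMfvepSimulation:
    def test_pulse_counts_match_streams(self, streams):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        rec = vf.simulate_mfvep(gt, streams)
        for k in range(streams.n_streams):
            n = sum(1 for t, _, w in rec.events if t == "pulse" and w == k)
            assert n == streams.onsets_per_stream

    def test_stream_superposition(self, streams):
        """Simulating two single-stream recordings and summing equals the
        joint simulation (linearity of the generator)."""
        from vepforward.stimulus_protocols import PulseStreamSet

        gt = vf.default_ground_truth(noise_amplitude=0.0)
        joint = vf.simulate_mfvep(
            gt,
            PulseStreamSet(75.0, streams.n_frames, streams.onsets[:2]),
        )
        only0 = vf.simulate_mfvep(
            gt, PulseStreamSet(75.0, streams.n_frames, [streams.onsets[0]])
        )
        # the joint run minus the stream-0-only run must equal the pure
        # wedge-1 response train (linearity of the generator)
        residual = joint.data - only0.data
        # rebuild the expected wedge-1 contribution
        expected = np.zeros_like(residual)
        fs = 512.0
        kern_len = int(0.4 * fs)
        t_k = np.arange(kern_len) / fs
        pad = int(fs)
        for a in gt.areas:
            kern = gt.weights[a] * vf.evoked_kernel(
                t_k - gt.kernel_lags_ms[a] / 1000.0
            )
            topo = gt.topographies[a].values[1]
            for f in streams.onsets[1]:
                s = pad + int(round(f / 75.0 * fs))
                expected[:, s : s + kern_len] += np.outer(topo, kern)
        assert np.abs(residual - expected).max() < 1e-9

    def test_seed_determinism(self, streams):
        gt = vf.default_ground_truth(noise_amplitude=2.0, seed=7)
        a = vf.simulate_mfvep(gt, streams)
        b = vf.simulate_mfvep(gt, streams)
        assert np.array_equal(a.data, b.data)


class TestSsvepSimulation:
    def test_spectrum_recovery_noise_free(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        rec = vf.simulate_ssvep(gt, n_epochs=1)
        spec = vf.ssvep_spectrum(rec, 18.75, layout=gt.layout,
                                 wedges=gt.wedges)
        expected = sum(
            gt.ssvep_mag[a][18.75]
            * gt.topographies[a].values
            * np.exp(1j * (gt.ssvep_phase[18.75]
                           - 2 * np.pi * 18.75 * gt.ssvep_lags_ms[a] / 1000.0))
            for a in gt.areas
        )
        assert np.abs(spec.values - expected).max() < 1e-9

    def test_onset_transient_excluded_by_discard_window(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        with_onset = vf.simulate_ssvep(gt, n_epochs=1, onset_transient=True)
        without = vf.simulate_ssvep(gt, n_epochs=1, onset_transient=False)
        for f in (7.5, 18.75):
            a = vf.ssvep_spectrum(with_onset, f, layout=gt.layout).values
            b = vf.ssvep_spectrum(without, f, layout=gt.layout).values
            assert np.abs(a - b).max() < 1e-9

    def test_paired_opposite_wedges_do_not_contaminate(self):
        """Two wedges 180 degrees apart flicker simultaneously at the two
        frequencies; integer cycles in 4 s keep their spectral bins
        orthogonal."""
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        paired = vf.simulate_ssvep(gt, n_epochs=1, pair_opposite=True)
        solo = vf.simulate_ssvep(gt, n_epochs=1, pair_opposite=False)
        for f in (7.5, 18.75):
            a = vf.ssvep_spectrum(paired, f, layout=gt.layout).values
            b = vf.ssvep_spectrum(solo, f, layout=gt.layout).values
            assert np.abs(a - b).max() < 1e-8

    def test_missing_magnitude_rejected(self):
        gt = vf.default_ground_truth(noise_amplitude=0.0)
        with pytest.raises(ValueError):
            vf.simulate_ssvep(gt, frequencies=(7.5, 12.8))


class TestGroundTruthValidation:
    def test_lag_bounds_enforced(self):
        with pytest.raises(ValueError):
            gt = vf.default_ground_truth()
            vf.GroundTruth(
                topographies=gt.topographies,
                weights=gt.weights,
                kernel_lags_ms={"V1": 0.0, "V2": 80.0, "V3": 55.0},
                ssvep_mag=gt.ssvep_mag,
                ssvep_lags_ms=gt.ssvep_lags_ms,
                ssvep_phase=gt.ssvep_phase,
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            vf.default_ground_truth(noise_amplitude=-1.0)


class TestRecordingIO:
    def test_hdf5_round_trip(self, tmp_path):
        gt = vf.default_ground_truth(noise_amplitude=1.0, seed=3)
        rec = vf.simulate_transient(gt, n_trials=1)
        path = tmp_path / "rec.h5"
        vf.save_recording(rec, path)
        back = vf.load_recording(path)
        assert np.allclose(back.data, rec.data)
        assert back.events == rec.events
        assert back.sample_rate == rec.sample_rate
        assert back.channel_ids == rec.channel_ids


class TestEndToEndHeadline:
    def test_v1_single_area_r2_dominates_all_four_signals(self, predicted):
        """With Table-1-patterned generating weights, the V1 single-area
        stacked R^2 exceeds V2's and V3's for the transient C1, the
        multifocal C1 and both steady-state signals."""
        preds = list(predicted.values())

        def r2s(obs):
            des = vf.stack_and_zscore(obs, preds)
            return {a: vf.fit_model(des, (a,)).r2 for a in predicted}

        results = {}
        gt = vf.default_ground_truth(noise_amplitude=2.0, seed=0)
        # transient
        rec = vf.simulate_transient(gt, n_trials=10)
        results["transient"] = r2s(
            vf.c1_topography(vf.epoch_average(rec), gt.layout)
        )
        # multifocal
        streams = vf.pulse_streams_from_msequence(vf.generate_msequence(12))
        mrec = vf.detrend_segments(vf.simulate_mfvep(gt, streams), 0.5)
        mev = vf.mfvep_deconvolve(mrec, streams, method="average")
        results["mfvep"] = r2s(vf.c1_topography(mev, gt.layout))
        # steady state, both frequencies
        srec = vf.simulate_ssvep(gt, n_epochs=1)
        for f in (7.5, 18.75):
            spec = vf.ssvep_spectrum(srec, f, layout=gt.layout,
                                     wedges=gt.wedges)
            axis = vf.principal_phase_axis(spec)
            results[f"ssvep_{f:g}"] = r2s(vf.project_phase(spec, axis))
        for name, rr in results.items():
            assert rr["V1"] > rr["V2"], name
            assert rr["V1"] > rr["V3"], name
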