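"""Preprocessing chain: filtering, epoching, rejection, CSD, averaging."""

import numpy as np
import pytest

from erpgan.datasets import GO, NOGO, ChannelLayout, ERPDataset
from erpgan.preprocessing import (
    CsdSpec,
    EpochSpec,
    Epochs,
    FilterSpec,
    RejectionCriteria,
    _window_len,
    artifact_flags,
    average_and_crop,
    bandpass_filter,
    baseline_correct,
    combine_subjects,
    csd_matrix,
    csd_transform,
    design_filter,
    downsample,
    filter_gain_db,
    interpolate_electrode,
    interpolation_weights,
    preprocess_session,
    reject_artifacts,
    segment,
)
from erpgan.simulate import (
    TaskDesign,
    generate_single_trial_eeg,
    make_scenario,
    subject_template,
)


class TestFilter:
    def test_slope_maps_to_order(self):
        assert FilterSpec().order == 8  # 48 dB/oct at 6 dB/oct/order
        with pytest.raises(ValueError, match="multiple of 6"):
            FilterSpec(slope_db_oct=50)
        with pytest.raises(ValueError, match="highpass"):
            FilterSpec(highpass_hz=20.0, lowpass_hz=18.0)

    def test_dc_removed(self):
        x = np.full((2, 2000), 7.0)
        y = bandpass_filter(x, 256.0)
        assert np.abs(y[:, 200:-200]).max() < 1e-6 * 7.0

    def test_passband_gain_near_unity(self):
        # evaluate the designed transfer function at 5 Hz
        gain = 10 ** (filter_gain_db(FilterSpec(), 256.0, 5.0) / 20)
        assert 0.95 < gain < 1.05

    def test_stopband_attenuation_one_octave(self):
        spec = FilterSpec()
        rel = filter_gain_db(spec, 256.0, 36.0) - filter_gain_db(spec, 256.0, 9.0)
        assert rel <= -40.0

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            design_filter(FilterSpec(), 30.0)

    def test_zero_phase_no_lag(self):
        t = np.arange(4000) / 256.0
        x = np.sin(2 * np.pi * 5.0 * t)
        y = bandpass_filter(x, 256.0)
        mid = slice(1000, 3000)
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert lag == 0


class TestDownsample:
    def test_length_arithmetic(self):
        out = downsample(np.zeros(2000), 500.0, 256.0)
        assert out.shape[-1] == 1024

    def test_sine_preserved(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = downsample(x, 500.0, 256.0)
        spec = np.abs(np.fft.rfft(y[200:-200]))
        freqs = np.fft.rfftfreq(y[200:-200].size, 1 / 256.0)
        assert abs(freqs[np.argmax(spec)] - 10.0) < 0.2
        assert abs(y[500:-500].max() - 1.0) < 0.01

    def test_constant_preserved_and_bad_target(self):
        # constant up to the polyphase FIR's passband ripple
        np.testing.assert_allclose(downsample(np.full(1000, 3.0), 500.0, 256.0)[10:-10],
                                   3.0, rtol=1e-3)
        with pytest.raises(ValueError, match="below"):
            downsample(np.zeros(100), 256.0, 256.0)


class TestSegment:
    def _recording(self, n_trials=450, **kwargs):
        scenario = make_scenario("paper_like", n_subjects=2, seed=1)
        return generate_single_trial_eeg(TaskDesign(n_trials=n_trials), scenario,
                                         seed=2, **kwargs)

    def test_all_correct_yields_design_counts(self, small_scenario):
        from erpgan.simulate import BehaviorModel

        rec = generate_single_trial_eeg(
            TaskDesign(n_trials=450), small_scenario, seed=2,
            behavior=BehaviorModel(go_accuracy=1.0, nogo_false_alarm=0.0),
        )
        epochs = segment(rec)
        assert epochs.n_epochs(GO) == 315
        assert epochs.n_epochs(NOGO) == 135
        assert epochs.t0_ms == -2000.0

    def test_behavioral_exclusions(self, small_scenario):
        rec = generate_single_trial_eeg(TaskDesign(n_trials=60), small_scenario, seed=4)
        # flag one Go trial as responding after the 1200 ms deadline
        go_idx = next(i for i, t in enumerate(rec.trials) if t.condition == GO)
        rec.trials[go_idx].rt_ms = 1300.0
        n_correct_go = sum(
            t.condition == GO and t.correct and t.rt_ms is not None and t.rt_ms < 1200.0
            for t in rec.trials
        )
        epochs = segment(rec)
        assert epochs.n_epochs(GO) == n_correct_go
        assert epochs.log["behavior_excluded"] >= 1

    def test_edge_marker_dropped(self, small_scenario):
        rec = generate_single_trial_eeg(TaskDesign(n_trials=10), small_scenario,
                                        seed=5, edge_pad_ms=3000.0)
        rec.onsets[0] = 0  # marker at the very first sample: no pre-stimulus data
        epochs = segment(rec)
        assert epochs.log["edge_dropped"] == 1


class TestRejection:
    fs = 256.0

    def brute_force(self, epoch, criteria=RejectionCriteria()):
        """Window-by-window scan, independent of the production code."""
        n_ch, n_t = epoch.shape
        w200, w100 = _window_len(200.0, self.fs), _window_len(100.0, self.fs)
        fired = set()
        for c in range(n_ch):
            x = epoch[c]
            if any(abs(x[i + 1] - x[i]) > criteria.max_step for i in range(n_t - 1)):
                fired.add("step")
            if any(x[i:i + w200].max() - x[i:i + w200].min() > criteria.max_diff_200ms
                   for i in range(n_t - w200 + 1)):
                fired.add("diff_200ms")
            if np.abs(x).max() > criteria.abs_limit:
                fired.add("amplitude")
            if any(x[i:i + w100].max() - x[i:i + w100].min() < criteria.min_range_100ms
                   for i in range(n_t - w100 + 1)):
                fired.add("flat_100ms")
        return fired

    def test_all_zero_epoch_removed(self):
        flags = artifact_flags(np.zeros((2, 300)), self.fs)
        assert flags["flat_100ms"] and not flags["amplitude"]

    def test_single_60uv_step_removed(self):
        rng = np.random.default_rng(0)
        epoch = rng.normal(0, 3.0, size=(3, 300))
        epoch[1, 150:] += 60.0  # one adjacent-sample jump above the 50 µV rule
        assert artifact_flags(epoch, self.fs)["step"]

    def test_10uv_sine_kept(self):
        t = np.arange(300) / self.fs
        epoch = 10.0 * np.sin(2 * np.pi * 5.0 * t)[None, :]
        assert not any(artifact_flags(epoch, self.fs).values())

    def test_oracle_agreement_on_random_epochs(self, rng):
        """Production rules match the brute-force scan on 100 random epochs."""
        criteria = RejectionCriteria()
        for _ in range(100):
            kind = rng.integers(0, 4)
            scale = [0.2, 3.0, 35.0, 55.0][kind]
            epoch = rng.normal(0, scale, size=(4, 256))
            if kind == 3:
                epoch = np.cumsum(epoch, axis=-1) / 6  # drifting walk
            flags = artifact_flags(epoch, self.fs, criteria)
            assert {k for k, v in flags.items() if v} == self.brute_force(epoch, criteria)

    def test_whole_epoch_any_channel_semantics(self):
        epochs_arr = np.random.default_rng(3).normal(0, 5.0, size=(4, 2, 300))
        epochs_arr[2, 1, 100] = 300.0  # amplitude violation on one channel only
        ep = Epochs({GO: epochs_arr, NOGO: epochs_arr[:0]}, self.fs, -200.0,
                    ChannelLayout.standard(("Cz", "Fz")))
        kept = reject_artifacts(ep)
        assert kept.n_epochs(GO) == 3
        log = kept.log["rejection"][GO]
        assert log["rejected"][0][0] == 2 and "amplitude" in log["rejected"][0][1]


class TestBaselineAndAverage:
    def _epochs(self, data, fs=256.0):
        n_ch = data.shape[1]
        names = ("Fz", "Cz", "Pz", "Oz")[:n_ch]
        return Epochs({GO: data, NOGO: data.copy()}, fs, -2000.0,
                      ChannelLayout.standard(names))

    def test_baseline_window_mean_zero(self, rng):
        ep = self._epochs(rng.normal(2.0, 5.0, size=(6, 2, 1024)))
        out = baseline_correct(ep)
        sl = slice(int(1800 * 256 / 1000), int(2000 * 256 / 1000))
        assert np.abs(out.data[GO][..., sl].mean(axis=-1)).max() < 1e-12

    def test_constant_epoch_zeroed(self):
        ep = self._epochs(np.full((1, 2, 1024), 7.0))
        np.testing.assert_allclose(baseline_correct(ep).data[GO], 0.0, atol=1e-12)

    def test_offset_removed_template_recovered(self, rng):
        tmpl = np.sin(np.linspace(0, 6 * np.pi, 1024))[None, None, :] * np.ones((4, 2, 1))
        tmpl -= tmpl[..., :512].mean(axis=-1, keepdims=True)
        out = baseline_correct(self._epochs(tmpl + 3.0), window_ms=(-2000.0, 0.0))
        np.testing.assert_allclose(out.data[GO], tmpl, atol=1e-12)

    def test_average_shapes_and_crop(self, rng):
        data = rng.normal(size=(10, 2, 1024))
        ds = average_and_crop(self._epochs(data))
        assert ds.n_times == 256  # 0-1000 ms at 256 Hz, half-open
        assert ds.t0_ms == 0.0
        np.testing.assert_allclose(
            ds.data[GO][0], data.mean(axis=0)[:, 512:768], atol=1e-12)

    def test_identical_epochs_average_to_one(self, rng):
        single = rng.normal(size=(1, 2, 1024))
        data = np.repeat(single, 5, axis=0)
        ds = average_and_crop(self._epochs(data))
        np.testing.assert_allclose(ds.data[GO][0], single[0][:, 512:768], atol=1e-12)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        sds = []
        for n in (8, 32):
            data = rng.normal(size=(n, 2, 1024))
            sds.append(average_and_crop(self._epochs(data)).data[GO].std())
        assert abs(sds[0] / sds[1] - 2.0) < 0.35

    def test_empty_condition_raises(self):
        ep = Epochs({GO: np.zeros((0, 2, 1024)), NOGO: np.zeros((1, 2, 1024))},
                    256.0, -2000.0, ChannelLayout.standard(("Cz", "Fz")))
        with pytest.raises(ValueError, match="no surviving epochs"):
            average_and_crop(ep)


class TestCsd:
    def test_constant_map_is_zero(self):
        layout = ChannelLayout.standard()
        out = csd_matrix(layout) @ np.ones(layout.n_channels)
        assert np.abs(out).max() < 1e-8

    def test_linearity(self, paper_like_cohort):
        a = paper_like_cohort
        b = a.copy()
        b.data[GO] = b.data[GO][::-1]
        b.data[NOGO] = b.data[NOGO][::-1]
        lhs = csd_transform(a).data[GO] + csd_transform(b).data[GO]
        summed = a.copy()
        summed.data[GO] = a.data[GO] + b.data[GO]
        np.testing.assert_allclose(lhs, csd_transform(summed).data[GO], atol=1e-9)

    def test_center_surround_sign(self):
        """A single positive deflection maps to a source with a negative ring."""
        layout = ChannelLayout.standard_60()
        # sharp operator (long Legendre series, light regularization) so the
        # surround of a point source is resolved
        op = csd_matrix(layout, CsdSpec(legendre_degree=50, precision=1e-5))
        cz = layout.index("Cz")
        v = np.zeros(60)
        v[cz] = 1.0
        out = op @ v
        assert out[cz] > 0 and out[cz] == out.max()
        dists = np.linalg.norm(layout.pos2d - layout.pos2d[cz], axis=1)
        # the sink ring sits just beyond the electrodes inside the positive lobe
        ring = np.flatnonzero((dists > 0.55) & (dists < 0.85))
        assert ring.size >= 4 and (out[ring] < 0).all()

    def test_matches_reference_spherical_spline_implementation(self, rng):
        """Independent oracle: the spherical-spline CSD shipped with mne."""
        import mne

        layout = ChannelLayout.standard_60()
        data = rng.normal(size=(60, 5))
        spec = CsdSpec(legendre_degree=50, precision=1e-5, head_radius_m=1.0)
        ds = ERPDataset(["S0"], {GO: data[None]}, 256.0, 0.0, layout)
        mine = csd_transform(ds, spec).data[GO][0]
        info = mne.create_info(layout.names, 256.0, "eeg")
        mont = mne.channels.make_dig_montage(
            ch_pos=dict(zip(layout.names, layout.pos3d)), coord_frame="head")
        evk = mne.EvokedArray(data.copy(), info)
        evk.set_montage(mont)
        ref = mne.preprocessing.compute_current_source_density(
            evk, sphere=(0.0, 0.0, 0.0, 1.0), lambda2=1e-5, stiffness=4,
            n_legendre_terms=50).get_data()
        np.testing.assert_allclose(mine, ref, rtol=1e-6, atol=1e-9)

    def test_units_updated(self, paper_like_cohort):
        assert csd_transform(paper_like_cohort).units == "uV/m2"


class TestInterpolation:
    def test_constant_field_preserved(self):
        layout = ChannelLayout.standard_60()
        w = interpolation_weights(layout, "FCz")
        assert abs(w.sum() - 1.0) < 1e-9  # constant maps to the constant

    def test_smooth_field_error_small(self):
        """Interpolating a low-order spherical harmonic field."""
        layout = ChannelLayout.standard_60()
        field = layout.pos3d[:, 2] + 0.5 * layout.pos3d[:, 0] * layout.pos3d[:, 2]
        w = interpolation_weights(layout, "FCz")
        ti = layout.index("FCz")
        err = abs(w @ field - field[ti])
        assert err < 0.05 * (field.max() - field.min())

    def test_linear_in_data(self, rng):
        layout = ChannelLayout.standard_60()
        w = interpolation_weights(layout, "Cz")
        a, b = rng.normal(size=(2, 60))
        assert abs((w @ (a + b)) - (w @ a + w @ b)) < 1e-12

    def test_matches_reference_interpolation_matrix(self):
        from mne.channels.interpolation import _make_interpolation_matrix

        layout = ChannelLayout.standard_60()
        ti = layout.index("FCz")
        good = [i for i in range(60) if i != ti]
        ref = np.zeros(60)
        ref[good] = _make_interpolation_matrix(
            layout.pos3d[good], layout.pos3d[[ti]])[0]
        np.testing.assert_allclose(interpolation_weights(layout, "FCz"), ref, atol=1e-8)

    def test_missing_target_rejected(self, paper_like_cohort):
        with pytest.raises(KeyError):
            interpolate_electrode(paper_like_cohort, "XX9")


class TestEndToEnd:
    def test_template_recovery_through_full_chain(self):
        """40 trials/condition recover the band-limited templates (r > 0.95)."""
        scenario = make_scenario("paper_like", n_subjects=2, seed=9)
        design = TaskDesign(n_trials=133)  # ~40 Nogo at the 70/30 ratio
        from erpgan.simulate import BehaviorModel

        rec = generate_single_trial_eeg(
            design, scenario, seed=12,
            behavior=BehaviorModel(go_accuracy=1.0, nogo_false_alarm=0.0),
        )
        ds = preprocess_session(rec, subject="S000")
        for cond in (GO, NOGO):
            # reference: the template as the linear chain preserves it --
            # band-limited in continuous context, then baseline-corrected
            tmpl = subject_template(scenario, cond)
            pad = np.zeros((tmpl.shape[0], 256 * 9))
            pad[:, 256 * 4 : 256 * 5] = tmpl
            filt = bandpass_filter(pad, 256.0)
            filt -= filt[:, 256 * 4 - 51 : 256 * 4].mean(axis=1, keepdims=True)
            ref = filt[:, 256 * 4 : 256 * 5]
            rec_avg = ds.data[cond][0]
            r = np.corrcoef(rec_avg.ravel(), ref.ravel())[0, 1]
            assert r > 0.95

    def test_injected_artifact_trial_rejected_alone(self):
        """A >50 µV step removes exactly the injected trial (raw-level rules)."""
        scenario = make_scenario("paper_like", n_subjects=2, seed=9)
        design = TaskDesign(n_trials=12, iti_range_ms=(2600.0, 2900.0))
        rec = generate_single_trial_eeg(
            design, scenario, seed=3, artifacts=[(5, "step")],
            noise_sd_white=2.0, noise_sd_pink=2.0,
        )
        epochs = segment(rec)
        kept = reject_artifacts(epochs)
        cond = rec.trials[5].condition
        n_cond_markers = sum(
            t.condition == cond and (t.correct and (t.rt_ms is None) == (cond == NOGO))
            for t in rec.trials
        )
        rej = kept.log["rejection"]
        total_rejected = sum(len(v["rejected"]) for v in rej.values())
        assert total_rejected == 1
        assert rej[cond]["n_kept"] == rej[cond]["n_in"] - 1

    def test_superposition_through_linear_stages(self, rng):
        """Filter/downsample/baseline/CSD are jointly linear."""
        layout = ChannelLayout.standard()
        a = rng.normal(size=(8, 2000))
        b = rng.normal(size=(8, 2000))

        def chain(x):
            y = downsample(x, 500.0, 256.0)
            y = bandpass_filter(y, 256.0)
            y = y - y[:, :50].mean(axis=1, keepdims=True)
            return csd_matrix(layout) @ y

        np.testing.assert_allclose(chain(a) + chain(b), chain(a + b), atol=1e-8)
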