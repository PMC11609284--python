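"""EEG pipeline: preprocessing, epoching, rejection, CFA correction,
component ranking/removal, ROI extraction."""

import numpy as np
import pandas as pd
import pytest

from cardiostop.eeg import (
    CfaTemplate,
    EpochSet,
    decompose_session,
    estimate_cfa,
    extract_epochs,
    preprocess,
    r_locked_power,
    rank_components_by_ecg_coherence,
    reject_epochs,
    remove_components,
    roi_mean_amplitude,
    subtract_cfa,
)
from cardiostop.eeg import ComponentSet
from cardiostop.montage import load_montage, subset_montage
from cardiostop.pipeline import component_epochs
from cardiostop.simulate import (
    cfa_pattern,
    default_cfa_waveform,
    render_eeg,
    simulate_rr_series,
    simulate_session,
)

from conftest import mini_config

FS = 250.0
CH8 = ["Fz", "FCz", "Cz", "CPz", "Pz", "C3", "C4", "T7"]


@pytest.fixture(scope="module")
def montage8():
    return subset_montage(load_montage(), CH8)


@pytest.fixture(scope="module")
def cfa_only(montage8):
    """Pure R-locked artifact on 8 channels, no noise, no ERPs."""
    tl = simulate_rr_series(58.2, 53.5, 150, rng=11, start_time=3.0)
    n = int((tl.r_peak_times[-1] + 3.0) * FS)
    ev = pd.DataFrame(columns=["event_type", "time_s", "condition", "outcome"])
    eeg, _ = render_eeg(
        ev, [], montage8, FS, n,
        cfa_waveform=default_cfa_waveform(FS), r_peak_times=tl.r_peak_times,
    )
    return eeg, tl


class TestPreprocess:
    def test_average_reference_zero_channel_mean(self, rng):
        x = rng.standard_normal((6, 4000))
        out = preprocess(x, FS)
        assert np.max(np.abs(out.mean(axis=0))) < 1e-9

    def test_common_signal_annihilated(self):
        t = np.arange(4000) / FS
        common = np.sin(2 * np.pi * 7 * t)
        x = np.tile(common, (5, 1))
        out = preprocess(x, FS)
        assert np.max(np.abs(out)) < 1e-9

    def test_50hz_attenuated_20db(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.vstack([np.sin(2 * np.pi * 50 * t), -np.sin(2 * np.pi * 50 * t)])
        out = preprocess(x, FS, rereference=False)
        core = slice(2000, -2000)
        ratio = np.sqrt(np.mean(out[0, core] ** 2)) / np.sqrt(np.mean(x[0, core] ** 2))
        assert ratio < 0.1

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((1, 100)), FS)


class TestEpoching:
    def test_constant_channel_zero_after_baseline(self):
        x = np.full((2, 2000), 5.0)
        ep = extract_epochs(x, FS, ["a", "b"], np.array([4.0]))
        assert np.allclose(ep.data, 0.0)
        assert np.max(np.abs(ep.data[:, :, : int(0.1 * FS)].mean(axis=2))) < 1e-9

    def test_underrunning_event_dropped(self):
        x = np.zeros((2, 2000))
        ep = extract_epochs(x, FS, ["a", "b"], np.array([0.0, 4.0]))
        assert ep.n_epochs == 1 and ep.n_dropped == 1

    def test_injected_template_roundtrip(self, montage8):
        """Forward-model round-trip: with no noise the baseline-corrected
        epoch equals the injected waveform exactly."""
        from cardiostop.montage import gaussian_scalp_pattern
        from cardiostop.simulate import ErpTemplate

        tpl = ErpTemplate(
            "p", "go_cue", (200.0, 400.0), 3.0,
            gaussian_scalp_pattern(montage8, ["Cz"], 25.0), {"none": 1.0},
        )
        ev = pd.DataFrame(
            {"event_type": ["go_cue"], "time_s": [3.0], "condition": ["none"], "outcome": [""]}
        )
        eeg, _ = render_eeg(ev, [tpl], montage8, FS, int(6 * FS))
        ep = extract_epochs(eeg, FS, CH8, np.array([3.0]), window_ms=(-100.0, 1000.0))
        wave = tpl.waveform(FS)
        j0 = int(round((200.0 + 100.0) * FS / 1000.0))
        i = CH8.index("Cz")
        assert np.allclose(ep.data[0, i, j0 : j0 + len(wave)],
                           tpl.channel_weights[i] * wave, atol=1e-12)

    def test_first_n_per_trial_selection(self):
        x = np.zeros((2, 8000))
        times = np.array([2.0, 3.0, 4.0, 5.0, 2.5, 3.5])
        tids = np.array([1, 1, 1, 1, 2, 2])
        ep = extract_epochs(x, FS, ["a", "b"], times, trial_ids=tids, first_n_per_trial=3)
        assert ep.n_epochs == 5
        assert 5.0 not in ep.event_times_s


class TestRejection:
    def _epochs(self, data):
        return EpochSet(data, (-100.0, 1000.0), (0.0, 0.0), FS,
                        [f"c{i}" for i in range(data.shape[1])])

    def test_threshold_rule(self):
        n = int(1.1 * FS)
        data = np.zeros((3, 2, n))
        data[1, 0, 50] = 101.0
        kept, rate = reject_epochs(self._epochs(data))
        assert kept.n_epochs == 2 and rate == pytest.approx(1 / 3)

    def test_at_threshold_kept(self):
        n = int(1.1 * FS)
        data = np.full((4, 2, n), 99.0)
        kept, rate = reject_epochs(self._epochs(data))
        assert kept.n_epochs == 4 and rate == 0.0

    def test_constructed_two_percent_rate(self, rng):
        n = int(1.1 * FS)
        data = rng.standard_normal((100, 3, n))
        data[[7, 42], 1, 10] = 150.0
        kept, rate = reject_epochs(self._epochs(data))
        assert rate == pytest.approx(0.02) and kept.n_epochs == 98


class TestCfa:
    def test_template_recovers_artifact_and_subtraction_kills_power(self, cfa_only, montage8):
        eeg, tl = cfa_only
        p0 = r_locked_power(eeg, FS, tl)
        tpl = estimate_cfa(eeg, FS, tl, n_triggers=400, rng=3)
        assert tpl.counts["systole"] >= 10 and tpl.counts["diastole"] >= 10
        # template around R reproduces the artifact shape
        wave, start_ms = default_cfa_waveform(FS)
        i = CH8.index("T7")
        k0 = int(round((start_ms + 1000.0) * FS / 1000.0))
        got = tpl.data["systole"][i, k0 : k0 + len(wave)]
        want = cfa_pattern(montage8)[i] * wave
        assert np.corrcoef(got, want)[0, 1] > 0.99
        for phase in ("systole", "diastole"):
            corrected = subtract_cfa(eeg, FS, tpl, tl, phase=phase)
            assert r_locked_power(corrected, FS, tl) < 0.1 * p0

    def test_zero_data_zero_template(self, montage8):
        tl = simulate_rr_series(60.0, 0.0, 50, rng=0, start_time=3.0)
        eeg = np.zeros((8, int((tl.r_peak_times[-1] + 3) * FS)))
        tpl = estimate_cfa(eeg, FS, tl, n_triggers=100, rng=0)
        assert not tpl.data["systole"].any() and not tpl.data["diastole"].any()

    def test_pre_anchor_baseline_near_zero(self, cfa_only):
        eeg, tl = cfa_only
        tpl = estimate_cfa(eeg, FS, tl, n_triggers=300, rng=1)
        b0 = int(round(900 * FS / 1000.0))  # -100..0 ms within (-1000, 2000)
        b1 = int(round(1000 * FS / 1000.0))
        for phase in ("systole", "diastole"):
            assert np.max(np.abs(tpl.data[phase][:, b0:b1].mean(axis=1))) < 1e-9

    def test_more_triggers_reduce_template_variance(self, montage8):
        """Monte-Carlo: doubling the trigger count shrinks the noise
        variance of the estimated template."""
        tl = simulate_rr_series(60.0, 30.0, 120, rng=2, start_time=3.0)
        n = int((tl.r_peak_times[-1] + 3) * FS)
        var = {50: [], 200: []}
        for seed in range(6):
            noise = np.random.default_rng(seed).normal(0, 5.0, (4, n))
            for n_trig in var:
                tpl = estimate_cfa(noise[:, :], FS, tl, n_triggers=n_trig, rng=seed + 100)
                var[n_trig].append(np.var(tpl.data["diastole"]))
        assert np.mean(var[200]) < np.mean(var[50])

    def test_subtracting_own_template_is_identity_elsewhere(self, cfa_only):
        eeg, tl = cfa_only
        tpl = estimate_cfa(eeg, FS, tl, n_triggers=400, rng=3)
        corrected = subtract_cfa(eeg, FS, tpl, tl, phase="systole")
        assert np.max(np.abs(corrected)) < 0.15 * np.max(np.abs(eeg))

    def test_channel_mismatch_rejected(self, cfa_only):
        eeg, tl = cfa_only
        tpl = estimate_cfa(eeg, FS, tl, n_triggers=100, rng=0)
        with pytest.raises(ValueError):
            subtract_cfa(eeg[:4], FS, tpl, tl, phase="systole")

    def test_vep_roi_unchanged_when_windows_disjoint(self):
        """Orthogonality: when the movement epochs (baseline and ROI) lie
        entirely beyond the subtracted artifact support, CFA correction
        leaves the P2 ROI amplitude exactly unchanged (noise-free
        session, coupling offset pushed to R+550 ms to create the gap)."""
        cfg = mini_config(
            trials_per_block=8, go_per_block=5, stop_per_block=3,
            noise_sd_uv=0.0, ecg_noise_sd_uv=0.0, trigger_jitter_sd_ms=0.0,
            systole_offset_ms=550.0, rmssd_ms=10.0,
        )
        s = simulate_session(cfg, seed=55)
        periods = list(zip(s.trials["trial_start_s"], s.trials["go_cue_time_s"]))
        tpl = estimate_cfa(s.eeg, s.fs, s.timeline, 300, rng=1, periods=periods)
        corrected = subtract_cfa(s.eeg, s.fs, tpl, s.timeline, phase="systole")
        from cardiostop.eeg import ROI_DEFINITIONS

        roi = ROI_DEFINITIONS["p2"]
        chans = [c for c in roi["channels"] if c in s.channels]
        before = roi_mean_amplitude(
            component_epochs(s, "p2", "systole", eeg=s.eeg), chans, roi["window_ms"]
        )
        after = roi_mean_amplitude(
            component_epochs(s, "p2", "systole", eeg=corrected), chans, roi["window_ms"]
        )
        assert np.allclose(before, after, atol=1e-9)


class TestComponents:
    def test_decompose_reconstruct_lossless(self, noisy_mini_session):
        comp = decompose_session(noisy_mini_session)
        recon = comp.reconstruct()
        err = np.linalg.norm(recon - noisy_mini_session.eeg) / np.linalg.norm(
            noisy_mini_session.eeg
        )
        assert err < 1e-6

    def test_remove_none_restores_input(self, noisy_mini_session):
        comp = decompose_session(noisy_mini_session)
        assert np.allclose(remove_components(comp, []), noisy_mini_session.eeg)

    def test_remove_one_source_leaves_other(self, montage8, rng):
        n = 5000
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        m1 = np.linspace(1, 2, 8)
        m2 = np.linspace(2, -1, 8)
        data = np.outer(m1, s1) + np.outer(m2, s2)
        comp = ComponentSet(
            sources=np.vstack([s1, s2]), mixing=np.column_stack([m1, m2]),
            names=["a", "b"], residual=np.zeros((8, n)), data=data,
        )
        only_a = remove_components(comp, [1])
        assert np.allclose(only_a, np.outer(m1, s1), atol=1e-10)

    def test_ecg_itself_ranks_first(self, rng):
        from cardiostop.simulate import simulate_rr_series, synthesize_ecg

        tl = simulate_rr_series(60.0, 20.0, 60, rng=1)
        ecg = synthesize_ecg(tl, FS)
        n = len(ecg.samples)
        noise = rng.standard_normal(n)
        comp = ComponentSet(
            sources=np.vstack([noise, ecg.samples]),
            mixing=np.ones((4, 2)), names=["noise", "ecg"],
            residual=np.zeros((4, n)),
        )
        ranked = rank_components_by_ecg_coherence(comp, ecg.samples, FS)
        assert ranked.order[0] == 1
        assert ranked.coherence[1] > 0.99
        assert ranked.coherence[0] < 0.5

    def test_constant_component_ranked_last(self, rng):
        n = 4000
        ecg = rng.standard_normal(n)
        comp = ComponentSet(
            sources=np.vstack([np.full(n, 3.0), ecg]),
            mixing=np.ones((3, 2)), names=["const", "ecg"],
            residual=np.zeros((3, n)),
        )
        ranked = rank_components_by_ecg_coherence(comp, ecg, FS)
        assert ranked.order[-1] == 0

    def test_r_locked_source_ranked_first_in_session(self, noisy_mini_session):
        comp = decompose_session(noisy_mini_session)
        ranked = rank_components_by_ecg_coherence(
            comp, noisy_mini_session.ecg.samples, noisy_mini_session.fs
        )
        assert comp.names[ranked.order[0]] in ("cfa", "hep")

    def test_blind_ica_hook_separates_and_reconstructs(self, montage8, rng):
        from cardiostop.eeg import decompose_ica

        n = 6000
        t = np.arange(n) / FS
        s1 = np.sign(np.sin(2 * np.pi * 3 * t))
        s2 = rng.laplace(size=n)
        data = np.outer(np.linspace(1, 2, 8), s1) + np.outer(np.linspace(2, -1, 8), s2)
        comp = decompose_ica(data, n_components=2, rng=0)
        assert np.allclose(comp.reconstruct(), data, atol=1e-8)
        # each recovered source matches one true source up to sign/scale
        corr = np.abs(np.corrcoef(np.vstack([comp.sources, s1, s2]))[:2, 2:])
        assert corr.max(axis=1).min() > 0.95

    def test_removing_hep_source_empties_roi(self):
        """Known-truth injection: deleting the heartbeat-evoked component
        zeroes the HEP ROI amplitude (no artifact, no noise)."""
        gains = {
            "hep": {"systole": 1.0, "diastole": 1.0, "none": 1.0},
            "p2": {"systole": 0.0, "diastole": 0.0, "none": 0.0},
            "go": {"systole": 0.0, "diastole": 0.0, "none": 0.0},
            "n2": {"systole": 0.0, "diastole": 0.0, "none": 0.0},
            "p3": {"systole": 0.0, "diastole": 0.0, "none": 0.0},
        }
        cfg = mini_config(
            trials_per_block=6, go_per_block=4, stop_per_block=2,
            noise_sd_uv=0.0, ecg_noise_sd_uv=0.0, cfa_gain=0.0,
            template_gains=gains,
        )
        s = simulate_session(cfg, seed=77)
        comp = decompose_session(s)
        idx = [comp.names.index("hep")]
        cleaned = remove_components(comp, idx)
        from cardiostop.eeg import ROI_DEFINITIONS

        roi = ROI_DEFINITIONS["hep"]
        ep = component_epochs(s, "hep", "systole", eeg=cleaned)
        vals = roi_mean_amplitude(ep, roi["channels"], roi["window_ms"])
        assert np.max(np.abs(vals)) < 1e-9


class TestRoi:
    def _epochs(self, data):
        return EpochSet(data, (0.0, 1000.0), (0.0, 0.0), FS,
                        [f"c{i}" for i in range(data.shape[1])])

    def test_constant_epoch(self):
        n = int(1.0 * FS)
        ep = self._epochs(np.ones((2, 3, n)))
        assert np.allclose(roi_mean_amplitude(ep, ["c0", "c1"], (100.0, 400.0)), 1.0)

    def test_half_window_pulse(self):
        n = int(1.0 * FS)
        data = np.zeros((1, 2, n))
        j0 = int(0.2 * FS)
        j1 = int(0.3 * FS)  # pulse covers exactly half of the 200-400 window
        data[0, :, j0:j1] = 3.0
        ep = self._epochs(data)
        assert roi_mean_amplitude(ep, ["c0", "c1"], (200.0, 400.0))[0] == pytest.approx(1.5)

    def test_disjoint_rois_independent(self, rng):
        n = int(1.0 * FS)
        data = rng.standard_normal((4, 4, n))
        ep = self._epochs(data)
        a = roi_mean_amplitude(ep, ["c0", "c1"], (100.0, 300.0))
        data2 = np.array(data)
        data2[:, 2:, :] = 99.0  # changing other channels leaves the ROI alone
        ep2 = self._epochs(data2)
        assert np.array_equal(a, roi_mean_amplitude(ep2, ["c0", "c1"], (100.0, 300.0)))

    def test_unknown_channel_rejected(self):
        ep = self._epochs(np.zeros((1, 2, int(FS))))
        with pytest.raises(KeyError):
            roi_mean_amplitude(ep, ["nope"], (100.0, 200.0))
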