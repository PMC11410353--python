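"""Preprocessing rules: referencing, baselining, rejection, filtering,
interpolation, and the fixed stage order."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

import oddwave as ow
from oddwave.preprocessing import design_lowpass
from conftest import make_epochs


@pytest.fixture()
def ref_layout():
    lay = ow.make_layout("chain-4")
    lay.reference_channels = ["C", "D"]  # treat C/D as M1/M2 stand-ins
    lay.neighbors = {"A": ["B"], "B": ["A"]}
    return ow.ChannelLayout(lay.name, lay.channel_names, lay.positions,
                            lay.neighbors, lay.reference_channels)


class TestRereference:
    def test_mastoid_mean_subtracted(self, ref_layout):
        data = np.zeros((1, 4, 10))
        data[0, 0] = 10.0   # scalp A
        data[0, 2] = 2.0    # ref C
        data[0, 3] = 4.0    # ref D
        out = ow.rereference(make_epochs(data, ref_layout))
        assert np.allclose(out.data[0, 0], 7.0)

    def test_zero_reference_is_identity(self, ref_layout):
        data = np.random.default_rng(0).normal(size=(2, 4, 10))
        data[:, 2:] = 0.0
        out = ow.rereference(make_epochs(data, ref_layout))
        assert np.allclose(out.data, data)

    def test_idempotent(self, ref_layout, rng):
        ep = make_epochs(rng.normal(size=(3, 4, 20)), ref_layout)
        once = ow.rereference(ep)
        twice = ow.rereference(once)
        assert np.allclose(once.data, twice.data)

    def test_missing_reference_channel(self, ref_layout, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 5)), ref_layout)
        with pytest.raises(KeyError):
            ow.rereference(ep, ["M9"])

    def test_input_not_mutated(self, ref_layout, rng):
        data = rng.normal(size=(2, 4, 10))
        ep = make_epochs(data.copy(), ref_layout)
        ow.rereference(ep)
        assert np.array_equal(ep.data, data)


class TestDemeanAndBaseline:
    def test_constant_epoch_demeans_to_zero(self, chain4):
        ep = make_epochs(np.full((2, 4, 30), 5.0), chain4)
        assert np.allclose(ow.demean_epochs(ep).data, 0.0)

    def test_demean_output_always_zero_mean(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(3, 4, 50)), chain4)
        out = ow.demean_epochs(ep)
        assert np.allclose(out.data.mean(axis=2), 0.0, atol=1e-12)

    def test_baseline_constant_removed(self, chain4):
        ep = make_epochs(np.full((1, 4, 300), 5.0), chain4)
        out = ow.baseline_correct(ep, (-100, 0))
        assert np.allclose(out.data, 0.0)

    def test_baseline_zero_mean_leaves_poststim_unchanged(self, chain4, rng):
        data = rng.normal(size=(1, 4, 300))
        times = np.arange(-150, 150, dtype=float)
        base = (times >= -100) & (times < 0)
        data -= data[:, :, base].mean(axis=2, keepdims=True)
        ep = make_epochs(data.copy(), chain4, times=times)
        out = ow.baseline_correct(ep, (-100, 0))
        assert np.allclose(out.data, data, atol=1e-12)

    def test_linear_ramp_baseline_mean_exactly_zero(self, chain4):
        times = np.arange(-150, 150, dtype=float)
        ep = make_epochs(np.tile(times, (1, 4, 1)), chain4, times=times)
        out = ow.baseline_correct(ep, (-100, 0))
        base = (times >= -100) & (times < 0)
        assert np.allclose(out.data[:, :, base].mean(axis=2), 0.0, atol=1e-12)

    def test_empty_baseline_window_raises(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 10)), chain4,
                         times=np.arange(10, dtype=float))
        with pytest.raises(ValueError):
            ow.baseline_correct(ep, (-100, 0))


class TestRejectArtifacts:
    def _epoch_with_spike(self, chain4, amp, t_ms):
        times = np.arange(-150, 750, dtype=float)
        data = np.zeros((1, 4, len(times)))
        data[0, 1, int(t_ms + 150)] = amp
        return make_epochs(data, chain4, times=times)

    @pytest.mark.parametrize("amp,t_ms,kept", [
        (80.0, 300, False),    # above threshold inside window -> removed
        (80.0, 700, True),     # outside -150..600 window -> kept
        (74.9, 300, True),     # below threshold everywhere -> kept
        (-80.0, 0, False),     # absolute amplitude rule
        (75.0, 300, True),     # rule is 'exceeds': exactly 75 stays
    ])
    def test_boundary_decisions(self, chain4, amp, t_ms, kept):
        ep = self._epoch_with_spike(chain4, amp, t_ms)
        out, log = ow.reject_artifacts(ep)
        assert bool(log.table["kept"].iloc[0]) is kept
        assert out.n_trials == int(kept)

    def test_log_partitions_trials(self, chain4, rng):
        ep = make_epochs(rng.normal(0, 40, size=(50, 4, 900)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        out, log = ow.reject_artifacts(ep)
        assert log.n_kept + log.n_removed == 50
        assert out.n_trials == log.n_kept
        assert {"trial", "kept", "channel", "time_ms", "peak_uv"} <= set(log.table.columns)

    def test_reference_channels_not_screened(self, ref_layout):
        times = np.arange(-150, 750, dtype=float)
        data = np.zeros((1, 4, len(times)))
        data[0, 3, 300] = 200.0  # huge excursion on a reference channel
        out, log = ow.reject_artifacts(make_epochs(data, ref_layout))
        assert out.n_trials == 1

    def test_injected_artifacts_caught_clean_trials_kept(self, mesh12):
        """120 uV pulses at 5% rate: >=99% of injected trials removed, <1%
        of clean trials removed, at a 10 uV single-trial noise floor."""
        kern = ow.EffectKernel.default(mesh12, peak_channel="E11")
        params = ow.SimulationParams(sigma_trial=10.0, mu_subj=0, sigma_subj=0,
                                     artifact_rate=0.05, artifact_amplitude=120)
        plan = ow.build_session(17, conditions=["+asp", "-asp"], n_reps=1,
                                n_deviants=70, n_run_standards=420, n_habituation=16)
        ep = ow.simulate_participant_epochs(plan, params, kern, mesh12,
                                            np.random.default_rng(55))
        assert ep.n_trials >= 1000
        _, log = ow.reject_artifacts(ep)
        art = ep.metadata["artifact"].to_numpy()
        removed = ~log.table["kept"].to_numpy()
        assert removed[art].mean() >= 0.99
        assert removed[~art].mean() < 0.01

    def test_window_outside_epoch_raises(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 100)), chain4,
                         times=np.arange(100, dtype=float))
        with pytest.raises(ValueError):
            ow.reject_artifacts(ep, window_ms=(-150, 600))


class TestLowpassFilter:
    def test_dc_passes_unchanged(self, chain4):
        ep = make_epochs(np.full((1, 4, 900), 3.0), chain4,
                         times=np.arange(-150, 750, dtype=float))
        out = ow.lowpass_filter(ep, 30.0)
        assert np.allclose(out.data, 3.0, rtol=1e-3)

    def test_60hz_attenuated_20db(self, chain4):
        taps, report = design_lowpass(30.0, 1000.0)
        w, h = signal.freqz(taps, worN=8192, fs=1000.0)
        mag60 = np.abs(h)[np.argmin(np.abs(w - 60.0))]
        assert 20 * np.log10(1 / mag60) >= 20.0
        # and on data: a 60 Hz sinusoid shrinks by >= 20 dB
        t = np.arange(-150, 750) / 1000.0
        ep = make_epochs(np.tile(np.sin(2 * np.pi * 60 * t), (1, 4, 1)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        out = ow.lowpass_filter(ep, 30.0)
        mid = slice(200, 700)  # avoid edge transients
        ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(ep.data[0, 0, mid]).max()
        assert 20 * np.log10(1 / ratio) >= 20.0

    def test_zero_phase_preserves_symmetry(self, chain4):
        times = np.arange(-150, 750, dtype=float)
        center = 450
        pulse = np.exp(-0.5 * ((np.arange(900) - center) / 10.0) ** 2)
        ep = make_epochs(np.tile(pulse, (1, 4, 1)), chain4, times=times)
        out = ow.lowpass_filter(ep, 30.0)
        y = out.data[0, 0]
        assert np.argmax(y) == center
        w = 150
        assert np.allclose(y[center - w:center], y[center + 1:center + w + 1][::-1],
                           atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 900)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        with pytest.raises(ValueError):
            ow.lowpass_filter(ep, 600.0)

    def test_design_report_logged(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 900)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        out = ow.lowpass_filter(ep, 30.0)
        rec = out.history[-1]
        assert rec["step"] == "lowpass"
        assert rec["stopband_attenuation_db"] > 40
        assert abs(rec["passband_ripple_db"]) < 0.5


class TestInterpolation:
    def test_equal_distance_neighbors_average(self, chain4):
        data = np.zeros((1, 4, 10))
        data[0, 0] = 2.0  # A
        data[0, 2] = 4.0  # C
        out = ow.interpolate_bad_channels(make_epochs(data, chain4), ["B"])
        assert np.allclose(out.data[0, 1], 3.0)

    def test_no_bad_channels_is_identity(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(2, 4, 10)), chain4)
        out = ow.interpolate_bad_channels(ep, [])
        assert np.allclose(out.data, ep.data)

    def test_more_than_three_bad_raises(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 10)), chain4)
        with pytest.raises(ValueError, match="at most 3"):
            ow.interpolate_bad_channels(ep, ["A", "B", "C", "D"])

    def test_isolated_bad_channel_raises(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(1, 4, 10)), chain4)
        with pytest.raises(ValueError, match="no good neighbors"):
            ow.interpolate_bad_channels(ep, ["A", "B"])  # A's only neighbor is bad


class TestPipelineOrder:
    def test_canonical_order_recorded(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(4, 4, 900)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        out, _ = ow.run_preproc(ep)
        steps = [h["step"] for h in out.history]
        assert steps == ["interpolate", "rereference", "demean", "ica",
                         "baseline", "reject", "lowpass"]
        assert out.history[3]["status"] == "skipped"

    def test_order_override_warns_and_logs(self, chain4, rng):
        ep = make_epochs(rng.normal(size=(2, 4, 900)), chain4,
                         times=np.arange(-150, 750, dtype=float))
        with pytest.warns(UserWarning, match="non-standard"):
            out, _ = ow.run_preproc(ep, order_override=["demean", "reject"])
        assert out.history[0]["step"] == "order_override"
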