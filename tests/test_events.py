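"""Detector behaviour: alpha density, K-complexes, REM arousals."""
import numpy as np
import pytest

from sleepssm import (
    AlphaParams,
    ArousalParams,
    Hypnogram,
    KCParams,
    SignalRecord,
    Stage,
    alpha_density,
    detect_kcomplexes,
    detect_rem_arousals,
    first_kc_latency,
    read_signal_csv,
    rem_arousal_density,
    write_signal_csv,
)
from sleepssm.errors import RoleError, ValidationError
from sleepssm.events import ArousalEvent, KComplexEvent
from sleepssm.synthetic import generate_eeg

FS = 100.0


def make_alpha_record(coverage_micro, n_micro, seed, fs=FS):
    """Pink-noise occipital record with alpha injected into given micro-epochs."""
    sched = [(m * 3.0 + 0.15, (m + 1) * 3.0 - 0.15) for m in coverage_micro]
    rec, _ = generate_eeg(
        n_micro * 3.0, fs, alpha_schedule=sched, seed=seed, roles=("occipital",)
    )
    return rec


class TestAlphaDensity:
    def test_counting_rule_on_scheduled_bursts(self):
        rec = make_alpha_record([0, 2], 4, seed=11)
        res = alpha_density(rec, (0.0, 0.2))
        assert res.n_micro == 4
        assert list(res.micro_labels) == [True, False, True, False]
        assert res.alpha_prop == 0.5

    def test_pure_sinusoid_saturates_with_sub_unit_k(self):
        t = np.arange(int(30 * FS)) / FS
        x = 20.0 * np.sin(2 * np.pi * 10.0 * t)
        rec = SignalRecord({"O1": x}, FS, {"occipital": ["O1"]})
        res = alpha_density(rec, (0.0, 0.5), AlphaParams(k=0.9))
        assert res.alpha_prop == 1.0

    def test_known_coverage_recovered(self, rng):
        n_micro = 60
        chosen = np.sort(rng.choice(n_micro, size=12, replace=False))
        rec = make_alpha_record(chosen, n_micro, seed=13)
        res = alpha_density(rec, (0.0, 3.0))
        assert res.alpha_prop == pytest.approx(0.2, abs=0.02)

    def test_amplitude_scale_invariance(self, rng):
        n_micro = 20
        chosen = np.sort(rng.choice(n_micro, size=5, replace=False))
        rec = make_alpha_record(chosen, n_micro, seed=17)
        res1 = alpha_density(rec, (0.0, 1.0))
        scaled = SignalRecord(
            {k: 7.3 * v for k, v in rec.channels.items()}, rec.fs_hz, rec.roles, rec.t0_s
        )
        res2 = alpha_density(scaled, (0.0, 1.0))
        assert list(res1.micro_labels) == list(res2.micro_labels)

    def test_window_shorter_than_micro_epoch_rejected(self):
        rec = make_alpha_record([], 4, seed=19)
        with pytest.raises(ValidationError, match="micro-epoch"):
            alpha_density(rec, (0.0, 0.02))

    def test_missing_occipital_role_rejected(self):
        rec = SignalRecord({"F3": np.zeros(3000)}, FS, {"frontal": ["F3"]})
        with pytest.raises(RoleError):
            alpha_density(rec, (0.0, 0.5))


class TestKComplex:
    def make_record(self, kc_times, seed=23, dur=120.0, **kw):
        rec, _ = generate_eeg(dur, FS, kc_times=kc_times, seed=seed, roles=("frontal",), **kw)
        return rec

    def test_supra_threshold_template_detected(self):
        events = detect_kcomplexes(self.make_record([60.0]))
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_to_peak_uv >= 75.0
        assert 0.5 <= ev.duration_s <= 3.0
        assert abs(ev.t_start_s - 60.0) < 0.5

    def test_low_amplitude_template_rejected(self):
        events = detect_kcomplexes(self.make_record([60.0], kc_pp_uv=40.0))
        assert events == []

    def test_overlong_template_rejected(self):
        events = detect_kcomplexes(self.make_record([60.0], kc_dur_s=4.0))
        assert events == []

    @pytest.mark.parametrize("n", [0, 1, 5])
    def test_exact_recovery(self, n):
        times = [30.0 + 20.0 * i for i in range(n)]
        events = detect_kcomplexes(self.make_record(times, dur=30.0 + 20.0 * n + 30.0))
        assert len(events) == n

    def test_merged_across_derivations(self):
        # the same template lands on F3 and F4; one merged event results
        rec = self.make_record([60.0])
        assert len(detect_kcomplexes(rec)) == 1


class TestFirstKCLatency:
    def test_minutes_of_earliest(self):
        evs = [
            KComplexEvent(900.0, 901.0, 100.0, "F3"),
            KComplexEvent(300.0, 301.0, 100.0, "F4"),
        ]
        assert first_kc_latency(evs) == pytest.approx(5.0)

    def test_empty_missing(self):
        assert first_kc_latency([]) is None

    def test_matches_brute_force_min(self, rng):
        for _ in range(200):
            starts = rng.uniform(0, 3000, size=rng.integers(1, 12))
            evs = [KComplexEvent(float(s), float(s) + 1.0, 100.0, "F3") for s in starts]
            assert first_kc_latency(evs) == pytest.approx(min(starts) / 60.0)


def rem_hypnogram():
    # REM epochs 10..19 (300-600 s), preceded by N2 sleep
    return Hypnogram(tuple([Stage.W] * 2 + [Stage.N2] * 8 + [Stage.REM] * 10 + [Stage.N2] * 4))


def arousal_record(schedule, seed):
    rec, _ = generate_eeg(
        330.0, FS, arousal_schedule=schedule, seed=seed, t0_s=285.0,
        roles=("occipital", "chin_emg"),
    )
    return rec


class TestRemArousals:
    def test_full_gates_detect_one_event(self):
        evs = detect_rem_arousals(arousal_record([((320.0, 324.0), True)], 29), rem_hypnogram())
        assert len(evs) == 1
        assert evs[0].emg_confirmed
        assert evs[0].stage_context is Stage.REM

    def test_short_shift_rejected(self):
        evs = detect_rem_arousals(arousal_record([((320.0, 322.0), True)], 31), rem_hypnogram())
        assert evs == []

    def test_missing_emg_burst_rejected(self):
        evs = detect_rem_arousals(arousal_record([((320.0, 324.0), False)], 37), rem_hypnogram())
        assert evs == []

    def test_unstable_pre_period_rejected(self):
        # shift beginning 5 s into the first REM epoch: the preceding 10 s
        # include wake when the run is preceded by W instead of N2
        hyp_wake = Hypnogram(
            tuple([Stage.W] * 2 + [Stage.N2] * 7 + [Stage.W] + [Stage.REM] * 10 + [Stage.N2] * 4)
        )
        rec = arousal_record([((305.0, 310.0), True)], 41)
        assert detect_rem_arousals(rec, hyp_wake) == []
        assert len(detect_rem_arousals(rec, rem_hypnogram())) == 1

    def test_no_rem_warns_empty(self):
        hyp = Hypnogram((Stage.W, Stage.N1, Stage.N2))
        rec = arousal_record([], 43)
        with pytest.warns(UserWarning, match="no REM"):
            assert detect_rem_arousals(rec, hyp) == []

    def test_events_contained_in_rem_epochs(self, rng):
        hyp = rem_hypnogram()
        sched = [((float(s), float(s) + 4.5), True) for s in [315.0, 360.0, 420.0, 500.0]]
        evs = detect_rem_arousals(arousal_record(sched, 47), hyp)
        assert evs
        for ev in evs:
            epoch = int(ev.t_start_s // 30)
            assert hyp.epochs[epoch] is Stage.REM


class TestRemArousalDensity:
    def test_counting(self):
        hyp = rem_hypnogram()
        evs = [ArousalEvent(300.0 + 30.0 * j + 5.0, 300.0 + 30.0 * j + 9.0, Stage.REM, True)
               for j in (0, 2, 5, 7)]
        assert rem_arousal_density(evs, hyp) == pytest.approx(0.4)

    def test_no_arousals_zero(self):
        assert rem_arousal_density([], rem_hypnogram()) == 0.0

    def test_no_rem_missing_with_warning(self):
        hyp = Hypnogram((Stage.W, Stage.N2))
        with pytest.warns(UserWarning):
            assert rem_arousal_density([], hyp) is None

    def test_matches_brute_force_membership_count(self, rng):
        hyp = rem_hypnogram()
        for _ in range(300):
            starts = rng.uniform(0, 720, size=rng.integers(0, 10))
            evs = [ArousalEvent(float(s), float(s) + 4.0, Stage.REM, True) for s in starts]
            expected = len(
                {int(s // 30) for s in starts if hyp.epochs[int(s // 30)] is Stage.REM
                 if int(s // 30) < len(hyp.epochs)}
            ) / 10
            assert rem_arousal_density(evs, hyp) == pytest.approx(expected)


def test_signal_csv_round_trip(tmp_path, rng):
    rec, _ = generate_eeg(5.0, FS, seed=53, t0_s=120.0)
    path = tmp_path / "sig.csv"
    write_signal_csv(rec, path, float_format="%.6f")
    back = read_signal_csv(path)
    assert back.fs_hz == rec.fs_hz
    assert back.t0_s == rec.t0_s
    assert back.roles == rec.roles
    for name in rec.channels:
        np.testing.assert_allclose(back.channels[name], rec.channels[name], atol=1e-6)
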