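import dataclasses

import numpy as np
import pytest

from vascage.core import PulseWave, convert_pressure
from vascage.fiducials import pressure_inflections
from vascage.indices import (CaviCoefficients, IndexConfig, augmentation,
                             cavi, compute_panel, distensibility, ppg_panel,
                             pulse_pressure, transit_time_pwv,
                             wave_separation)
from vascage.synthetic import SyntheticSpec, make_root_beat, make_subject


class TestTransitTimePwv:
    def test_delayed_copy_recovers_imposed_speed(self, subject_mid):
        subject, _ = subject_mid
        wave = subject.wave("carotid", "pressure")
        delayed = wave.with_samples(
            np.roll(wave.samples, int(round(0.05 * wave.fs))))
        pwv, reliable = transit_time_pwv(wave, delayed, delta_x=0.5)
        assert reliable
        assert pwv == pytest.approx(10.0, rel=1e-6)

    def test_linear_in_path_length(self, subject_mid):
        subject, _ = subject_mid
        a = subject.wave("carotid", "pressure")
        b = subject.wave("femoral", "pressure")
        v1, _ = transit_time_pwv(a, b, 0.5)
        v2, _ = transit_time_pwv(a, b, 1.0)
        assert v2 == pytest.approx(2 * v1)

    def test_synthetic_subject_speeds_within_5pc(self, population_small):
        for subject, truth in population_small:
            pwv, reliable = transit_time_pwv(
                subject.wave("carotid", "pressure"),
                subject.wave("femoral", "pressure"),
                subject.path_lengths["cf"])
            assert reliable
            want = subject.path_lengths["cf"] / truth.transit_delays["cf"]
            assert pwv == pytest.approx(want, rel=0.05)

    def test_sub_resolution_delay_flagged(self, subject_mid):
        subject, _ = subject_mid
        wave = subject.wave("carotid", "pressure")
        delayed = wave.with_samples(np.roll(wave.samples, 1))
        _, reliable = transit_time_pwv(wave, delayed, 0.5)
        assert not reliable

    def test_offset_invariance(self, subject_mid):
        subject, _ = subject_mid
        a = subject.wave("carotid", "pressure")
        b = subject.wave("femoral", "pressure")
        v1, _ = transit_time_pwv(a, b, 0.5)
        v2, _ = transit_time_pwv(a.with_samples(a.samples + 1000.0),
                                 b.with_samples(b.samples + 1000.0), 0.5)
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestPressureScalars:
    def test_pulse_pressure_offset_invariant(self, subject_mid):
        subject, _ = subject_mid
        wave = subject.wave("aortic_root", "pressure")
        pp = pulse_pressure(wave)
        assert pp > 0
        assert pulse_pressure(wave.with_samples(wave.samples + 123.0)) \
            == pytest.approx(pp)

    def test_constant_beat_has_zero_pp(self):
        wave = PulseWave(np.full(100, 9e3), 500.0, "brachial", "pressure")
        assert pulse_pressure(wave) == 0.0

    def test_augmentation_hand_case(self, subject_mid):
        subject, _ = subject_mid
        fids = pressure_inflections(subject.wave("aortic_root", "pressure"))
        fids = dataclasses.replace(fids, p1=13332.0, p2=14665.2,
                                   degenerate=False)
        ap, aix, ok = augmentation(fids, pp=6666.1)
        assert ok
        assert ap == pytest.approx(1333.2)
        assert aix == pytest.approx(0.2, rel=1e-3)

    def test_augmentation_degenerate_flagged(self, subject_mid):
        subject, _ = subject_mid
        fids = pressure_inflections(subject.wave("aortic_root", "pressure"))
        fids = dataclasses.replace(fids, p1=fids.p2, degenerate=True)
        ap, aix, ok = augmentation(fids, pp=5000.0)
        assert not ok and ap == 0.0 and aix == 0.0


class TestWaveSeparation:
    def test_pure_forward_wave_identity(self, subject_mid):
        subject, _ = subject_mid
        p = subject.wave("aortic_root", "pressure")
        c0 = 7.3
        u = PulseWave(p.samples / (1060.0 * c0), p.fs, "aortic_root",
                      "flow_velocity")
        sep = wave_separation(p, u, 1060.0)
        assert sep.c == pytest.approx(c0, rel=1e-12)
        assert np.allclose(sep.pb.samples, 0.0, atol=1e-12 * np.ptp(p.samples))
        assert sep.rm == 0.0

    def test_reconstruction_identity(self, subject_mid):
        subject, _ = subject_mid
        p = subject.wave("aortic_root", "pressure")
        u = subject.wave("aortic_root", "flow_velocity")
        sep = wave_separation(p, u, subject.rho)
        rebuilt = sep.pf.samples + sep.pb.samples
        target = p.samples - p.samples[0]
        assert np.max(np.abs(rebuilt - target)) < 1e-9 * np.ptp(p.samples)

    def test_recovers_reflection_gain(self):
        for gain in (0.1, 0.25, 0.4):
            p, u, _ = make_root_beat(SyntheticSpec(reflection_gain=gain))
            sep = wave_separation(p, u, 1060.0)
            assert sep.rm == pytest.approx(gain, abs=0.02)

    def test_flat_velocity_rejected(self, subject_mid):
        subject, _ = subject_mid
        p = subject.wave("aortic_root", "pressure")
        u = PulseWave(np.full(p.n, 0.3), p.fs, "aortic_root",
                      "flow_velocity")
        with pytest.raises(ValueError):
            wave_separation(p, u, 1060.0)


class TestCavi:
    def test_zero_pwv_returns_offset(self):
        assert cavi(16000.0, 10666.0, 5334.0, 0.0, 1060.0,
                    CaviCoefficients(c1=1.0, c2=3.0)) == 3.0

    def test_hand_value(self):
        sbp = convert_pressure(120.0, "mmHg", "Pa")
        dbp = convert_pressure(80.0, "mmHg", "Pa")
        value = cavi(sbp, dbp, sbp - dbp, 8.0, 1060.0, CaviCoefficients())
        assert value == pytest.approx(10.32, abs=0.01)

    def test_quadratic_in_pwv(self):
        sbp, dbp = 16000.0, 10000.0
        lo = cavi(sbp, dbp, sbp - dbp, 4.0, 1060.0)
        hi = cavi(sbp, dbp, sbp - dbp, 8.0, 1060.0)
        assert hi == pytest.approx(4 * lo)

    def test_nonphysical_pressures_rejected(self):
        with pytest.raises(ValueError):
            cavi(10000.0, 16000.0, 6000.0, 8.0, 1060.0)


class TestDistensibility:
    def test_hand_value(self):
        # 10% relative area change over 40 mmHg brachial pulse pressure
        assert distensibility(1e-5, 1e-4, 5332.88) \
            == pytest.approx(1.8752e-5, rel=1e-4)

    def test_zero_area_change(self):
        assert distensibility(0.0, 1e-4, 5000.0) == 0.0

    def test_synthetic_carotid_matches_truth(self, population_small):
        for subject, truth in population_small:
            area = subject.wave("carotid", "area").samples
            bpp = pulse_pressure(subject.wave("brachial", "pressure"))
            dc = distensibility(np.ptp(area), area.min(), bpp)
            assert dc == pytest.approx(truth.dc_true, rel=0.05)


class TestPpgPanel:
    def test_si_hand_value(self, subject_mid):
        from vascage.fiducials import ppg_landmarks, sdppg_landmarks
        subject, _ = subject_mid
        wave = subject.wave("digital", "ppg")
        fids = dataclasses.replace(ppg_landmarks(wave), delta_t=0.25)
        panel = ppg_panel(fids, sdppg_landmarks(wave), height=1.75)
        assert panel["SI_ppg"] == pytest.approx(7.0)

    def test_agi_hand_value(self, subject_mid):
        from vascage.fiducials import SdppgLandmarks, ppg_landmarks
        subject, _ = subject_mid
        sd = SdppgLandmarks(
            times={k: i * 0.05 for i, k in enumerate("abcde")},
            values={"a": 1.0, "b": -1.0, "c": -0.1, "d": -0.2, "e": 0.1})
        fids = ppg_landmarks(subject.wave("digital", "ppg"))
        panel = ppg_panel(fids, sd, height=1.75)
        assert panel["AGI"] == pytest.approx(-0.8)
        assert panel["d_over_a"] == pytest.approx(-0.2)

    def test_ri_orientation_flag(self, subject_mid):
        from vascage.fiducials import ppg_landmarks, sdppg_landmarks
        subject, _ = subject_mid
        wave = subject.wave("digital", "ppg")
        fids, sd = ppg_landmarks(wave), sdppg_landmarks(wave)
        s_over_d = ppg_panel(fids, sd, 1.75, IndexConfig())["RI_ppg"]
        d_over_s = ppg_panel(fids, sd, 1.75, IndexConfig(
            ri_systolic_over_diastolic=False))["RI_ppg"]
        assert s_over_d == pytest.approx(1.0 / d_over_s)


class TestComputePanel:
    def test_all_indices_present_on_full_subject(self, subject_mid):
        subject, _ = subject_mid
        panel = compute_panel(subject)
        assert panel.is_complete()

    def test_no_reflection_zeroes_rm_and_flags_ap(self):
        subject, _ = make_subject(SyntheticSpec(reflection_gain=0.0), 45.0)
        panel = compute_panel(subject)
        assert panel.get("RM") == pytest.approx(0.0, abs=1e-12)
        # a single-peak beat has no distinct P1/P2 shoulders
        assert "AP" in panel.missing or abs(panel.get("AP")) < 1.0

    def test_missing_ankle_ppg_degrades_only_ftpwv(self, subject_mid):
        subject, _ = subject_mid
        waves = {k: v for k, v in subject.waves.items()
                 if k != ("ankle", "ppg")}
        degraded = dataclasses.replace(subject, waves=waves)
        panel = compute_panel(degraded)
        assert set(panel.missing) == {"ftPWV"}

    def test_stiffness_sweep_raises_cfpwv(self):
        speeds = []
        for scale in (0.8, 1.2, 1.6, 2.0):
            subject, _ = make_subject(
                SyntheticSpec(stiffness_scale=scale), 45.0)
            speeds.append(compute_panel(subject).get("cfPWV"))
        assert np.all(np.diff(speeds) > 0)
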