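"""Synthetic cohort, schedules, and instrument simulation."""

import io
import math

import numpy as np
import pytest

from fdnirs.occlusion import VENOUS_PROTOCOL, datavalues_from_channels
from fdnirs.probe import DataTypeKind
from fdnirs.sensitivity import HemodynamicScenario, partial_pathlengths
from fdnirs.synthetic import (
    ATT_RANGE,
    BONE_DEPTH_RANGE,
    FOREARM_COHORT,
    InstrumentModel,
    OcclusionSchedule,
    SubjectAnatomy,
    apply_instrument,
    default_scenarios,
    generate_cohort,
    layered_media,
    make_subject,
    noiseless_channel_matrix,
    simulate_occlusion,
    write_channels,
    LAYER_COMPOSITIONS,
)


class TestCohort:
    def test_fixed_cohort_anatomies(self):
        cohort = generate_cohort(14)
        assert [s.att_mm for s in cohort[:3]] == [3.0, 4.0, 2.5]
        assert cohort[0].mtt_mm == 11.0 and cohort[0].bone_depth_mm == 14.0
        assert cohort[13].bone_depth_mm == 26.0

    def test_seeded_cohort_is_deterministic_and_in_range(self):
        a = generate_cohort(100, seed=7)
        b = generate_cohort(100, seed=7)
        assert a == b
        for s in a:
            assert ATT_RANGE[0] <= s.att_mm <= ATT_RANGE[1]
            assert BONE_DEPTH_RANGE[0] <= s.bone_depth_mm <= BONE_DEPTH_RANGE[1]

    def test_make_subject_layout(self):
        media = make_subject(FOREARM_COHORT[0])
        med = media[690.0]
        assert [l.thickness for l in med.layers] == [3.0, 11.0, math.inf]
        assert med.layers[0].mus_prime == pytest.approx(1.0)
        assert med.layers[1].mua == pytest.approx(0.0170, abs=5e-5)

    def test_zero_adipose_thickness_degenerates_cleanly(self):
        media = layered_media([0.0, 11.0], LAYER_COMPOSITIONS)
        assert len(media[690.0].layers) == 2


class TestScenarioLibrary:
    def test_default_amplitudes(self):
        lib = default_scenarios()
        assert lib["venous_default"].amplitudes == (5.0, 10.0, 0.0)
        assert lib["arterial_default"].amplitudes == (5.0, 10.0, 0.0)
        d_oxy, d_deoxy = lib["arterial_muscle"].delta_hb()
        assert d_deoxy[1] == 20.0 and d_oxy[1] == -20.0

    def test_all_venous_scenarios_have_inert_bone(self):
        lib = default_scenarios()
        venous = [lib["venous_default"], *lib["venous_adipose_sweep"]]
        assert all(s.amplitudes[2] == 0.0 for s in venous)


class TestSchedule:
    def test_envelope_phases(self):
        sched = OcclusionSchedule(
            HemodynamicScenario("venous", (5.0, 10.0, 0.0)), VENOUS_PROTOCOL
        )
        t = np.array([0.0, 30.0, 60.0, 90.0, 119.9, 120.0, 140.0])
        env = sched.envelope(t)
        assert np.all(env[:2] == 0)  # baseline
        assert env[3] == pytest.approx(0.5)  # mid-ramp
        assert env[4] == pytest.approx(1.0, abs=1e-2)
        assert 0 < env[6] < env[5]  # exponential recovery

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            OcclusionSchedule(
                HemodynamicScenario("arterial", (5.0, 10.0, 0.0)), VENOUS_PROTOCOL
            )

    def test_ramp_rates(self):
        sched = OcclusionSchedule(
            HemodynamicScenario("venous", (6.0, 12.0, 0.0)), VENOUS_PROTOCOL
        )
        assert sched.ramp_rates_um_per_s() == pytest.approx([0.1, 0.2, 0.0])


class TestSimulation:
    def test_zero_schedule_zero_noise_gives_constant_channels(self, subject1_media):
        sched = OcclusionSchedule(
            HemodynamicScenario("venous", (0.0, 0.0, 0.0)), VENOUS_PROTOCOL
        )
        quiet = InstrumentModel(amplitude_noise_rel=0.0, phase_noise_rad=0.0)
        frame = simulate_occlusion(subject1_media, sched, quiet)
        for _, sub in frame.groupby(["channel", "wavelength_nm"]):
            assert sub.ac.std() == pytest.approx(0.0, abs=1e-15)
            assert sub.phase_rad.std() == pytest.approx(0.0, abs=1e-15)

    def test_same_seed_gives_identical_csv(self, subject1_media):
        sched = OcclusionSchedule(
            HemodynamicScenario("venous", (5.0, 10.0, 0.0)), VENOUS_PROTOCOL
        )
        texts = []
        for _ in range(2):
            frame = simulate_occlusion(subject1_media, sched, InstrumentModel(seed=42))
            buf = io.StringIO()
            write_channels(frame, buf)
            texts.append(buf.getvalue())
        assert texts[0] == texts[1]

    def test_noise_levels_match_configuration(self, venous_run):
        """Baseline-phase sample scatter reproduces the configured noise SDs
        within 10% (relative amplitude, absolute phase)."""
        inst = InstrumentModel(seed=3)
        frame = apply_instrument(
            venous_run["time"], venous_run["responses"], inst
        )
        base = frame[frame.time_s < 60.0]
        sub = base[(base.channel == "1A") & (base.wavelength_nm == 690.0)]
        assert sub.shape[0] >= 140
        # pool all channels/wavelengths for n >= 500
        rel_sds, pha_sds = [], []
        for _, grp in base.groupby(["channel", "wavelength_nm"]):
            rel_sds.append(grp.ac.std() / grp.ac.mean())
            pha_sds.append(grp.phase_rad.std())
        assert np.mean(rel_sds) == pytest.approx(inst.amplitude_noise_rel, rel=0.10)
        assert np.mean(pha_sds) == pytest.approx(inst.phase_noise_rad, rel=0.10)

    def test_couplings_shift_sd_but_not_ds_values(self, venous_run):
        """Instrument gains/offsets move single-distance data values but are
        invisible to the dual-slope reduction."""
        quiet = dict(amplitude_noise_rel=0.0, phase_noise_rad=0.0)
        plain = apply_instrument(
            venous_run["time"], venous_run["responses"], InstrumentModel(**quiet)
        )
        coupled = apply_instrument(
            venous_run["time"],
            venous_run["responses"],
            InstrumentModel.with_random_couplings(5, **quiet),
        )
        v0 = datavalues_from_channels(plain)
        v1 = datavalues_from_channels(coupled)
        key_sd = (DataTypeKind.SDI25, 690.0)
        key_ds = (DataTypeKind.DSI, 690.0)
        assert not np.allclose(v0[key_sd], v1[key_sd], atol=1e-6)
        assert np.allclose(v0[key_ds], v1[key_ds], atol=1e-12)
        key_dsp = (DataTypeKind.DSPHI, 830.0)
        assert np.allclose(v0[key_dsp], v1[key_dsp], atol=1e-12)

    def test_linearization_window(self, subject1_media):
        """For small per-layer Δμa the nonlinear forward response change
        matches the partial-pathlength linearization within 3%."""
        med = subject1_media[690.0]
        dmua = np.array([4e-4, 8e-4, 0.0])
        from fdnirs.sensitivity import _datavalue
        from fdnirs.probe import DEFAULT_GEOMETRY

        for kind in (DataTypeKind.SDI25, DataTypeKind.SDI37, DataTypeKind.DSPHI):
            base = [l.mua for l in med.layers]
            y0 = _datavalue(med, kind, DEFAULT_GEOMETRY)
            y1 = _datavalue(med.with_mua(base + dmua), kind, DEFAULT_GEOMETRY)
            pl = partial_pathlengths(med, kind)
            linear = float(np.dot(pl.per_layer, dmua))
            assert (y1 - y0) == pytest.approx(linear, rel=0.03)

    def test_layer_mismatch_rejected(self, subject1_media):
        sched = OcclusionSchedule(
            HemodynamicScenario("venous", (5.0, 10.0)), VENOUS_PROTOCOL
        )
        with pytest.raises(ValueError, match="layers"):
            noiseless_channel_matrix(subject1_media, sched)
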