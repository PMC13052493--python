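"""Partial pathlengths, layer sensitivities, and the ratio engine."""

from dataclasses import replace

import numpy as np
import pytest

from fdnirs.chromophores import delta_hb_from_delta_mua, lookup_extinction
from fdnirs.probe import DataTypeKind
from fdnirs.sensitivity import (
    HemodynamicScenario,
    LayerAbsorptionChange,
    normalized_sensitivity,
    partial_pathlengths,
    ratio_deltaT,
    ratio_deoxy_oxy,
    scenario_to_absorption,
    sweep_ratios,
    _datavalue,
)
from fdnirs.probe import DEFAULT_GEOMETRY
from fdnirs.synthetic import LAYER_COMPOSITIONS, layered_media, make_subject, SubjectAnatomy

ALL_KINDS = list(DataTypeKind)


@pytest.fixture(scope="module")
def two_layer_media():
    return layered_media([7.0], LAYER_COMPOSITIONS[:2])


class TestPartialPathlengths:
    def test_single_layer_equals_total(self):
        med = layered_media([], LAYER_COMPOSITIONS[1:2])[690.0]
        pl = partial_pathlengths(med, DataTypeKind.SDI25)
        assert pl.per_layer[0] == pl.total

    def test_chain_rule_sum(self, two_layer_media):
        """Σk lk must equal the derivative w.r.t. a global μa shift."""
        med = two_layer_media[690.0]
        pl = partial_pathlengths(med, DataTypeKind.SDI25)
        h = 1e-5
        mua = [l.mua for l in med.layers]
        y_up = _datavalue(med.with_mua([m + h for m in mua]), DataTypeKind.SDI25, DEFAULT_GEOMETRY)
        y_dn = _datavalue(med.with_mua([m - h for m in mua]), DataTypeKind.SDI25, DEFAULT_GEOMETRY)
        assert pl.total == pytest.approx((y_up - y_dn) / (2 * h), rel=1e-3)

    def test_matches_richardson_extrapolated_derivative(self, two_layer_media):
        """Independent higher-order differentiation oracle."""
        med = two_layer_media[690.0]
        pl = partial_pathlengths(med, DataTypeKind.SDPHI37)
        for k in range(2):
            mua = [l.mua for l in med.layers]

            def f(x):
                m = list(mua)
                m[k] = x
                return _datavalue(med.with_mua(m), DataTypeKind.SDPHI37, DEFAULT_GEOMETRY)

            h = 4e-5
            d_h = (f(mua[k] + h) - f(mua[k] - h)) / (2 * h)
            d_h2 = (f(mua[k] + h / 2) - f(mua[k] - h / 2)) / h
            richardson = (4 * d_h2 - d_h) / 3
            assert pl.per_layer[k] == pytest.approx(richardson, rel=1e-4)

    def test_intensity_pathlength_is_negative(self, two_layer_media):
        pl = partial_pathlengths(two_layer_media[690.0], DataTypeKind.SDI25)
        assert all(l < 0 for l in pl.per_layer)


class TestNormalizedSensitivity:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_sums_to_one(self, two_layer_media, kind):
        prof = normalized_sensitivity(two_layer_media[690.0], kind)
        assert sum(prof.per_layer) == pytest.approx(1.0, abs=1e-12)

    def test_deep_layer_ordering_across_kinds(self, two_layer_media):
        """Bottom-layer sensitivity grows SDI25 < SDI37 < DSI, and phase
        beats intensity at matched configuration."""
        med = two_layer_media[690.0]
        s2 = {
            k: normalized_sensitivity(med, k).per_layer[1]
            for k in ALL_KINDS
        }
        assert s2[DataTypeKind.SDI25] < s2[DataTypeKind.SDI37] < s2[DataTypeKind.DSI]
        assert s2[DataTypeKind.SDPHI25] > s2[DataTypeKind.SDI25]
        assert s2[DataTypeKind.SDPHI37] > s2[DataTypeKind.SDI37]
        assert s2[DataTypeKind.DSPHI] > s2[DataTypeKind.DSI]

    def test_deep_interface_kills_bottom_sensitivity(self):
        med = layered_media([30.0], LAYER_COMPOSITIONS[:2])[690.0]
        prof = normalized_sensitivity(med, DataTypeKind.SDI25)
        assert prof.per_layer[1] < 0.05


class TestScenarioToAbsorption:
    def test_zero_scenario(self):
        ch = scenario_to_absorption(HemodynamicScenario("venous", (0.0, 0.0, 0.0)))
        assert np.all(ch.dmua == 0)

    def test_arterial_sign_flips_across_isosbestic(self):
        ch = scenario_to_absorption(HemodynamicScenario("arterial", (0.0, 20.0, 0.0)))
        assert ch.dmua[1, 0] > 0  # 690 nm: deoxy gain dominates
        assert ch.dmua[1, 1] < 0  # 830 nm: oxy loss dominates

    def test_venous_matches_hand_arithmetic(self):
        s = 0.75
        ch = scenario_to_absorption(HemodynamicScenario("venous", (5.0, 10.0, 0.0), s))
        for j, lam in enumerate((690.0, 830.0)):
            eps_o, eps_d, _ = lookup_extinction(lam)
            expected = np.log(10) * (eps_o * s + eps_d * (1 - s)) * 1e-7 * 10.0
            assert ch.dmua[1, j] == pytest.approx(expected, rel=1e-12)
        assert np.all(ch.dmua[2] == 0)

    def test_invalid_saturation(self):
        with pytest.raises(ValueError):
            HemodynamicScenario("venous", (5.0,), saturation=1.2)


class TestRatioEngine:
    def test_homogeneous_change_gives_unity(self, two_layer_media):
        """Identical Δμa in every layer at both wavelengths → ratio 1,
        because sensitivities are normalized."""
        ch = LayerAbsorptionChange(np.full((2, 2), 3e-4))
        for kx, ky in [(DataTypeKind.SDI25, DataTypeKind.DSI),
                       (DataTypeKind.SDPHI25, DataTypeKind.SDPHI37)]:
            assert ratio_deltaT(kx, ky, two_layer_media, ch) == pytest.approx(1.0, abs=1e-10)
            assert ratio_deoxy_oxy(kx, ky, two_layer_media, ch) == pytest.approx(1.0, abs=1e-10)

    def test_equals_bruteforce_inversion(self, two_layer_media):
        """Engine ≡ direct per-kind inversion oracle on random changes."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            ch = LayerAbsorptionChange(rng.uniform(-5e-4, 5e-4, (2, 2)))
            for kx, ky in [(DataTypeKind.SDI25, DataTypeKind.SDI37),
                           (DataTypeKind.SDPHI25, DataTypeKind.DSPHI)]:
                eff = {}
                for kind in (kx, ky):
                    eff[kind] = [
                        float(np.dot(
                            normalized_sensitivity(two_layer_media[lam], kind, lam).per_layer,
                            ch.dmua[:, j],
                        ))
                        for j, lam in enumerate((690.0, 830.0))
                    ]
                _, _, t_x = delta_hb_from_delta_mua(*eff[kx])
                _, _, t_y = delta_hb_from_delta_mua(*eff[ky])
                ox, dx, _ = delta_hb_from_delta_mua(*eff[kx])
                oy, dy, _ = delta_hb_from_delta_mua(*eff[ky])
                assert ratio_deltaT(kx, ky, two_layer_media, ch) == pytest.approx(
                    t_y / t_x, rel=1e-10
                )
                assert ratio_deoxy_oxy(kx, ky, two_layer_media, ch) == pytest.approx(
                    (dy - oy) / (dx - ox), rel=1e-10
                )

    def test_muscle_dominant_three_layer_ratio_below_one_at_shallow_bone(self):
        media = make_subject(SubjectAnatomy(0, 1.5, 13.5))  # bone at 15 mm
        ch = scenario_to_absorption(HemodynamicScenario("venous", (5.0, 10.0, 0.0)))
        assert ratio_deltaT(DataTypeKind.SDI25, DataTypeKind.SDI37, media, ch) < 1.0

    def test_phase_ratios_not_above_intensity_ratios_arterial(self):
        for depth in (15.0, 20.0, 25.0):
            media = make_subject(SubjectAnatomy(0, 3.0, depth - 3.0))
            ch = scenario_to_absorption(HemodynamicScenario("arterial", (5.0, 10.0, 0.0)))
            ri = ratio_deoxy_oxy(DataTypeKind.SDI25, DataTypeKind.SDI37, media, ch)
            rp = ratio_deoxy_oxy(DataTypeKind.SDPHI25, DataTypeKind.SDPHI37, media, ch)
            assert rp <= ri


class TestSweeps:
    def test_two_layer_table_structure(self):
        scen = HemodynamicScenario("venous", (5.0, 10.0))
        tab = sweep_ratios(
            lambda l1, d: layered_media([l1], LAYER_COMPOSITIONS[:2]),
            scen,
            [2.0, 5.0],
        )
        assert set(tab.columns) == {"L1_mm", "bone_depth_mm", "kind_pair", "ratio"}
        assert tab.bone_depth_mm.isna().all()  # no bone-depth axis in two-layer
        assert len(tab) == 2 * 4

    def test_scattering_contrast_raises_intensity_ratios(self):
        """More scattering in the top layer (relative to muscle) pushes the
        deep-over-shallow intensity ratios up at intermediate thickness."""
        scen = HemodynamicScenario("venous", (5.0, 10.0))
        vals = []
        for mus1 in (0.3, 1.0, 1.5):
            comps = (replace(LAYER_COMPOSITIONS[0], mus_ref=mus1),) + LAYER_COMPOSITIONS[1:2]
            media = layered_media([5.5], comps)
            ch = scenario_to_absorption(scen)
            vals.append(ratio_deltaT(DataTypeKind.SDI25, DataTypeKind.DSI, media, ch))
        assert vals[0] < vals[1] < vals[2]

    def test_top_layer_absorption_has_negligible_influence(self):
        """Sweeping μa of the top layer across its physiological range moves
        the ratios by well under 10%."""
        base = layered_media([1.5, 12.5], LAYER_COMPOSITIONS)
        ch = scenario_to_absorption(HemodynamicScenario("venous", (5.0, 10.0, 0.0)))
        vals = []
        for mua1 in np.linspace(0.003, 0.029, 5):
            media = {
                lam: med.with_mua([mua1] + [l.mua for l in med.layers[1:]])
                for lam, med in base.items()
            }
            vals.append(ratio_deltaT(DataTypeKind.SDI25, DataTypeKind.SDI37, media, ch))
        vals = np.array(vals)
        assert (vals.max() - vals.min()) / vals.min() < 0.10

    def test_bone_depth_must_exceed_l1(self):
        scen = HemodynamicScenario("venous", (5.0, 10.0, 0.0))
        with pytest.raises(ValueError):
            sweep_ratios(
                lambda l1, d: layered_media([l1, d - l1], LAYER_COMPOSITIONS),
                scen,
                [5.0],
                [4.0],
            )
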