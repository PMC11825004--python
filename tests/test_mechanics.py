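"""Cantilever stiffness, force conversion, preload and force/area."""

import dataclasses
import math

import numpy as np
import pytest

import pillartrack as pt
from pillartrack.errors import ConfigError, PillarTrackError


def circle_cfg(**kw):
    base = dict(pillar_kind="circle", E=1e6, L=500.0, a=500.0,
                diameter_um=100.0, um_per_px=1.0, fps=100.0)
    base.update(kw)
    return pt.PlatformConfig(**base)


def rect_cfg(**kw):
    base = dict(pillar_kind="rectangle", E=2e6, L=250.0, a=200.0,
                width_um=90.0, thickness_um=55.0, um_per_px=1.0, fps=100.0)
    base.update(kw)
    return pt.PlatformConfig(**base)


class TestStiffness:
    def test_tip_load_limit_is_textbook_cantilever(self):
        # a = L must collapse to 3EI/L^3 exactly
        cfg = circle_cfg()
        I = math.pi * 100.0 ** 4 / 64.0
        expected = 3.0 * 1e6 * I / 500.0 ** 3 * 1e-6
        assert pt.pillar_stiffness(cfg) == pytest.approx(expected, rel=1e-14)

    def test_circle_numeric_value_against_closed_form(self):
        # independent numeric evaluation of 6EI / (a^2 (3L - a))
        cfg = circle_cfg(a=400.0)
        I = math.pi * 100.0 ** 4 / 64.0
        k = 6.0 * 1e6 * I / (400.0 ** 2 * (3 * 500.0 - 400.0)) * 1e-6
        assert pt.pillar_stiffness(cfg) == pytest.approx(k, rel=1e-12)

    def test_rect_second_moment_orientation(self):
        # bending thickness b enters cubed; swapping w and b must change I
        cfg = rect_cfg()
        assert pt.second_moment_of_area(cfg) == pytest.approx(
            90.0 * 55.0 ** 3 / 12.0)
        swapped = rect_cfg(width_um=55.0, thickness_um=90.0)
        assert pt.second_moment_of_area(swapped) > \
            pt.second_moment_of_area(cfg)

    def test_linearity_in_youngs_modulus(self):
        assert pt.pillar_stiffness(circle_cfg(E=2e6)) == pytest.approx(
            2 * pt.pillar_stiffness(circle_cfg(E=1e6)), rel=1e-14)

    def test_dimensional_scaling_of_geometry(self):
        # scaling every length by s scales k by s (I/L^3 ~ s^4/s^3)
        s = 1.7
        k1 = pt.pillar_stiffness(circle_cfg(a=400.0))
        k2 = pt.pillar_stiffness(circle_cfg(
            L=500.0 * s, a=400.0 * s, diameter_um=100.0 * s))
        assert k2 == pytest.approx(s * k1, rel=1e-12)

    def test_attachment_readout_uses_shorter_lever(self):
        tip = circle_cfg(a=300.0)
        att = circle_cfg(a=300.0, deflection_read_at="attachment")
        assert pt.pillar_stiffness(att) == pytest.approx(
            3 * 1e6 * math.pi * 100 ** 4 / 64 / 300.0 ** 3 * 1e-6)
        assert pt.pillar_stiffness(att) > pt.pillar_stiffness(tip)

    def test_attachment_above_tip_rejected(self):
        with pytest.raises(ConfigError):
            circle_cfg(a=600.0)


def fake_traces(deflection, baseline=380.0, area=None, um_per_px=1.0):
    n = len(deflection)
    deflection = np.asarray(deflection, dtype=float)
    area = np.full(n, 28000.0) if area is None else np.asarray(area)
    distance = baseline - deflection
    return pt.TraceSet(
        t=np.arange(n) / 100.0, distance_px=distance / um_per_px,
        distance_um=distance, deflection_um=deflection,
        tissue_area_px2=area / um_per_px ** 2, tissue_area_um2=area,
        baseline_distance_um=baseline, fps=100.0, um_per_px=um_per_px,
        centroids=np.zeros((n, 2, 2)))


class TestForceConversion:
    def test_zero_deflection_zero_force(self):
        cfg = circle_cfg(gap_design_um=380.0)
        force = pt.deflection_to_force(fake_traces(np.zeros(10)), cfg)
        assert np.all(force.F_uN == 0)

    def test_peak_force_is_half_k_delta(self):
        cfg = circle_cfg(gap_design_um=380.0)
        k = pt.pillar_stiffness(cfg)
        delta = np.array([0, 2.0, 8.0, 3.0, 0])
        force = pt.deflection_to_force(fake_traces(delta), cfg)
        assert force.F_uN.max() == pytest.approx(k * 8.0 / 2.0, rel=1e-12)

    def test_force_exactly_linear_in_deflection(self):
        cfg = circle_cfg()
        delta = np.array([0.5, 1.0, 4.0])
        f1 = pt.deflection_to_force(fake_traces(delta), cfg).F_uN
        f3 = pt.deflection_to_force(fake_traces(3 * delta), cfg).F_uN
        assert np.allclose(f3, 3 * f1, rtol=1e-14)


class TestRestingTension:
    def test_design_gap_equal_baseline_gives_zero(self):
        cfg = circle_cfg(gap_design_um=380.0)
        assert pt.resting_tension(cfg, fake_traces(np.zeros(5))) == 0.0

    def test_stated_arithmetic(self):
        # design 400, baseline 380, k = 0.2 -> preload 2.0 uN
        cfg = circle_cfg(gap_design_um=400.0)
        k = pt.pillar_stiffness(cfg)
        scale = 0.2 / k
        cfg = dataclasses.replace(cfg, E=cfg.E * scale)
        assert pt.pillar_stiffness(cfg) == pytest.approx(0.2)
        assert pt.resting_tension(cfg, fake_traces(np.zeros(5))) == \
            pytest.approx(2.0)

    def test_invariant_to_contraction_amplitude(self):
        cfg = circle_cfg(gap_design_um=400.0)
        small = pt.resting_tension(cfg, fake_traces([0, 1, 0]))
        large = pt.resting_tension(cfg, fake_traces([0, 30, 0]))
        assert small == large

    def test_baseline_wider_than_design_clamps_with_warning(self):
        cfg = circle_cfg(gap_design_um=350.0)  # baseline 380 > design
        with pytest.warns(UserWarning, match="design gap"):
            assert pt.resting_tension(cfg, fake_traces(np.zeros(5))) == 0.0


class TestForcePerArea:
    def test_constant_area_ratio(self):
        out = pt.force_per_area(np.array([0, 2.0, 4.0]), np.full(3, 2000.0))
        assert out[2] == pytest.approx(4.0 / 2000.0)

    def test_doubling_area_halves_ratio(self):
        F = np.array([1.0, 3.0])
        a = np.array([1000.0, 1000.0])
        assert np.allclose(pt.force_per_area(F, 2 * a),
                           pt.force_per_area(F, a) / 2)

    def test_elementwise_against_direct_division(self):
        rng = np.random.default_rng(0)
        F = rng.random(50)
        area = 20000 + 500 * np.sin(np.linspace(0, 6, 50))
        assert np.allclose(pt.force_per_area(F, area), F / area)

    def test_zero_area_frames_are_nan_not_inf(self):
        with pytest.warns(UserWarning, match="5%"):
            out = pt.force_per_area(np.array([1.0, 1.0]),
                                    np.array([0.0, 100.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.01)

    def test_all_nonpositive_area_rejected(self):
        with pytest.raises(PillarTrackError):
            pt.force_per_area(np.ones(3), np.zeros(3))
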