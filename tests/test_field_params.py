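"""Height, functional, spatial and hybrid parameter formulas."""

import numpy as np
import pytest

from conftest import random_surfaces
from microwear import (
    HeightMap,
    ParamSettings,
    bearing_curve,
    functional_params,
    gen_background,
    height_params,
    hybrid_params,
    spatial_params,
)
from microwear.errors import ConfigurationError


def sinusoid(n=1024, lam=10.0, field=160.0, amp=1.0):
    dx = field / n
    x = np.arange(n) * dx
    z = amp * np.sin(2 * np.pi * x / lam)
    return HeightMap(np.tile(z, (n, 1)), dx, dx)


class TestHeightParams:
    def test_zero_surface_degenerate(self):
        p, flags = height_params(HeightMap(np.zeros((8, 8)), 1, 1))
        assert all(v == 0.0 for v in p.values())
        assert "degenerate_surface" in flags

    def test_sinusoid_closed_forms(self):
        p, _ = height_params(sinusoid())
        assert p["Sa"] == pytest.approx(2 / np.pi, rel=5e-3)
        assert p["Sq"] == pytest.approx(1 / np.sqrt(2), rel=5e-3)
        assert p["Ssk"] == pytest.approx(0.0, abs=1e-9)
        assert p["Sku"] == pytest.approx(1.5, rel=5e-3)
        assert p["Sp"] == pytest.approx(1.0, rel=5e-3)
        assert p["Sv"] == pytest.approx(1.0, rel=5e-3)
        assert p["Sz"] == pytest.approx(2.0, rel=5e-3)

    def test_gaussian_moments(self, rng):
        z = rng.standard_normal((512, 512))
        p, _ = height_params(HeightMap(z - z.mean(), 1, 1))
        se = 1 / 512  # ~1/sqrt(n) scales
        assert p["Sq"] == pytest.approx(1.0, abs=3 * se)
        assert p["Ssk"] == pytest.approx(0.0, abs=3 * np.sqrt(6) / 512)
        assert p["Sku"] == pytest.approx(3.0, abs=3 * np.sqrt(24) / 512)


class TestBearingCurve:
    def test_bilevel_step(self):
        z = np.zeros((10, 10))
        z[:5] = 1.0
        z[5:] = -1.0
        c = bearing_curve(HeightMap(z, 1, 1))
        assert c.height_at(40.0) == pytest.approx(1.0)
        assert c.height_at(60.0) == pytest.approx(-1.0)

    def test_uniform_heights_linear(self, rng):
        z = rng.uniform(0, 1, (100, 100))
        c = bearing_curve(HeightMap(z - 0.0, 1, 1))
        r = np.linspace(5, 95, 19)
        np.testing.assert_allclose(c.height_at(r), 1 - r / 100, atol=0.02)

    def test_monotone_non_increasing(self, rough_surface):
        c = bearing_curve(rough_surface)
        h = c.height_at(np.linspace(0, 100, 501))
        assert np.all(np.diff(h) <= 1e-12)


class TestFunctionalParams:
    def test_flat_surface_all_zero(self):
        p, flags = functional_params(HeightMap(np.zeros((8, 8)), 1, 1))
        assert p["Sxp"] == 0.0
        assert all(p[k] == 0.0 for k in ("Vm", "Vv", "Vmp", "Vmc", "Vvc", "Vvv"))
        assert "degenerate_surface" in flags

    def test_bilevel_hand_computed(self):
        # half at +1, half at -1 (h = 2 µm): c(10%) = +1, c(80%) = -1
        z = np.zeros((10, 10))
        z[:5] = 1.0
        z[5:] = -1.0
        p, _ = functional_params(HeightMap(z, 1, 1))
        assert p["Vvv"] == pytest.approx(0.0, abs=1e-12)  # Vv at c = -1: nothing below
        assert p["Vv"] == pytest.approx(1.0)  # Vv(10%) at c = +1: mean of 2 over half area

    def test_invalid_ratio_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            ParamSettings(p_material=80, q_material=10)

    @pytest.mark.parametrize("hm", random_surfaces(20), ids=lambda h: "s")
    def test_vv_nonincreasing_vm_nondecreasing(self, hm):
        curve = bearing_curve(hm)
        z = hm.valid_heights()
        r = np.linspace(1, 99, 25)
        c = curve.height_at(r)
        vv = [np.mean(np.maximum(ci - z, 0)) for ci in c]
        vm = [np.mean(np.maximum(z - ci, 0)) for ci in c]
        assert np.all(np.diff(vv) <= 1e-12)
        assert np.all(np.diff(vm) >= -1e-12)

    def test_volume_split_matches_direct_integrals(self):
        # independent oracle: numpy percentiles + direct truncated means
        for hm in random_surfaces(10, seed=5):
            p, _ = functional_params(hm)
            z = hm.valid_heights()
            c10 = np.percentile(z, 90.0)
            c80 = np.percentile(z, 20.0)
            vm10 = np.mean(np.maximum(z - c10, 0))
            vm80 = np.mean(np.maximum(z - c80, 0))
            vv10 = np.mean(np.maximum(c10 - z, 0))
            vv80 = np.mean(np.maximum(c80 - z, 0))
            assert p["Vmp"] + p["Vmc"] == pytest.approx(vm80, rel=1e-6)
            assert p["Vvc"] + p["Vvv"] == pytest.approx(vv10, rel=1e-6)
            assert p["Vvv"] == pytest.approx(vv80, rel=1e-6)
            assert p["Vm"] == pytest.approx(vm10, rel=1e-6)


class TestSpatialParams:
    def test_grooves_parallel_y_give_std_90_and_low_str(self, rng):
        n, dx = 256, 0.625
        x = np.arange(n) * dx
        z = np.tile(np.sin(2 * np.pi * x / 8.0), (n, 1)) + 1e-3 * rng.standard_normal((n, n))
        p, _ = spatial_params(HeightMap(z, dx, dx))
        assert abs(p["Std"] - 90.0) <= 1.0
        assert p["Str"] < 0.1

    def test_rotation_by_90_shifts_std_only(self):
        hm = gen_background((128, 128), 0.625, 0.2, 3.0, seed=3)
        from microwear import add_striations, StriationSet

        hm = add_striations(hm, StriationSet(rate=40, orientation=30.0), np.random.default_rng(4))
        rot = HeightMap(np.rot90(hm.heights).copy(), hm.dx, hm.dy)
        a, _ = spatial_params(hm)
        b, _ = spatial_params(rot)
        assert (a["Std"] - b["Std"]) % 180 == pytest.approx(90.0, abs=1.5) or (
            b["Std"] - a["Std"]
        ) % 180 == pytest.approx(90.0, abs=1.5)
        assert b["Sal"] == pytest.approx(a["Sal"], rel=0.02)
        assert b["Str"] == pytest.approx(a["Str"], rel=0.02)

    def test_isotropic_surface_str_high_sal_near_theory(self):
        L = 4.0
        hm = gen_background((256, 256), 0.625, 0.5, L, seed=1)
        p, _ = spatial_params(hm)
        # squared-exponential ACF exp(-r²/(2L²)) crosses 0.2 at L·sqrt(2 ln 5)
        r02 = L * np.sqrt(2 * np.log(5.0))
        assert p["Str"] > 0.5
        assert p["Sal"] == pytest.approx(r02, rel=0.30)

    def test_constant_surface_flagged(self):
        p, flags = spatial_params(HeightMap(np.ones((16, 16)), 1, 1))
        assert p["Str"] == 0.0
        assert {"degenerate_surface", "std_invalid"} <= flags


class TestHybridParams:
    def test_flat_zero(self):
        p, _ = hybrid_params(HeightMap(np.zeros((8, 8)), 1, 1))
        assert p["Sdq"] == 0.0 and p["Sdr"] == 0.0

    def test_sinusoid_closed_form(self):
        p, _ = hybrid_params(sinusoid())
        assert p["Sdq"] == pytest.approx(np.pi * np.sqrt(2) / 10, rel=5e-3)

    def test_constant_tilt_gradient(self):
        y, x = np.mgrid[0:64, 0:64] * 1.0
        p, _ = hybrid_params(HeightMap(0.25 * x, 1, 1))
        assert p["Sdq"] == pytest.approx(0.25, rel=1e-9)


class TestScaleEquivariance:
    def test_height_scaling(self, rough_surface):
        k = 3.7
        scaled = rough_surface.copy_with(heights=rough_surface.heights * k)
        a = {}
        b = {}
        for hm, dst in ((rough_surface, a), (scaled, b)):
            for fn in (height_params, functional_params, spatial_params, hybrid_params):
                dst.update(fn(hm)[0])
        for name in ("Sa", "Sq", "Sp", "Sv", "Sz", "Smc", "Sxp", "Vm", "Vv", "Vmp",
                     "Vmc", "Vvc", "Vvv", "Sdq"):
            assert b[name] == pytest.approx(k * a[name], rel=1e-6), name
        for name in ("Ssk", "Sku", "Str", "Std"):
            assert b[name] == pytest.approx(a[name], rel=1e-6), name
        # Smr uses an absolute reference height, so it is equivariant only
        # when the reference is scaled along with the surface
        big = rough_surface.copy_with(heights=rough_surface.heights * 10)
        smr = functional_params(rough_surface, settings=ParamSettings(smr_cref=0.1))[0]["Smr"]
        smr_k = functional_params(big, settings=ParamSettings(smr_cref=1.0))[0]["Smr"]
        assert smr_k == pytest.approx(smr, rel=1e-6)

    @pytest.mark.parametrize("hm", random_surfaces(10, seed=7), ids=lambda h: "s")
    def test_moment_inequalities(self, hm):
        p, _ = height_params(hm)
        assert p["Sa"] <= p["Sq"] + 1e-12
        assert p["Sku"] >= p["Ssk"] ** 2 + 1 - 1e-9
        assert p["Sz"] == pytest.approx(p["Sp"] + p["Sv"], abs=1e-9)
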