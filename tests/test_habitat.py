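import numpy as np
import pytest
from scipy.integrate import quad

from homerange.grids import ResourceGrid
from homerange.habitat import (
    ResourceCoefficient,
    functional_response,
    integrate_resource_value,
    load_coefficients,
    local_mean,
    map_habitat_value,
    save_coefficients,
)

CONST = ResourceCoefficient(name="shade", mode="constant", b0=0.5,
                            integration_upper=10.0)
LOGI = ResourceCoefficient(name="shrub", mode="logistic", lower=0.0, upper=1.0,
                           midpoint=1.0, scale=0.1, integration_upper=10.0)


class TestFunctionalResponse:
    def test_constant_ignores_availability(self):
        assert functional_response(CONST, 3.0) == 0.5
        assert functional_response(CONST, 0.0) == 0.5

    def test_logistic_asymptotes(self):
        assert functional_response(LOGI, 0.0) == pytest.approx(1.0, abs=1e-4)
        assert functional_response(LOGI, 100.0) == pytest.approx(0.0, abs=1e-9)

    def test_logistic_midpoint_is_mean_of_asymptotes(self):
        assert functional_response(LOGI, 1.0) == pytest.approx(0.5)

    def test_negative_availability_rejected(self):
        with pytest.raises(ValueError):
            functional_response(CONST, -0.1)


class TestIntegrateResourceValue:
    def test_constant_integrates_exactly(self):
        assert integrate_resource_value(CONST, 2.0) == pytest.approx(1.0)

    def test_zero_amount_is_zero(self):
        assert integrate_resource_value(LOGI, 0.0) == 0.0
        assert integrate_resource_value(CONST, 0.0) == 0.0

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            integrate_resource_value(CONST, 11.0)
        with pytest.raises(ValueError):
            integrate_resource_value(CONST, -1.0)

    def test_logistic_matches_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the same response
        expected, _ = quad(lambda h: functional_response(LOGI, h), 0.0, 5.0)
        got = integrate_resource_value(LOGI, 5.0)
        assert got == pytest.approx(expected, abs=1e-4)

    def test_monotone_nondecreasing_in_amount(self):
        amounts = np.linspace(0, 10, 41)
        vals = integrate_resource_value(LOGI, amounts)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_threshold_shape_saturates(self):
        # a declining logistic response accumulates almost nothing at
        # high availability: the value curve flattens
        v4 = integrate_resource_value(LOGI, 4.0)
        v10 = integrate_resource_value(LOGI, 10.0)
        assert v10 - v4 < 1e-6
        assert v4 == pytest.approx(1.0, abs=0.01)  # ~ upper * midpoint

    def test_second_order_convergence(self):
        smooth = ResourceCoefficient(name="s", mode="logistic", lower=0.1,
                                     upper=0.9, midpoint=2.0, scale=0.8,
                                     integration_upper=6.0)
        exact, _ = quad(lambda h: functional_response(smooth, h), 0.0, 5.0,
                        epsabs=1e-13)
        errs = []
        for step in (0.2, 0.1, 0.05):
            got = integrate_resource_value(smooth, 5.0, step=step)
            errs.append(abs(got - exact))
        # halving the step should shrink error ~4x (trapezoid is 2nd order)
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.3)

    def test_fixed_availability_mode(self):
        # value scales linearly with amount at the site-level rate
        got = integrate_resource_value(LOGI, 3.0, mode="fixed",
                                       site_availability=1.0)
        assert got == pytest.approx(0.5 * 3.0)
        with pytest.raises(ValueError):
            integrate_resource_value(LOGI, 3.0, mode="fixed")


class TestMapHabitatValue:
    def test_auto_baseline_is_min(self):
        rg = ResourceGrid(name="shade", values=np.array([[0.0, 1.0, 2.0]]))
        coef = ResourceCoefficient(name="shade", mode="constant", b0=1.0,
                                   integration_upper=5.0)
        vg = map_habitat_value([rg], [coef], baseline="auto")
        np.testing.assert_allclose(vg.values, [[0.0, 1.0, 2.0]])
        assert vg.baseline == 0.0

    def test_scaled_coefficient_doubles_value(self, rng):
        vals = rng.uniform(0, 3, (4, 4))
        rg = ResourceGrid(name="shade", values=vals)
        c1 = ResourceCoefficient(name="shade", mode="constant", b0=1.0,
                                 integration_upper=5.0)
        c2 = ResourceCoefficient(name="shade", mode="constant", b0=2.0,
                                 integration_upper=5.0)
        v1 = map_habitat_value([rg], [c1], baseline="auto")
        v2 = map_habitat_value([rg], [c2], baseline="auto")
        np.testing.assert_allclose(v2.values, 2.0 * v1.values, rtol=1e-12)

    def test_min_cell_is_exactly_zero(self, rng):
        grids = [
            ResourceGrid(name=n, values=rng.uniform(0, 2, (7, 7)))
            for n in ("shrub", "dwd", "shade", "substrate")
        ]
        coefs = [
            ResourceCoefficient(name=n, mode="constant", b0=b,
                                integration_upper=3.0)
            for n, b in (("shrub", 0.4), ("dwd", 0.3), ("shade", 0.5),
                         ("substrate", 1.0))
        ]
        vg = map_habitat_value(grids, coefs, baseline="auto")
        assert vg.values.min() == 0.0
        assert np.all(vg.values >= 0.0)

    def test_shape_mismatch_rejected(self):
        a = ResourceGrid(name="a", values=np.ones((3, 3)))
        b = ResourceGrid(name="b", values=np.ones((3, 4)))
        ca = ResourceCoefficient(name="a", mode="constant", b0=1.0,
                                 integration_upper=5.0)
        cb = ResourceCoefficient(name="b", mode="constant", b0=1.0,
                                 integration_upper=5.0)
        with pytest.raises(ValueError, match="shape"):
            map_habitat_value([a, b], [ca, cb])


class TestLocalMean:
    def test_constant_grid_unchanged(self):
        g = ResourceGrid(name="x", values=np.full((6, 6), 2.5))
        out = local_mean(g, radius=26.0)
        np.testing.assert_allclose(out.values, 2.5)

    def test_small_radius_is_identity(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 7.0
        g = ResourceGrid(name="x", values=vals)
        out = local_mean(g, radius=10.0)  # < 15 m cell size
        np.testing.assert_allclose(out.values, vals)

    def test_huge_radius_gives_global_mean(self, rng):
        vals = rng.uniform(0, 5, (5, 5))
        g = ResourceGrid(name="x", values=vals)
        out = local_mean(g, radius=1e6)
        np.testing.assert_allclose(out.values, vals.mean())

    def test_default_radius_mixes_neighbourhood(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 49.0
        g = ResourceGrid(name="x", values=vals)
        out = local_mean(g)  # 26 m: centre plus rook+diagonal neighbours
        assert out.values[3, 3] > 0
        assert out.values[3, 4] == out.values[3, 3]
        assert out.values[0, 0] == 0.0


def test_coefficient_config_roundtrip(tmp_path):
    coefs = [CONST, LOGI]
    path = tmp_path / "coefs.yaml"
    save_coefficients(path, coefs)
    back = load_coefficients(path)
    assert back == coefs


def test_coefficient_validation():
    with pytest.raises(ValueError):
        ResourceCoefficient(name="x", mode="nope")
    with pytest.raises(ValueError):
        ResourceCoefficient(name="x", mode="constant", b0=1.0,
                            integration_upper=0.0)
    with pytest.raises(ValueError):
        ResourceCoefficient(name="x", mode="logistic", scale=-1.0)
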