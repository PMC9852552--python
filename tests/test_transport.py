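"""Transport model: closed form, sweeps, optimum, knockdown, BVP oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voclift import (
    BoundaryConditions,
    CarrierParams,
    bound_fraction,
    bvp_oracle,
    gen_transport_scenario,
    optimal_kd,
    predict_knockdown,
    steady_state_flux,
    sweep,
)


def make_params(ct=100.0, kds=(10.0,), ds=1.0, dc=1.0, ell=1.0):
    return CarrierParams(ct, kds, ds, dc, ell)


class TestBoundFraction:
    @pytest.mark.parametrize(
        "s, kds, expected",
        [
            (0.0, (10.0,), 0.0),            # no ligand, no binding
            (10.0, (10.0,), 0.5),           # half saturation at s = Kd
            (10.0, (10.0, 40.0), 0.7),      # sum of two hyperbolas
        ],
    )
    def test_saturation_values(self, s, kds, expected):
        assert bound_fraction(s, make_params(kds=kds)) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(-1.0, make_params())

    @given(st.floats(0.0, 1e4), st.floats(0.01, 1e3))
    def test_monotone_and_bounded(self, s, step):
        p = make_params(kds=(5.0, 50.0))
        y1, y2 = bound_fraction(s, p), bound_fraction(s + step, p)
        assert 0.0 <= y1 < y2 <= 2.0


class TestCarrierParams:
    def test_kds_sorted_ascending(self):
        p = make_params(kds=(40.0, 10.0))
        assert p.dissociation_constants == (10.0, 40.0)

    @pytest.mark.parametrize("bad", [{"kds": (0.0,)}, {"kds": (1.0, 2.0, 3.0)},
                                     {"ds": -1.0}, {"ell": 0.0}])
    def test_invalid_params_rejected(self, bad):
        kw = dict(ct=10.0, kds=(10.0,), ds=1.0, dc=1.0, ell=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            make_params(**kw)

    def test_negative_boundary_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(-1.0, 5.0)


class TestSteadyStateFlux:
    def test_hand_evaluated_enhancement(self):
        # D_s = D_c, C_T=100, Kd=10, S0=20, SL=5: E = 1 + 100*(2/3 - 1/3)/15
        r = steady_state_flux(make_params(), BoundaryConditions(20.0, 5.0))
        assert r.enhancement == pytest.approx(1 + 100 * (20 / 30 - 5 / 15) / 15,
                                              rel=1e-12)

    def test_no_carrier_reduces_to_fick(self):
        r = steady_state_flux(make_params(ct=0.0), BoundaryConditions(20.0, 5.0))
        assert r.carrier_flux == 0.0
        assert r.enhancement == 1.0
        assert r.total_flux == pytest.approx(15.0)

    def test_decomposition_identity_and_signs(self):
        for seed in range(25):
            p, bc = gen_transport_scenario(seed)
            r = steady_state_flux(p, bc)
            assert r.total_flux == r.free_flux + r.carrier_flux
            assert np.sign(r.free_flux) == np.sign(bc.s0 - bc.sL)
            assert np.sign(r.carrier_flux) == np.sign(bc.s0 - bc.sL)
            assert r.enhancement > 1.0

    def test_zero_gradient_analytic_limit(self):
        p = make_params()
        exact = steady_state_flux(p, BoundaryConditions(10.0, 10.0))
        assert exact.total_flux == 0.0
        eps = 1e-7
        near = steady_state_flux(p, BoundaryConditions(10.0 + eps, 10.0))
        assert exact.enhancement == pytest.approx(near.enhancement, rel=1e-6)

    def test_enhancement_minus_one_linear_in_ct(self):
        bc = BoundaryConditions(20.0, 5.0)
        cts = np.geomspace(1.0, 1000.0, 7)
        slopes = [(steady_state_flux(make_params(ct=ct), bc).enhancement - 1) / ct
                  for ct in cts]
        assert np.ptp(slopes) / slopes[0] < 1e-12

    def test_total_flux_strictly_increasing_in_s0(self):
        p = make_params()
        fluxes = [steady_state_flux(p, BoundaryConditions(s0, 5.0)).total_flux
                  for s0 in np.linspace(6.0, 100.0, 40)]
        assert np.all(np.diff(fluxes) > 0)

    def test_two_site_degeneracy_matches_doubled_single_site(self):
        bc = BoundaryConditions(20.0, 5.0)
        two = steady_state_flux(make_params(ct=50.0, kds=(8.0, 8.0)), bc)
        one = steady_state_flux(make_params(ct=100.0, kds=(8.0,)), bc)
        assert two.total_flux == one.total_flux
        assert two.enhancement == one.enhancement


class TestOptimalKd:
    def test_geometric_mean_example(self):
        kd = optimal_kd(BoundaryConditions(20.0, 5.0), make_params())
        assert kd == pytest.approx(10.0, rel=1e-3)

    def test_matches_analytic_optimum_on_random_pairs(self, rng):
        p = make_params()
        for _ in range(20):
            sL = float(rng.uniform(0.5, 50.0))
            s0 = sL * float(rng.uniform(1.2, 30.0))
            kd = optimal_kd(BoundaryConditions(s0, sL), p)
            assert kd == pytest.approx(np.sqrt(s0 * sL), rel=1e-3)

    def test_near_equal_boundaries_tend_to_common_value(self):
        kd = optimal_kd(BoundaryConditions(8.0 + 1e-6, 8.0), make_params())
        assert kd == pytest.approx(8.0, rel=1e-3)

    def test_requires_strict_gradient(self):
        with pytest.raises(ValueError):
            optimal_kd(BoundaryConditions(5.0, 5.0), make_params())
        with pytest.raises(ValueError):
            optimal_kd(BoundaryConditions(5.0, 0.0), make_params())


class TestSweep:
    bc = BoundaryConditions(20.0, 5.0)

    def test_carrier_axis_linear_and_monotone(self):
        t = sweep(make_params(), self.bc, "carrier_concentration",
                  np.geomspace(1.0, 1000.0, 12))
        assert np.all(np.diff(t.enhancement) > 0)
        slopes = (t.enhancement - 1) / t.axis_value
        assert np.ptp(slopes) / slopes.iloc[0] < 1e-12

    def test_kd_axis_bell_shaped_and_asymptotes_to_one(self):
        t = sweep(make_params(), self.bc, "dissociation_constant",
                  np.geomspace(1e-3, 1e6, 200))
        e = t.enhancement.to_numpy()
        peak = int(np.argmax(e))
        assert 0 < peak < e.size - 1          # interior maximum
        assert np.all(np.diff(e[:peak + 1]) > 0)
        assert np.all(np.diff(e[peak:]) < 0)  # unimodal on the log grid
        assert e[-1] == pytest.approx(1.0, abs=1e-3)

    def test_gradient_ratio_axis_enhancement_above_one(self):
        t = sweep(make_params(), self.bc, "gradient_ratio",
                  np.geomspace(1.01, 100.0, 30))
        assert t.enhancement.min() > 1.0

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            sweep(make_params(), self.bc, "temperature", [1.0, 2.0])

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep(make_params(), self.bc, "carrier_concentration", [2.0, 1.0])


class TestPredictKnockdown:
    bc = BoundaryConditions(20.0, 5.0)

    def test_identity_scale_gives_zero(self):
        red = predict_knockdown(make_params(), self.bc, 1.0, [(10.0, 1.0)])
        assert red == pytest.approx(0.0, abs=1e-12)

    def test_carrier_dominated_limit(self):
        # D_s -> 0: total flux is all carrier, reduction -> 100*(1 - scale)
        p = make_params(ds=1e-6, dc=1.0)
        red = predict_knockdown(p, self.bc, 0.6, [(10.0, 1.0)])
        assert red == pytest.approx(40.0, abs=0.01)

    def test_empty_compound_set_rejected(self):
        with pytest.raises(ValueError):
            predict_knockdown(make_params(), self.bc, 0.6, [])

    def test_weights_and_two_site_compounds(self):
        compounds = [(10.0, 0.5), ((5.0, 50.0), 0.5)]
        red = predict_knockdown(make_params(), self.bc, 0.6, compounds)
        assert 0.0 < red < 40.0


class TestBvpOracle:
    def test_pure_fick_without_carrier(self):
        p = make_params(ct=0.0)
        assert bvp_oracle(p, BoundaryConditions(20.0, 5.0)) == pytest.approx(15.0)

    def test_matches_closed_form_derived_case(self):
        p, bc = make_params(), BoundaryConditions(20.0, 5.0)
        closed = steady_state_flux(p, bc).total_flux
        assert bvp_oracle(p, bc) == pytest.approx(closed, rel=1e-3)

    def test_two_site_agreement(self):
        p = make_params(kds=(10.0, 40.0), dc=0.5)
        bc = BoundaryConditions(20.0, 5.0)
        closed = steady_state_flux(p, bc).total_flux
        assert bvp_oracle(p, bc) == pytest.approx(closed, rel=1e-3)

    def test_grid_independence(self):
        p, bc = make_params(), BoundaryConditions(20.0, 5.0)
        f1 = bvp_oracle(p, bc, grid_points=4001)
        f2 = bvp_oracle(p, bc, grid_points=8001)
        assert abs(f2 / f1 - 1) < 1e-4

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            bvp_oracle(make_params(), BoundaryConditions(20.0, 5.0), grid_points=10)


class TestReferenceScenario:
    def test_reproduces_all_four_published_outputs(self, ref_scenario):
        sc = ref_scenario
        bc = sc.boundary_conditions
        kd_mb = sc.kd_by_compound["methylbenzoate"]
        e1 = steady_state_flux(sc.carrier_params(kd_mb), bc).enhancement
        e2 = steady_state_flux(sc.carrier_params(sc.methylbenzoate_two_site),
                               bc).enhancement
        assert e1 == pytest.approx(1.67, abs=5e-3)
        assert e2 == pytest.approx(1.98, abs=5e-3)
        assert optimal_kd(bc, sc.carrier_params(kd_mb)) == pytest.approx(24.4, abs=0.05)
        red = predict_knockdown(sc.carrier_params(kd_mb), bc, 0.6,
                                [(kd, 1.0) for kd in sc.kd_by_compound.values()])
        assert red == pytest.approx(18.0, abs=0.1)

    def test_measured_anchor_kds_preserved(self, ref_scenario):
        assert ref_scenario.kd_by_compound["benzylbenzoate"] == 6.5
        assert ref_scenario.kd_by_compound["2-phenylethanol"] == 396.0
        kd_mb = ref_scenario.kd_by_compound["methylbenzoate"]
        lo, hi = ref_scenario.methylbenzoate_two_site
        assert lo < kd_mb < hi
        assert lo * hi == pytest.approx(kd_mb**2, rel=1e-9)
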