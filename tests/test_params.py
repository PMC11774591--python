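"""Dimensionless groups, supply numbers, and closed-form design rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcelsim.params import (ASYMMETRY_PEAK, DA_ONSET, ParameterError,
                            PhysicalParams, Shape, asymmetry_predictor,
                            balance_report, compute_dimensionless,
                            corner_numbers, evaluate_design_rules,
                            peclet_corner, peclet_corner_deficient,
                            read_params_config, v0_required)


def make_params(**overrides):
    base = dict(rho=1000.0, mu=1e-3, v0=1e-3, a=1e-3, L=1e-2, h=1e-3,
                k=1e-15, D1=1e-9, D2=1e-9, Rmax=1e-3, K_half=2e-5, c0=0.2)
    base.update(overrides)
    return PhysicalParams(**base)


class TestGroups:
    def test_peclet_channel_definition(self):
        d = compute_dimensionless(make_params(v0=1e-3, L=1e-2, D1=1e-9))
        assert d.Pe1 == pytest.approx(1e4, rel=1e-12)

    def test_reynolds_definition(self):
        d = compute_dimensionless(make_params(rho=1000, mu=1e-3, v0=1e-3,
                                              a=1e-3))
        assert d.Re == pytest.approx(1.0, rel=1e-12)

    def test_supply_number_identities_cylinder(self):
        d = compute_dimensionless(make_params())
        assert d.Sd == pytest.approx(2 * d.Rd / d.Da, rel=1e-12)
        assert d.Sc == pytest.approx(d.Sd * d.Pe1, rel=1e-12)

    def test_supply_number_identities_sphere(self):
        d = compute_dimensionless(make_params(), shape="sphere")
        assert d.Sd == pytest.approx(3 * d.Rd / d.Da, rel=1e-12)
        assert d.Sc == pytest.approx(d.Sd * d.Pe1, rel=1e-12)

    def test_transpiration_peclet_and_warning(self):
        with pytest.warns(UserWarning, match="Pe2"):
            d = compute_dimensionless(make_params(k=1e-14, v0=1e-3, a=1e-4,
                                                  D2=1e-13))
        assert d.Pe2 == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_parameter_names_offender(self):
        with pytest.raises(ParameterError, match="'D2'"):
            make_params(D2=-1.0)

    def test_large_half_rate_warns(self):
        with pytest.warns(UserWarning, match="K_half"):
            make_params(K_half=0.15 * 0.2)

    def test_cn_defaults_to_threshold_fraction(self):
        p = make_params()
        assert p.cn == pytest.approx(1e-3 * p.c0)


class TestDesignRules:
    def test_static_margin_marginal_case(self):
        # Sd*(1 - Da/Da_onset) = 2*(1 - 2/4) = 1: exactly marginal
        d = compute_dimensionless(make_params())
        d = d.__class__(**{**d.__dict__, "Da": 2.0, "Sd": 2.0})
        rep = evaluate_design_rules(d, da_onset=4.0)
        assert rep.static_margin == pytest.approx(0.0, abs=1e-12)
        assert rep.static_prevention_ok

    def test_microfluidic_unsatisfiable_at_da_four(self):
        d = compute_dimensionless(make_params())
        d = d.__class__(**{**d.__dict__, "Da": 4.0})
        rep = evaluate_design_rules(d)
        assert rep.microfluidic_unsatisfiable
        assert not rep.microfluidic_prevention_ok
        assert math.isinf(rep.v0_required)

    def test_asymmetry_predictor_value(self):
        # sqrt(Da)*Sc at Da=8, Sc=2 sits at the analytical peak 4*sqrt(2)
        d = compute_dimensionless(make_params())
        d = d.__class__(**{**d.__dict__, "Da": 8.0, "Sc": 2.0})
        rep = evaluate_design_rules(d)
        assert rep.asymmetry_predictor == pytest.approx(4 * math.sqrt(2))
        assert rep.asymmetry_peak == pytest.approx(ASYMMETRY_PEAK)

    def test_asymmetry_predictor_independent_of_a_and_L(self):
        base = asymmetry_predictor(make_params())
        for fa, fL in [(2.0, 1.0), (1.0, 3.0), (0.5, 5.0)]:
            p = make_params(a=1e-3 * fa, L=1e-2 * fL)
            assert asymmetry_predictor(p) == pytest.approx(base, rel=1e-12)

    def test_v0_required_constant_conventions(self):
        d = compute_dimensionless(make_params())
        d = d.__class__(**{**d.__dict__, "Da": 2.0})
        v_div = v0_required(d, constant_divide=True)
        v_mul = v0_required(d, constant_divide=False)
        assert v_mul == pytest.approx(16 * v_div, rel=1e-12)

    def test_margin_monotone_in_supply(self):
        d0 = compute_dimensionless(make_params())
        margins = []
        for sd in [0.5, 1.0, 2.0, 4.0]:
            d = d0.__class__(**{**d0.__dict__, "Da": 2.0, "Sd": sd})
            margins.append(evaluate_design_rules(d).static_margin)
        assert np.all(np.diff(margins) > 0)

    def test_necrosis_type_rate_induced_above_onset(self):
        d0 = compute_dimensionless(make_params())
        for shape, onset in DA_ONSET.items():
            d = d0.__class__(**{**d0.__dict__, "Da": onset + 1.0,
                                "shape": shape})
            rep = evaluate_design_rules(d)
            assert rep.necrosis_type.value == "rate-induced"


class TestCornerNumbers:
    def test_corner_supply_number_arithmetic(self):
        d0 = compute_dimensionless(make_params())
        d = d0.__class__(**{**d0.__dict__, "Rd": 1.0, "Sd": 1.0,
                            "Sc": 1e3, "q": 1e-3})
        _, sc_rho = corner_numbers(d)
        assert sc_rho == pytest.approx(1.0, rel=1e-12)

    def test_zero_eddy_ratio_kills_corner_supply(self):
        assert peclet_corner(1.0, 1.0, 100.0, q=0.0) == 0.0
        assert peclet_corner_deficient(1.0, 100.0, q=0.0) == 0.0

    def test_deficient_supply_limit_ratio(self):
        """The closed-form corner Péclet number approaches the deficient-
        supply scaling q*Rd*Sc with a fixed 1/4 prefactor as RdSd -> 0
        (the scaling law keeps only the order of magnitude)."""
        q, Pe1 = 1e-3, 1e3
        ratios = []
        for rdsd in [1e-2, 1e-4, 1e-6]:
            rd = sd = math.sqrt(rdsd)
            full = peclet_corner(rd, sd, Pe1, q)
            scaling = peclet_corner_deficient(rd, sd * Pe1, q)
            ratios.append(full / scaling)
        assert ratios[-1] == pytest.approx(0.25, rel=1e-5)
        assert abs(ratios[1] - 0.25) < abs(ratios[0] - 0.25)

    def test_explicit_form_rejects_unit_radius(self):
        with pytest.raises(ParameterError):
            peclet_corner(1.0, 1.0, 10.0, 1e-3, rn0_star=1.0)


class TestBalance:
    def test_unit_gradients_reproduce_supply_numbers(self):
        d0 = compute_dimensionless(make_params())
        d = d0.__class__(**{**d0.__dict__, "Sd": 3.0, "Sc": 7.0})
        rep = balance_report(d, rn_star=0.0)
        assert rep.nd / rep.nR == pytest.approx(3.0)
        assert rep.nc / rep.nR == pytest.approx(7.0)


class TestConfig:
    def test_roundtrip(self, tmp_path):
        cfg = tmp_path / "p.cfg"
        cfg.write_text("[fluid]\nrho = 1000\nmu = 1e-3\nv0 = 1e-3\n"
                       "[construct]\na = 1e-3\nL = 1e-2\nh = 1e-3\n"
                       "k = 1e-15\nD1 = 1e-9\nD2 = 1e-9\nRmax = 1e-3\n"
                       "K_half = 2e-5\nc0 = 0.2\nshape = sphere\n")
        p, shape = read_params_config(str(cfg))
        assert shape is Shape.sphere
        assert p.a == 1e-3

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("speed = 3\n")
        with pytest.raises(ParameterError, match="speed"):
            read_params_config(str(cfg))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(v0=st.floats(1e-6, 1e-2), a=st.floats(1e-5, 1e-3),
       L=st.floats(2e-3, 5e-2), Rmax=st.floats(1e-6, 1e-1))
def test_group_identities_hold_for_random_parameters(v0, a, L, Rmax):
    """Sc = Sd*Pe1 and Sd = 2Rd/Da are exact algebraic identities of the
    definitions, for any admissible dimensional inputs."""
    p = make_params(v0=v0, a=a, L=L, Rmax=Rmax)
    d = compute_dimensionless(p)
    assert d.Sc == pytest.approx(d.Sd * d.Pe1, rel=1e-12)
    assert d.Sd == pytest.approx(2 * d.Rd / d.Da, rel=1e-12)
    assert d.Sc_rho == pytest.approx(d.q * d.Rd * d.Sd * d.Sc, rel=1e-12)
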