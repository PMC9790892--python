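"""indistinguishable_dynamics: error system, DAE reduction, classification."""

import numpy as np
import pytest
import sympy as sp

from obscstr import symbols as sym
from obscstr.cases import WASHOUT_CASES
from obscstr.indistinguishable import (build_error_system, classify_case,
                                       closed_form_error,
                                       constraint_forces_zero_error,
                                       default_reduction, delta_identity,
                                       delta_monod_difference,
                                       reduce_for_output)
from obscstr.scenarios import generate_scenario
from obscstr.verification import reduced_for_scenario, simulate_pair

YN = {True: "Yes", False: "No", None: "-"}

# Expected label grid with uncertainty present, per (case, subcase):
# (obs nu1, nu2, nu3, dD, det nu1, nu2, nu3, dD); '-' marks the measured
# state.  Wash-out sub-rows exist only where biomass is the measured output.
WITH_UNC = {
    (1, "generic"): ("No", "No", "-", "No", "Yes", "Yes", "-", "Yes"),
    (2, "generic"): ("-", "No", "No", "No", "-", "Yes", "Yes", "Yes"),
    (2, "washout_ic"): ("-", "No", "No", "Yes", "-", "Yes", "Yes", "No"),
    (2, "washout_asymptotic"): ("-", "No", "No", "No", "-", "Yes", "Yes", "No"),
    (3, "generic"): ("Yes", "-", "Yes", "Yes", "Yes", "-", "Yes", "Yes"),
    (4, "generic"): ("Yes", "Yes", "-", "Yes", "Yes", "Yes", "-", "Yes"),
    (5, "generic"): ("-", "No", "No", "No", "-", "Yes", "Yes", "Yes"),
    (5, "washout_ic"): ("-", "No", "No", "Yes", "-", "Yes", "Yes", "Yes"),
    (5, "washout_asymptotic"): ("-", "No", "No", "No", "-", "Yes", "Yes", "Yes"),
    (6, "generic"): ("No", "-", "No", "No", "Yes", "-", "Yes", "Yes"),
    (7, "generic"): ("-", "Yes", "Yes", "Yes", "-", "Yes", "Yes", "Yes"),
    (7, "washout_ic"): ("-", "Yes", "Yes", "No", "-", "Yes", "Yes", "No"),
    (7, "washout_asymptotic"): ("-", "Yes", "Yes", "No", "-", "Yes", "Yes", "No"),
    (8, "generic"): ("Yes", "-", "Yes", "Yes", "Yes", "-", "Yes", "Yes"),
    (9, "generic"): ("Yes", "Yes", "-", "Yes", "Yes", "Yes", "-", "Yes"),
}

# Expected grid without uncertainty: (obs nu1..nu3, det nu1..nu3)
WITHOUT_UNC = {
    (1, "generic"): ("Yes", "No", "-", "Yes", "Yes", "-"),
    (2, "generic"): ("-", "No", "Yes", "-", "Yes", "Yes"),
    (2, "washout_ic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (2, "washout_asymptotic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (3, "generic"): ("Yes", "-", "Yes", "Yes", "-", "Yes"),
    (4, "generic"): ("Yes", "Yes", "-", "Yes", "Yes", "-"),
    (5, "generic"): ("-", "Yes", "No", "-", "Yes", "Yes"),
    (5, "washout_ic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (5, "washout_asymptotic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (6, "generic"): ("Yes", "-", "No", "Yes", "-", "Yes"),
    (7, "generic"): ("-", "Yes", "Yes", "-", "Yes", "Yes"),
    (7, "washout_ic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (7, "washout_asymptotic"): ("-", "No", "No", "-", "Yes", "Yes"),
    (8, "generic"): ("Yes", "-", "Yes", "Yes", "-", "Yes"),
    (9, "generic"): ("Yes", "Yes", "-", "Yes", "Yes", "-"),
}


def _row(cls, with_unc):
    j = cls.case.output_index
    keys = ("nu1", "nu2", "nu3") + (("delta",) if with_unc else ())
    obs = tuple("-" if k == f"nu{j}" else YN[cls.states[k].observable]
                for k in keys)
    det = tuple("-" if k == f"nu{j}" else YN[cls.states[k].detectable]
                for k in keys)
    return obs + det


class TestErrorSystem:
    def test_zero_point_is_equilibrium(self, model_factory):
        """eps == 0 with dD == 0 annihilates every error equation."""
        for form in ("S", "O", "SO"):
            err = build_error_system(model_factory(1, form), True)
            subs = {e: 0 for e in sym.EPS}
            subs[sym.delta_Delta] = 0
            for comp in err.rhs:
                assert sp.simplify(comp.subs(subs)) == 0

    def test_extended_dimension_is_six(self, model_factory):
        err = build_error_system(model_factory(2, "S"), True)
        assert err.dimension == 6

    def test_oxygen_error_carries_total_dilution(self, model_factory):
        """The third error equation contains -(u1 + u2)*eps3: both known
        inputs enter it only through that product."""
        err = build_error_system(model_factory(1, "O"), True)
        assert sp.simplify(sp.diff(err.rhs[2], sym.u1) + sym.eps3) == 0
        assert sp.simplify(sp.diff(err.rhs[2], sym.u2) + sym.eps3) == 0

    def test_error_rhs_matches_paired_difference(self):
        """Numerically, d(nu - z)/dt from two separate systems equals the
        error rhs evaluated at (nu, eps)."""
        from obscstr.verification import paired_difference_residual
        scen = generate_scenario(12)
        res = paired_difference_residual(scen, 9, with_uncertainty=True,
                                         horizon=(0.0, 10.0))
        assert res < 1e-6


class TestReduction:
    def test_case1_with_uncertainty(self, model_factory):
        """Measured oxygen, O-form kinetics: dD = -eps1*(mu_O + Yo*mo) and
        the eps1 equation decays at beta_m + u1 + Yo*mo."""
        red = default_reduction(1, True)
        mu_o = sym.mu_max0 * sym.nu3 / (sym.K_o0 + sym.nu3)
        expected_dd = -sym.eps1 * (mu_o + sym.Y_o * sym.m_o)
        assert sp.simplify(red.algebraic - expected_dd) == 0
        expected_e1 = -sym.eps1 * (sym.beta_m + sym.u1 + sym.Y_o * sym.m_o)
        assert sp.simplify(red.differential[1] - expected_e1) == 0

    def test_case5_with_uncertainty(self, model_factory):
        """Measured biomass, S-form kinetics: pure-decay differential part
        and dD = (mu_S' - mu_S)*nu1."""
        red = default_reduction(5, True)
        assert sp.simplify(red.differential[2] + sym.u1 * sym.eps2) == 0
        assert sp.simplify(red.differential[3]
                           + (sym.u1 + sym.u2) * sym.eps3) == 0
        mu_s = sym.mu_max0 * sym.nu2 / (sym.K_s0 + sym.nu2)
        mu_sp = mu_s.subs(sym.nu2, sym.nu2 - sym.eps2)
        assert sp.simplify(red.algebraic - (mu_sp - mu_s) * sym.nu1) == 0

    def test_case1_without_uncertainty_constraint(self):
        """The algebraic constraint factors as -eps1*(mu_O + Yo*mo), which
        forces eps1 == 0."""
        red = default_reduction(1, False)
        mu_o = sym.mu_max0 * sym.nu3 / (sym.K_o0 + sym.nu3)
        expected = -sym.eps1 * (mu_o + sym.Y_o * sym.m_o) / sym.Y_o
        assert sp.simplify(red.algebraic - expected) == 0

    def test_measured_error_eliminated(self):
        for cid in range(1, 10):
            for unc in (True, False):
                red = default_reduction(cid, unc)
                eps_j = sym.EPS[red.constrained_index - 1]
                assert not red.algebraic.has(eps_j)
                for e in red.differential.values():
                    assert not e.has(eps_j)

    def test_matching_forms_equalise_growth_rates(self):
        """When the measured state is the only Monod argument, the reduced
        expressions contain no shifted (copy) kinetics."""
        red = default_reduction(1, True)  # O-form, oxygen measured
        for e in (red.algebraic, *red.differential.values()):
            assert not e.has(sym.eps3)


class TestDeltaIdentity:
    def test_single_fraction_equals_monod_difference(self):
        diff = delta_monod_difference() - delta_identity()
        assert sp.simplify(diff) == 0

    def test_zero_at_zero_error(self):
        assert delta_identity(eps2=0) == 0

    def test_numeric_value(self):
        val = delta_identity(nu2=2.0, eps2=0.5, nu1=1.5)
        subs = {sym.mu_max0: 0.4, sym.K_s0: 1.0}
        got = float(val.subs(subs))
        expected = 0.4 * (2.0 / 3.0 - 1.5 / 2.5) * 1.5
        assert got == pytest.approx(expected, rel=1e-12)

    def test_constraint_forces_zero(self):
        """Equality of the Monod fractions cross-multiplies to
        Ks0*eps2 = 0, whose only solution is eps2 = 0."""
        res = constraint_forces_zero_error()
        assert sp.expand(res["residual"] + sym.K_s0 * sym.eps2) == 0
        assert res["solutions"] == [0]


class TestClosedForm:
    def test_zero_initial_condition_stays_zero(self):
        scen = generate_scenario(2)
        red = reduced_for_scenario(1, scen, True)
        cf = closed_form_error(red, scen, eps1_0=0.0)
        t = np.linspace(*scen.horizon, 50)
        assert np.all(cf(t) == 0.0)

    def test_log_slope_with_constant_inputs(self):
        """Constant u1: decay rate is exactly u1 + beta_m + Yo*mo."""
        import dataclasses
        from obscstr.signals import Constant
        scen = generate_scenario(2, perturb_params=False)
        scen = dataclasses.replace(
            scen, inputs=dataclasses.replace(scen.inputs, u1=Constant(0.1)))
        red = reduced_for_scenario(1, scen, True)
        cf = closed_form_error(red, scen, eps1_0=1.0)
        rate = 0.1 + 0.05 + 0.2 * 0.02  # u1 + beta_m + Yo*mo = 0.154
        log_slope = (np.log(cf(10.0)) - np.log(cf(0.0))) / 10.0
        assert log_slope == pytest.approx(-rate, rel=1e-12)
        assert cf.decay_rate(0.0) == pytest.approx(rate, rel=1e-12)

    def test_time_varying_u1_matches_quadrature(self):
        from scipy.integrate import quad
        scen = generate_scenario(5, perturb_params=False)
        red = reduced_for_scenario(1, scen, True)
        cf = closed_form_error(red, scen, eps1_0=0.7)
        t1 = 23.0
        integ, _ = quad(lambda s: float(scen.inputs.u1(s)), 0.0, t1,
                        limit=200)
        expected = 0.7 * np.exp(-integ - cf.c * t1)
        assert cf(t1) == pytest.approx(expected, rel=1e-8)

    def test_unsupported_case_raises(self):
        scen = generate_scenario(2)
        red = reduced_for_scenario(5, scen, True)  # biomass measured: no eps1
        with pytest.raises(ValueError):
            closed_form_error(red, scen, eps1_0=1.0)


class TestClassification:
    @pytest.mark.parametrize("key", sorted(WITH_UNC))
    def test_with_uncertainty_labels(self, key):
        cid, sub = key
        cls = classify_case(cid, True, subcase=sub)
        assert _row(cls, True) == WITH_UNC[key]

    @pytest.mark.parametrize("key", sorted(WITHOUT_UNC))
    def test_without_uncertainty_labels(self, key):
        cid, sub = key
        cls = classify_case(cid, False, subcase=sub)
        assert _row(cls, False) == WITHOUT_UNC[key]

    def test_uncertainty_never_strengthens_labels(self):
        """Removing the unknown input can only keep or strengthen a state's
        label (observable >= detectable >= unobservable) in the generic
        (positive-biomass) regime.  Wash-out sub-rows are excluded: there the
        with-uncertainty grid keeps the geometry-inherited observability of
        case 7 while the uncertainty-free constraint analysis demotes it, so
        the ordering genuinely reverses."""
        strength = {"observable": 2, "detectable": 1, "unobservable": 0,
                    "measured": 3}
        for cid in range(1, 10):
            with_u = classify_case(cid, True, subcase="generic")
            without = classify_case(cid, False, subcase="generic")
            for k in ("nu1", "nu2", "nu3"):
                assert (strength[without.label(k)]
                        >= strength[with_u.label(k)]), (cid, k)

    def test_delta_not_applicable_without_uncertainty(self):
        cls = classify_case(3, False)
        assert cls.states["delta"].label == "n/a"

    def test_washout_subcase_only_for_measured_biomass(self):
        with pytest.raises(ValueError):
            classify_case(1, True, subcase="washout_ic")

    def test_asserted_flags_confined_to_washout_delta(self):
        for (cid, sub), _ in WITH_UNC.items():
            cls = classify_case(cid, True, subcase=sub)
            for k in ("nu1", "nu2", "nu3"):
                assert not cls.states[k].asserted
            if sub == "generic":
                assert not cls.states["delta"].asserted
            else:
                assert cls.states["delta"].asserted
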