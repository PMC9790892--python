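"""model_core: Monod laws, mean parameterisation, affine decomposition."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from obscstr import symbols as sym
from obscstr.config import DEFAULT_KINETIC_BOUNDS
from obscstr.model import (CSTRParameters, StateVector, SubstituteKinetics,
                           TrueKinetics, build_affine_model,
                           delta_unknown_input, mean_parameterize, monod_rate,
                           true_rhs)
from obscstr.scenarios import generate_scenario

conc = st.floats(min_value=1e-3, max_value=20.0, allow_nan=False)


@pytest.mark.parametrize("kin, state, expected", [
    # half saturation in S gives mu_max/2
    (SubstituteKinetics(0.5, 1.0, 0.2, "S"), StateVector(1, 1.0, 5.0), 0.25),
    # Monod vanishes at zero substrate
    (SubstituteKinetics(0.5, 1.0, 0.2, "S"), StateVector(1, 0.0, 5.0), 0.0),
    # product of two half-saturations gives mu_max/4
    (SubstituteKinetics(0.6, 2.0, 0.5, "SO"), StateVector(1, 2.0, 0.5), 0.15),
    # O-form at half saturation
    (SubstituteKinetics(0.4, 1.0, 0.2, "O"), StateVector(1, 3.0, 0.2), 0.2),
])
def test_monod_rate_closed_form(kin, state, expected):
    assert monod_rate(state, kin) == pytest.approx(expected, abs=1e-12)


def test_monod_rate_rejects_bad_inputs():
    kin = SubstituteKinetics(0.5, 1.0, 0.2, "S")
    with pytest.raises(ValueError):
        kin.mu(-1.0, 1.0)
    with pytest.raises(ValueError):
        SubstituteKinetics(0.5, -1.0, 0.2, "S")


@given(s=conc, o=conc, ds=st.floats(min_value=1e-3, max_value=5.0))
def test_monod_monotone_and_bounded(s, o, ds):
    """mu_S strictly increasing in substrate, mu_O in oxygen, both < mu_max."""
    kin_s = SubstituteKinetics(0.5, 1.0, 0.2, "S")
    kin_o = SubstituteKinetics(0.5, 1.0, 0.2, "O")
    assert kin_s.mu(s + ds, o) > kin_s.mu(s, o)
    assert kin_o.mu(s, o + ds) > kin_o.mu(s, o)
    assert 0 <= kin_s.mu(s, o) < 0.5
    assert 0 <= kin_o.mu(s, o) < 0.5


class TestMeanParameterize:
    def test_degenerate_interval(self):
        sub = mean_parameterize(
            {"mu_max": (0.4, 0.4), "Ks": (1, 1), "Ko": (0.2, 0.2)})
        assert sub.mu_max0 == 0.4

    def test_midpoint(self):
        sub = mean_parameterize(
            {"mu_max": (0.3, 0.5), "Ks": (0.2, 0.6), "Ko": (0.1, 0.3)}, "S")
        assert sub.Ks0 == pytest.approx(0.4)
        assert sub.form == "S"

    @given(lo=st.floats(0.01, 1.0), width=st.floats(0.0, 2.0))
    def test_all_fields_are_midpoints(self, lo, width):
        bounds = {k: (lo, lo + width) for k in ("mu_max", "Ks", "Ko")}
        sub = mean_parameterize(bounds, "SO")
        mid = lo + width / 2  # independent midpoint computation
        for v in (sub.mu_max0, sub.Ks0, sub.Ko0):
            assert v == pytest.approx(mid, rel=1e-12)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            mean_parameterize({"mu_max": (0.5, 0.3), "Ks": (1, 1),
                               "Ko": (0.2, 0.2)})


class TestAffineModel:
    def test_rho_constant(self, model_factory):
        m = model_factory(1, "SO")
        assert m.field_rho == sp.Matrix([1, -1 / sym.Y_s, -1 / sym.Y_o])
        assert m.field_rho.jacobian(sp.Matrix(sym.NU)).is_zero_matrix

    def test_field_u2_structure(self, model_factory):
        m = model_factory(2, "S")
        assert m.field_u2[0] == 0 and m.field_u2[1] == 0
        assert sp.simplify(m.field_u2[2] - (sym.O_s - sym.nu3)) == 0

    def test_o_form_drift_independent_of_substrate(self, model_factory):
        m = model_factory(3, "O")
        for comp in m.drift:
            assert sp.diff(comp, sym.nu2) == 0

    def test_drift_matches_hand_arithmetic(self, params, sub_so):
        m = build_affine_model(params, sub_so, 1)
        x, s, o = 1.2, 2.5, 4.0
        mu = sub_so.mu_max0 * s / (sub_so.Ks0 + s) * o / (sub_so.Ko0 + o)
        expected = [mu * x - params.beta_m * x,
                    -mu * x / params.Ys - params.ms * x,
                    -mu * x / params.Yo - params.mo * x]
        subs = {sym.nu1: x, sym.nu2: s, sym.nu3: o, **m.numeric_subs()}
        got = [float(c.subs(subs)) for c in m.drift]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invalid_output_index(self, params, sub_so):
        with pytest.raises(ValueError):
            build_affine_model(params, sub_so, 4)


class TestTrueRHSAndDelta:
    def test_washout_row_invariant(self):
        scen = generate_scenario(0)
        d = true_rhs([0.0, 2.0, 5.0], scen.params, scen.true_kin,
                     scen.inputs, 1.0)
        assert d[0] == 0.0

    def test_decomposition_identity(self):
        """Decomposition identity: the true dynamics equal the affine pieces
        plus rho times the unknown input, at random points."""
        rng = np.random.default_rng(5)
        for seed in range(5):
            scen = generate_scenario(seed)
            sub = scen.substitute("SO")
            m = build_affine_model(scen.params, sub, 1)
            for _ in range(20):
                state = rng.uniform([0.01, 0.01, 0.01], [5, 6, 10])
                t = float(rng.uniform(*scen.horizon))
                delta = delta_unknown_input(state, scen.true_kin, sub, t)
                lhs = true_rhs(state, scen.params, scen.true_kin,
                               scen.inputs, t)
                rhs = m.rhs_numeric(state, t, scen.inputs, delta)
                assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_delta_zero_at_washout_and_matching_kinetics(self):
        scen = generate_scenario(3)
        sub = scen.substitute("SO")
        assert delta_unknown_input([0.0, 1, 1], scen.true_kin, sub, 0.0) == 0.0

    def test_positivity_preserved_along_flow(self):
        scen = generate_scenario(8)
        sol = solve_ivp(
            lambda t, y: true_rhs(y, scen.params, scen.true_kin,
                                  scen.inputs, t),
            scen.horizon, scen.ic_original.as_array(), rtol=1e-8, atol=1e-10)
        assert sol.success
        assert np.min(sol.y) > -1e-9


def test_state_vector_validation():
    with pytest.raises(ValueError):
        StateVector(-0.1, 1.0, 1.0)
    with pytest.raises(ValueError):
        StateVector(np.nan, 1.0, 1.0)


def test_parameters_must_be_positive():
    with pytest.raises(ValueError):
        CSTRParameters(Ys=0.65, Yo=0.2, Sin=5, Oin=0.5, Os=10,
                       beta_m=-0.05, ms=0.05, mo=0.02)
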