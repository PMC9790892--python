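"""Indistinguishable-dynamics (error-system) stage.

Two trajectories of the uncertain CSTR model with identical known inputs and
identical measured output but different initial conditions and unknown inputs
are indistinguishable; their difference eps = nu - z obeys the error system

    deps1/dt = mu_hat*nu1 - mu_hat'*(nu1 - eps1) - beta_m*eps1 - u1*eps1 + dD
    deps2/dt = -(1/Ys)*[mu_hat*nu1 - mu_hat'*(nu1 - eps1) + dD]
               - ms*eps1 - u1*eps2
    deps3/dt = -(1/Yo)*[mu_hat*nu1 - mu_hat'*(nu1 - eps1) + dD]
               - mo*eps1 - (u1 + u2)*eps3

where mu_hat' is the copy's substitute growth rate (same structure and
constants, evaluated at z = nu - eps) and dD = Delta - Delta' is the
unknown-input difference.  Imposing zero measured error eps_j == 0 reduces
the system to a DAE: with uncertainty the j-th equation is solved for dD and
substituted (the reduced differential part comes out linear in the remaining
errors); without uncertainty it becomes an algebraic constraint that may
force an error coordinate to vanish identically.

States and the unknown-input difference are then classified as
observable / detectable / unobservable.  Observability of unmeasured states
with uncertainty present is inherited from the geometric rank condition
(the sufficient-condition stage); the reduced DAE supplies detectability via
its triangular exponential-decay structure and, without uncertainty, supplies
observability via constraint forcing (factoring, or the Monod-difference
identity that reduces the constraint to K0*eps = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import sympy as sp

from . import symbols as sym
from .cases import SUBCASES, WASHOUT_CASES, CaseSpec, case_spec
from .geometry import is_geometrically_observable
from .model import AffineModel

STATE_KEYS = ("nu1", "nu2", "nu3")
DELTA_KEY = "delta"


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSystem:
    """Original+copy error dynamics for one case."""

    model: AffineModel
    rhs: tuple                  # 3 sympy expressions in (nu, eps, u, dD)
    with_uncertainty: bool
    eps: tuple = sym.EPS
    delta_diff: sp.Symbol = sym.delta_Delta

    @property
    def dimension(self) -> int:
        """Combined (nu, eps) state dimension of the extended dynamics."""
        return len(sym.NU) + len(self.eps)


@dataclass(frozen=True)
class ReducedDAE:
    """Error system after imposing zero measured error.

    With uncertainty, ``algebraic`` is the explicit expression for the
    unknown-input difference dD; without, it is the right-hand side of the
    constraint ``0 = algebraic``.
    """

    case: CaseSpec
    model: AffineModel
    constrained_index: int       # measured state j (eps_j == 0 imposed)
    algebraic: sp.Expr
    differential: dict           # remaining {state index: d(eps_i)/dt expr}
    with_uncertainty: bool
    closed_forms: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Assessment:
    """Observability/detectability verdict for one state (or for dD)."""

    observable: Optional[bool]
    detectable: Optional[bool]
    basis: str = ""
    asserted: bool = False

    @property
    def label(self) -> str:
        if self.observable is None and self.detectable is None:
            return "n/a"
        if self.observable:
            return "observable"
        if self.detectable:
            return "detectable"
        return "unobservable"


MEASURED = Assessment(observable=True, detectable=True, basis="measured output")


@dataclass(frozen=True)
class CaseClassification:
    case: CaseSpec
    subcase: str
    with_uncertainty: bool
    states: dict                 # 'nu1'|'nu2'|'nu3'|'delta' -> Assessment

    def label(self, key: str) -> str:
        if key == f"nu{self.case.output_index}":
            return "measured"
        return self.states[key].label

    def to_dict(self) -> dict:
        out = {"case": self.case.case_id, "subcase": self.subcase,
               "with_uncertainty": self.with_uncertainty}
        for key in STATE_KEYS + (DELTA_KEY,):
            a = self.states[key]
            out[key] = {"label": self.label(key), "observable": a.observable,
                        "detectable": a.detectable, "basis": a.basis,
                        "asserted": a.asserted}
        return out


# ---------------------------------------------------------------------------
# construction and reduction
# ---------------------------------------------------------------------------

def build_error_system(model: AffineModel,
                       with_uncertainty: bool = True) -> ErrorSystem:
    """Error dynamics between the model and its structurally identical copy."""
    mu = model.mu_hat
    mu_prime = mu.subs({sym.nu2: sym.nu2 - sym.eps2,
                        sym.nu3: sym.nu3 - sym.eps3}, simultaneous=True)
    bracket = mu * sym.nu1 - mu_prime * (sym.nu1 - sym.eps1)
    dD = sym.delta_Delta if with_uncertainty else sp.Integer(0)
    rhs = (
        bracket - sym.beta_m * sym.eps1 - sym.u1 * sym.eps1 + dD,
        -(bracket + dD) / sym.Y_s - sym.m_s * sym.eps1 - sym.u1 * sym.eps2,
        -(bracket + dD) / sym.Y_o - sym.m_o * sym.eps1
        - (sym.u1 + sym.u2) * sym.eps3,
    )
    return ErrorSystem(model=model, rhs=rhs, with_uncertainty=with_uncertainty)


def reduce_for_output(err: ErrorSystem, model: AffineModel = None) -> ReducedDAE:
    """Impose eps_j == 0 (and deps_j/dt == 0) for the measured state j.

    With uncertainty the j-th equation is solved for dD (always possible:
    rho has no zero component, so dD enters the measured equation with a
    nonzero coefficient) and the solution is substituted into the remaining
    equations.  Without uncertainty the j-th equation becomes the algebraic
    constraint ``0 = algebraic``.  Whenever the measured coordinate is the
    only state the substitute Monod depends on, the substitution makes the
    original and copy growth rates identical automatically.
    """
    model = model or err.model
    j = model.output_index
    eps_j = sym.EPS[j - 1]
    rhs = [e.subs(eps_j, 0) for e in err.rhs]
    others = [i for i in (1, 2, 3) if i != j]
    if err.with_uncertainty:
        sols = sp.solve(sp.Eq(rhs[j - 1], 0), sym.delta_Delta)
        if len(sols) != 1:
            raise ValueError(
                f"measured equation not uniquely solvable for dD (case "
                f"output nu{j}); got {len(sols)} solutions")
        d_expr = sp.cancel(sp.together(sols[0]))
        differential = {i: sp.simplify(sp.expand(
            rhs[i - 1].subs(sym.delta_Delta, d_expr))) for i in others}
        algebraic = d_expr
    else:
        algebraic = sp.cancel(sp.together(rhs[j - 1]))
        differential = {i: sp.simplify(sp.expand(rhs[i - 1])) for i in others}
    if algebraic.has(eps_j):
        raise AssertionError("measured error survived the reduction")
    case = CaseSpec(_case_id(j, model.substitute.form), j,
                    model.substitute.form)
    return ReducedDAE(case=case, model=model, constrained_index=j,
                      algebraic=algebraic, differential=differential,
                      with_uncertainty=err.with_uncertainty)


def _case_id(output_index: int, form: str) -> int:
    from .cases import ALL_CASES
    for c in ALL_CASES:
        if c.output_index == output_index and c.form == form:
            return c.case_id
    raise ValueError(f"no case with output nu{output_index}, form {form}")


# ---------------------------------------------------------------------------
# symbolic identities (S-form Monod difference)
# ---------------------------------------------------------------------------

def delta_monod_difference(nu2=None, eps2=None, nu1=None) -> sp.Expr:
    """Difference-of-Monods form of the S-case growth-rate mismatch:
    [mu_hat_S(nu2) - mu_hat_S(nu2 - eps2)] * nu1."""
    nu2 = sym.nu2 if nu2 is None else sp.sympify(nu2)
    eps2 = sym.eps2 if eps2 is None else sp.sympify(eps2)
    nu1 = sym.nu1 if nu1 is None else sp.sympify(nu1)
    return sym.mu_max0 * (nu2 / (sym.K_s0 + nu2)
                          - (nu2 - eps2) / (sym.K_s0 + nu2 - eps2)) * nu1


def delta_identity(nu2=None, eps2=None, nu1=None) -> sp.Expr:
    """Single-fraction form of the S-case mismatch:

        mu_max0 * Ks0*eps2 / [(Ks0 + nu2)(Ks0 + nu2 - eps2)] * nu1.

    Symbolically identical to :func:`delta_monod_difference`; raises for a
    numerically singular denominator (eps2 == Ks0 + nu2).
    """
    nu2 = sym.nu2 if nu2 is None else sp.sympify(nu2)
    eps2 = sym.eps2 if eps2 is None else sp.sympify(eps2)
    nu1 = sym.nu1 if nu1 is None else sp.sympify(nu1)
    denom = (sym.K_s0 + nu2) * (sym.K_s0 + nu2 - eps2)
    if denom.is_number and denom == 0:
        raise ZeroDivisionError("singular input: eps2 equals Ks0 + nu2")
    return sym.mu_max0 * sym.K_s0 * eps2 / denom * nu1


def constraint_forces_zero_error() -> dict:
    """Equality of the two S-form Monod fractions forces eps2 = 0.

    Cross-multiplying mu_hat_S(nu2) = mu_hat_S(nu2 - eps2) leaves
    Ks0*eps2 = 0; with Ks0 > 0 the unique solution is eps2 = 0.
    Returns the sympy solution set for eps2.
    """
    lhs = sym.nu2 / (sym.K_s0 + sym.nu2)
    rhs = (sym.nu2 - sym.eps2) / (sym.K_s0 + sym.nu2 - sym.eps2)
    cross = sp.expand((sym.K_s0 + sym.nu2) * (sym.nu2 - sym.eps2)
                      - sym.nu2 * (sym.K_s0 + sym.nu2 - sym.eps2))
    sols = sp.solve(sp.Eq(cross, 0), sym.eps2)
    return {"residual": cross, "solutions": sols,
            "fraction_equation": sp.Eq(lhs, rhs)}


# ---------------------------------------------------------------------------
# closed-form error solution
# ---------------------------------------------------------------------------

class ClosedFormError:
    """gamma(t) = eps1(t0) * exp(-int_{t0}^{t} u1 - c*(t - t0)) with the
    constant c extracted from the reduced eps1 equation."""

    def __init__(self, eps1_0: float, t0: float, u1_signal, c: float):
        self.eps1_0 = float(eps1_0)
        self.t0 = float(t0)
        self.u1 = u1_signal
        self.c = float(c)

    def __call__(self, t):
        import numpy as np
        t = np.atleast_1d(np.asarray(t, dtype=float))
        integ = np.array([self.u1.integral(self.t0, ti) for ti in t])
        out = self.eps1_0 * np.exp(-integ - self.c * (t - self.t0))
        return out if out.size > 1 else float(out[0])

    def decay_rate(self, t: float) -> float:
        """Instantaneous decay rate u1(t) + c (1/h)."""
        return float(self.u1(t)) + self.c


def closed_form_error(reduced: ReducedDAE, scenario,
                      eps1_0: float) -> ClosedFormError:
    """Closed-form eps1 trajectory for reductions whose eps1 equation is
    deps1/dt = -eps1*(u1 + c) with c a positive parameter constant.

    Applies to the with-uncertainty reductions for measured substrate or
    oxygen with a matching single-variable Monod form (the constant is
    beta_m + Yo*mo or beta_m + Ys*ms); other cases raise ValueError.
    """
    if 1 not in reduced.differential:
        raise ValueError("reduction has no eps1 differential equation "
                         "(measured output is nu1)")
    e = reduced.differential[1]
    diag = sp.simplify(sp.cancel(e / sym.eps1))
    if diag.has(*sym.EPS) or diag.has(*sym.NU):
        raise ValueError("eps1 equation is not autonomous-linear; no "
                         "gamma-form closed solution for this case")
    c_expr = sp.simplify(-diag - sym.u1)
    if c_expr.has(sym.u1, sym.u2):
        raise ValueError("eps1 decay is not of the u1 + constant form")
    c = float(c_expr.subs(reduced.model.numeric_subs()))
    if c <= 0:
        raise ValueError(f"nonpositive decay constant {c}")
    return ClosedFormError(eps1_0=eps1_0, t0=scenario.horizon[0],
                           u1_signal=scenario.inputs.u1, c=c)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

#: wash-out sub-case labels for the unknown-input difference with
#: uncertainty present.  These six cells encode the declarative wash-out case analyses
#: (IC: biomass zero from the initial condition, so dD = (mu'-mu)*nu1 is
#: identically zero; asymptotic: biomass decays to zero); they are recorded
#: as asserted conclusions rather than re-derived, because the underlying
#: treatment of the IC/asymptotic distinction is declarative.
_DELTA_WASHOUT = {
    (2, "washout_ic"): Assessment(True, False, "wash-out (IC) analysis",
                                  asserted=True),
    (2, "washout_asymptotic"): Assessment(False, False,
                                          "wash-out (asymptotic) analysis",
                                          asserted=True),
    (5, "washout_ic"): Assessment(True, True, "wash-out (IC) analysis",
                                  asserted=True),
    (5, "washout_asymptotic"): Assessment(False, True,
                                          "wash-out (asymptotic) analysis",
                                          asserted=True),
    (7, "washout_ic"): Assessment(False, False, "wash-out (IC) analysis",
                                  asserted=True),
    (7, "washout_asymptotic"): Assessment(False, False,
                                          "wash-out (asymptotic) analysis",
                                          asserted=True),
}


def _forced_zero_states(reduced: ReducedDAE, washout: bool) -> set:
    """Error coordinates forced to vanish identically by the algebraic
    constraint of an uncertainty-free reduction.

    A coordinate k is forced when the constraint factors as eps_k times a
    sign-definite expression (sign decided under the physical positivity of
    states, parameters and the copy state z_k = nu_k - eps_k > 0).  In a
    wash-out sub-case nu1 = 0 annihilates kinetic mismatch terms first,
    which typically leaves the constraint vacuous.
    """
    if reduced.with_uncertainty:
        return set()
    cons = reduced.algebraic
    if washout:
        cons = sp.simplify(cons.subs(sym.nu1, 0))
    if cons == 0:
        return set()
    forced = set()
    for k in (1, 2, 3):
        eps_k = sym.EPS[k - 1]
        if not cons.has(eps_k):
            continue
        if sp.simplify(cons.subs(eps_k, 0)) != 0:
            continue
        q = sp.cancel(sp.together(cons) / eps_k)
        if q.has(*sym.EPS):
            # replace eps_k via the positive copy coordinate z_k
            q = sp.simplify(q.subs(eps_k, sym.NU[k - 1] - sym.Z[k - 1]))
        if q.has(*sym.EPS):
            continue
        q = sp.simplify(q)
        if q.is_positive or q.is_negative:
            forced.add(k)
    return forced


def _decaying_states(reduced: ReducedDAE, forced: set, washout: bool) -> set:
    """Error coordinates whose reduced ODE decays exponentially.

    Detects the triangular structure deps_i/dt = a_i(t)*eps_i + b_i(eps_rest)
    with a_i sign-definite negative (it always contains -u1, and the known
    inputs are strictly positive) and b_i vanishing once already-decaying
    (or forced-zero) errors are set to zero; the cascade is resolved
    iteratively, mirroring the role of the gamma forcing term."""
    sub = {sym.EPS[k - 1]: 0 for k in forced}
    if washout:
        sub[sym.nu1] = 0
    eqs = {i: sp.simplify(sp.expand(e.subs(sub)))
           for i, e in reduced.differential.items() if i not in forced}
    settled = set(forced)
    decaying = set()
    progress = True
    while progress:
        progress = False
        for i, e in eqs.items():
            if i in decaying:
                continue
            eps_i = sym.EPS[i - 1]
            diag = sp.simplify(sp.diff(e, eps_i))
            if diag.has(*sym.EPS):
                continue
            if diag.is_negative is not True:
                continue
            rest = sp.simplify(e - diag * eps_i)
            rest0 = sp.simplify(rest.subs(
                {sym.EPS[k - 1]: 0 for k in (decaying | settled | {i})}))
            if rest0 != 0:
                continue
            if any(rest.has(sym.EPS[k - 1])
                   for k in (1, 2, 3) if k not in decaying | settled | {i}):
                continue
            decaying.add(i)
            progress = True
    return decaying


def classify_states(reduced: ReducedDAE, subcase: str = "generic",
                    geometric_observable: Optional[bool] = None
                    ) -> CaseClassification:
    """Per-state and per-dD observability/detectability labels.

    Rules, in order:

    * the measured state is 'measured';
    * a state whose error is algebraically forced to zero for all t
      (uncertainty-free constraint factoring / Monod-difference identity)
      is observable;
    * when the geometric sufficient condition holds for the case, unmeasured
      states inherit observability (the output map is injective away from
      singular points, so equal outputs imply equal states) — except in
      uncertainty-free wash-out sub-cases, where the vanishing biomass
      removes the kinetic coupling the rank condition relies on;
    * a state whose reduced error ODE decays exponentially (negative
      sign-definite diagonal, forcing terms driven by already-decaying
      errors) is detectable;
    * dD is observable with the geometric condition (matching condition plus
      state observability), detectable when its expression vanishes as the
      driving errors decay; wash-out sub-cases follow the declarative
      conclusions and are flagged ``asserted``.
    """
    if subcase not in SUBCASES:
        raise ValueError(f"unknown subcase {subcase!r}")
    case = reduced.case
    if subcase != "generic" and case.case_id not in WASHOUT_CASES:
        raise ValueError(
            f"case {case.case_id} measures nu{case.output_index}; wash-out "
            "sub-cases exist only for measured biomass (nu1)")
    washout = subcase != "generic"
    geo = (geometric_observable if geometric_observable is not None
           else is_geometrically_observable(case.case_id))

    forced = _forced_zero_states(reduced, washout)
    decaying = _decaying_states(reduced, forced, washout)

    states = {}
    j = reduced.constrained_index
    for i, key in enumerate(STATE_KEYS, start=1):
        if i == j:
            states[key] = MEASURED
            continue
        if not reduced.with_uncertainty and i in forced:
            states[key] = Assessment(True, True,
                                     "algebraic constraint forces eps = 0")
        elif geo and (reduced.with_uncertainty or not washout):
            states[key] = Assessment(True, True, "geometric rank condition")
        elif i in decaying or i in forced:
            states[key] = Assessment(False, True,
                                     "exponential decay of reduced error ODE")
        else:
            states[key] = Assessment(False, False, "no decay structure found")

    if not reduced.with_uncertainty:
        states[DELTA_KEY] = Assessment(None, None, "no uncertainty present")
    elif washout:
        states[DELTA_KEY] = _DELTA_WASHOUT[(case.case_id, subcase)]
    elif geo:
        states[DELTA_KEY] = Assessment(
            True, True, "matching condition with observable states")
    else:
        d0 = sp.simplify(reduced.algebraic.subs(
            {e: 0 for e in sym.EPS}))
        if d0 == 0:
            states[DELTA_KEY] = Assessment(
                False, True, "dD vanishes with the decaying errors")
        else:
            states[DELTA_KEY] = Assessment(False, False,
                                           "dD does not vanish at zero error")
    return CaseClassification(case=case, subcase=subcase,
                              with_uncertainty=reduced.with_uncertainty,
                              states=states)


@lru_cache(maxsize=None)
def default_reduction(case_id: int, with_uncertainty: bool) -> ReducedDAE:
    """Reduced DAE for a case at the canonical default parameters (cached:
    the symbolic reduction is parameter-symbolic, so it is identical for
    every call with the same case)."""
    from .config import DEFAULT_KINETIC_BOUNDS, DEFAULT_PARAMS
    from .model import build_affine_model, mean_parameterize
    case = case_spec(case_id)
    sub = mean_parameterize(DEFAULT_KINETIC_BOUNDS, form=case.form)
    model = build_affine_model(DEFAULT_PARAMS, sub, case.output_index)
    err = build_error_system(model, with_uncertainty=with_uncertainty)
    return reduce_for_output(err, model)


@lru_cache(maxsize=None)
def _classify_default(case_id: int, with_uncertainty: bool,
                      subcase: str) -> CaseClassification:
    return classify_states(default_reduction(case_id, with_uncertainty),
                           subcase=subcase)


def classify_case(case_id: int, with_uncertainty: bool,
                  subcase: str = "generic", params=None) -> CaseClassification:
    """Build, reduce and classify one case end to end."""
    if params is None:
        return _classify_default(case_id, with_uncertainty, subcase)
    from .model import build_affine_model, mean_parameterize
    from .config import DEFAULT_KINETIC_BOUNDS
    case = case_spec(case_id)
    sub = mean_parameterize(DEFAULT_KINETIC_BOUNDS, form=case.form)
    model = build_affine_model(params, sub, case.output_index)
    err = build_error_system(model, with_uncertainty=with_uncertainty)
    reduced = reduce_for_output(err, model)
    return classify_states(reduced, subcase=subcase)
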