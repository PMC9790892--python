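"""Cognitive CSTR model and its uncertainty-decomposed affine form.

The bioreactor is a continuous stirred tank reactor (CSTR) in aerobic phase
with three aggregated state variables: biomass X = nu1, substrate S = nu2 and
dissolved oxygen O = nu3 (all g/L).  The mass-balance dynamics are

    dX/dt = r - beta_m*X - D*X
    dS/dt = -r/Ys - ms*X + (Sin - S)*D
    dO/dt = -r/Yo - mo*X + (Oin - O)*D + (Os - O)*kLa

with reaction kinetics r = mu(t)*X, where mu is a (time-varying, uncertain)
Monod growth-rate law.  For observability analysis the uncertain kinetics is
replaced by an exactly known, time-invariant substitute Monod function
mu_hat, and the mismatch is eliminated into a scalar unknown input

    Delta(nu, t) = [mu_SO(t) - mu_hat(nu)] * nu1

entering through the constant direction field rho = [1, -1/Ys, -1/Yo], which
yields the affine form  dnu/dt = phi_hat(nu) + theta1(nu)*u1 + theta2(nu)*u2
+ rho*Delta with known inputs u1 = D and u2 = kLa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import sympy as sp

from . import symbols as sym
from .signals import TimeSignal

Form = Literal["S", "O", "SO"]

#: which state coordinates (1-based) each Monod form depends on
FORM_STATES = {"S": (2,), "O": (3,), "SO": (2, 3)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaBounds:
    """Box bounds of the invariant set Omega (g/L), 0 < lower < upper."""

    lower: tuple  # (X_low, S_low, O_low)
    upper: tuple  # (X_up, S_up, O_up)

    def __post_init__(self):
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("Omega bounds need 3 components")
        for lo, up in zip(self.lower, self.upper):
            if not (0 < lo < up):
                raise ValueError(f"need 0 < lower < upper, got [{lo}, {up}]")

    def contains(self, state, rtol: float = 0.0) -> bool:
        s = np.asarray(state, dtype=float)
        lo = np.asarray(self.lower) * (1 - rtol)
        up = np.asarray(self.upper) * (1 + rtol)
        return bool(np.all(s >= lo) and np.all(s <= up))

    def sample(self, rng: np.random.Generator, margin: float = 0.0):
        lo = np.asarray(self.lower)
        up = np.asarray(self.upper)
        span = up - lo
        return rng.uniform(lo + margin * span, up - margin * span)


@dataclass(frozen=True)
class StateVector:
    """Concentrations (X, S, O) in g/L; finite and non-negative."""

    nu1: float
    nu2: float
    nu3: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state must be finite")
        if np.any(arr < 0):
            raise ValueError(f"state must be non-negative, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.nu1, self.nu2, self.nu3], dtype=float)

    def in_omega(self, bounds: OmegaBounds) -> bool:
        return bounds.contains(self.as_array())


@dataclass(frozen=True)
class CSTRParameters:
    """Positive yield/maintenance/inflow parameters of the CSTR."""

    Ys: float     # substrate yield coefficient [-]
    Yo: float     # oxygen yield coefficient [-]
    Sin: float    # inflow substrate concentration [g/L]
    Oin: float    # inflow dissolved oxygen concentration [g/L]
    Os: float     # oxygen saturation constant [g/L]
    beta_m: float  # biomass mortality rate [1/h]
    ms: float     # substrate maintenance coefficient [1/h]
    mo: float     # oxygen maintenance coefficient [1/h]

    def __post_init__(self):
        for name in ("Ys", "Yo", "Sin", "Oin", "Os", "beta_m", "ms", "mo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    def subs_map(self) -> dict:
        """Numeric substitution dict for the shared parameter symbols."""
        return {s: getattr(self, name) for name, s in sym.PARAM_SYMBOLS.items()}


@dataclass(frozen=True)
class TrueKinetics:
    """Time-varying bounded Monod coefficients of the 'true' kinetics.

    mu_max(t) [1/h], Ks(t) [g/L], Ko(t) [g/L] are strictly positive bounded
    signals; ``form`` selects the S-only, O-only or product (SO) Monod law.
    The nine-case analysis fixes the SO product as the true kinetics.
    """

    mu_max: TimeSignal
    Ks: TimeSignal
    Ko: TimeSignal
    form: Form = "SO"

    def __post_init__(self):
        if self.form not in FORM_STATES:
            raise ValueError(f"unknown form {self.form!r}")
        for name in ("mu_max", "Ks", "Ko"):
            sig = getattr(self, name)
            if sig.lower <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def mu(self, t, s, o) -> float:
        """Specific growth rate at time t, substrate s, oxygen o."""
        return _monod(self.form, self.mu_max(t), self.Ks(t), self.Ko(t), s, o)


@dataclass(frozen=True)
class SubstituteKinetics:
    """Time-invariant substitute Monod function (exactly known)."""

    mu_max0: float  # [1/h]
    Ks0: float      # [g/L]
    Ko0: float      # [g/L]
    form: Form = "SO"

    def __post_init__(self):
        if self.form not in FORM_STATES:
            raise ValueError(f"unknown form {self.form!r}")
        for name in ("mu_max0", "Ks0", "Ko0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mu(self, s, o) -> float:
        return _monod(self.form, self.mu_max0, self.Ks0, self.Ko0, s, o)

    def expr(self, s=None, o=None) -> sp.Expr:
        """Symbolic mu_hat with symbolic constants, evaluated at state
        expressions ``s``, ``o`` (default: the canonical state symbols)."""
        s = sym.nu2 if s is None else s
        o = sym.nu3 if o is None else o
        return monod_expr(self.form, s, o)

    def subs_map(self) -> dict:
        return {sym.mu_max0: self.mu_max0, sym.K_s0: self.Ks0,
                sym.K_o0: self.Ko0}


@dataclass(frozen=True)
class InputSignals:
    """Known inputs: dilution rate u1 = D(t) and oxygen transfer u2 = kLa(t),
    strictly positive and bounded (1/h)."""

    u1: TimeSignal
    u2: TimeSignal
    u1_bound: float
    u2_bound: float

    def __post_init__(self):
        if self.u1.lower <= 0 or self.u1.upper > self.u1_bound + 1e-12:
            raise ValueError("u1 must satisfy 0 < u1(t) <= u1_bound")
        if self.u2.lower <= 0 or self.u2.upper > self.u2_bound + 1e-12:
            raise ValueError("u2 must satisfy 0 < u2(t) <= u2_bound")


@dataclass(frozen=True)
class AffineModel:
    """Symbolic affine decomposition for one measured-output case.

    drift = phi_hat(nu) uses only the substitute kinetics; field_u1/field_u2
    multiply the known inputs; field_rho = [1, -1/Ys, -1/Yo] carries the
    unknown input.  ``output_index`` selects the measured coordinate.
    """

    drift: sp.Matrix
    field_u1: sp.Matrix
    field_u2: sp.Matrix
    field_rho: sp.Matrix
    output_index: int
    substitute: SubstituteKinetics
    params: CSTRParameters

    @property
    def output(self) -> sp.Expr:
        return sym.NU[self.output_index - 1]

    @property
    def mu_hat(self) -> sp.Expr:
        return self.substitute.expr()

    def numeric_subs(self) -> dict:
        m = self.params.subs_map()
        m.update(self.substitute.subs_map())
        return m

    def rhs_numeric(self, state, t, inputs: InputSignals, delta: float = 0.0):
        """Evaluate drift + theta1*u1 + theta2*u2 + rho*delta at a point."""
        x, s, o = np.asarray(state, dtype=float)
        p = self.params
        mu = self.substitute.mu(s, o)
        d = float(inputs.u1(t))
        kla = float(inputs.u2(t))
        drift = np.array([
            mu * x - p.beta_m * x,
            -mu * x / p.Ys - p.ms * x,
            -mu * x / p.Yo - p.mo * x,
        ])
        th1 = np.array([-x, p.Sin - s, p.Oin - o])
        th2 = np.array([0.0, 0.0, p.Os - o])
        rho = np.array([1.0, -1.0 / p.Ys, -1.0 / p.Yo])
        return drift + th1 * d + th2 * kla + rho * delta


@dataclass(frozen=True)
class UnknownInputTrace:
    """Sampled unknown-input signal Delta(nu(t), t) with a known bound."""

    t: np.ndarray
    delta: np.ndarray
    bound: float

    def __post_init__(self):
        if np.any(np.abs(self.delta) > self.bound + 1e-12):
            raise ValueError("|delta| exceeds its declared bound")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _monod(form: Form, mu_max, Ks, Ko, s, o):
    if s < 0 or o < 0:
        raise ValueError("negative concentration")
    if mu_max <= 0 or Ks <= 0 or Ko <= 0:
        raise ValueError("non-positive kinetic parameter")
    if form == "S":
        return mu_max * s / (Ks + s)
    if form == "O":
        return mu_max * o / (Ko + o)
    return mu_max * (s / (Ks + s)) * (o / (Ko + o))


def monod_expr(form: Form, s: sp.Expr, o: sp.Expr) -> sp.Expr:
    """Symbolic Monod law with the shared substitute-constant symbols."""
    if form == "S":
        return sym.mu_max0 * s / (sym.K_s0 + s)
    if form == "O":
        return sym.mu_max0 * o / (sym.K_o0 + o)
    if form == "SO":
        return sym.mu_max0 * (s / (sym.K_s0 + s)) * (o / (sym.K_o0 + o))
    raise ValueError(f"unknown form {form!r}")


def monod_rate(state: StateVector, kin, t: float = 0.0) -> float:
    """Specific growth rate mu [1/h] of either kinetics at ``state``.

    ``kin`` is a TrueKinetics (evaluated at time t) or SubstituteKinetics.
    """
    if isinstance(kin, TrueKinetics):
        return float(kin.mu(t, state.nu2, state.nu3))
    if isinstance(kin, SubstituteKinetics):
        return float(kin.mu(state.nu2, state.nu3))
    raise TypeError(f"unsupported kinetics type {type(kin).__name__}")


def mean_parameterize(bounds: dict, form: Form = "SO") -> SubstituteKinetics:
    """Substitute kinetics from per-parameter [min, max] bounds.

    Each constant is the arithmetic midpoint of the corresponding bound
    interval; ``bounds`` maps 'mu_max', 'Ks', 'Ko' to (min, max) pairs.
    """
    mids = {}
    for name in ("mu_max", "Ks", "Ko"):
        lo, hi = bounds[name]
        if not (0 < lo <= hi):
            raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
        mids[name] = 0.5 * (lo + hi)
    return SubstituteKinetics(mu_max0=mids["mu_max"], Ks0=mids["Ks"],
                              Ko0=mids["Ko"], form=form)


def build_affine_model(params: CSTRParameters, sub: SubstituteKinetics,
                       output_index: int) -> AffineModel:
    """Symbolic affine-form components for one measured-output case."""
    if output_index not in (1, 2, 3):
        raise ValueError(f"output_index must be 1, 2 or 3, got {output_index}")
    mu = monod_expr(sub.form, sym.nu2, sym.nu3)
    drift = sp.Matrix([
        mu * sym.nu1 - sym.beta_m * sym.nu1,
        -mu * sym.nu1 / sym.Y_s - sym.m_s * sym.nu1,
        -mu * sym.nu1 / sym.Y_o - sym.m_o * sym.nu1,
    ])
    th1 = sp.Matrix([-sym.nu1, sym.S_in - sym.nu2, sym.O_in - sym.nu3])
    th2 = sp.Matrix([0, 0, sym.O_s - sym.nu3])
    rho = sp.Matrix([1, -1 / sym.Y_s, -1 / sym.Y_o])
    return AffineModel(drift=drift, field_u1=th1, field_u2=th2, field_rho=rho,
                       output_index=output_index, substitute=sub, params=params)


def true_rhs(state, params: CSTRParameters, true_kin: TrueKinetics,
             inputs: InputSignals, t: float) -> np.ndarray:
    """Right-hand side of the cognitive CSTR model with the true kinetics
    r(t) = mu(t)*X(t)."""
    x, s, o = np.asarray(state, dtype=float)
    mu = true_kin.mu(t, s, o)
    r = mu * x
    d = float(inputs.u1(t))
    kla = float(inputs.u2(t))
    return np.array([
        r - params.beta_m * x - x * d,
        -r / params.Ys - params.ms * x + (params.Sin - s) * d,
        -r / params.Yo - params.mo * x + (params.Oin - o) * d
        + (params.Os - o) * kla,
    ])


def delta_unknown_input(state, true_kin: TrueKinetics,
                        sub: SubstituteKinetics, t: float) -> float:
    """Unknown input Delta = [mu_true(t) - mu_hat]*nu1 at a point."""
    x, s, o = np.asarray(state, dtype=float)
    if x == 0.0:
        return 0.0
    return float((true_kin.mu(t, s, o) - sub.mu(s, o)) * x)


def delta_bound(true_kin: TrueKinetics, sub: SubstituteKinetics,
                omega: OmegaBounds) -> float:
    """Conservative bound on |Delta| over Omega: both growth rates are below
    their mu_max ceilings, so |Delta| <= (max mu_true + mu_max0) * X_bar."""
    return (true_kin.mu_max.upper + sub.mu_max0) * omega.upper[0]
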