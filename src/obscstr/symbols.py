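"""Shared sympy symbol table for the CSTR analysis.

All symbolic stages of the pipeline (affine model construction, Lie-derivative
observability, error-system reduction) operate on the same globally named
symbols so expressions from different modules compose without renaming.

State symbols are declared positive: the invariant set of the bioreactor is a
box of strictly positive concentrations, and positivity assumptions let sympy
decide the sign of reduction coefficients (e.g. that a constraint factor
``mu_hat_O + Y_o*m_o`` is strictly positive).  Error symbols are merely real —
an error can take either sign.
"""

import sympy as sp

# state: biomass X, substrate S, dissolved oxygen O (g/L)
nu1, nu2, nu3 = sp.symbols("nu1 nu2 nu3", positive=True)
NU = (nu1, nu2, nu3)

# copy state z = nu - eps (used for sign reasoning on reduced constraints)
z1, z2, z3 = sp.symbols("z1 z2 z3", positive=True)
Z = (z1, z2, z3)

# error coordinates eps = nu - z
eps1, eps2, eps3 = sp.symbols("epsilon1 epsilon2 epsilon3", real=True)
EPS = (eps1, eps2, eps3)

# known inputs: dilution rate D and oxygen transfer kLa (1/h), strictly positive
u1, u2 = sp.symbols("u1 u2", positive=True)

# unknown-input difference delta-Delta between original and copy
delta_Delta = sp.Symbol("deltaDelta", real=True)

# CSTR parameters (all strictly positive)
Y_s, Y_o = sp.symbols("Y_s Y_o", positive=True)
S_in, O_in, O_s = sp.symbols("S_in O_in O_s", positive=True)
beta_m, m_s, m_o = sp.symbols("beta_m m_s m_o", positive=True)

# time-invariant substitute Monod constants
mu_max0, K_s0, K_o0 = sp.symbols("mu_max0 K_s0 K_o0", positive=True)

PARAM_SYMBOLS = {
    "Ys": Y_s,
    "Yo": Y_o,
    "Sin": S_in,
    "Oin": O_in,
    "Os": O_s,
    "beta_m": beta_m,
    "ms": m_s,
    "mo": m_o,
}

KINETIC_SYMBOLS = {
    "mu_max0": mu_max0,
    "Ks0": K_s0,
    "Ko0": K_o0,
}
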