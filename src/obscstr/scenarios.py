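"""Seeded generation of complete simulation scenarios.

A scenario bundles everything a paired simulation needs: a CSTR parameter
set, bounded time-varying true kinetics, strictly positive bounded input
signals, and a pair of distinct initial conditions inside the invariant box.
Regeneration with the same seed is bit-for-bit reproducible; scenarios can be
round-tripped through YAML so a failing case is replayable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from . import config as cfg
from .model import (CSTRParameters, InputSignals, OmegaBounds, StateVector,
                    SubstituteKinetics, TrueKinetics, mean_parameterize)
from .signals import Constant, PiecewiseConstant, Sinusoid, TimeSignal, \
    signal_from_dict

#: minimum per-component separation between original and copy ICs [g/L]
MIN_IC_SEPARATION = 1e-3


@dataclass(frozen=True)
class ScenarioBundle:
    params: CSTRParameters
    true_kin: TrueKinetics
    kinetic_bounds: dict
    inputs: InputSignals
    ic_original: StateVector
    ic_copy: StateVector
    omega: OmegaBounds
    horizon: tuple
    seed: int
    washout: bool = False

    def substitute(self, form: str = "SO") -> SubstituteKinetics:
        """Mean-parameterised substitute kinetics for this scenario."""
        return mean_parameterize(self.kinetic_bounds, form=form)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "washout": self.washout,
            "horizon": list(self.horizon),
            "params": dataclasses.asdict(self.params),
            "kinetic_bounds": {k: list(v) for k, v in self.kinetic_bounds.items()},
            "true_kin": {
                "form": self.true_kin.form,
                "mu_max": self.true_kin.mu_max.to_dict(),
                "Ks": self.true_kin.Ks.to_dict(),
                "Ko": self.true_kin.Ko.to_dict(),
            },
            "inputs": {
                "u1": self.inputs.u1.to_dict(),
                "u2": self.inputs.u2.to_dict(),
                "u1_bound": self.inputs.u1_bound,
                "u2_bound": self.inputs.u2_bound,
            },
            "ic_original": [float(v) for v in self.ic_original.as_array()],
            "ic_copy": [float(v) for v in self.ic_copy.as_array()],
            "omega": {"lower": list(self.omega.lower),
                      "upper": list(self.omega.upper)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioBundle":
        tk = d["true_kin"]
        return cls(
            params=CSTRParameters(**d["params"]),
            true_kin=TrueKinetics(
                mu_max=signal_from_dict(tk["mu_max"]),
                Ks=signal_from_dict(tk["Ks"]),
                Ko=signal_from_dict(tk["Ko"]),
                form=tk["form"]),
            kinetic_bounds={k: tuple(v) for k, v in d["kinetic_bounds"].items()},
            inputs=InputSignals(
                u1=signal_from_dict(d["inputs"]["u1"]),
                u2=signal_from_dict(d["inputs"]["u2"]),
                u1_bound=d["inputs"]["u1_bound"],
                u2_bound=d["inputs"]["u2_bound"]),
            ic_original=StateVector(*d["ic_original"]),
            ic_copy=StateVector(*d["ic_copy"]),
            omega=OmegaBounds(lower=tuple(d["omega"]["lower"]),
                              upper=tuple(d["omega"]["upper"])),
            horizon=tuple(d["horizon"]),
            seed=d["seed"],
            washout=d["washout"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioBundle":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_input_signal(seed: int, bound: float,
                          kind: str = "sinusoid",
                          horizon: tuple = cfg.DEFAULT_HORIZON) -> TimeSignal:
    """A strictly positive signal with 0 < s(t) <= bound for all t.

    Draws stay well away from zero (floor >= 0.42*bound for the sinusoid
    kind) so that error modes decaying at the dilution rate reach small
    tolerances within the verification horizon.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return Constant(float(rng.uniform(0.4, 0.95) * bound))
    if kind == "sinusoid":
        amp_frac = float(rng.uniform(0.05, 0.3))
        mean = float(rng.uniform(0.6, 0.95 / (1 + amp_frac)) * bound)
        omega = float(rng.uniform(0.05, 0.5))       # rad/h
        phase = float(rng.uniform(0, 2 * np.pi))
        return Sinusoid(mean=mean, amp=amp_frac * mean, omega=omega,
                        phase=phase)
    if kind == "piecewise":
        n = int(rng.integers(3, 6))
        t0, tf = horizon
        knots = np.sort(rng.uniform(t0, tf, size=n - 1))
        knots = np.concatenate([[t0], knots])
        levels = rng.uniform(0.4, 0.95, size=n) * bound
        return PiecewiseConstant(tuple(float(k) for k in knots),
                                 tuple(float(v) for v in levels))
    raise ValueError(f"unknown signal kind {kind!r}")


def _kinetic_signal(rng: np.random.Generator, lo: float, hi: float) -> TimeSignal:
    """Smooth bounded signal strictly inside [lo, hi]: midpoint plus a
    sinusoid with amplitude at most 80% of the half-width."""
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    amp = float(rng.uniform(0.2, 0.8)) * half if half > 0 else 0.0
    omega = float(rng.uniform(0.05, 0.5))
    phase = float(rng.uniform(0, 2 * np.pi))
    return Sinusoid(mean=mid, amp=amp, omega=omega, phase=phase)


def _perturbed_params(rng: np.random.Generator,
                      base: CSTRParameters) -> CSTRParameters:
    fields = dataclasses.asdict(base)
    return CSTRParameters(**{k: v * float(rng.uniform(0.8, 1.2))
                             for k, v in fields.items()})


def generate_scenario(seed: int, washout: bool = False,
                      equal_ic: bool = False,
                      horizon: tuple = cfg.DEFAULT_HORIZON,
                      perturb_params: bool = True) -> ScenarioBundle:
    """Full seeded scenario satisfying every downstream precondition.

    washout: original IC starts with zero biomass (nu1 = 0), the other two
    components interior to Omega.  equal_ic: copy IC equals the original.
    perturb_params: draw parameters uniformly within +-20% of the canonical
    defaults (False keeps the defaults exactly).
    """
    t0, tf = horizon
    if tf <= t0:
        raise ValueError("horizon length must be positive")
    ss = np.random.SeedSequence(seed)
    r_par, r_kin, r_u1, r_u2, r_ic = [np.random.default_rng(s)
                                      for s in ss.spawn(5)]

    params = (_perturbed_params(r_par, cfg.DEFAULT_PARAMS)
              if perturb_params else cfg.DEFAULT_PARAMS)
    kb = dict(cfg.DEFAULT_KINETIC_BOUNDS)
    true_kin = TrueKinetics(
        mu_max=_kinetic_signal(r_kin, *kb["mu_max"]),
        Ks=_kinetic_signal(r_kin, *kb["Ks"]),
        Ko=_kinetic_signal(r_kin, *kb["Ko"]),
        form="SO")
    u1_bound = cfg.DEFAULT_INPUT_BOUNDS["D"]
    u2_bound = cfg.DEFAULT_INPUT_BOUNDS["kLa"]
    inputs = InputSignals(
        u1=generate_input_signal(int(r_u1.integers(2**31)), u1_bound,
                                 "sinusoid", horizon),
        u2=generate_input_signal(int(r_u2.integers(2**31)), u2_bound,
                                 "sinusoid", horizon),
        u1_bound=u1_bound, u2_bound=u2_bound)

    omega = cfg.DEFAULT_OMEGA
    ic_orig = omega.sample(r_ic, margin=0.1)
    if washout:
        ic_orig[0] = 0.0
    if equal_ic:
        ic_copy = ic_orig.copy()
    else:
        ic_copy = omega.sample(r_ic, margin=0.1)
        # enforce a minimum separation so convergence tests are non-trivial
        for i in range(3):
            while abs(ic_copy[i] - ic_orig[i]) < MIN_IC_SEPARATION:
                ic_copy[i] = omega.sample(r_ic, margin=0.1)[i]

    return ScenarioBundle(
        params=params, true_kin=true_kin, kinetic_bounds=kb, inputs=inputs,
        ic_original=StateVector(*ic_orig), ic_copy=StateVector(*ic_copy),
        omega=omega, horizon=(float(t0), float(tf)), seed=seed,
        washout=washout)
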