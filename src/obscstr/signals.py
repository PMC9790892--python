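"""Bounded positive time signals.

The analysis only assumes that the known inputs D(t), kLa(t) and the
time-varying "true" kinetic coefficients are strictly positive and bounded.
These classes realise that contract with smooth or piecewise-constant shapes
and carry their own exact running integral, which the closed-form error
solution gamma(t) = eps1(t0)*exp(-int u1 - c*(t-t0)) needs without quadrature
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSignal",
    "Constant",
    "Sinusoid",
    "PiecewiseConstant",
    "signal_from_dict",
]


class TimeSignal:
    """A scalar function of time with known [min, max] bounds."""

    lower: float
    upper: float

    def value(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def integral(self, t0: float, t1: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, t):
        return self.value(t)

    def to_dict(self) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Constant(TimeSignal):
    c: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"constant signal must be positive, got {self.c}")

    @property
    def lower(self):
        return self.c

    @property
    def upper(self):
        return self.c

    def value(self, t):
        return self.c * np.ones_like(np.asarray(t, dtype=float))

    def integral(self, t0, t1):
        return self.c * (t1 - t0)

    def to_dict(self):
        return {"kind": "constant", "c": self.c}


@dataclass(frozen=True)
class Sinusoid(TimeSignal):
    """mean + amp*sin(omega*t + phase); requires 0 < amp < mean so the
    signal stays strictly positive."""

    mean: float
    amp: float
    omega: float
    phase: float = 0.0

    def __post_init__(self):
        if not (0 <= self.amp < self.mean):
            raise ValueError("need 0 <= amp < mean for strict positivity")

    @property
    def lower(self):
        return self.mean - self.amp

    @property
    def upper(self):
        return self.mean + self.amp

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.mean + self.amp * np.sin(self.omega * t + self.phase)

    def integral(self, t0, t1):
        if self.omega == 0.0:
            return (self.mean + self.amp * math.sin(self.phase)) * (t1 - t0)
        osc = (math.cos(self.omega * t0 + self.phase)
               - math.cos(self.omega * t1 + self.phase)) / self.omega
        return self.mean * (t1 - t0) + self.amp * osc

    def to_dict(self):
        return {"kind": "sinusoid", "mean": self.mean, "amp": self.amp,
                "omega": self.omega, "phase": self.phase}


@dataclass(frozen=True)
class PiecewiseConstant(TimeSignal):
    """Right-open steps: value is levels[i] on [knots[i], knots[i+1]);
    the last level extends to +inf."""

    knots: tuple = field(default=())
    levels: tuple = field(default=())

    def __post_init__(self):
        if len(self.levels) != len(self.knots):
            raise ValueError("need one level per knot")
        if not self.levels:
            raise ValueError("empty piecewise signal")
        if any(lv <= 0 for lv in self.levels):
            raise ValueError("levels must be positive")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")

    @property
    def lower(self):
        return min(self.levels)

    @property
    def upper(self):
        return max(self.levels)

    def value(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.knots, t, side="right") - 1, 0, None)
        return np.asarray(self.levels)[idx]

    def integral(self, t0, t1):
        if t1 < t0:
            return -self.integral(t1, t0)
        total = 0.0
        edges = list(self.knots) + [math.inf]
        for i, lv in enumerate(self.levels):
            a = max(t0, edges[i])
            b = min(t1, edges[i + 1])
            if b > a:
                total += lv * (b - a)
        # leading segment before the first knot uses the first level
        if t0 < edges[0]:
            total += self.levels[0] * (min(t1, edges[0]) - t0)
        return total

    def to_dict(self):
        return {"kind": "piecewise", "knots": list(self.knots),
                "levels": list(self.levels)}


def signal_from_dict(d: dict) -> TimeSignal:
    kind = d["kind"]
    if kind == "constant":
        return Constant(d["c"])
    if kind == "sinusoid":
        return Sinusoid(d["mean"], d["amp"], d["omega"], d.get("phase", 0.0))
    if kind == "piecewise":
        return PiecewiseConstant(tuple(d["knots"]), tuple(d["levels"]))
    raise ValueError(f"unknown signal kind {kind!r}")
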