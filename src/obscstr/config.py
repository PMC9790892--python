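"""Canonical defaults and run configuration.

The analysis itself is structural/symbolic, so its conclusions do not hinge on
particular parameter values; the numeric defaults below are plausible
magnitudes for an aerobic activated-sludge CSTR (rates in 1/h, concentrations
in g/L) and define the conditions under which the numerical verification
stage runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import CSTRParameters, OmegaBounds

#: canonical CSTR parameter set
DEFAULT_PARAMS = CSTRParameters(
    Ys=0.65,      # substrate yield [-]
    Yo=0.2,       # oxygen yield [-]
    Sin=5.0,      # inflow substrate [g/L]
    Oin=0.5,      # inflow dissolved oxygen [g/L]
    Os=10.0,      # oxygen saturation [g/L]
    beta_m=0.05,  # biomass mortality [1/h]
    ms=0.05,      # substrate maintenance [1/h]
    mo=0.02,      # oxygen maintenance [1/h]
)

#: bounds of the time-varying true Monod coefficients
DEFAULT_KINETIC_BOUNDS = {
    "mu_max": (0.3, 0.5),   # [1/h]
    "Ks": (0.5, 1.5),       # [g/L]
    "Ko": (0.1, 0.3),       # [g/L]
}

#: invariant-set box Omega (X, S, O) [g/L]
DEFAULT_OMEGA = OmegaBounds(lower=(0.05, 0.05, 0.05), upper=(5.0, 6.0, 10.0))

#: upper bounds on the known inputs [1/h]
DEFAULT_INPUT_BOUNDS = {"D": 0.15, "kLa": 6.0}

#: default scenario horizon [h]
DEFAULT_HORIZON = (0.0, 50.0)

#: horizon used by the convergence-verification stage [h]; long enough for
#: the slowest error mode (decay rate ~ the dilution-rate floor) to fall
#: below the detectability tolerance
VERIFY_HORIZON = (0.0, 250.0)

#: absolute terminal tolerance for detectability [g/L] and the fraction of
#: the horizon used as the terminal window
DETECT_TOL = 1e-5
TERMINAL_WINDOW = 0.1

#: whole-horizon tolerance for constraint-enforced (observable) coordinates
OBSERVE_TOL = 1e-7


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    cases: tuple = tuple(range(1, 10))
    seed: int = 0
    n_verify_seeds: int = 3
    horizon: tuple = DEFAULT_HORIZON
    verify_horizon: tuple = VERIFY_HORIZON
    detect_tol: float = DETECT_TOL
    observe_tol: float = OBSERVE_TOL
    with_uncertainty: bool = True
    run_verification: bool = True
    output_dir: str = "obscstr_results"
    params: CSTRParameters = field(default_factory=lambda: DEFAULT_PARAMS)
    kinetic_bounds: dict = field(
        default_factory=lambda: dict(DEFAULT_KINETIC_BOUNDS))
    input_bounds: dict = field(
        default_factory=lambda: dict(DEFAULT_INPUT_BOUNDS))
    omega: OmegaBounds = field(default_factory=lambda: DEFAULT_OMEGA)

    def __post_init__(self):
        if any(c not in range(1, 10) for c in self.cases):
            raise ValueError("case ids must lie in 1..9")
        if self.detect_tol <= 0 or self.observe_tol <= 0:
            raise ValueError("tolerances must be positive")


def config_to_dict(cfg: AnalysisConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["params"] = dataclasses.asdict(cfg.params)
    d["omega"] = {"lower": list(cfg.omega.lower), "upper": list(cfg.omega.upper)}
    d["cases"] = list(cfg.cases)
    d["horizon"] = list(cfg.horizon)
    d["verify_horizon"] = list(cfg.verify_horizon)
    d["kinetic_bounds"] = {k: list(v) for k, v in cfg.kinetic_bounds.items()}
    return d


def config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    if "params" in d:
        d["params"] = CSTRParameters(**d["params"])
    if "omega" in d:
        d["omega"] = OmegaBounds(lower=tuple(d["omega"]["lower"]),
                                 upper=tuple(d["omega"]["upper"]))
    for key in ("cases", "horizon", "verify_horizon"):
        if key in d:
            d[key] = tuple(d[key])
    if "kinetic_bounds" in d:
        d["kinetic_bounds"] = {k: tuple(v)
                               for k, v in d["kinetic_bounds"].items()}
    return AnalysisConfig(**d)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
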