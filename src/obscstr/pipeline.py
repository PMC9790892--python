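"""Case orchestration: all nine cases through both stages, both uncertainty
settings, with consolidated summary tables.

The consolidated coding follows the legend M (measured), O (observable),
UO (unobservable), D (detectable); for the geometric stage O/UO mean meeting
or failing the sufficient rank condition for the full model.  Cases with
measured biomass carry wash-out sub-rows; a consolidated cell whose sub-rows
disagree is rendered as the union (e.g. "O/D").
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cases import ALL_CASES, SUBCASES, WASHOUT_CASES, enumerate_cases
from .config import AnalysisConfig, config_to_dict
from .geometry import classify_geometric
from .indistinguishable import STATE_KEYS, classify_case
from .scenarios import generate_scenario
from .verification import (make_washout_asymptotic, simulate_pair,
                           verify_convergence)

_STRENGTH = {"M": 3, "O": 2, "D": 1, "UO": 0}


@dataclasses.dataclass(frozen=True)
class SummaryTable:
    geometric: pd.DataFrame        # per-case sufficient-condition verdicts
    with_uncertainty: pd.DataFrame   # per-(case, sub-row) obs/det labels
    without_uncertainty: pd.DataFrame
    consolidated: pd.DataFrame     # M/O/UO/D coding, 3 stages x 3 states

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.geometric.to_csv(out / "table_geometric.csv", index=False)
        self.with_uncertainty.to_csv(
            out / "table_ind_with_uncertainty.csv", index=False)
        self.without_uncertainty.to_csv(
            out / "table_ind_without_uncertainty.csv", index=False)
        self.consolidated.to_csv(out / "table_consolidated.csv", index=False)


def _subcases_for(case_id: int):
    return SUBCASES if case_id in WASHOUT_CASES else ("generic",)


def _yn(flag):
    if flag is None:
        return "-"
    return "Yes" if flag else "No"


def _classification_rows(case_ids, with_uncertainty: bool) -> pd.DataFrame:
    rows = []
    for cid in case_ids:
        for sub in _subcases_for(cid):
            cls = classify_case(cid, with_uncertainty, subcase=sub)
            row = {"case": cid, "output": f"nu{cls.case.output_index}",
                   "form": cls.case.form, "subcase": sub}
            keys = STATE_KEYS + (("delta",) if with_uncertainty else ())
            for key in keys:
                a = cls.states[key]
                measured = key == f"nu{cls.case.output_index}"
                row[f"obs_{key}"] = "-" if measured else _yn(a.observable)
                row[f"det_{key}"] = "-" if measured else _yn(a.detectable)
            rows.append(row)
    return pd.DataFrame(rows)


def _code(label: str) -> str:
    return {"measured": "M", "observable": "O", "detectable": "D",
            "unobservable": "UO"}[label]


def _union(codes) -> str:
    uniq = sorted(set(codes), key=lambda c: -_STRENGTH[c])
    return "/".join(uniq)


def consolidated_coding(case_ids=range(1, 10)) -> pd.DataFrame:
    """Table of M/O/UO/D codes composed from the three upstream stages."""
    rows = []
    for cid in case_ids:
        geo = classify_geometric(cid)
        row = {"case": cid, "output": f"nu{geo.case.output_index}",
               "form": geo.case.form}
        for i, key in enumerate(STATE_KEYS, start=1):
            if i == geo.case.output_index:
                row[f"geom_{key}"] = "M"
            else:
                row[f"geom_{key}"] = ("O" if geo.verdict == "observable"
                                      else "UO")
        for with_unc, prefix in ((True, "unc"), (False, "nounc")):
            subrows = [classify_case(cid, with_unc, subcase=s)
                       for s in _subcases_for(cid)]
            for key in STATE_KEYS:
                codes = [_code(c.label(key)) for c in subrows]
                row[f"{prefix}_{key}"] = _union(codes)
        rows.append(row)
    return pd.DataFrame(rows)


def run_verification(case_id: int, config: AnalysisConfig,
                     with_uncertainty: bool = True) -> list:
    """Simulate and check one case over the configured seeds/sub-cases."""
    results = []
    rng = np.random.default_rng(config.seed + 1000 * case_id)
    for k in range(config.n_verify_seeds):
        seed = int(rng.integers(2**31))
        for sub in _subcases_for(case_id):
            if sub == "washout_ic":
                scen = generate_scenario(seed, washout=True,
                                         horizon=config.verify_horizon)
            else:
                scen = generate_scenario(seed, horizon=config.verify_horizon)
                if sub == "washout_asymptotic":
                    scen = make_washout_asymptotic(scen)
            cls = classify_case(case_id, with_uncertainty, subcase=sub)
            traj = simulate_pair(scen, case_id,
                                 with_uncertainty=with_uncertainty,
                                 subcase=sub)
            checks = verify_convergence(traj, cls, tol=config.detect_tol,
                                        observe_tol=config.observe_tol)
            results.append({"case": case_id, "subcase": sub, "seed": seed,
                            "with_uncertainty": with_uncertainty,
                            "checks": checks})
    return results


def run_all(config: AnalysisConfig) -> tuple:
    """Run every configured case through both stages; write artifacts.

    Returns (SummaryTable, ok) where ok is False if any verification check
    failed or was inconclusive.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    geo_rows, geo_reports = [], {}
    for cid in config.cases:
        rep = classify_geometric(cid)
        geo_reports[cid] = rep
        geo_rows.append({"case": cid, "output": f"nu{rep.case.output_index}",
                         "form": rep.case.form,
                         "observable": "Yes" if rep.verdict == "observable"
                         else "No"})
    geometric = pd.DataFrame(geo_rows)

    with_unc = _classification_rows(config.cases, True)
    without_unc = _classification_rows(config.cases, False)
    consolidated = consolidated_coding(config.cases)

    summary = SummaryTable(geometric=geometric, with_uncertainty=with_unc,
                           without_uncertainty=without_unc,
                           consolidated=consolidated)
    summary.write(out)

    with open(out / "geometric_reports.json", "w") as fh:
        json.dump({str(cid): rep.to_dict()
                   for cid, rep in geo_reports.items()},
                  fh, indent=2, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)

    ok = True
    if config.run_verification:
        ver_rows = []
        for cid in config.cases:
            for res in run_verification(cid, config,
                                        config.with_uncertainty):
                for chk in res["checks"]:
                    ver_rows.append({
                        "case": res["case"], "subcase": res["subcase"],
                        "seed": res["seed"], "key": chk.key,
                        "label": chk.label, "criterion": chk.criterion,
                        "value": chk.value, "passed": chk.passed,
                        "inconclusive": chk.inconclusive})
                    if not chk.passed or chk.inconclusive:
                        ok = False
        pd.DataFrame(ver_rows).to_csv(out / "verification.csv", index=False)
    return summary, ok


__all__ = ["ALL_CASES", "SummaryTable", "consolidated_coding",
           "enumerate_cases", "run_all", "run_verification"]
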