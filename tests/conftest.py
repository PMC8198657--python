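"""Shared fixtures: parameter sets, solved scenarios, calibrated model.

Expensive whole-kidney solves and the two-stage calibration run once per
session and are shared across test modules.
"""

import numpy as np
import pytest

import nephrosim as ns
from nephrosim.params import ParameterSet
from nephrosim.solutes import SOLUTES


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def scenario_table():
    return {
        "nd": ns.nondiabetic(),
        "nd_sglt2i": ns.with_sglt2i(ns.nondiabetic()),
        "dm_mod": ns.moderate_diabetes(),
        "dm_mod_txt": ns.moderate_diabetes(gfr_mode="results_text"),
        "dm_sev": ns.severe_diabetes(),
        "dm_mod_sglt2i": ns.with_sglt2i(
            ns.moderate_diabetes(gfr_mode="results_text")),
        "dm_sev_sglt2i": ns.with_sglt2i(ns.severe_diabetes()),
    }


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated parameter set plus the two stage results."""
    from nephrosim.calibration import calibrate
    params, results = calibrate()
    return params, results


@pytest.fixture(scope="session")
def solutions(calibrated, scenario_table):
    """Solved kidney for every scenario, on the calibrated parameters."""
    params, _ = calibrated
    model = ns.KidneyModel(params)
    return {k: model.solve(s) for k, s in scenario_table.items()}


@pytest.fixture(scope="session")
def reports(solutions):
    return {k: ns.KidneyReport.from_solution(s) for k, s in solutions.items()}


@pytest.fixture(scope="session")
def nd_solution(solutions):
    return solutions["nd"]


def make_inert_params(base: ParameterSet) -> ParameterSet:
    """All transporters and permeabilities off: an inert tube."""
    p = base.copy()
    for seg, cfg in p.raw["segments"].items():
        cfg["has_cell"] = False
        cfg["pf_transcell"] = 0.0
        cfg["pf_para"] = 0.0
        for key in ("apical_perm", "basolateral_perm", "paracellular_perm"):
            if key in cfg:
                cfg[key] = {s: 0.0 for s in SOLUTES}
        for t in cfg.get("transporters", {}).values():
            t["vmax"] = 0.0
    return p


@pytest.fixture(scope="session")
def inert_params(default_params):
    return make_inert_params(default_params)
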