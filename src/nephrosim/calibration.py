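"""Calibration of under-determined baseline parameters to printed anchors.

The baseline transport parameters of a human kidney model are not fully
identifiable from first principles, so a small number of multiplicative
scale factors are tuned against published whole-kidney observables
("anchors").  Calibration runs in two stages: glucose (SGLT2/SGLT1/GLUT
capacities and the paracellular glucose permeability of the proximal
segments) and sodium (TAL NKCC2 capacity, proximal paracellular NaCl
permeability, distal Na pathways, and the medullary gradient scale).

Anchors are split into *fit* anchors, which enter the least-squares
objective, and *holdout* anchors, which are only reported and never
optimised against — every diabetes/SGLT2-inhibition prediction that is not
itself a fit anchor remains a genuine test of the model.

The optimiser is a deterministic Nelder-Mead simplex started from the
packaged parameter file (scales = 1); repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import KidneyModel
from .params import ParameterSet
from .reporting import KidneyReport
from .scenarios import (Scenario, moderate_diabetes, nondiabetic,
                        severe_diabetes, with_sglt2i)


class CalibrationError(RuntimeError):
    """Raised when calibration cannot reach the required fit residual."""


@dataclass(frozen=True)
class CalibrationAnchor:
    """One published observable the model is compared against."""

    id: str
    scenario: str          # key into the scenario table below
    observable: str        # name of a derived quantity (see _OBSERVABLES)
    target: float
    weight: float = 1.0
    role: str = "fit"      # "fit" | "holdout"
    #: soft anchors pull the objective but cannot fail calibration (used
    #: for constraints the literature states only approximately)
    hard: bool = True
    #: absolute acceptance tolerance in the observable's own units; when
    #: None the default relative fit tolerance applies
    tol: float | None = None


#: scenario keys used by anchors; moderate diabetes uses the results-text
#: GFR variant (+10%), the variant whose macula-densa predictions the
#: published macula-densa values correspond to (reports record the variant used).
_SCENARIOS: Dict[str, Callable[[], Scenario]] = {
    "nd": nondiabetic,
    "nd_sglt2i": lambda: with_sglt2i(nondiabetic()),
    "dm_mod": moderate_diabetes,
    "dm_mod_txt": lambda: moderate_diabetes(gfr_mode="results_text"),
    "dm_sev": severe_diabetes,
    "dm_mod_sglt2i": lambda: with_sglt2i(moderate_diabetes()),
    "dm_sev_sglt2i": lambda: with_sglt2i(severe_diabetes()),
}


def _observable(report: KidneyReport, sglt_fractions: Dict[str, float],
                name: str, context: Dict[str, KidneyReport]) -> float:
    if name == "pct_glucose_fraction":
        return report.proximal_glucose_fractions()[0]
    if name == "s3_glucose_fraction":
        return report.proximal_glucose_fractions()[1]
    if name == "glucose_fe":
        return float(report.fractional_excretion["glucose"])
    if name == "sglt1_glucose_fraction":
        return sglt_fractions["SGLT1"]
    if name == "md_cl_superficial":
        return report.macula_densa_cl["superficial"]
    if name == "na_fe":
        return float(report.fractional_excretion["Na"])
    if name == "tna_ratio_vs_nd":
        return report.tna_total / context["nd"].tna_total
    raise KeyError(f"unknown observable {name!r}")


GLUCOSE_FIT_ANCHORS = (
    CalibrationAnchor("nd_pct_fraction", "nd", "pct_glucose_fraction",
                      0.97, tol=0.02),
    CalibrationAnchor("nd_s3_fraction", "nd", "s3_glucose_fraction",
                      0.026, tol=0.02),
    CalibrationAnchor("ndi_glucose_fe", "nd_sglt2i", "glucose_fe", 0.40,
                      tol=0.03),
    CalibrationAnchor("ndi_pct_fraction", "nd_sglt2i",
                      "pct_glucose_fraction", 0.145, weight=0.5, tol=0.08,
                      hard=False),
    CalibrationAnchor("ndi_s3_fraction", "nd_sglt2i", "s3_glucose_fraction",
                      0.397, weight=0.5, tol=0.08, hard=False),
    # the ~60% SGLT1 sizing constraint is arithmetically inconsistent with
    # the printed inhibition results (14.5% PCT + 40% excreted leave at most
    # ~45% for SGLT1), so it enters only as a weak pull
    CalibrationAnchor("ndi_sglt1_fraction", "nd_sglt2i",
                      "sglt1_glucose_fraction", 0.60, weight=0.15,
                      hard=False, tol=0.25),
)

GLUCOSE_HOLDOUT_ANCHORS = (
    CalibrationAnchor("sev_pct_fraction", "dm_sev", "pct_glucose_fraction",
                      0.737, role="holdout"),
    CalibrationAnchor("sev_s3_fraction", "dm_sev", "s3_glucose_fraction",
                      0.091, role="holdout"),
    CalibrationAnchor("sev_glucose_fe", "dm_sev", "glucose_fe", 0.16,
                      role="holdout"),
    CalibrationAnchor("modi_glucose_fe", "dm_mod_sglt2i", "glucose_fe",
                      0.531, role="holdout"),
    CalibrationAnchor("sevi_glucose_fe", "dm_sev_sglt2i", "glucose_fe",
                      0.668, role="holdout"),
)

SODIUM_FIT_ANCHORS = (
    CalibrationAnchor("nd_md_cl", "nd", "md_cl_superficial", 28.3,
                      tol=0.5),
    CalibrationAnchor("nd_na_fe", "nd", "na_fe", 0.005, weight=0.05,
                      hard=False),
)

SODIUM_HOLDOUT_ANCHORS = (
    CalibrationAnchor("mod_md_cl", "dm_mod_txt", "md_cl_superficial", 21.3,
                      role="holdout"),
    CalibrationAnchor("sev_md_cl", "dm_sev", "md_cl_superficial", 18.6,
                      role="holdout"),
    CalibrationAnchor("mod_tna_ratio", "dm_mod", "tna_ratio_vs_nd", 1.17,
                      role="holdout"),
    CalibrationAnchor("sev_tna_ratio", "dm_sev", "tna_ratio_vs_nd", 1.24,
                      role="holdout"),
)

#: multiplicative scale groups: name -> list of parameter paths
GLUCOSE_SCALE_PATHS: Dict[str, List[str]] = {
    "sglt2": ["segments.PCT.transporters.SGLT2.vmax"],
    "sglt1": ["segments.S3.transporters.SGLT1.vmax"],
    "glut": ["segments.PCT.transporters.GLUT2.vmax",
             "segments.S3.transporters.GLUT1.vmax"],
    "para_glucose": ["segments.PCT.paracellular_perm.glucose",
                     "segments.S3.paracellular_perm.glucose"],
}

SODIUM_SCALE_PATHS: Dict[str, List[str]] = {
    "nkcc2": ["segments.mTAL.transporters.NKCC2.vmax",
              "segments.cTAL.transporters.NKCC2.vmax"],
    "para_nacl": ["segments.PCT.paracellular_perm.Na",
                  "segments.PCT.paracellular_perm.Cl",
                  "segments.S3.paracellular_perm.Na",
                  "segments.S3.paracellular_perm.Cl"],
    "distal_na": ["segments.DCT.transporters.NCC.vmax",
                  "segments.CNT.transporters.ENaC.vmax",
                  "segments.CCD.transporters.ENaC.vmax"],
    "gradient": ["interstitium.gradient_scale"],
}


def apply_scales(params: ParameterSet, scale_paths: Dict[str, List[str]],
                 scales: Dict[str, float]) -> ParameterSet:
    """Return a copy of ``params`` with scale factors multiplied in."""
    out = params.copy()
    for name, factor in scales.items():
        for path in scale_paths[name]:
            out.scale(path, float(factor))
    return out


@dataclass
class CalibrationResult:
    """Fitted parameters plus a residual report over all anchors."""

    params: ParameterSet
    scales: Dict[str, float]
    report: pd.DataFrame          # anchor, scenario, target, achieved, ...
    objective: float
    n_evaluations: int

    @property
    def fit_max_rel_error(self) -> float:
        """Largest |relative error| over the hard fit anchors."""
        fit = self.report[(self.report.role == "fit") & self.report.hard]
        return float(fit.rel_error.abs().max())

    def to_json(self) -> str:
        return self.report.to_json(orient="records", indent=2)


class _ProximalEvaluator:
    """Fast glucose-anchor evaluation from proximal-only solves.

    Downstream segments transport essentially no glucose, so the glucose
    fit anchors are computed from PCT+S3 solves alone inside the
    optimisation loop; the final report re-evaluates on the full kidney.
    """

    def __init__(self, grid_points: Optional[int]):
        self.grid_points = grid_points
        self.n_evaluations = 0

    def evaluate(self, params: ParameterSet,
                 anchors: Sequence[CalibrationAnchor]) -> Dict[str, float]:
        model = KidneyModel(params, grid_points=self.grid_points)
        cache: Dict[str, Dict[str, float]] = {}
        out = {}
        for a in anchors:
            if a.scenario not in cache:
                cache[a.scenario] = model.solve_proximal(
                    _SCENARIOS[a.scenario]())
            out[a.id] = float(cache[a.scenario][a.observable])
        self.n_evaluations += 1
        return out


class _AnchorEvaluator:
    """Solves each scenario once per parameter set and caches reports."""

    def __init__(self, grid_points: Optional[int]):
        self.grid_points = grid_points
        self.n_evaluations = 0

    def evaluate(self, params: ParameterSet,
                 anchors: Sequence[CalibrationAnchor]) -> Dict[str, float]:
        needed = {a.scenario for a in anchors}
        if any(a.observable == "tna_ratio_vs_nd" for a in anchors):
            needed.add("nd")
        model = KidneyModel(params, grid_points=self.grid_points)
        reports: Dict[str, KidneyReport] = {}
        sglt: Dict[str, Dict[str, float]] = {}
        for key in sorted(needed):
            sol = model.solve(_SCENARIOS[key]())
            reports[key] = KidneyReport.from_solution(sol)
            filt = sol.filtered[-1]  # glucose is the last solute
            sglt[key] = {k: v / filt
                         for k, v in sol.sglt_glucose_reabsorption().items()}
        self.n_evaluations += 1
        return {a.id: _observable(reports[a.scenario], sglt[a.scenario],
                                  a.observable, reports)
                for a in anchors}


def _objective(achieved: Dict[str, float],
               anchors: Sequence[CalibrationAnchor]) -> float:
    """Tolerance-banded weighted least squares.

    Anchors with an explicit tolerance contribute nothing while inside
    their band and grow quadratically outside it; anchors without one use
    plain relative error.  The banding stops the optimiser from trading
    already-acceptable fit error along weakly-identified parameter
    directions (which would silently degrade held-out predictions).
    """
    total = 0.0
    for a in anchors:
        err = achieved[a.id] - a.target
        if a.tol is not None:
            excess = max(abs(err) - a.tol, 0.0) / a.tol
            total += a.weight * excess * excess
        else:
            rel = err / a.target
            total += a.weight * rel * rel
    return total


def _calibrate(base_params: ParameterSet,
               scale_paths: Dict[str, List[str]],
               fit_anchors: Sequence[CalibrationAnchor],
               holdout_anchors: Sequence[CalibrationAnchor],
               free: Optional[Sequence[str]],
               grid_points: Optional[int],
               max_evals: int,
               fit_tolerance: float,
               evaluator=None) -> CalibrationResult:
    free = list(free) if free is not None else list(scale_paths)
    evaluator = evaluator or _AnchorEvaluator(grid_points)

    def run(x: np.ndarray) -> float:
        scales = {name: float(np.exp(v)) for name, v in zip(free, x)}
        params = apply_scales(base_params, scale_paths, scales)
        try:
            achieved = evaluator.evaluate(params, fit_anchors)
        except Exception:
            return 1e6  # infeasible parameter region
        return _objective(achieved, fit_anchors)

    x0 = np.zeros(len(free))
    res = minimize(run, x0, method="Nelder-Mead",
                   options={"maxfev": max_evals, "xatol": 2e-3,
                            "fatol": 1e-6, "adaptive": False})
    scales = {name: float(np.exp(v)) for name, v in zip(free, res.x)}
    fitted = apply_scales(base_params, scale_paths, scales)

    # final report over fit + holdout anchors at the default grid
    all_anchors = list(fit_anchors) + list(holdout_anchors)
    achieved = _AnchorEvaluator(None).evaluate(fitted, all_anchors)
    rows = [{
        "anchor": a.id, "scenario": a.scenario, "observable": a.observable,
        "target": a.target, "achieved": achieved[a.id],
        "rel_error": (achieved[a.id] - a.target) / a.target,
        "weight": a.weight, "role": a.role, "hard": a.hard,
    } for a in all_anchors]
    report = pd.DataFrame(rows)

    result = CalibrationResult(params=fitted, scales=scales, report=report,
                               objective=float(res.fun),
                               n_evaluations=evaluator.n_evaluations)
    failures = []
    for a in fit_anchors:
        if not a.hard:
            continue
        err = abs(achieved[a.id] - a.target)
        limit = a.tol if a.tol is not None else fit_tolerance * abs(a.target)
        if err > limit:
            failures.append((a, achieved[a.id], err - limit))
    if failures:
        worst = max(failures, key=lambda f: f[2])
        raise CalibrationError(
            f"calibration failed: fit anchor {worst[0].id!r} achieved "
            f"{worst[1]:.4g} vs target {worst[0].target:.4g} "
            f"(outside tolerance)")
    return result


def calibrate_glucose(base_params: Optional[ParameterSet] = None,
                      free: Optional[Sequence[str]] = None,
                      grid_points: Optional[int] = 30,
                      max_evals: int = 150,
                      fit_tolerance: float = 0.08) -> CalibrationResult:
    """Tune glucose-pathway capacities against the glucose anchors.

    Fit anchors: non-diabetic PCT/S3 fractional glucose reabsorption
    (97%/2.6%), fractional glucose excretion under 90% SGLT2 inhibition
    (40%) and the SGLT1-mediated share of filtered glucose under inhibition
    (~60%, sizing constraint, lower weight).  Severe-diabetes and
    diabetic-inhibition excretions are holdouts.

    ``grid_points`` controls the axial resolution used inside the
    optimisation loop (the final report always re-evaluates at the default
    resolution); ``free`` restricts the tuned scale groups.
    """
    return _calibrate(base_params or ParameterSet.default(),
                      GLUCOSE_SCALE_PATHS, GLUCOSE_FIT_ANCHORS,
                      GLUCOSE_HOLDOUT_ANCHORS, free, grid_points,
                      max_evals, fit_tolerance,
                      evaluator=_ProximalEvaluator(grid_points))


def calibrate_sodium(base_params: ParameterSet,
                     free: Optional[Sequence[str]] = ("nkcc2", "distal_na"),
                     grid_points: Optional[int] = 30,
                     max_evals: int = 120,
                     fit_tolerance: float = 0.05) -> CalibrationResult:
    """Tune Na-pathway capacities after glucose calibration.

    Fit anchors: non-diabetic superficial macula densa [Cl-] (28.3 mM) and
    a physiological non-diabetic Na fractional excretion (~0.5%).  Diabetic
    macula densa [Cl-] and T_Na increases are holdouts.
    """
    return _calibrate(base_params, SODIUM_SCALE_PATHS, SODIUM_FIT_ANCHORS,
                      SODIUM_HOLDOUT_ANCHORS, free, grid_points,
                      max_evals, fit_tolerance)


def calibrate(base_params: Optional[ParameterSet] = None,
              grid_points: Optional[int] = 30,
              glucose_kwargs: Optional[dict] = None,
              sodium_kwargs: Optional[dict] = None):
    """Run both calibration stages; returns ``(params, [results])``."""
    g = calibrate_glucose(base_params, grid_points=grid_points,
                          **(glucose_kwargs or {}))
    s = calibrate_sodium(g.params, grid_points=grid_points,
                         **(sodium_kwargs or {}))
    return s.params, [g, s]
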