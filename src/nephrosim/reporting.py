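"""Derived whole-kidney quantities and figure-style tables.

All mol/day quantities are single-model-kidney values (1e6 nephrons), the
same arithmetic used by the published predictions (e.g. 151.2 L/day x 8.6 mM
= 1.30 mol/day of filtered glucose).  ``T_Na`` is total tubular Na+
reabsorption; its active part is the Na/K-ATPase-mediated flux (3 Na+ per
pump cycle) summed over every epithelial cell, and the passive part is the
remainder, so active + passive = total exactly.  When net paracellular Na+
transport is secretory (S3 under SGLT2 inhibition) the active part may
exceed the total.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .architecture import single_kidney_gfr
from .model import KidneySolution
from .params import ParameterSet
from .scenarios import Scenario
from .solutes import IDX, SOLUTES, plasma_vector
from .units import flow_umol_s_to_mol_day


def filtered_load(scenario: Scenario, solute: str,
                  params: Optional[ParameterSet] = None) -> float:
    """Filtered load of a solute (mol/day) under a scenario.

    Pure arithmetic: scenario-applied single-kidney GFR times plasma
    concentration; no tubules are solved.
    """
    params = params or ParameterSet.default()
    p, arch = scenario.apply(params)
    _, gfr_l_day = single_kidney_gfr(arch)
    conc_mm = p.plasma[IDX[solute]]
    return gfr_l_day * conc_mm * 1e-3  # L/day * mmol/L -> mol/day


def macula_densa_cl(solution: KidneySolution, class_id: str) -> float:
    """Luminal [Cl-] (mM) at the macula densa (cortical TAL outlet)."""
    return solution.macula_densa_cl(class_id)


def tna_split(solution: KidneySolution):
    """``(total, active, passive)`` whole-kidney Na+ reabsorption, mol/day."""
    total = flow_umol_s_to_mol_day(
        float(solution.segmental_reabsorption()["Na"].sum()))
    active = flow_umol_s_to_mol_day(solution.active_na_reabsorption())
    return total, active, total - active


@dataclass
class KidneyReport:
    """Every derived quantity reported for one solved scenario."""

    scenario_name: str
    gfr_mode: str
    gfr_l_day: float
    filtered: pd.Series                  # mol/day per solute
    segmental: pd.DataFrame              # mol/day, segment x solute
    water_segmental: pd.Series           # L/day per segment
    excretion: pd.Series                 # mol/day per solute
    urine_volume_l_day: float
    fractional_excretion: pd.Series
    macula_densa_cl: Dict[str, float]    # per nephron class, mM
    tna_total: float
    tna_active: float
    tna_passive: float
    sglt_glucose: Dict[str, float] = field(default_factory=dict)  # mol/day

    @classmethod
    def from_solution(cls, sol: KidneySolution) -> "KidneyReport":
        to_day = flow_umol_s_to_mol_day
        filtered = pd.Series({s: to_day(sol.filtered[i])
                              for i, s in enumerate(SOLUTES)})
        segmental = sol.segmental_reabsorption().apply(
            lambda col: col.map(to_day))
        water = sol.water_reabsorption() * 86_400.0 * 1e-3  # cm^3/s -> L/day
        excretion = pd.Series({s: to_day(sol.urine_flows[i])
                               for i, s in enumerate(SOLUTES)})
        fe = excretion / filtered
        md = {nc.id: sol.macula_densa_cl(nc.id)
              for nc in sol.architecture.nephron_classes}
        total, active, passive = tna_split(sol)
        sglt = {k: to_day(v)
                for k, v in sol.sglt_glucose_reabsorption().items()}
        return cls(
            scenario_name=sol.scenario.name,
            gfr_mode=sol.scenario.gfr_mode,
            gfr_l_day=sol.gfr_l_day,
            filtered=filtered, segmental=segmental, water_segmental=water,
            excretion=excretion,
            urine_volume_l_day=sol.urine_volume_l_day,
            fractional_excretion=fe, macula_densa_cl=md,
            tna_total=total, tna_active=active, tna_passive=passive,
            sglt_glucose=sglt)

    def conservation_residual(self) -> pd.Series:
        """filtered - sum(segmental) - excretion, relative, per solute."""
        reab = self.segmental.sum(axis=0)
        return (self.filtered - reab - self.excretion) / self.filtered

    def proximal_glucose_fractions(self):
        """(PCT, S3) glucose reabsorption as fractions of the filtered load."""
        f = self.filtered["glucose"]
        return (self.segmental.loc["PCT", "glucose"] / f,
                self.segmental.loc["S3", "glucose"] / f)

    def summary(self) -> str:
        lines = [
            f"scenario: {self.scenario_name} (gfr_mode={self.gfr_mode})",
            f"GFR: {self.gfr_l_day:.1f} L/day",
            f"urine volume: {self.urine_volume_l_day:.2f} L/day",
            "filtered loads (mol/day): " + ", ".join(
                f"{s}={self.filtered[s]:.3g}" for s in SOLUTES),
            "excretion (mol/day): " + ", ".join(
                f"{s}={self.excretion[s]:.3g}" for s in SOLUTES),
            "fractional excretion: " + ", ".join(
                f"{s}={self.fractional_excretion[s]:.4f}" for s in SOLUTES),
            "macula densa [Cl-] (mM): " + ", ".join(
                f"{c}={v:.1f}" for c, v in self.macula_densa_cl.items()),
            f"T_Na total/active/passive (mol/day): "
            f"{self.tna_total:.2f}/{self.tna_active:.2f}/{self.tna_passive:.2f}",
        ]
        return "\n".join(lines)


def normalize_report(report: KidneyReport,
                     reference: KidneyReport) -> Dict[str, object]:
    """Element-wise ratios of a report to a reference report.

    Zero-reference entries are flagged as NaN (``undefined``), never raised.
    A report normalised by itself is identically 1 everywhere defined.
    """
    def ratio(a, b):
        b_arr = np.asarray(b, dtype=float)
        return a / np.where(b_arr == 0.0, np.nan, b_arr)

    return {
        "gfr": report.gfr_l_day / reference.gfr_l_day,
        "filtered": ratio(report.filtered, reference.filtered),
        "segmental": ratio(report.segmental, reference.segmental),
        "excretion": ratio(report.excretion, reference.excretion),
        "urine_volume": (report.urine_volume_l_day /
                         reference.urine_volume_l_day
                         if reference.urine_volume_l_day else np.nan),
        "tna_total": report.tna_total / reference.tna_total,
        "tna_active": report.tna_active / reference.tna_active,
    }


def figure_tables(reports: List[KidneyReport], outdir: str,
                  reference: Optional[KidneyReport] = None,
                  excretion_reference: Optional[KidneyReport] = None
                  ) -> List[str]:
    """Write figure-shaped CSV tables for a set of scenario reports.

    Produces a glucose-handling table (filtered, excretion, PCT and S3
    transport), a solute/water transport table, and — when ``reference`` is
    given — normalised variants (segmental transport and filtration by the
    reference, excretion by ``excretion_reference`` when supplied, since
    baseline glucose excretion is essentially zero).
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    os.makedirs(outdir, exist_ok=True)
    written = []

    glu = pd.DataFrame({
        r.scenario_name: {
            "filtered": r.filtered["glucose"],
            "excretion": r.excretion["glucose"],
            "PCT": r.segmental.loc["PCT", "glucose"],
            "S3": r.segmental.loc["S3", "glucose"],
        } for r in reports}).T
    path = os.path.join(outdir, "glucose_handling.csv")
    glu.to_csv(path)
    written.append(path)

    rows = {}
    for r in reports:
        for sol in ("Na", "K", "Cl"):
            rows[(r.scenario_name, sol)] = {
                "filtered_mol_day": r.filtered[sol],
                "excretion_mol_day": r.excretion[sol],
                **{f"reab_{seg}": r.segmental.loc[seg, sol]
                   for seg in r.segmental.index},
            }
        rows[(r.scenario_name, "water")] = {
            "filtered_mol_day": r.gfr_l_day,
            "excretion_mol_day": r.urine_volume_l_day,
            **{f"reab_{seg}": r.water_segmental.get(seg, np.nan)
               for seg in r.segmental.index},
        }
    transport = pd.DataFrame(rows).T
    path = os.path.join(outdir, "solute_water_transport.csv")
    transport.to_csv(path)
    written.append(path)

    if reference is not None:
        norm_rows = {}
        for r in reports:
            n = normalize_report(r, reference)
            exc_ref = excretion_reference or reference
            n_exc = normalize_report(r, exc_ref)
            norm_rows[r.scenario_name] = {
                "gfr": n["gfr"],
                **{f"filtered_{s}": n["filtered"][s] for s in SOLUTES},
                **{f"excretion_{s}": n_exc["excretion"][s] for s in SOLUTES},
                "urine_volume": n["urine_volume"],
                "tna_total": n["tna_total"],
                "tna_active": n["tna_active"],
            }
        path = os.path.join(outdir, "normalized.csv")
        pd.DataFrame(norm_rows).T.to_csv(path)
        written.append(path)
    return written
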