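"""Whole-kidney model object and solution container.

:class:`KidneyModel` binds a parameter set to the nephron architecture;
``solve(scenario)`` integrates all six nephron classes, merges their
connecting-tubule outflows (population-weighted, 10:1 into cortical
collecting ducts), carries the shared collecting duct through the medulla
with successive inner-medullary coalescence, and returns a
:class:`KidneySolution` with full axial profiles, kidney-scaled transport
bookkeeping, and urine composition.

Everything is deterministic: identical inputs give bit-identical solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .architecture import (KidneyArchitecture, SegmentGeometry,
                           build_default_architecture, merge_flows,
                           single_kidney_gfr)
from .interstitium import InterstitialProfile
from .params import ParameterSet
from .scenarios import Scenario, nondiabetic
from .solutes import CL, N_SOLUTES, SOLUTES
from .solver import LuminalState, SegmentSolution, SolverError, solve_segment
from .units import (flow_cm3_s_to_l_day, flow_umol_s_to_mol_day,
                    sngfr_to_cm3_per_s)

INLET_PRESSURE_MMHG = 20.0


@dataclass
class KidneySolution:
    """Solved state of the whole model kidney for one scenario."""

    scenario: Scenario
    architecture: KidneyArchitecture
    params_hash: str
    nephrons: Dict[str, List[SegmentSolution]]       # per class, PCT..CNT
    collecting_duct: List[Tuple[SegmentSolution, float]]  # (solution, ducts)
    urine_fv: float                                  # kidney total, cm^3/s
    urine_flows: np.ndarray                          # kidney total, umol/s
    filtered: np.ndarray                             # kidney total, umol/s
    gfr_ml_min: float
    gfr_l_day: float

    # -- reporting primitives ---------------------------------------------

    @property
    def urine_volume_l_day(self) -> float:
        return flow_cm3_s_to_l_day(self.urine_fv)

    @property
    def urine_conc(self) -> np.ndarray:
        return self.urine_flows / self.urine_fv

    def class_count(self, class_id: str) -> float:
        return self.architecture.class_count(class_id)

    def segmental_reabsorption(self) -> pd.DataFrame:
        """Kidney-scaled per-segment reabsorption (umol/s), by solute.

        Rows are segment ids in anatomical order; nephron-segment rows sum
        the population-weighted contribution of every class.
        """
        rows: Dict[str, np.ndarray] = {}
        order: List[str] = []

        def add(seg_id, values):
            if seg_id not in rows:
                rows[seg_id] = np.zeros(N_SOLUTES)
                order.append(seg_id)
            rows[seg_id] += values

        for cid, segs in self.nephrons.items():
            n = self.class_count(cid)
            for s in segs:
                add(s.segment_id, n * s.reabsorption)
        for s, ducts in self.collecting_duct:
            add(s.segment_id, ducts * s.reabsorption)
        return pd.DataFrame([rows[k] for k in order], index=order,
                            columns=SOLUTES)

    def water_reabsorption(self) -> pd.Series:
        rows: Dict[str, float] = {}
        for cid, segs in self.nephrons.items():
            n = self.class_count(cid)
            for s in segs:
                rows[s.segment_id] = rows.get(s.segment_id, 0.0) \
                    + n * s.water_reabsorption
        for s, ducts in self.collecting_duct:
            rows[s.segment_id] = rows.get(s.segment_id, 0.0) \
                + ducts * s.water_reabsorption
        return pd.Series(rows)

    def conservation_residual(self) -> np.ndarray:
        """Per-solute relative residual of filtered = reabsorbed + excreted."""
        reab = self.segmental_reabsorption().to_numpy().sum(axis=0)
        return (self.filtered - reab - self.urine_flows) / \
            np.maximum(np.abs(self.filtered), 1e-12)

    def water_conservation_residual(self) -> float:
        filtered = self.gfr_ml_min / 60.0  # cm^3/s
        reab = float(self.water_reabsorption().sum())
        return (filtered - reab - self.urine_fv) / filtered

    def macula_densa_cl(self, class_id: str) -> float:
        """Luminal [Cl-] (mM) at the cortical TAL outlet (macula densa)."""
        for s in self.nephrons[class_id]:
            if s.segment_id == "cTAL":
                return float(s.conc[-1, CL])
        raise KeyError(f"{class_id}: no cTAL segment")

    def active_na_reabsorption(self) -> float:
        """Kidney-total Na/K-ATPase-mediated Na reabsorption, umol/s."""
        total = 0.0
        for cid, segs in self.nephrons.items():
            n = self.class_count(cid)
            total += n * sum(s.active_na for s in segs)
        total += sum(ducts * s.active_na for s, ducts in self.collecting_duct)
        return total

    def sglt_glucose_reabsorption(self) -> Dict[str, float]:
        """Kidney-total SGLT2/SGLT1-mediated glucose reabsorption, umol/s."""
        out = {"SGLT2": 0.0, "SGLT1": 0.0}
        for cid, segs in self.nephrons.items():
            n = self.class_count(cid)
            for s in segs:
                for k, v in s.sglt_glucose.items():
                    out[k] += n * v
        return out

    def profiles_frame(self) -> pd.DataFrame:
        """Tidy axial profiles: one row per (class, segment, grid node)."""
        recs = []
        for cid, segs in self.nephrons.items():
            for s in segs:
                for i in range(len(s.x)):
                    recs.append((self.scenario.name, cid, s.segment_id,
                                 s.x[i], s.fv[i], s.pressure[i], s.v_te[i],
                                 *s.conc[i]))
        for s, _ in self.collecting_duct:
            for i in range(len(s.x)):
                recs.append((self.scenario.name, "CD", s.segment_id,
                             s.x[i], s.fv[i], s.pressure[i], s.v_te[i],
                             *s.conc[i]))
        cols = ["scenario", "class", "segment", "x", "Fv", "P", "V_te"] + \
            [f"c_{s}" for s in SOLUTES]
        return pd.DataFrame.from_records(recs, columns=cols)


class KidneyModel:
    """Multi-nephron steady-state kidney transport model.

    Parameters
    ----------
    params:
        A :class:`ParameterSet`; defaults to the packaged canonical file.
    grid_points:
        Override for the axial grid resolution of every segment.
    """

    def __init__(self, params: Optional[ParameterSet] = None,
                 grid_points: Optional[int] = None):
        self.params = params or ParameterSet.default()
        self.grid_points = grid_points

    # -- scenario machinery ------------------------------------------------

    def _base_architecture(self) -> KidneyArchitecture:
        cfg = dict(self.params.raw.get("architecture") or {})
        if self.grid_points is not None:
            cfg["grid_points"] = self.grid_points
        return build_default_architecture(cfg)

    def prepared(self, scenario: Scenario):
        """(applied params, applied architecture, reference architecture)."""
        ref_arch = self._base_architecture()
        params, arch = scenario.apply(self.params, self._base_architecture())
        return params, arch, ref_arch

    # -- solving -----------------------------------------------------------

    def solve(self, scenario: Optional[Scenario] = None) -> KidneySolution:
        scenario = scenario or nondiabetic()
        params, arch, ref_arch = self.prepared(scenario)
        plasma = params.plasma
        icfg = params.raw.get("interstitium", {})
        interstitium = InterstitialProfile(
            plasma, arch.outer_medulla_depth, arch.inner_medulla_depth,
            om_boundary_osm=float(icfg.get("om_boundary_osm", 600.0)),
            papilla_osm=float(icfg.get("papilla_osm", 1200.0)),
            gradient_scale=float(icfg.get("gradient_scale", 1.0)))
        tcfg = params.raw.get("torque", {})
        t_sens = float(tcfg.get("sensitivity", 1.0))
        t_clamp = tuple(tcfg.get("clamp", (0.2, 3.0)))
        ref_outlet = float(tcfg.get("ref_outlet_frac", 0.35))

        nephrons: Dict[str, List[SegmentSolution]] = {}
        for nc in arch.nephron_classes:
            nephrons[nc.id] = self._solve_nephron(
                nc.id, arch, ref_arch, params, plasma, interstitium,
                t_sens, t_clamp, ref_outlet)

        cd, urine_fv, urine_flows = self._solve_collecting_duct(
            arch, params, interstitium, nephrons)

        gfr_ml_min, gfr_l_day = single_kidney_gfr(arch)
        filtered = (gfr_ml_min / 60.0) * plasma  # cm^3/s * mM = umol/s
        return KidneySolution(
            scenario=scenario, architecture=arch,
            params_hash=params.content_hash(),
            nephrons=nephrons, collecting_duct=cd,
            urine_fv=urine_fv, urine_flows=urine_flows,
            filtered=filtered, gfr_ml_min=gfr_ml_min, gfr_l_day=gfr_l_day)

    def solve_proximal(self, scenario: Optional[Scenario] = None
                       ) -> Dict[str, object]:
        """Solve only the proximal tubule (PCT + S3) of every class.

        A fast surrogate for glucose-handling quantities: downstream
        segments carry no meaningful glucose transport, so the S3 outlet
        glucose flow approximates urinary excretion.  Returns kidney-scaled
        filtered loads, PCT/S3 glucose reabsorption and SGLT-mediated
        shares, plus the per-class segment solutions.
        """
        scenario = scenario or nondiabetic()
        params, arch, ref_arch = self.prepared(scenario)
        plasma = params.plasma
        icfg = params.raw.get("interstitium", {})
        interstitium = InterstitialProfile(
            plasma, arch.outer_medulla_depth, arch.inner_medulla_depth,
            om_boundary_osm=float(icfg.get("om_boundary_osm", 600.0)),
            papilla_osm=float(icfg.get("papilla_osm", 1200.0)),
            gradient_scale=float(icfg.get("gradient_scale", 1.0)))
        tcfg = params.raw.get("torque", {})
        solutions: Dict[str, List[SegmentSolution]] = {}
        pct = s3 = sglt2 = sglt1 = 0.0
        filtered_glu = 0.0
        glu = len(plasma) - 1
        for nc in arch.nephron_classes:
            segs = self._solve_nephron(
                nc.id, arch, ref_arch, params, plasma, interstitium,
                float(tcfg.get("sensitivity", 1.0)),
                tuple(tcfg.get("clamp", (0.2, 3.0))),
                float(tcfg.get("ref_outlet_frac", 0.35)),
                through="S3")
            solutions[nc.id] = segs
            n = arch.class_count(nc.id)
            filtered_glu += n * sngfr_to_cm3_per_s(nc.sngfr) * plasma[glu]
            pct += n * segs[0].reabsorption[glu]
            s3 += n * segs[1].reabsorption[glu]
            for s in segs:
                sglt2 += n * s.sglt_glucose.get("SGLT2", 0.0)
                sglt1 += n * s.sglt_glucose.get("SGLT1", 0.0)
        return {
            "solutions": solutions,
            "filtered_glucose": filtered_glu,
            "pct_glucose_fraction": pct / filtered_glu,
            "s3_glucose_fraction": s3 / filtered_glu,
            "glucose_fe": 1.0 - (pct + s3) / filtered_glu,
            "sglt2_glucose_fraction": sglt2 / filtered_glu,
            "sglt1_glucose_fraction": sglt1 / filtered_glu,
        }

    def _solve_nephron(self, class_id, arch, ref_arch, params, plasma,
                       interstitium, t_sens, t_clamp, ref_outlet,
                       through: Optional[str] = None
                       ) -> List[SegmentSolution]:
        nc = arch.nephron_class(class_id)
        ref_nc = ref_arch.nephron_class(class_id)
        segs = arch.segments[class_id]
        ref_segs = {s.segment_id: s for s in ref_arch.segments[class_id]}
        ref_prox_len = sum(ref_segs[sid].length for sid in ("PCT", "S3"))
        sngfr_ref = sngfr_to_cm3_per_s(ref_nc.sngfr)

        inlet = LuminalState(0.0, sngfr_to_cm3_per_s(nc.sngfr),
                             INLET_PRESSURE_MMHG, plasma.copy())
        out: List[SegmentSolution] = []
        prox_ref_offset = 0.0
        prev_guess = None
        for geom in segs:
            pars = params.segment_params(class_id, geom.segment_id)
            torque_ref = None
            if pars.torque_sensitive:
                ref_geom = ref_segs[geom.segment_id]
                offset = prox_ref_offset
                scale = ref_geom.length / geom.length

                # the torque signal compares local flow with the reference
                # axial flow profile at reference geometry: hypertrophied
                # radius effects are already expressed by the geometry
                # multipliers themselves, and diabetic hyperfiltration must
                # augment (not depress) transcellular density
                def torque_ref(x, offset=offset, scale=scale,
                               ref_geom=ref_geom):
                    s = min((offset + x * scale) / ref_prox_len, 1.0)
                    q_ref = sngfr_ref * (1.0 - (1.0 - ref_outlet) * s)
                    return q_ref, ref_geom.radius
                prox_ref_offset += ref_geom.length
            sol = solve_segment(inlet, geom, pars, interstitium,
                                torque_ref=torque_ref,
                                torque_sensitivity=t_sens,
                                torque_clamp=t_clamp,
                                initial_cell_guess=prev_guess
                                if pars.has_cell else None)
            out.append(sol)
            prev_guess = sol.final_cell_guess if pars.has_cell else None
            inlet = sol.outlet
            if through is not None and geom.segment_id == through:
                break
        return out

    def _solve_collecting_duct(self, arch, params, interstitium, nephrons):
        # population-weighted merge of all CNT outflows into the CCD pool
        outlets = []
        weights = []
        for nc in arch.nephron_classes:
            o = nephrons[nc.id][-1].outlet
            outlets.append(np.concatenate([[o.fv], o.flows]))
            weights.append(arch.class_count(nc.id))
        total = merge_flows(outlets, weights)
        n_ccd = arch.n_ccd
        fv = total[0] / n_ccd
        flows = total[1:] / n_ccd
        pressure = float(np.average(
            [nephrons[nc.id][-1].outlet.pressure
             for nc in arch.nephron_classes], weights=weights))
        inlet = LuminalState(0.0, fv, pressure, flows / fv)

        cd: List[Tuple[SegmentSolution, float]] = []
        ducts = n_ccd
        schedule = arch.topology.imcd_merge_schedule
        for geom in arch.collecting_duct:
            pars = params.segment_params("CD", geom.segment_id)
            if geom.segment_id != "IMCD" or not schedule:
                sol = solve_segment(inlet, geom, pars, interstitium)
                cd.append((sol, ducts))
                inlet = sol.outlet
                continue
            # IMCD: solve piecewise between successive merge depths
            bounds = [0.0] + [f for f, _ in schedule] + [1.0]
            factors = [fac for _, fac in schedule] + [1]
            x_done = 0.0
            for (lo, hi), factor in zip(zip(bounds[:-1], bounds[1:]), factors):
                if hi <= lo:
                    continue
                length = (hi - lo) * geom.length
                piece = SegmentGeometry(
                    "IMCD", length, geom.inner_diameter,
                    max(20, int(round(geom.grid_points * (hi - lo)))),
                    depth_start=geom.depth_start
                    + (geom.depth_end - geom.depth_start) * lo,
                    depth_end=geom.depth_start
                    + (geom.depth_end - geom.depth_start) * hi)
                # axial pump profile windows are defined on the whole IMCD
                piece_pars = params.segment_params("CD", "IMCD")
                piece_pars.pump_axial_profile = [
                    (max((w_lo - lo) / (hi - lo), 0.0),
                     min((w_hi - lo) / (hi - lo), 1.0), f)
                    for (w_lo, w_hi, f) in pars.pump_axial_profile
                    if w_hi > lo and w_lo < hi]
                sol = solve_segment(inlet, piece, piece_pars, interstitium)
                cd.append((sol, ducts))
                o = sol.outlet
                if factor > 1:
                    ducts /= factor
                    o = LuminalState(0.0, o.fv * factor, o.pressure,
                                     o.conc.copy(), o.v_te)
                inlet = o
                x_done += length

        urine_fv = inlet.fv * ducts
        urine_flows = inlet.flows * ducts
        return cd, urine_fv, urine_flows
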