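"""Steady-state solution of the tubular conservation equations.

At every axial grid point of a cell-bearing segment the epithelial cell
compartment is an algebraic root-finding problem: five solute mass balances
(apical influx = basolateral efflux), cell electroneutrality against a fixed
impermeant cytosolic anion, and a zero net transepithelial current (open
circuit) condition that determines the transepithelial potential.  The
system is solved by a damped Newton iteration with a finite-difference
Jacobian evaluated in one vectorised batch, warm-started from the previous
grid point (axial continuation).

The luminal balance equations

    dFv/dx   = -2 pi r Jv
    d(F_i)/dx = -2 pi r J_i          (F_i = Fv c_i)
    dP/dx    = -8 mu Fv / (pi r^4)   (Poiseuille, diagnostic)

are integrated on a fixed cell-centred grid with an explicit trapezoidal
(Heun) predictor-corrector in the conservative variables, with deterministic
adaptive sub-stepping where the local relative change is large.  Because the
scheme integrates the flows themselves, inlet minus outlet flow equals the
accumulated transmural flux integral exactly, for water and every solute.

Descending limb segments carry no cell compartment; their fluxes use a
single-barrier transmural law with lumped permeabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np

from .fluxes import (ghk_flux, glut_flux, kcl_flux, logmean, nak_atpase_flux,
                     ncc_flux, nhe3_flux, nkcc2_flux, paracellular_flux,
                     sglt_flux, torque_multiplier, water_flux)
from .architecture import SegmentGeometry
from .interstitium import InterstitialProfile
from .params import SegmentParams
from .solutes import CL, GLU, K, NA, N_SOLUTES, UREA, Z
from .units import DYN_PER_MMHG, RT_OVER_F, VISCOSITY

INTERSTITIAL_PRESSURE_MMHG = 5.0


class SolverError(RuntimeError):
    """Raised when the cell or segment solver fails to converge."""


@dataclass
class LuminalState:
    """Axial state of the tubular fluid at one position."""

    x: float                 # cm from segment inlet
    fv: float                # cm^3/s
    pressure: float          # mmHg
    conc: np.ndarray         # mM, ordered per solutes.SOLUTES
    v_te: float = 0.0        # mV, lumen minus interstitium

    def __post_init__(self) -> None:
        if self.fv <= 0:
            raise SolverError(f"luminal flow must be positive, got {self.fv}")
        if np.any(self.conc < 0):
            raise SolverError("negative luminal concentration")

    @property
    def flows(self) -> np.ndarray:
        return self.fv * self.conc


@dataclass
class CellState:
    """Epithelial cell compartment at one grid point."""

    conc: np.ndarray         # cytosolic concentrations, mM
    impermeant_anion: float  # mM
    v_apical: float          # mV, lumen minus cell
    v_basolateral: float     # mV, cell minus interstitium

    @property
    def v_te(self) -> float:
        return self.v_apical + self.v_basolateral

    def electroneutrality_residual(self) -> float:
        return float(np.sum(Z * self.conc) - self.impermeant_anion)


# -------------------------------------------------------------------------
# cell problem
# -------------------------------------------------------------------------

_TRANSCELLULAR_CARRIERS = {"NHE3", "SGLT2", "SGLT1", "NKCC2", "NCC",
                           "ENaC", "ROMK", "NaKATPase", "GLUT1", "GLUT2",
                           "KCl_cotransport"}


class CellProblem:
    """Pre-assembled flux evaluation for one segment's epithelium.

    Evaluates apical, basolateral and paracellular fluxes for a batch of
    candidate cell states at a fixed luminal/interstitial bath, which lets
    the Newton solver build its finite-difference Jacobian in one call.
    """

    def __init__(self, pars: SegmentParams, torque_mult: float = 1.0,
                 pump_mult: float = 1.0):
        self.pars = pars
        self.tm = torque_mult if pars.torque_sensitive else 1.0
        self.pump_mult = pump_mult
        t = pars.transporters
        # flux scale per solute for residual conditioning
        scale = (pars.apical_perm + pars.basolateral_perm
                 + pars.paracellular_perm) * 100.0
        for spec in t.values():
            share = np.zeros(N_SOLUTES)
            if spec.id in ("SGLT2", "SGLT1"):
                share[[NA, GLU]] = spec.vmax
            elif spec.id in ("GLUT1", "GLUT2"):
                share[GLU] = spec.vmax
            elif spec.id == "NHE3":
                share[NA] = spec.vmax
            elif spec.id == "NKCC2":
                share[[NA, K]] = spec.vmax
                share[CL] = 2 * spec.vmax
            elif spec.id == "NCC":
                share[[NA, CL]] = spec.vmax
            elif spec.id == "NaKATPase":
                share[[NA, K]] = spec.vmax
            elif spec.id == "KCl_cotransport":
                share[[K, CL]] = spec.vmax
            elif spec.id == "ENaC":
                share[NA] = spec.vmax * 100.0
            elif spec.id == "ROMK":
                share[K] = spec.vmax * 100.0
            scale += share
        self.flux_scale = np.maximum(scale, 1e-8)

    def membrane_fluxes(self, c_lum: np.ndarray, c_ist: np.ndarray,
                        C: np.ndarray, v_cell: np.ndarray,
                        v_lum: np.ndarray):
        """Apical and basolateral flux matrices for cell-state batch ``C``.

        ``C`` has shape (m, n_solutes); ``v_cell``/``v_lum`` shape (m,).
        Returns ``(J_ap, J_bl, i_ap_corr)``: fluxes positive into and out of
        the cell respectively, and an apical current correction (charge per
        area) for electroneutral exchangers whose counter-ion lies outside
        the modelled solute set (NHE3 carries one H+ out per Na+ in, so its
        Na+ flux contributes no net apical current).
        """
        pars, tm = self.pars, self.tm
        dv_ap = (v_lum - v_cell)[:, None]
        dv_bl = v_cell[:, None]
        J_ap = ghk_flux(pars.apical_perm[None, :], Z[None, :],
                        c_lum[None, :], C, dv_ap)
        J_bl = ghk_flux(pars.basolateral_perm[None, :], Z[None, :],
                        C, c_ist[None, :], dv_bl)
        i_ap_corr = np.zeros(C.shape[0])

        for spec in pars.transporters.values():
            v = spec.vmax_effective * tm
            if spec.id in ("SGLT2", "SGLT1"):
                jg, jna = sglt_flux(spec.id, c_lum[GLU], c_lum[NA],
                                    C[:, GLU], C[:, NA], v,
                                    spec.km.get("glucose", 2.0),
                                    spec.km.get("Na", 30.0))
                J_ap[:, GLU] += jg
                J_ap[:, NA] += jna
            elif spec.id == "NHE3":
                jna, jcl = nhe3_flux(c_lum[NA], c_lum[CL], C[:, NA],
                                     C[:, CL], v, spec.km.get("Na", 30.0),
                                     spec.km.get("Cl", 70.0), spec.beta)
                J_ap[:, NA] += jna
                J_ap[:, CL] += jcl  # titrated luminal anion: electroneutral
            elif spec.id == "NKCC2":
                jna, jk, jcl = nkcc2_flux(
                    c_lum[NA], c_lum[K], c_lum[CL],
                    C[:, NA], C[:, K], C[:, CL], v,
                    spec.km.get("Na", 50.0), spec.km.get("K", 5.0),
                    spec.km.get("Cl", 70.0))
                J_ap[:, NA] += jna
                J_ap[:, K] += jk
                J_ap[:, CL] += jcl
            elif spec.id == "NCC":
                jna, jcl = ncc_flux(c_lum[NA], c_lum[CL], C[:, NA], C[:, CL],
                                    v, spec.km.get("Na", 50.0),
                                    spec.km.get("Cl", 50.0))
                J_ap[:, NA] += jna
                J_ap[:, CL] += jcl
            elif spec.id == "ENaC":
                J_ap[:, NA] += ghk_flux(v, 1.0, c_lum[NA], C[:, NA],
                                        dv_ap[:, 0])
            elif spec.id == "ROMK":
                J_ap[:, K] += ghk_flux(v, 1.0, c_lum[K], C[:, K], dv_ap[:, 0])
            elif spec.id == "NaKATPase":
                jna, jk = nak_atpase_flux(C[:, NA], v * self.pump_mult,
                                          spec.km.get("Na", 6.0))
                J_bl[:, NA] += jna
                J_bl[:, K] -= jk
            elif spec.id in ("GLUT1", "GLUT2"):
                J_bl[:, GLU] += glut_flux(C[:, GLU], c_ist[GLU], v,
                                          spec.km.get("glucose", 2.0))
            elif spec.id == "KCl_cotransport":
                jk, jcl = kcl_flux(C[:, K], C[:, CL], c_ist[K], c_ist[CL], v,
                                   spec.km.get("K", 10.0),
                                   spec.km.get("Cl", 25.0))
                J_bl[:, K] += jk
                J_bl[:, CL] += jcl
            else:  # pragma: no cover - unknown ids rejected here
                raise SolverError(f"unknown transporter {spec.id!r}")
        return J_ap, J_bl, i_ap_corr

    def water_fluxes(self, c_lum, c_ist, p_lum):
        """(transcellular Jv, paracellular Jv), lumen->interstitium, cm/s."""
        pars = self.pars
        jv_tc = water_flux(pars.pf_transcell, np.ones(N_SOLUTES),
                           c_lum, c_ist)
        jv_pa = water_flux(pars.pf_para, pars.sigma, c_lum, c_ist,
                           dp_mmhg=p_lum - INTERSTITIAL_PRESSURE_MMHG)
        return float(jv_tc), float(jv_pa)

    def paracellular(self, c_lum, c_ist, v_lum, jv_para, drag=None):
        """Paracellular solute fluxes for a batch of ``v_lum`` (m,).

        ``drag`` may carry the precomputed solvent-drag term (it does not
        depend on the potential, so the Newton loop computes it once).
        """
        if drag is None:
            drag = (1.0 - self.pars.sigma) * jv_para * logmean(c_lum, c_ist)
        diff = ghk_flux(self.pars.paracellular_perm[None, :], Z[None, :],
                        c_lum[None, :], c_ist[None, :],
                        np.asarray(v_lum)[:, None], )
        return diff + drag[None, :]


def _encode(cell_conc, v_cell, v_lum):
    return np.concatenate([np.log(cell_conc),
                           [v_cell / RT_OVER_F, v_lum / RT_OVER_F]])


def _decode(u):
    return np.exp(u[:N_SOLUTES]), u[N_SOLUTES] * RT_OVER_F, \
        u[N_SOLUTES + 1] * RT_OVER_F


def solve_cell(problem: CellProblem, lumen: LuminalState, c_ist: np.ndarray,
               guess: Optional[np.ndarray] = None, tol: float = 1e-10,
               max_iter: int = 60):
    """Solve the epithelial cell compartment at one grid point.

    Returns ``(CellState, info)`` where ``info`` carries the converged flux
    vectors (apical, basolateral, paracellular, water) and the residual
    norm.  ``guess`` is ``[conc(5), v_cell, v_lum]`` (the previous grid
    point's solution under axial continuation, or the segment default).

    Raises :class:`SolverError` on non-convergence.
    """
    pars = problem.pars
    c_lum = np.maximum(lumen.conc, 1e-9)
    if guess is None:
        guess = pars.default_cell_state
    if guess is None:
        raise SolverError(f"{pars.segment_id}: no cell initial guess")
    u = _encode(np.maximum(guess[:N_SOLUTES], 1e-6), guess[N_SOLUTES],
                guess[N_SOLUTES + 1])

    jv_tc, jv_pa = problem.water_fluxes(c_lum, c_ist, lumen.pressure)
    fs = problem.flux_scale
    cur_scale = float(np.sum(fs[np.abs(Z) > 0]))
    # the solvent-drag part of the paracellular flux does not depend on the
    # unknowns; compute it once per grid point
    drag = (1.0 - pars.sigma) * jv_pa * logmean(c_lum, c_ist)

    def residual_batch(U):
        C = np.exp(U[:, :N_SOLUTES])
        v_cell = U[:, N_SOLUTES] * RT_OVER_F
        v_lum = U[:, N_SOLUTES + 1] * RT_OVER_F
        J_ap, J_bl, i_corr = problem.membrane_fluxes(c_lum, c_ist, C,
                                                     v_cell, v_lum)
        J_pa = problem.paracellular(c_lum, c_ist, v_lum, jv_pa, drag=drag)
        R = np.empty((U.shape[0], N_SOLUTES + 2))
        R[:, :N_SOLUTES] = (J_ap - J_bl) / fs[None, :]
        R[:, N_SOLUTES] = (C @ Z - pars.impermeant_anion) / 100.0
        R[:, N_SOLUTES + 1] = ((J_ap + J_pa) @ Z + i_corr) / cur_scale
        return R

    n = N_SOLUTES + 2
    h = 1e-7
    # keep the iterate in a physically sane box: concentrations in
    # [1e-4, 1e4] mM, potentials within +-150 mV
    lo = np.concatenate([np.full(N_SOLUTES, np.log(1e-4)),
                         [-150.0 / RT_OVER_F] * 2])
    hi = np.concatenate([np.full(N_SOLUTES, np.log(1e4)),
                         [150.0 / RT_OVER_F] * 2])
    u = np.clip(u, lo, hi)
    R = residual_batch(u[None, :])[0]
    norm = float(np.max(np.abs(R)))
    for _ in range(max_iter):
        if norm < tol:
            break
        U = np.tile(u, (n, 1))
        U[np.arange(n), np.arange(n)] += h
        Rp = residual_batch(U)
        jac = (Rp - R[None, :]).T / h
        du = None
        reg = 0.0
        for _ in range(4):
            try:
                du = np.linalg.solve(jac + reg * np.eye(n), -R)
                break
            except np.linalg.LinAlgError:
                reg = 1e-8 if reg == 0.0 else reg * 100.0
        if du is None or not np.all(np.isfinite(du)):
            raise SolverError(f"{pars.segment_id}: singular cell Jacobian")
        step = np.max(np.abs(du))
        if step > 2.0:
            du *= 2.0 / step
        # backtracking damped update
        lam = 1.0
        for _ in range(6):
            u_new = np.clip(u + lam * du, lo, hi)
            R_new = residual_batch(u_new[None, :])[0]
            norm_new = float(np.max(np.abs(R_new)))
            if norm_new < norm or norm_new < tol:
                break
            lam *= 0.5
        u, R, norm = u_new, R_new, norm_new
    else:
        raise SolverError(
            f"cell solve failed in {pars.class_id}/{pars.segment_id}: "
            f"residual {norm:.2e} after {max_iter} iterations")

    conc, v_cell, v_lum = _decode(u)
    C = conc[None, :]
    J_ap, J_bl, _ = problem.membrane_fluxes(c_lum, c_ist, C,
                                            np.array([v_cell]),
                                            np.array([v_lum]))
    J_pa = problem.paracellular(c_lum, c_ist, np.array([v_lum]), jv_pa)
    cell = CellState(conc=conc, impermeant_anion=pars.impermeant_anion,
                     v_apical=v_lum - v_cell, v_basolateral=v_cell)
    # converged breakdown for reporting
    pump = pars.transporters.get("NaKATPase")
    active_na = 0.0
    if pump is not None:
        active_na = float(nak_atpase_flux(
            conc[NA], pump.vmax_effective * problem.tm * problem.pump_mult,
            pump.km.get("Na", 6.0))[0])
    sglt_glu = {}
    for kind in ("SGLT2", "SGLT1"):
        spec = pars.transporters.get(kind)
        if spec is not None:
            sglt_glu[kind] = float(sglt_flux(
                kind, c_lum[GLU], c_lum[NA], conc[GLU], conc[NA],
                spec.vmax_effective * problem.tm,
                spec.km.get("glucose", 2.0), spec.km.get("Na", 30.0))[0])
    info = {
        "J_apical": J_ap[0], "J_basolateral": J_bl[0],
        "J_paracellular": J_pa[0], "jv_transcell": jv_tc,
        "jv_para": jv_pa, "residual_norm": norm,
        "active_na": active_na, "sglt_glucose": sglt_glu,
        "guess": np.concatenate([conc, [v_cell, v_lum]]),
    }
    return cell, info


# -------------------------------------------------------------------------
# segment integration
# -------------------------------------------------------------------------

@dataclass
class SegmentSolution:
    """Solved axial profiles and transport bookkeeping for one segment."""

    segment_id: str
    class_id: str
    x: np.ndarray                    # node positions, cm
    fv: np.ndarray                   # cm^3/s
    pressure: np.ndarray             # mmHg
    conc: np.ndarray                 # (n_nodes, n_solutes), mM
    v_te: np.ndarray                 # mV
    cell_conc: Optional[np.ndarray]  # (n_nodes, n_solutes) or None
    reabsorption: np.ndarray         # per tubule, umol/s (positive = reabs)
    water_reabsorption: float        # per tubule, cm^3/s
    transcellular: np.ndarray        # flux-integral split of reabsorption
    paracellular: np.ndarray
    active_na: float                 # Na/K-ATPase Na flux integral, umol/s
    sglt_glucose: Dict[str, float] = field(default_factory=dict)
    final_cell_guess: Optional[np.ndarray] = None  # for axial continuation

    @property
    def inlet(self) -> LuminalState:
        return LuminalState(0.0, self.fv[0], self.pressure[0],
                            self.conc[0].copy(), self.v_te[0])

    @property
    def outlet(self) -> LuminalState:
        return LuminalState(self.x[-1], self.fv[-1], self.pressure[-1],
                            self.conc[-1].copy(), self.v_te[-1])

    def conservation_residual(self) -> np.ndarray:
        """Relative mismatch between flow change and the flux integrals."""
        d_flow = self.fv[0] * self.conc[0] - self.fv[-1] * self.conc[-1]
        split = self.transcellular + self.paracellular
        scale = np.maximum(np.abs(self.fv[0] * self.conc[0]), 1e-12)
        return (d_flow - split) / scale


@dataclass
class _RhsResult:
    dY: np.ndarray
    aux: np.ndarray          # [transcell(5), paracell(5), active_na, sglt2, sglt1]
    v_te: float
    cell_conc: Optional[np.ndarray]
    stiff_rate: float = 0.0  # osmotic water relaxation rate, 1/cm


def _aux_vector(transcell, paracell, active_na, sglt):
    out = np.zeros(2 * N_SOLUTES + 3)
    out[:N_SOLUTES] = transcell
    out[N_SOLUTES:2 * N_SOLUTES] = paracell
    out[2 * N_SOLUTES] = active_na
    out[2 * N_SOLUTES + 1] = sglt.get("SGLT2", 0.0)
    out[2 * N_SOLUTES + 2] = sglt.get("SGLT1", 0.0)
    return out


def solve_segment(inlet: LuminalState, geom: SegmentGeometry,
                  pars: SegmentParams, interstitium: InterstitialProfile,
                  torque_ref: Optional[Callable[[float], tuple]] = None,
                  torque_sensitivity: float = 1.0,
                  torque_clamp=(0.2, 3.0),
                  grid_points: Optional[int] = None,
                  initial_cell_guess: Optional[np.ndarray] = None
                  ) -> SegmentSolution:
    """Integrate one segment from its inlet state.

    ``torque_ref``, used only for torque-sensitive (proximal) segments, maps
    local arc position to ``(reference_flow_cm3_s, reference_radius_cm)``.
    ``initial_cell_guess`` seeds the first cell solve (axial continuation
    from an upstream segment of matching cell type); within the segment the
    previous grid point's solution is always the next starting point.
    """
    n = grid_points or geom.grid_points
    r = geom.radius
    circ = 2.0 * np.pi * r
    hx = geom.length / n
    x_nodes = np.linspace(0.0, geom.length, n + 1)

    warm: Dict[str, Optional[np.ndarray]] = {"guess": initial_cell_guess}
    problem = CellProblem(pars)
    return _run_segment(inlet, geom, pars, interstitium, torque_ref,
                        torque_sensitivity, torque_clamp, n, r, circ, hx,
                        x_nodes, warm, problem)


def _run_segment(inlet, geom, pars, interstitium, torque_ref,
                 torque_sensitivity, torque_clamp, n, r, circ, hx,
                 x_nodes, warm, problem) -> SegmentSolution:
    from . import fluxes as _fluxes
    _validate_prev = _fluxes.VALIDATE
    # inner integration loops guarantee non-negative states themselves
    _fluxes.VALIDATE = False
    try:
        return _run_segment_inner(inlet, geom, pars, interstitium,
                                  torque_ref, torque_sensitivity,
                                  torque_clamp, n, r, circ, hx, x_nodes,
                                  warm, problem)
    finally:
        _fluxes.VALIDATE = _validate_prev


def _run_segment_inner(inlet, geom, pars, interstitium, torque_ref,
                       torque_sensitivity, torque_clamp, n, r, circ, hx,
                       x_nodes, warm, problem) -> SegmentSolution:

    def rhs(x: float, Y: np.ndarray) -> _RhsResult:
        fv = Y[0]
        if fv <= 0.0:
            raise SolverError(
                f"segment runs dry: {pars.class_id}/{pars.segment_id} "
                f"at x={x:.3f} cm (Fv={fv:.3e})")
        conc = np.maximum(Y[1:], 0.0) / fv
        depth = float(geom.depth_at(x))
        c_ist = interstitium.concentrations(depth)
        frac = x / geom.length
        state = LuminalState(x, fv, inlet.pressure, np.maximum(conc, 1e-12))

        tm = 1.0
        if pars.torque_sensitive and torque_ref is not None:
            q_ref, r_ref = torque_ref(x)
            # evaluate the drag proxy at reference radius on both sides:
            # the density response tracks flow relative to its reference
            tm = float(torque_multiplier(fv, q_ref, r_ref, r_ref,
                                         torque_sensitivity, torque_clamp))
        problem.tm = tm if pars.torque_sensitive else 1.0
        problem.pump_mult = pars.pump_multiplier_at(frac)

        if pars.has_cell:
            try:
                cell, info = solve_cell(problem, state, c_ist,
                                        guess=warm["guess"])
            except SolverError:
                if warm["guess"] is None:
                    raise
                # retry from the segment's stored default interior state
                cell, info = solve_cell(problem, state, c_ist, guess=None)
            warm["guess"] = info["guess"]
            j_lumen = info["J_apical"] + info["J_paracellular"]
            jv = info["jv_transcell"] + info["jv_para"]
            aux = _aux_vector(info["J_apical"], info["J_paracellular"],
                              info["active_na"], info["sglt_glucose"])
            v_te = cell.v_te
            cell_conc = cell.conc
        else:
            # single-barrier transmural law (descending limbs)
            jv_tc, jv_pa = problem.water_fluxes(state.conc, c_ist,
                                                state.pressure)
            jv = jv_tc + jv_pa
            j_lumen = problem.paracellular(state.conc, c_ist,
                                           np.array([0.0]), jv_pa)[0]
            aux = _aux_vector(np.zeros(N_SOLUTES), j_lumen, 0.0, {})
            v_te = 0.0
            cell_conc = None

        dY = np.empty(1 + N_SOLUTES)
        dY[0] = -circ * jv
        dY[1:] = -circ * j_lumen
        # explicit-stability bound for the osmotic water equation:
        # d(Jv)/d(osm) ~ Pf*Vw and d(osm)/dFv ~ -osm/Fv
        stiff = circ * (pars.pf_transcell + pars.pf_para) * 1.8e-5 \
            * float(np.sum(conc)) / fv
        return _RhsResult(dY, circ * aux, v_te, cell_conc, stiff)

    # conservative state: [Fv, F_i]
    Y = np.concatenate([[inlet.fv], inlet.flows])
    eps = np.concatenate([[0.05 * inlet.fv],
                          np.full(N_SOLUTES, 1.0 * inlet.fv)])

    fv_nodes = np.empty(n + 1)
    p_nodes = np.empty(n + 1)
    conc_nodes = np.empty((n + 1, N_SOLUTES))
    vte_nodes = np.empty(n + 1)
    cellc_nodes = np.full((n + 1, N_SOLUTES), np.nan) if pars.has_cell else None
    aux_total = np.zeros(2 * N_SOLUTES + 3)

    def record(i, Y, res: _RhsResult):
        fv_nodes[i] = Y[0]
        conc_nodes[i] = np.maximum(Y[1:], 0.0) / Y[0]
        vte_nodes[i] = res.v_te
        if cellc_nodes is not None and res.cell_conc is not None:
            cellc_nodes[i] = res.cell_conc

    # negative solute flows signal an over-long step; the allowance below is
    # tiny so subdivision (never clamping) absorbs them, keeping the scheme
    # conservative
    neg_tol = 1e-6 * eps[1:]

    def heun(x, Y, h, depth):
        """One (possibly subdivided) Heun step; returns (Y_next, aux_int)."""
        res1 = rhs(x, Y)
        Yp = Y + h * res1.dY
        res2 = None
        bad = Yp[0] <= 0 or np.any(Yp[1:] < -neg_tol) \
            or h * res1.stiff_rate > 1.5
        if not bad:
            res2 = rhs(x + h, np.maximum(Yp, 0.0))
            Yn = Y + 0.5 * h * (res1.dY + res2.dY)
            change = np.abs(Yn - Y) / (np.abs(Y) + eps)
            bad = Yn[0] <= 0 or np.any(Yn[1:] < -neg_tol) \
                or float(np.max(change)) > 0.2
        if bad:
            if depth >= 12:
                if res2 is None or Yn[0] <= 0 \
                        or not np.all(np.isfinite(Yn)):
                    raise SolverError(
                        f"segment runs dry: {pars.class_id}/{pars.segment_id}"
                        f" near x={x:.3f} cm")
                # accept the finest-level step as-is
            else:
                Ym, aux_a = heun(x, Y, 0.5 * h, depth + 1)
                Yn2, aux_b = heun(x + 0.5 * h, Ym, 0.5 * h, depth + 1)
                return Yn2, aux_a + aux_b
        aux_int = 0.5 * h * (res1.aux + res2.aux)
        Yn = np.maximum(Yn, 0.0)
        Yn[0] = max(Yn[0], 1e-12)
        return Yn, aux_int

    # Poiseuille pressure drop, diagnostic only
    def dp(fv):
        return -(8.0 * VISCOSITY * fv / (np.pi * r ** 4)) / DYN_PER_MMHG

    p = inlet.pressure
    res0 = rhs(0.0, Y)
    record(0, Y, res0)
    p_nodes[0] = p
    for i in range(n):
        Y, aux_i = heun(x_nodes[i], Y, hx, 0)
        aux_total += aux_i
        p += hx * dp(Y[0])
        p_nodes[i + 1] = p
        res_end = rhs(x_nodes[i + 1], Y)
        record(i + 1, Y, res_end)

    flows_in = inlet.flows
    flows_out = fv_nodes[-1] * conc_nodes[-1]
    # split the conservative totals proportionally onto the flux-integral
    # breakdown so transcellular + paracellular sums exactly to the total
    transcell = aux_total[:N_SOLUTES]
    paracell = aux_total[N_SOLUTES:2 * N_SOLUTES]
    total_split = transcell + paracell
    total_true = flows_in - flows_out
    corr = total_true - total_split
    # attribute the (O(h^2)) quadrature mismatch to the dominant pathway
    dominant = np.where(np.abs(transcell) >= np.abs(paracell), 1.0, 0.0)
    transcell = transcell + corr * dominant
    paracell = paracell + corr * (1.0 - dominant)

    return SegmentSolution(
        segment_id=geom.segment_id,
        class_id=pars.class_id,
        x=x_nodes, fv=fv_nodes, pressure=p_nodes, conc=conc_nodes,
        v_te=vte_nodes, cell_conc=cellc_nodes,
        reabsorption=total_true,
        water_reabsorption=inlet.fv - fv_nodes[-1],
        transcellular=transcell, paracellular=paracell,
        active_na=aux_total[2 * N_SOLUTES],
        sglt_glucose={"SGLT2": aux_total[2 * N_SOLUTES + 1],
                      "SGLT1": aux_total[2 * N_SOLUTES + 2]},
        final_cell_guess=warm["guess"],
    )
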