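"""Epithelial cell compartment: equilibria, uniqueness, ODE cross-check."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import root

from nephrosim.params import ParameterSet
from nephrosim.solutes import CL, K, NA, N_SOLUTES, Z, plasma_vector
from nephrosim.solver import CellProblem, LuminalState, solve_cell
from nephrosim.units import RT_OVER_F


@pytest.fixture(scope="module")
def params():
    return ParameterSet.default()


def _symmetric_passive_pars(params):
    """PCT parameters with all transporters off and channels open."""
    pars = params.segment_params("superficial", "PCT")
    for t in pars.transporters.values():
        t.vmax = 0.0
    # open apical/basolateral channels for the ions so a Donnan state exists
    pars.apical_perm = np.array([1e-5, 1e-5, 1e-5, 1e-5, 1e-6])
    pars.basolateral_perm = pars.apical_perm.copy()
    return pars


class TestEquilibria:
    def test_symmetric_bath_reaches_donnan_state(self, params):
        """Transporters off, symmetric bath: zero fluxes, Donnan ratios."""
        pars = _symmetric_passive_pars(params)
        plasma = plasma_vector()
        lumen = LuminalState(0.0, 1e-6, 5.0, plasma.copy())
        problem = CellProblem(pars)
        cell, info = solve_cell(problem, lumen, plasma)
        # all net membrane fluxes vanish
        assert np.all(np.abs(info["J_apical"]) < 1e-12)
        assert np.all(np.abs(info["J_basolateral"]) < 1e-12)
        # permeant ions satisfy the same Donnan factor exp(-zV/RT)
        factor_na = cell.conc[NA] / plasma[NA]
        factor_k = cell.conc[K] / plasma[K]
        factor_cl = cell.conc[CL] / plasma[CL]
        assert factor_na == pytest.approx(factor_k, rel=1e-6)
        assert factor_cl == pytest.approx(1.0 / factor_na, rel=1e-6)
        v_donnan = -RT_OVER_F * np.log(factor_na)
        assert cell.v_basolateral == pytest.approx(v_donnan, rel=1e-6)
        # electroneutrality against the impermeant anion
        assert abs(cell.electroneutrality_residual()) < 1e-8

    def test_pump_keeps_cell_sodium_below_bath(self, params):
        pars = params.segment_params("superficial", "PCT")
        plasma = plasma_vector()
        lumen = LuminalState(0.0, 1e-6, 5.0, plasma.copy())
        cell, _ = solve_cell(CellProblem(pars), lumen, plasma)
        assert cell.conc[NA] < 0.25 * plasma[NA]
        assert cell.conc[K] > plasma[K]

    def test_perturbed_guess_reaches_same_root(self, params):
        pars = params.segment_params("superficial", "PCT")
        plasma = plasma_vector()
        lumen = LuminalState(0.0, 1e-6, 5.0, plasma.copy())
        problem = CellProblem(pars)
        cell_a, info_a = solve_cell(problem, lumen, plasma)
        guess = pars.default_cell_state.copy()
        guess[:N_SOLUTES] *= 1.10
        guess[N_SOLUTES:] *= 0.9
        cell_b, _ = solve_cell(problem, lumen, plasma, guess=guess)
        assert np.allclose(cell_a.conc, cell_b.conc, rtol=1e-8)
        assert cell_a.v_te == pytest.approx(cell_b.v_te, abs=1e-6)

    def test_residual_norm_below_tolerance(self, params):
        pars = params.segment_params("superficial", "mTAL")
        plasma = plasma_vector()
        lumen = LuminalState(0.0, 4e-7, 15.0, plasma * 0.6 + 1.0)
        _, info = solve_cell(CellProblem(pars), lumen, plasma)
        assert info["residual_norm"] < 1e-10


class TestOdeCrossCheck:
    def test_steady_state_matches_transient_cell_odes(self, params):
        """Independent oracle: integrate the cell mass-balance ODEs.

        The transient system evolves cytosolic concentrations with
        dc/dt proportional to (apical influx - basolateral efflux), with
        the two potentials re-solved at every instant from cell charge
        conservation and the open-circuit condition.  Its long-time state
        must agree with the algebraic root found by the Newton solver.
        """
        pars = params.segment_params("superficial", "PCT")
        plasma = plasma_vector()
        lumen = LuminalState(0.0, 1e-6, 5.0, plasma.copy())
        problem = CellProblem(pars)
        jv_tc, jv_pa = problem.water_fluxes(lumen.conc, plasma,
                                            lumen.pressure)

        cur_scale = float(np.sum(problem.flux_scale))

        def potentials_for(c_cell, v_guess):
            def current_balance(v):
                C = c_cell[None, :]
                J_ap, J_bl, i_corr = problem.membrane_fluxes(
                    lumen.conc, plasma, C, np.array([v[0]]),
                    np.array([v[1]]))
                J_pa = problem.paracellular(lumen.conc, plasma,
                                            np.array([v[1]]), jv_pa)
                i_ap = float(J_ap[0] @ Z + i_corr[0] + J_pa[0] @ Z)
                i_cell = float((J_ap[0] - J_bl[0]) @ Z)
                return [i_ap / cur_scale, i_cell / cur_scale]
            sol = root(current_balance, v_guess, method="hybr")
            residual = current_balance(sol.x)
            assert max(abs(r) for r in residual) < 1e-8
            return sol.x

        v = np.array([-70.0, -1.0])
        area_over_volume = 1e3  # 1/cm; sets the transient speed only

        def rhs(t, c):
            nonlocal v
            c = np.maximum(c, 1e-6)
            v = potentials_for(c, v)
            J_ap, J_bl, _ = problem.membrane_fluxes(
                lumen.conc, plasma, c[None, :], np.array([v[0]]),
                np.array([v[1]]))
            return area_over_volume * (J_ap[0] - J_bl[0])

        # perturb the start charge-neutrally: the transient conserves cell
        # charge, so the initial state must satisfy electroneutrality
        c0 = pars.default_cell_state[:N_SOLUTES].copy()
        c0[K] += 12.0
        c0[CL] += 12.0
        c0[[3, 4]] *= 1.3
        ode = solve_ivp(rhs, (0.0, 5e4), c0, method="LSODA",
                        rtol=1e-10, atol=1e-10)
        assert ode.success
        cell, _ = solve_cell(problem, lumen, plasma)
        assert np.allclose(ode.y[:, -1], cell.conc, rtol=2e-3)
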