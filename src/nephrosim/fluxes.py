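"""Transmembrane and paracellular flux laws.

Sign conventions
----------------
Every law returns flux positive in its "forward" (cis -> trans) direction;
at the tubule level positive transmural flux means reabsorption
(lumen -> cell -> interstitium).  Potentials are differences ``V_cis -
V_trans`` in mV; concentrations are mM.  All functions broadcast over numpy
arrays so a whole finite-difference Jacobian batch can be evaluated in one
call.

Carrier forms
-------------
Cotransporters (SGLT1/2, NKCC2, NCC, KCl) are modelled as reversible
saturable carriers ``J = vmax * (occ_cis - occ_trans)``, where ``occ`` is a
product of Michaelis occupancies of the transported substrates with the Na
occupancy raised to the coupling stoichiometry.  This captures saturation,
coupling and reversibility without a full multi-state kinetic diagram; the
flux vanishes when the two occupancies match (the carrier's equilibrium
state) and is bounded by +/- vmax.

NHE3 exchanges Na+ for H+; with acid-base chemistry outside the model's
solute set, the proton side is represented by a fixed occupancy factor
``beta`` on the cytosolic face, preserving NHE3's role as the dominant
saturable apical Na+ entry path of the proximal tubule.
"""

from __future__ import annotations

import numpy as np

from .units import RT_OVER_F, RT_MMHG_PER_MOLAR, VBAR_W


class DomainError(ValueError):
    """Raised when a flux law is evaluated at a non-physical state."""


#: validation toggle: the cell solver evaluates flux laws tens of thousands
#: of times per tubule on states it already guarantees non-negative, and
#: switches the (redundant) domain checks off for those inner loops.
VALIDATE = True


def _check_positive(name, *values):
    if not VALIDATE:
        return
    for v in values:
        if np.any(np.asarray(v) < 0):
            raise DomainError(f"{name}: negative concentration")


def _mm(c, km):
    """Michaelis occupancy c/(c+km)."""
    return c / (c + km)


# -------------------------------------------------------------------------
# electrodiffusion
# -------------------------------------------------------------------------

def ghk_flux(permeability, valence, c_cis, c_trans, dv_mv):
    """Goldman-Hodgkin-Katz constant-field flux, cis -> trans positive.

    For ``valence == 0`` this is Fickian diffusion ``P*(c_cis - c_trans)``;
    the charged-solute expression reduces to the same limit as the potential
    difference approaches zero.

    Parameters are broadcast; ``dv_mv = V_cis - V_trans`` in mV.
    Units: permeability cm/s, concentrations mM, flux umol cm^-2 s^-1.
    """
    P = np.asarray(permeability, dtype=float)
    z = np.asarray(valence, dtype=float)
    c1 = np.asarray(c_cis, dtype=float)
    c2 = np.asarray(c_trans, dtype=float)
    phi = z * np.asarray(dv_mv, dtype=float) / RT_OVER_F
    phi = np.where(z == 0.0, 0.0, phi)
    small = np.abs(phi) < 1e-7
    phi_safe = np.where(small, 1.0, phi)
    em = np.exp(-phi_safe)
    # J = P * phi * (c1 - c2 e^-phi) / (1 - e^-phi); -expm1(-phi) = 1 - e^-phi
    denom = -np.expm1(-phi_safe)
    full = P * phi_safe * (c1 - c2 * em) / denom
    # second-order accurate small-phi expansion (includes the linear drift term)
    lin = P * (c1 - c2 + 0.5 * phi * (c1 + c2))
    return np.where(small, lin, full)


# -------------------------------------------------------------------------
# glucose carriers
# -------------------------------------------------------------------------

SGLT_STOICH = {"SGLT2": 1, "SGLT1": 2}


def sglt_flux(kind, lum_glu, lum_na, cell_glu, cell_na, vmax,
              km_glu, km_na, inhibition_fraction=0.0):
    """Apical Na+-glucose cotransport; returns ``(J_glucose, J_Na)``.

    SGLT2 couples 1 Na+ : 1 glucose, SGLT1 couples 2 Na+ : 1 glucose; the
    Na flux is exactly stoichiometry x glucose flux.  Effective capacity is
    ``vmax * (1 - inhibition_fraction)`` (pure capacity inhibition).
    """
    n = SGLT_STOICH[kind]
    _check_positive("sglt_flux", lum_glu, lum_na, cell_glu, cell_na)
    v_eff = vmax * (1.0 - inhibition_fraction)
    occ_lum = _mm(lum_glu, km_glu) * _mm(lum_na, km_na) ** n
    occ_cell = _mm(cell_glu, km_glu) * _mm(cell_na, km_na) ** n
    j_glu = v_eff * (occ_lum - occ_cell)
    return j_glu, n * j_glu


def glut_flux(cis_glu, trans_glu, vmax, km):
    """Facilitated glucose diffusion (GLUT1/GLUT2), symmetric carrier.

    ``J = vmax * (S_cis/(Km+S_cis) - S_trans/(Km+S_trans))``; odd under
    swapping the two faces and zero at equal concentrations.
    """
    _check_positive("glut_flux", cis_glu, trans_glu)
    return vmax * (_mm(cis_glu, km) - _mm(trans_glu, km))


# -------------------------------------------------------------------------
# coupled ion cotransporters / exchangers
# -------------------------------------------------------------------------

def nkcc2_flux(lum_na, lum_k, lum_cl, cell_na, cell_k, cell_cl,
               vmax, km_na=30.0, km_k=1.5, km_cl=100.0):
    """Apical Na-K-2Cl cotransport (TAL); returns ``(J_Na, J_K, J_Cl)``.

    Electroneutral 1Na:1K:2Cl flux stoichiometry (zero net charge per
    cycle).  Carrier occupancy uses one Michaelis site per substrate (the
    two Cl sites are lumped): with km_Cl well above the luminal [Cl-] range
    the flux is near-linear in luminal Cl-, which makes the diluting-segment
    outlet concentration respond exponentially to the transport-capacity /
    flow ratio — the flow sensitivity the macula densa signal relies on.
    """
    _check_positive("nkcc2_flux", lum_na, lum_k, lum_cl, cell_na, cell_k, cell_cl)
    occ_l = _mm(lum_na, km_na) * _mm(lum_k, km_k) * _mm(lum_cl, km_cl)
    occ_c = _mm(cell_na, km_na) * _mm(cell_k, km_k) * _mm(cell_cl, km_cl)
    j = vmax * (occ_l - occ_c)
    return j, j, 2.0 * j


def ncc_flux(lum_na, lum_cl, cell_na, cell_cl, vmax, km_na=50.0, km_cl=50.0):
    """Apical Na-Cl cotransport (DCT); returns ``(J_Na, J_Cl)``."""
    _check_positive("ncc_flux", lum_na, lum_cl, cell_na, cell_cl)
    occ_l = _mm(lum_na, km_na) * _mm(lum_cl, km_cl)
    occ_c = _mm(cell_na, km_na) * _mm(cell_cl, km_cl)
    j = vmax * (occ_l - occ_c)
    return j, j


def nhe3_flux(lum_na, lum_cl, cell_na, cell_cl, vmax, km_na=30.0,
              km_cl=70.0, beta=0.5):
    """Apical Na+/H+ exchange as net saturable, electroneutral NaX entry.

    ``beta`` is the fixed proton-side occupancy proxy on the cytosolic face
    (< 1: the outward proton gradient biases the exchanger toward Na entry).
    Because the model's anion pool lumps Cl- with the bicarbonate-family
    anions, the proton secreted per Na+ titrates one luminal anion; the net
    effect carried by this law is therefore a coupled (Na+ + anion) entry
    with zero current, returned as ``(J_Na, J_anion)`` with J_Na = J_anion.
    """
    _check_positive("nhe3_flux", lum_na, lum_cl, cell_na, cell_cl)
    occ_l = _mm(lum_na, km_na) * _mm(lum_cl, km_cl)
    occ_c = _mm(cell_na, km_na) * _mm(cell_cl, km_cl)
    j = vmax * (occ_l - beta * occ_c)
    return j, j


def kcl_flux(cell_k, cell_cl, trans_k, trans_cl, vmax, km_k=10.0, km_cl=25.0):
    """Basolateral K-Cl cotransport (cell -> interstitium positive)."""
    _check_positive("kcl_flux", cell_k, cell_cl, trans_k, trans_cl)
    occ_c = _mm(cell_k, km_k) * _mm(cell_cl, km_cl)
    occ_t = _mm(trans_k, km_k) * _mm(trans_cl, km_cl)
    j = vmax * (occ_c - occ_t)
    return j, j


def nak_atpase_flux(cell_na, vmax, km_na=6.0):
    """Basolateral Na/K pump; returns ``(J_Na_out, J_K_in)``.

    Pump rate ``vmax * (Na/(Na+Km))^3`` with 3 Na+ out : 2 K+ in per cycle,
    so the flux ratio is exactly 1.5 at every state.
    """
    rate = vmax * _mm(np.asarray(cell_na, dtype=float), km_na) ** 3
    return rate, (2.0 / 3.0) * rate


# -------------------------------------------------------------------------
# paracellular and water pathways
# -------------------------------------------------------------------------

def logmean(a, b):
    """Logarithmic mean concentration, continuous at a == b.

    Falls back to the arithmetic mean when either side is ~zero or the two
    values are nearly equal (where the log form is ill-conditioned).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    tiny = 1e-12
    close = (np.abs(a - b) <= 1e-6 * np.maximum(np.abs(a), np.abs(b))) \
        | (a <= tiny) | (b <= tiny)
    sa = np.where(close, 1.0, a)
    sb = np.where(close, 2.0, b)
    return np.where(close, 0.5 * (a + b), (sa - sb) / np.log(sa / sb))


def paracellular_flux(permeability, valence, sigma, c_lum, c_ist,
                      v_te_mv, jv_para):
    """Tight-junction solute flux, lumen -> interstitium positive.

    Sum of a convective solvent-drag term ``(1 - sigma) * Jv * c_logmean``
    and a GHK/Fick electrodiffusive term driven by the transepithelial
    potential ``v_te_mv = V_lumen - V_interstitium``.
    """
    diff = ghk_flux(permeability, valence, c_lum, c_ist, v_te_mv)
    drag = (1.0 - np.asarray(sigma, dtype=float)) * jv_para * logmean(c_lum, c_ist)
    return diff + drag


def water_flux(pf, sigma, c_cis, c_trans, dp_mmhg=0.0):
    """Osmotic volume flux, cis -> trans positive (cm/s).

    ``Jv = Pf * Vbar_w * sum_i sigma_i * (c_trans_i - c_cis_i) + hydraulic``
    where the hydraulic term converts the pressure difference ``dp_mmhg =
    P_cis - P_trans`` to an equivalent van 't Hoff concentration.  Zero at
    osmotic (and hydrostatic) equilibrium; linear in Pf.

    ``c_cis``/``c_trans`` are per-solute concentration vectors (last axis =
    solutes); ``sigma`` broadcasts against them.
    """
    c1 = np.asarray(c_cis, dtype=float)
    c2 = np.asarray(c_trans, dtype=float)
    osm = np.sum(np.asarray(sigma, dtype=float) * (c2 - c1), axis=-1)
    # mM -> mol/cm^3 carries 1e-6; pressure term: mmHg -> equivalent mM
    dp_equiv = np.asarray(dp_mmhg, dtype=float) / RT_MMHG_PER_MOLAR * 1e3
    return pf * VBAR_W * 1e-6 * (osm + dp_equiv)


# -------------------------------------------------------------------------
# flow (torque)-dependent transporter scaling
# -------------------------------------------------------------------------

def torque_multiplier(flow, ref_flow, radius, ref_radius,
                      sensitivity=1.0, clamp=(0.2, 3.0)):
    """Flow-dependent scaling of proximal transcellular transporter density.

    Microvillous drag torque is proportional to ``mu * Q / r^2``; the
    multiplier is ``1 + C_T * (tau/tau_ref - 1)`` clamped to ``clamp``.
    Applied to PCT/S3 transcellular transporters only, never paracellular.
    """
    tau_ratio = (np.asarray(flow, dtype=float) / ref_flow) * (ref_radius / radius) ** 2
    m = 1.0 + sensitivity * (tau_ratio - 1.0)
    return np.clip(m, clamp[0], clamp[1])
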