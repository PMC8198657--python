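"""Physical constants and unit conventions.

Internal unit system (consistent, CGS-flavoured):

* length            cm
* time              s
* concentration     mM  (1 mM = 1 umol/cm^3, so no conversion factor is needed
                    between mmol/L and umol/cm^3)
* volume flow       cm^3/s
* solute flow       umol/s
* solute flux J     umol cm^-2 s^-1 (per unit luminal membrane area)
* volume flux Jv    cm/s
* permeability      cm/s
* potential         mV
* pressure          mmHg (diagnostic only)

Externally reported quantities use the field's customary units: nL/min for
SNGFR, mL/min and L/day for GFR, mol/day or mmol/day for transport rates.
"""

# thermal voltage RT/F at 310 K, mV
RT_OVER_F = 26.7

# partial molar volume of water, cm^3/mol
VBAR_W = 18.0

# van 't Hoff conversion: osmotic pressure of 1 mol/L at 310 K in mmHg.
# Used only for the (small) hydraulic term of paracellular water flux.
RT_MMHG_PER_MOLAR = 19_330.0

# tubular fluid viscosity, g cm^-1 s^-1 (poise)
VISCOSITY = 7.2e-3

# dyn/cm^2 per mmHg
DYN_PER_MMHG = 1333.22

SECONDS_PER_DAY = 86_400.0
MINUTES_PER_DAY = 1440.0

# unit conversions ---------------------------------------------------------

NL_PER_MIN_TO_CM3_PER_S = 1e-6 / 60.0   # 1 nL/min in cm^3/s


def sngfr_to_cm3_per_s(sngfr_nl_min: float) -> float:
    """Convert a single-nephron GFR from nL/min to cm^3/s."""
    return sngfr_nl_min * NL_PER_MIN_TO_CM3_PER_S


def flow_cm3_s_to_l_day(flow: float) -> float:
    """Convert a volume flow from cm^3/s to L/day."""
    return flow * SECONDS_PER_DAY * 1e-3


def flow_umol_s_to_mol_day(flow: float) -> float:
    """Convert a solute flow from umol/s to mol/day."""
    return flow * SECONDS_PER_DAY * 1e-6
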