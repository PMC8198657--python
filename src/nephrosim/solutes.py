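"""Solute set carried by the model.

The transported solutes are Na+, K+, Cl-, urea and glucose (plus water).
The arrays below define the canonical ordering used by every state vector
and parameter table in the package; code indexes solutes through
:data:`IDX` rather than hard-coded positions so the list stays extensible.
"""

import numpy as np

SOLUTES = ("Na", "K", "Cl", "urea", "glucose")
N_SOLUTES = len(SOLUTES)

#: valence of each solute
Z = np.array([1.0, 1.0, -1.0, 0.0, 0.0])

#: name -> index
IDX = {name: i for i, name in enumerate(SOLUTES)}

NA = IDX["Na"]
K = IDX["K"]
CL = IDX["Cl"]
UREA = IDX["urea"]
GLU = IDX["glucose"]

#: non-diabetic plasma composition, mM
#: "Cl" is the total permeant monovalent anion (chloride plus the
#: bicarbonate-family anions outside the modelled solute set), chosen so the
#: protein-free filtrate is electroneutral: Na + K = Cl.
DEFAULT_PLASMA = {"Na": 140.0, "K": 5.0, "Cl": 145.0, "urea": 5.0, "glucose": 5.0}


def plasma_vector(plasma: dict | None = None) -> np.ndarray:
    """Plasma concentrations as an ordered vector (mM)."""
    p = dict(DEFAULT_PLASMA)
    if plasma:
        p.update(plasma)
    return np.array([p[s] for s in SOLUTES], dtype=float)
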