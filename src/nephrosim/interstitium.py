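"""Medullary interstitial composition as a boundary condition.

The model has no vasculature, so the corticomedullary osmotic gradient is
prescribed rather than computed: cortical interstitium equals plasma, total
osmolality rises piecewise-linearly to ``om_boundary_osm`` at the
outer-inner medullary boundary (NaCl-driven) and on to ``papilla_osm`` at
the papillary tip (half NaCl, half urea), reflecting standard antidiuretic
human gradient magnitudes.  K+ is held at its plasma value and glucose at
plasma glucose throughout.  The stated osmolality targets are referenced to
a nominal 290 mOsm plasma; the profile adds the corresponding increments on
top of the modelled plasma solutes, scaled by ``gradient_scale``.
"""

from __future__ import annotations

import numpy as np

from .solutes import CL, GLU, NA, UREA

NOMINAL_PLASMA_OSM = 290.0


class InterstitialProfile:
    """Per-solute interstitial concentration as a function of depth (cm)."""

    def __init__(self, plasma: np.ndarray, outer_depth: float,
                 inner_depth: float, om_boundary_osm: float = 600.0,
                 papilla_osm: float = 1200.0, gradient_scale: float = 1.0,
                 outer_stripe_frac: float = 0.3,
                 outer_stripe_osm: float = 320.0):
        self.plasma = np.asarray(plasma, dtype=float)
        self.outer_depth = outer_depth
        self.inner_depth = inner_depth
        self.d_om = max(om_boundary_osm - NOMINAL_PLASMA_OSM, 0.0) * gradient_scale
        self.d_im = max(papilla_osm - om_boundary_osm, 0.0) * gradient_scale
        # the axial osmolality rise is shallow across the outer stripe and
        # steep across the inner stripe, as in the real corticomedullary
        # profile; ``knee`` is the outer-stripe share of the OM increment
        self.stripe_frac = outer_stripe_frac
        self.knee = (max(outer_stripe_osm - NOMINAL_PLASMA_OSM, 0.0)
                     / max(om_boundary_osm - NOMINAL_PLASMA_OSM, 1e-12))

    def _om_profile(self, f_om: float) -> float:
        """Fractional OM osmolality increment at OM depth fraction f_om."""
        if f_om <= self.stripe_frac:
            return self.knee * f_om / self.stripe_frac
        return self.knee + (1.0 - self.knee) * \
            (f_om - self.stripe_frac) / (1.0 - self.stripe_frac)

    def concentrations(self, depth: float) -> np.ndarray:
        """Interstitial concentration vector (mM) at a medullary depth."""
        c = self.plasma.copy()
        if depth <= 0.0:
            return c
        f_om = self._om_profile(min(depth / self.outer_depth, 1.0))
        nacl = 0.5 * self.d_om * f_om          # per-ion increment, OM part
        if depth > self.outer_depth:
            f_im = min((depth - self.outer_depth) / self.inner_depth, 1.0)
            extra = self.d_im * f_im
            nacl += 0.25 * extra               # half the IM osmoles are NaCl
            c[UREA] += 0.5 * extra             # the other half urea
        c[NA] += nacl
        c[CL] += nacl
        return c

    def osmolality(self, depth: float) -> float:
        return float(np.sum(self.concentrations(depth)))
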