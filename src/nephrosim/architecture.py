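"""Nephron population, segment chains, geometry and coalescence topology.

The model kidney contains one superficial nephron class (85% of the
population, loops turning at the outer-inner medullary boundary) and five
juxtamedullary classes (15% combined) whose loops of Henle reach staggered
depths in the inner medulla, with fractions decreasing with depth so that
most long loops turn within the upper inner medulla.  Connecting tubules
coalesce 10:1 into cortical collecting ducts; the inner-medullary collecting
ducts coalesce successively toward the papillary tip.

Axial coordinate: arc length from the segment inlet (cm), cell-centred grid.
Medullary depth is measured in cm below the corticomedullary boundary
(cortex = 0); the outer-inner medullary boundary sits at ``outer_depth`` and
the papillary tip at ``outer_depth + inner_depth``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .units import MINUTES_PER_DAY, sngfr_to_cm3_per_s

#: ordered luminal chain of a nephron, upstream of the shared collecting duct
SUPERFICIAL_CHAIN = ("PCT", "S3", "SDL", "mTAL", "cTAL", "DCT", "CNT")
JUXTAMEDULLARY_CHAIN = ("PCT", "S3", "SDL", "LDL", "LAL", "mTAL", "cTAL", "DCT", "CNT")
COLLECTING_DUCT_CHAIN = ("CCD", "OMCD", "IMCD")

#: segment groups used by geometry scaling and scenario overlays
SEGMENT_GROUPS: Dict[str, Tuple[str, ...]] = {
    "proximal": ("PCT", "S3"),
    "distal": ("DCT", "CNT", "CCD", "OMCD", "IMCD"),
    "distal_length": ("DCT", "CNT"),
    "TAL": ("mTAL", "cTAL"),
    "all": SUPERFICIAL_CHAIN + ("LDL", "LAL") + COLLECTING_DUCT_CHAIN,
}


class InvalidParameterError(ValueError):
    """Raised for non-physical architecture or scenario parameters."""


@dataclass
class NephronClass:
    """One nephron population class."""

    id: str                      # "superficial" | "jm1".."jm5"
    population_fraction: float   # of the total nephron count
    sngfr: float                 # nL/min
    loop_turn_depth: float       # mm below the OM-IM boundary (0 = superficial)

    def __post_init__(self) -> None:
        if self.sngfr <= 0:
            raise InvalidParameterError(f"sngfr must be > 0, got {self.sngfr}")
        if not (0 < self.population_fraction <= 1):
            raise InvalidParameterError(
                f"population fraction out of (0,1]: {self.population_fraction}")


@dataclass
class SegmentGeometry:
    """Geometry of one tubular segment of one nephron class."""

    segment_id: str
    length: float          # cm
    inner_diameter: float  # cm
    grid_points: int = 40
    depth_start: float = 0.0  # cm below corticomedullary boundary at inlet
    depth_end: float = 0.0    # ... at outlet

    def __post_init__(self) -> None:
        if self.length <= 0 or self.inner_diameter <= 0:
            raise InvalidParameterError(
                f"{self.segment_id}: length and diameter must be positive")
        if self.grid_points < 20:
            raise InvalidParameterError(
                f"{self.segment_id}: at least 20 grid points required")

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter

    def depth_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Medullary depth (cm) at arc position ``x`` from the inlet."""
        return self.depth_start + (self.depth_end - self.depth_start) * (
            np.asarray(x) / self.length)


@dataclass
class CoalescenceTopology:
    """How tubules merge on the way to the papilla."""

    cnt_merge_ratio: int = 10                      # loops per cortical CD
    imcd_merge_schedule: Tuple[Tuple[float, int], ...] = (
        (0.2, 2), (0.4, 2), (0.6, 2), (0.8, 2))   # (IMCD depth fraction, factor)

    def papillary_duct_count(self, n_ccd: float) -> float:
        n = n_ccd
        for _, factor in self.imcd_merge_schedule:
            n /= factor
        return n


@dataclass
class KidneyArchitecture:
    """Complete structural description of the model kidney."""

    nephron_classes: List[NephronClass]
    segments: Dict[str, List[SegmentGeometry]]     # per class, PCT..CNT
    collecting_duct: List[SegmentGeometry]         # shared CCD/OMCD/IMCD
    topology: CoalescenceTopology = field(default_factory=CoalescenceTopology)
    total_nephrons: float = 1.0e6
    outer_medulla_depth: float = 1.0   # cm
    inner_medulla_depth: float = 1.5   # cm

    def __post_init__(self) -> None:
        total = sum(c.population_fraction for c in self.nephron_classes)
        if abs(total - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"population fractions sum to {total!r}, expected 1")

    def nephron_class(self, class_id: str) -> NephronClass:
        for c in self.nephron_classes:
            if c.id == class_id:
                return c
        raise KeyError(class_id)

    def class_count(self, class_id: str) -> float:
        """Number of nephrons in a class."""
        return self.nephron_class(class_id).population_fraction * self.total_nephrons

    @property
    def n_ccd(self) -> float:
        """Number of cortical collecting ducts in the kidney."""
        return self.total_nephrons / self.topology.cnt_merge_ratio


# -------------------------------------------------------------------------
# default architecture
# -------------------------------------------------------------------------

#: population fractions of the five juxtamedullary classes (decreasing with
#: loop depth: most long loops turn within the upper inner medulla) and the
#: inner-medullary depth fraction at which each loop turns.
_JM_FRACTIONS = (0.06, 0.04, 0.025, 0.02, 0.005)
_JM_TURN_FRACS = (0.2, 0.4, 0.6, 0.8, 1.0)

#: default segment geometry: (length cm, inner diameter um).  Values are
#: physiologically standard human-scale defaults and are calibration
#: adjustable through the parameter file; loop-limb lengths depend on class.
_DEFAULT_GEOMETRY = {
    "PCT": (1.0, 25.0),
    "S3": (0.5, 25.0),
    "SDL": (0.7, 15.0),
    "LDL": (None, 15.0),   # length = loop turn depth
    "LAL": (None, 15.0),
    "mTAL": (1.0, 20.0),
    "cTAL": (0.5, 20.0),
    "DCT": (0.5, 20.0),
    "CNT": (0.5, 22.0),
    "CCD": (0.2, 25.0),
    "OMCD": (1.0, 25.0),
    "IMCD": (None, 28.0),  # length = inner medullary depth
}


def _segment_chain(class_id: str, turn_frac: float, geometry: dict,
                   outer_depth: float, inner_depth: float,
                   grid_points: int,
                   proximal_length_factor: float = 1.0
                   ) -> List[SegmentGeometry]:
    """Build the ordered segment list for one nephron class."""
    chain = SUPERFICIAL_CHAIN if class_id == "superficial" else JUXTAMEDULLARY_CHAIN
    # depth of the S3/SDL transition (outer stripe of the outer medulla)
    s3_depth = 0.3 * outer_depth
    turn = turn_frac * inner_depth
    segs: List[SegmentGeometry] = []
    for seg_id in chain:
        length, diam_um = geometry[seg_id]
        if seg_id in ("PCT", "S3"):
            length = length * proximal_length_factor
        if seg_id == "LDL" or seg_id == "LAL":
            length = turn
        depth = {
            "PCT": (0.0, 0.0),
            "S3": (0.0, s3_depth),
            "SDL": (s3_depth, outer_depth),
            "LDL": (outer_depth, outer_depth + turn),
            "LAL": (outer_depth + turn, outer_depth),
            "mTAL": (outer_depth, 0.0),
            "cTAL": (0.0, 0.0),
            "DCT": (0.0, 0.0),
            "CNT": (0.0, 0.0),
        }[seg_id]
        segs.append(SegmentGeometry(seg_id, length, diam_um * 1e-4,
                                    grid_points, depth[0], depth[1]))
    return segs


def build_default_architecture(config: dict | None = None,
                               grid_points: int = 40) -> KidneyArchitecture:
    """Return the six-class architecture with default geometry.

    Superficial nephrons make up 85% of the population with SNGFR
    100 nL/min; the five juxtamedullary classes share the remaining 15%
    with SNGFR 133 nL/min and staggered loop-turn depths.  ``config`` may
    override any of the keys ``total_nephrons``, ``outer_medulla_depth_cm``,
    ``inner_medulla_depth_cm``, ``geometry`` (map segment -> [length_cm,
    diameter_um]), ``jm_fractions``, ``jm_turn_fracs``, ``sngfr``
    (map class -> nL/min) and ``grid_points``.
    """
    cfg = config or {}
    grid_points = int(cfg.get("grid_points", grid_points))
    outer_depth = float(cfg.get("outer_medulla_depth_cm", 1.0))
    inner_depth = float(cfg.get("inner_medulla_depth_cm", 1.5))
    geometry = dict(_DEFAULT_GEOMETRY)
    for k, v in cfg.get("geometry", {}).items():
        geometry[k] = (v[0], v[1])
    jm_fracs = tuple(cfg.get("jm_fractions", _JM_FRACTIONS))
    jm_turns = tuple(cfg.get("jm_turn_fracs", _JM_TURN_FRACS))
    sngfr_map = dict(cfg.get("sngfr", {}))
    # juxtamedullary proximal tubules are longer, in proportion to their
    # higher SNGFR (133/100), so the load per membrane area matches the
    # superficial class
    jm_prox_factor = float(cfg.get("jm_proximal_length_factor", 1.33))

    classes = [NephronClass("superficial", 0.85,
                            float(sngfr_map.get("superficial", 100.0)), 0.0)]
    for i, (frac, turn) in enumerate(zip(jm_fracs, jm_turns), start=1):
        cid = f"jm{i}"
        classes.append(NephronClass(
            cid, frac, float(sngfr_map.get(cid, 133.0)),
            loop_turn_depth=turn * inner_depth * 10.0))  # cm -> mm

    segments = {}
    for c, turn in zip(classes, (0.0,) + jm_turns):
        factor = 1.0 if c.id == "superficial" else jm_prox_factor
        segments[c.id] = _segment_chain(c.id, turn, geometry,
                                        outer_depth, inner_depth, grid_points,
                                        proximal_length_factor=factor)

    cd = []
    for seg_id in COLLECTING_DUCT_CHAIN:
        length, diam_um = geometry[seg_id]
        if seg_id == "IMCD":
            length = inner_depth
        depth = {"CCD": (0.0, 0.0), "OMCD": (0.0, outer_depth),
                 "IMCD": (outer_depth, outer_depth + inner_depth)}[seg_id]
        cd.append(SegmentGeometry(seg_id, length, diam_um * 1e-4,
                                  grid_points, depth[0], depth[1]))

    return KidneyArchitecture(
        nephron_classes=classes,
        segments=segments,
        collecting_duct=cd,
        topology=CoalescenceTopology(),
        total_nephrons=float(cfg.get("total_nephrons", 1.0e6)),
        outer_medulla_depth=outer_depth,
        inner_medulla_depth=inner_depth,
    )


# -------------------------------------------------------------------------
# operations
# -------------------------------------------------------------------------

def single_kidney_gfr(arch: KidneyArchitecture) -> Tuple[float, float]:
    """Whole-kidney GFR as ``(mL/min, L/day)``.

    GFR = total_nephrons x sum_over_classes(fraction x SNGFR); exactly
    linear in each SNGFR and in the nephron count.
    """
    nl_min = arch.total_nephrons * sum(
        c.population_fraction * c.sngfr for c in arch.nephron_classes)
    ml_min = nl_min * 1e-6
    l_day = ml_min * MINUTES_PER_DAY * 1e-3
    return ml_min, l_day


def scale_geometry(arch: KidneyArchitecture,
                   segment_selector: str | Iterable[str],
                   diameter_multiplier: float,
                   length_multiplier: float) -> KidneyArchitecture:
    """Return a copy of ``arch`` with selected segments scaled.

    ``segment_selector`` is a group name from :data:`SEGMENT_GROUPS` or an
    iterable of segment ids.  Scaling is multiplicative (scaling by *a* then
    *b* equals scaling by ``a*b``); the input architecture is unchanged.
    """
    if diameter_multiplier <= 0 or length_multiplier <= 0:
        raise InvalidParameterError("geometry multipliers must be positive")
    if isinstance(segment_selector, str):
        segment_ids = set(SEGMENT_GROUPS.get(segment_selector, (segment_selector,)))
    else:
        segment_ids = set(segment_selector)

    new = copy.deepcopy(arch)
    for chain in list(new.segments.values()) + [new.collecting_duct]:
        for seg in chain:
            if seg.segment_id in segment_ids:
                seg.inner_diameter *= diameter_multiplier
                seg.length *= length_multiplier
    return new


def merge_flows(flows: Sequence[np.ndarray],
                weights: Sequence[float]) -> np.ndarray:
    """Population-weighted sum of flow vectors at a coalescence node.

    ``flows[k]`` is the per-tubule flow vector (water + each solute) of
    stream ``k`` and ``weights[k]`` the number of tubules carrying it; the
    result is the total flow entering the merged duct population.  Exactly
    conservative: the output is the weighted sum, nothing more.
    """
    flows = [np.asarray(f, dtype=float) for f in flows]
    out = np.zeros_like(flows[0])
    for f, w in zip(flows, weights):
        out += w * f
    return out


def serialize_architecture(arch: KidneyArchitecture) -> dict:
    """Structured plain-dict form (YAML/JSON friendly)."""
    return {
        "total_nephrons": arch.total_nephrons,
        "outer_medulla_depth_cm": arch.outer_medulla_depth,
        "inner_medulla_depth_cm": arch.inner_medulla_depth,
        "nephron_classes": [
            {"id": c.id, "population_fraction": c.population_fraction,
             "sngfr_nl_min": c.sngfr, "loop_turn_depth_mm": c.loop_turn_depth}
            for c in arch.nephron_classes],
        "topology": {
            "cnt_merge_ratio": arch.topology.cnt_merge_ratio,
            "imcd_merge_schedule": [list(t) for t in arch.topology.imcd_merge_schedule]},
        "segments": {
            cid: [{"segment_id": s.segment_id, "length_cm": s.length,
                   "inner_diameter_cm": s.inner_diameter,
                   "grid_points": s.grid_points}
                  for s in chain]
            for cid, chain in list(arch.segments.items())
            + [("collecting_duct", arch.collecting_duct)]},
    }
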