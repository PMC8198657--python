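"""Parameter file handling and per-segment runtime parameter assembly.

All tunable model parameters — membrane and paracellular permeabilities,
transporter capacities and affinities, interstitial gradient, torque
sensitivity — live in one versioned YAML file shipped with the package
(``nephrosim/data/default_params.yaml``).  Nothing is hard-coded: scenarios
and calibration modify a :class:`ParameterSet` through explicit override /
scale paths of the form ``"segments.PCT.transporters.SGLT2.vmax"``.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .solutes import SOLUTES, plasma_vector

DEFAULT_PARAMS_RESOURCE = "default_params.yaml"


def _solute_vector(mapping: dict, default: float = 0.0) -> np.ndarray:
    return np.array([float(mapping.get(s, default)) for s in SOLUTES])


@dataclass
class TransporterSpec:
    """Capacity and affinities of one transporter population.

    ``vmax`` is a flux capacity per luminal membrane area (umol cm^-2 s^-1)
    for carriers and pumps; for pure channels mapped to GHK permeabilities
    (ENaC, ROMK) it is a permeability in cm/s.  Effective capacity is
    ``vmax * (1 - inhibition_fraction)``.
    """

    id: str
    vmax: float
    km: Dict[str, float] = field(default_factory=dict)
    inhibition_fraction: float = 0.0
    beta: float = 0.5  # NHE3 proton-side occupancy proxy only

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError(f"{self.id}: vmax must be >= 0")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise ValueError(f"{self.id}: inhibition fraction outside [0,1]")

    @property
    def vmax_effective(self) -> float:
        return self.vmax * (1.0 - self.inhibition_fraction)


@dataclass
class SegmentParams:
    """Runtime transport parameters for one segment of one nephron class."""

    segment_id: str
    class_id: str
    has_cell: bool
    apical_perm: np.ndarray        # cm/s, per solute
    basolateral_perm: np.ndarray
    paracellular_perm: np.ndarray
    sigma: np.ndarray              # paracellular reflection coefficients
    pf_transcell: float            # composite transcellular Pf, cm/s
    pf_para: float
    impermeant_anion: float        # mM, closes cell electroneutrality
    transporters: Dict[str, TransporterSpec]
    torque_sensitive: bool = False
    default_cell_state: Optional[np.ndarray] = None  # [c(5), Vcell, Vlum]
    # axially varying extra multiplier on the Na/K-ATPase, as a list of
    # (start_frac, end_frac, factor) windows along the segment
    pump_axial_profile: List[Tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("apical_perm", "basolateral_perm", "paracellular_perm"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{self.segment_id}: {name} must be >= 0")
        if np.any((self.sigma < 0) | (self.sigma > 1)):
            raise ValueError(f"{self.segment_id}: sigma outside [0,1]")
        if self.pf_transcell < 0 or self.pf_para < 0:
            raise ValueError(f"{self.segment_id}: Pf must be >= 0")

    def pump_multiplier_at(self, frac: float) -> float:
        m = 1.0
        for lo, hi, factor in self.pump_axial_profile:
            if lo <= frac < hi or (frac == 1.0 and hi >= 1.0):
                m *= factor
        return m


class ParameterSet:
    """A full model parameter tree with override/scale bookkeeping."""

    def __init__(self, raw: dict):
        self.raw = raw

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls) -> "ParameterSet":
        """Load the packaged canonical parameter file."""
        text = (resources.files("nephrosim") / "data" /
                DEFAULT_PARAMS_RESOURCE).read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def copy(self) -> "ParameterSet":
        return ParameterSet(copy.deepcopy(self.raw))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)

    def content_hash(self) -> str:
        """Stable hash of the parameter tree, logged for provenance."""
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- path access ------------------------------------------------------

    def _node(self, path: str, create: bool = False):
        parts = path.split(".")
        node = self.raw
        for p in parts[:-1]:
            if p not in node:
                if not create:
                    raise KeyError(path)
                node[p] = {}
            node = node[p]
        return node, parts[-1]

    def get(self, path: str):
        node, leaf = self._node(path)
        return node[leaf]

    def set(self, path: str, value) -> None:
        node, leaf = self._node(path, create=True)
        node[leaf] = value

    def scale(self, path: str, factor: float) -> None:
        """Multiply a numeric leaf in place."""
        node, leaf = self._node(path)
        node[leaf] = float(node[leaf]) * factor

    # -- convenience accessors --------------------------------------------

    @property
    def plasma(self) -> np.ndarray:
        return plasma_vector(self.raw.get("plasma", {}))

    def segment_params(self, class_id: str, segment_id: str) -> SegmentParams:
        """Assemble runtime parameters for one (class, segment) pair.

        Per-class sparse overrides under ``class_overrides.<class>.<segment>``
        are merged over the segment defaults.
        """
        seg = copy.deepcopy(self.raw["segments"][segment_id])
        overrides = (self.raw.get("class_overrides", {})
                     .get(class_id, {}).get(segment_id, {}))
        _deep_merge(seg, overrides)

        transporters = {}
        for tid, spec in seg.get("transporters", {}).items():
            transporters[tid] = TransporterSpec(
                id=tid,
                vmax=float(spec["vmax"]),
                km={k: float(v) for k, v in spec.get("km", {}).items()},
                inhibition_fraction=float(spec.get("inhibition_fraction", 0.0)),
                beta=float(spec.get("beta", 0.5)),
            )

        cell_state = None
        if seg.get("default_cell_state") is not None:
            cell_state = np.array([float(v) for v in seg["default_cell_state"]])

        return SegmentParams(
            segment_id=segment_id,
            class_id=class_id,
            has_cell=bool(seg.get("has_cell", True)),
            apical_perm=_solute_vector(seg.get("apical_perm", {})),
            basolateral_perm=_solute_vector(seg.get("basolateral_perm", {})),
            paracellular_perm=_solute_vector(seg.get("paracellular_perm", {})),
            sigma=_solute_vector(seg.get("sigma", {}), default=1.0),
            pf_transcell=float(seg.get("pf_transcell", 0.0)),
            pf_para=float(seg.get("pf_para", 0.0)),
            impermeant_anion=float(seg.get("impermeant_anion", 120.0)),
            transporters=transporters,
            torque_sensitive=bool(seg.get("torque_sensitive", False)),
            default_cell_state=cell_state,
            pump_axial_profile=[tuple(w) for w in seg.get("pump_axial_profile", [])],
        )


def _deep_merge(base: dict, overrides: dict) -> None:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_merge(base[k], v)
        else:
            base[k] = copy.deepcopy(v)
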