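"""Early-meets-late (EML) and extended early-meets-late (EEML) detection.

For every mesh edge whose two endpoints are mapped, the absolute local
activation difference is compared against a fraction of the mapped cycle
span: edges exceeding the lower fraction (default 25%) are flagged EEML
(conduction delay/block); edges exceeding the upper fraction (default
75%) are additionally flagged EML (head-meets-tail).  The comparison uses
relative activation differences only, so the flagged set is invariant
under any constant offset (or common rescaling) of the activation times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import ActivationMap, mapped_cycle_span
from .mesh import SurfaceMesh

DEFAULT_LOWER_FRACTION = 0.25
DEFAULT_UPPER_FRACTION = 0.75

KIND_EEML = "EEML"
KIND_EML = "EML"


class DegenerateMapError(ValueError):
    """Raised when the mapped span is zero and fractions are undefined."""


@dataclass
class BlockLineSet:
    """Flagged mesh edges with their activation differences.

    ``edges`` is (k, 2) vertex pairs (v0 < v1); ``dlat`` the |delta LAT| in
    ms; ``kind`` 'EEML' or 'EML' per edge.  The EML edges are a subset of
    the EEML edges whenever lower_fraction <= upper_fraction.
    """

    edges: np.ndarray
    dlat: np.ndarray
    kind: np.ndarray
    lower_fraction: float
    upper_fraction: float
    normalizer: float = field(default=np.nan)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def eml_edges(self) -> np.ndarray:
        return self.edges[self.kind == KIND_EML]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.edges}

    def eml_edge_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.eml_edges}


def detect_block_edges(
    amap: ActivationMap,
    mesh: SurfaceMesh,
    lower_fraction: float = DEFAULT_LOWER_FRACTION,
    upper_fraction: float = DEFAULT_UPPER_FRACTION,
    normalizer: str = "mapped_span",
) -> BlockLineSet:
    """Flag conduction-delay (EEML) and early-meets-late (EML) edges.

    An edge is flagged only if its |delta LAT| is strictly greater than
    fraction x normalizer; edges with an unmapped endpoint are skipped.
    ``normalizer`` is the mapped cycle span by default, or ``'tcl'`` to
    normalise by the tachycardia cycle length instead.
    """
    if not (0 < lower_fraction <= upper_fraction < 1):
        raise ValueError("need 0 < lower_fraction <= upper_fraction < 1")
    if normalizer == "mapped_span":
        norm = mapped_cycle_span(amap)
    elif normalizer == "tcl":
        norm = float(amap.tcl)
    else:
        raise ValueError("normalizer must be 'mapped_span' or 'tcl'")
    if norm == 0:
        raise DegenerateMapError("mapped span is zero; fractions are undefined")

    e = mesh.edges
    both_mapped = amap.mapped[e[:, 0]] & amap.mapped[e[:, 1]]
    ee = e[both_mapped]
    dlat = np.abs(amap.lat[ee[:, 0]] - amap.lat[ee[:, 1]])
    is_eeml = dlat > lower_fraction * norm  # strictly greater than
    is_eml = dlat > upper_fraction * norm
    kind = np.where(is_eml, KIND_EML, KIND_EEML)[is_eeml]
    return BlockLineSet(
        edges=ee[is_eeml],
        dlat=dlat[is_eeml],
        kind=kind,
        lower_fraction=float(lower_fraction),
        upper_fraction=float(upper_fraction),
        normalizer=float(norm),
    )


def offset_and_scale_check(
    amap: ActivationMap,
    mesh: SurfaceMesh,
    offset: float = 0.0,
    scale: float = 1.0,
    lower_fraction: float = DEFAULT_LOWER_FRACTION,
    upper_fraction: float = DEFAULT_UPPER_FRACTION,
) -> bool:
    """Self-test of the relative-difference property: True iff offsetting
    (and optionally rescaling) every LAT leaves both flagged edge sets
    identical."""
    base = detect_block_edges(amap, mesh, lower_fraction, upper_fraction)
    shifted = ActivationMap(lat=amap.lat * scale + offset, tcl=amap.tcl, reference_time=amap.reference_time)
    other = detect_block_edges(shifted, mesh, lower_fraction, upper_fraction)
    return base.edge_set() == other.edge_set() and base.eml_edge_set() == other.eml_edge_set()
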