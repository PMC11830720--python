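"""Central retinal vessel equivalents (CRAE, CRVE) and the AVR.

The revised Knudtson combination summarizes the calibers of the six
largest Zone B trunks of one class into a single central equivalent:
branch pairs combine as ``W = c * sqrt(W1^2 + W2^2)`` with c = 0.88 for
arterioles and c = 0.95 for venules, applied iteratively — at each round
the widths are sorted, the widest is paired with the narrowest, and an
odd middle element is carried to the next round — until one value
remains. AVR = CRAE / CRVE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .topology import VesselGraph
from .zones import ZoneAnnuli, zone_of_points

__all__ = [
    "KNUDTSON_COEFFICIENTS",
    "CaliberPanel",
    "knudtson_combine",
    "central_equivalent",
    "zone_b_trunk_widths",
    "caliber_panel",
]

#: Branch-combination coefficients of the revised Knudtson formulas.
KNUDTSON_COEFFICIENTS = {"artery": 0.88, "vein": 0.95}


@dataclass
class CaliberPanel:
    crae: Optional[float]  # µm
    crve: Optional[float]  # µm
    avr: Optional[float]
    contributing_widths: Dict[str, List[float]] = field(default_factory=dict)


def knudtson_combine(w1: float, w2: float, vessel_class: str) -> float:
    """Combine a branch pair: ``c * sqrt(w1^2 + w2^2)`` (µm).

    Symmetric in the pair — which branch is narrower never matters.
    """
    if vessel_class not in KNUDTSON_COEFFICIENTS:
        raise ValueError(f"vessel_class must be one of {sorted(KNUDTSON_COEFFICIENTS)}")
    if w1 < 0 or w2 < 0:
        raise ValueError("widths must be non-negative")
    c = KNUDTSON_COEFFICIENTS[vessel_class]
    return c * math.hypot(w1, w2)


def central_equivalent(
    widths: Sequence[float], vessel_class: str, n_use: int = 6
) -> Optional[float]:
    """Iterative pairwise reduction of the ``n_use`` largest trunk widths.

    Rounds: sort the current widths, combine widest with narrowest (then
    second-widest with second-narrowest, ...), carry the median element
    of an odd-sized round; repeat until one value remains. Returns
    ``None`` on an empty list; a single width is returned unchanged.
    """
    vals = sorted((float(w) for w in widths), reverse=True)[: int(n_use)]
    if not vals:
        return None
    current = vals
    while len(current) > 1:
        current = sorted(current)
        nxt = []
        lo, hi = 0, len(current) - 1
        while lo < hi:
            nxt.append(knudtson_combine(current[lo], current[hi], vessel_class))
            lo += 1
            hi -= 1
        if lo == hi:  # odd round: the median element is carried
            nxt.append(current[lo])
        current = nxt
    return current[0]


def zone_b_trunk_widths(graph: VesselGraph, annuli: ZoneAnnuli) -> List[float]:
    """Median per-point caliber of each segment's Zone B stretch (µm).

    The median over the in-zone points is robust to junction bulges at
    the segment ends.
    """
    out = []
    for seg in graph.segments:
        if seg.widths is None:
            continue
        labels = zone_of_points(seg.polyline, annuli)
        sel = labels == "B"
        if sel.sum() < 2:
            continue
        out.append(float(np.median(seg.widths[sel])))
    return out


def caliber_panel(
    artery_graph: VesselGraph,
    vein_graph: VesselGraph,
    annuli: ZoneAnnuli,
    n_use: int = 6,
) -> CaliberPanel:
    """CRAE/CRVE from Zone B trunk widths of each class, and their ratio.

    A class with no Zone B segment leaves its equivalent (and the AVR)
    missing.
    """
    widths_a = zone_b_trunk_widths(artery_graph, annuli)
    widths_v = zone_b_trunk_widths(vein_graph, annuli)
    crae = central_equivalent(widths_a, "artery", n_use) if widths_a else None
    crve = central_equivalent(widths_v, "vein", n_use) if widths_v else None
    avr = crae / crve if (crae and crve) else None
    return CaliberPanel(
        crae=crae,
        crve=crve,
        avr=avr,
        contributing_widths={
            "artery": sorted(widths_a, reverse=True)[:n_use],
            "vein": sorted(widths_v, reverse=True)[:n_use],
        },
    )
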