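"""Optic-disc fitting and the annular measurement zones.

The disc is reduced to an equivalent-area circle; distances are measured
from its edge in units of the disc diameter (DD). Zone A covers
(0, 0.5] DD beyond the edge, Zone B (0.5, 1] DD, Zone C (1, 2] DD.
Boundary points belong to the inner zone (intervals half-open outward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT_ZONE_RADII_DD

if TYPE_CHECKING:  # pragma: no cover
    from .topology import VesselGraph

__all__ = ["OpticDisc", "ZoneAnnuli", "fit_disc", "zone_of", "zone_of_points", "clip_to_zone"]


@dataclass(frozen=True)
class OpticDisc:
    """Fitted optic disc: centroid + equivalent-area circle diameter."""

    center: Tuple[float, float]  # (row, col) pixels
    diameter: float  # pixels

    def __post_init__(self):
        if not (self.diameter > 0):
            raise ValueError("disc diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def diameter_um(self, spacing: float) -> float:
        return self.diameter * spacing


@dataclass(frozen=True)
class ZoneAnnuli:
    """Zone edges in DD from the disc edge; defaults A 0.5, B 1, C 2."""

    disc: OpticDisc
    radii_dd: Sequence[float] = DEFAULT_ZONE_RADII_DD

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii_dd)
        if len(radii) != 3 or not (0 < radii[0] < radii[1] < radii[2]):
            raise ValueError("zone radii must be three strictly increasing positives")
        object.__setattr__(self, "radii_dd", radii)

    @property
    def outer_radius_px(self) -> float:
        """Pixel distance from disc center to the outer edge of Zone C."""
        return self.disc.radius + self.radii_dd[2] * self.disc.diameter


def fit_disc(disc_mask: np.ndarray) -> OpticDisc:
    """Fit the disc as the equivalent-area circle of the mask.

    Center is the foreground centroid; diameter is ``2*sqrt(area/pi)``,
    so an elliptical mask yields the scalar diameter of a circle with the
    same pixel area.
    """
    disc_mask = np.asarray(disc_mask, dtype=bool)
    rows, cols = np.nonzero(disc_mask)
    if rows.size == 0:
        raise ValueError("no disc: disc mask is empty")
    center = (float(rows.mean()), float(cols.mean()))
    diameter = 2.0 * math.sqrt(rows.size / math.pi)
    return OpticDisc(center=center, diameter=diameter)


def _edge_distance_dd(points: np.ndarray, annuli: ZoneAnnuli) -> np.ndarray:
    """Distance beyond the disc edge in DD units (negative inside disc)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.hypot(pts[:, 0] - annuli.disc.center[0], pts[:, 1] - annuli.disc.center[1])
    return (d - annuli.disc.radius) / annuli.disc.diameter


def zone_of_points(points: np.ndarray, annuli: ZoneAnnuli) -> np.ndarray:
    """Vectorized zone labels for an (n, 2) array of (row, col) points."""
    t = _edge_distance_dd(points, annuli)
    a, b, c = annuli.radii_dd
    labels = np.full(t.shape, "outside", dtype=object)
    labels[t <= c] = "C"
    labels[t <= b] = "B"
    labels[t <= a] = "A"
    labels[t <= 0] = "disc"
    return labels


def zone_of(point, annuli: ZoneAnnuli) -> str:
    """Zone label of one (row, col) point: disc | A | B | C | outside."""
    return str(zone_of_points(np.asarray(point, dtype=float)[None, :], annuli)[0])


def clip_to_zone(graph: "VesselGraph", annuli: ZoneAnnuli, zone: str) -> "VesselGraph":
    """Restrict a vessel graph to one zone.

    Each segment polyline is cut into its maximal runs of points lying in
    the requested zone; runs shorter than 2 points are dropped. Cut ends
    become endpoint nodes; an original node is kept (with its kind) when
    it itself lies in the zone.
    """
    from .topology import VesselGraph  # local import to avoid a cycle

    if zone not in ("disc", "A", "B", "C", "outside"):
        raise ValueError(f"unknown zone {zone!r}")

    clipped = VesselGraph(vessel_class=graph.vessel_class, spacing=graph.spacing)
    for seg in graph.segments:
        labels = zone_of_points(seg.polyline, annuli)
        inside = labels == zone
        # maximal runs of in-zone points
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            lo, hi = idx[s], idx[e]
            if hi - lo + 1 < 2:
                continue
            poly = seg.polyline[lo : hi + 1]
            widths = seg.widths[lo : hi + 1] if seg.widths is not None else None
            kinds = []
            for end_idx, node_id in ((lo, seg.node_ids[0]), (hi, seg.node_ids[1])):
                at_original = (end_idx in (0, len(seg.polyline) - 1)) and node_id is not None
                if at_original and zone_of(seg.polyline[end_idx], annuli) == zone:
                    kinds.append(graph.node_kind(node_id))
                else:
                    kinds.append("endpoint")
            clipped.add_free_segment(poly, widths, end_kinds=tuple(kinds))
    return clipped
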