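"""Branching, length, tortuosity, and density measures.

Branch and length statistics are restricted to Zone C, the annulus 1-2
disc diameters beyond the disc edge, where the measurement convention of
this pipeline places them. Tortuosity is the arc-chord ratio of a
centerline segment. Densities are foreground fractions: vessel (area)
density from the full masks, vessel length density from the centerlines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .topology import Segment, VesselGraph, polyline_length, smooth_polyline
from .zones import ZoneAnnuli, zone_of, zone_of_points

__all__ = [
    "BifurcationMeasure",
    "LengthStats",
    "bifurcation_angle",
    "bifurcation_asymmetry",
    "fit_direction",
    "direction_from_node",
    "bifurcation_measures",
    "zone_c_branch_stats",
    "segment_tortuosity",
    "zone_c_length_stats",
    "densities",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BifurcationMeasure:
    node: Tuple[float, float]
    angle: float  # degrees between daughter directions
    asymmetry: float  # percent, 0-100
    parent_width: Optional[float]  # µm
    daughter_widths: Tuple[float, float]  # µm


@dataclass(frozen=True)
class LengthStats:
    length_avg: Optional[float]  # µm
    curvature_avg: Optional[float]  # dimensionless >= 1
    n_segments: int


def bifurcation_angle(d1_dir, d2_dir, parent_dir=None) -> float:
    """Angle (degrees) between the two daughter direction vectors.

    Directions must point away from the bifurcation node. The parent
    direction is accepted for signature symmetry but does not enter the
    daughter-daughter angle.
    """
    out = []
    for v in (d1_dir, d2_dir):
        v = np.asarray(v, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("zero-length direction vector")
        out.append(v / norm)
    cosang = float(np.clip(np.dot(out[0], out[1]), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def bifurcation_asymmetry(w1: float, w2: float) -> float:
    """Squared-caliber branching asymmetry index, percent.

    ``100 * (1 - (min/max)^2)`` of the two daughter widths: 0 for equal
    daughters, approaching 100 as one daughter dominates.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError("daughter widths must be positive")
    lo, hi = sorted((float(w1), float(w2)))
    return 100.0 * (1.0 - (lo / hi) ** 2)


def fit_direction(polyline, skip_px: float = 0.0, fit_px: float = 5.0) -> np.ndarray:
    """Unit direction of a centerline leaving its first point.

    Least-squares line fit over the arc window
    ``[skip_px, skip_px + fit_px]`` of chain length, oriented away from
    the start. ``skip_px`` excludes the junction region, where the
    skeleton of two merging thick strokes bends toward the bisector; the
    same finite-arc definition applies to exact geometry and raster
    measurements alike.
    """
    poly = np.asarray(polyline, dtype=float)
    steps = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    i0 = int(np.searchsorted(cum, skip_px))
    if i0 >= len(poly) - 1:
        i0 = max(len(poly) - 2, 0)
    i1 = int(np.searchsorted(cum, cum[i0] + fit_px)) + 1
    pts = poly[i0 : max(i1, i0 + 2)]
    if len(pts) == 2:
        d = pts[1] - pts[0]
    else:
        # principal axis of the point cloud
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        if np.dot(d, pts[-1] - pts[0]) < 0:
            d = -d
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate direction fit")
    return d / norm


def direction_from_node(
    segment: Segment, fit_px: int = 5, spacing: float = 1.0, skip_px: float = 0.0
) -> np.ndarray:
    """Unit direction of a segment leaving its first node.

    The fit arc is ``max(fit_px, local width)`` so thick vessels are
    fitted over at least one caliber of centerline.
    """
    if segment.widths is not None and segment.widths.size:
        local_w_px = float(segment.widths[0]) / spacing
    else:
        local_w_px = 0.0
    return fit_direction(segment.polyline, skip_px, max(float(fit_px), local_w_px))


def _daughter_width(segment: Segment, exclusion_um: float) -> Optional[float]:
    """Median caliber of a daughter, skipping the junction bulge.

    The first ``exclusion_um`` of arc after the node sits inside the
    junction where the distance transform reflects the parent; it is
    excluded unless the segment is too short to spare it.
    """
    if segment.widths is None or segment.widths.size == 0:
        return None
    poly = segment.polyline
    steps = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    start = int(np.searchsorted(cum, exclusion_um))
    if start >= len(poly) - 1:
        start = len(poly) // 2
    return float(np.median(segment.widths[start:]))


def bifurcation_measures(
    graph: VesselGraph,
    fit_px: int = 5,
    include_crossings: bool = False,
    disc_center=None,
) -> List[BifurcationMeasure]:
    """Per-bifurcation geometry for all degree-3 nodes of a graph.

    With a disc center given, the parent is the incident segment whose
    far end lies closest to the disc (retinal trees radiate outward from
    the disc margin); otherwise the widest incident segment is taken
    (caliber conservation makes the parent the widest branch). The two
    remaining segments are the daughters. Degree-4 nodes are crossing
    suspects and skipped unless requested; degree >= 5 nodes are skipped
    with a log line.
    """
    out = []
    for node in graph.nodes:
        deg = graph.degree(node.id)
        if deg >= 5:
            logger.info("skipping degree-%d node at %s", deg, node.position)
            continue
        if node.kind == "crossing-suspect" and not include_crossings:
            continue
        if node.kind not in ("bifurcation", "crossing-suspect"):
            continue
        incident = graph.incident_segments(node.id)
        if len(incident) < 3:
            continue
        meds = [s.median_width() or 0.0 for s in incident]
        if disc_center is not None:
            far_d = [
                float(np.hypot(*(s.polyline[-1] - np.asarray(disc_center))))
                for s in incident
            ]
            parent_idx = int(np.argmin(far_d))
        else:
            parent_idx = int(np.argmax(meds))
        parent = incident[parent_idx]
        daughters = [s for i, s in enumerate(incident) if i != parent_idx]
        if len(daughters) > 2:  # degree-4 requested: use the two widest daughters
            dmeds = [s.median_width() or 0.0 for s in daughters]
            order = np.argsort(dmeds)[::-1][:2]
            daughters = [daughters[i] for i in order]
        parent_w = parent.median_width()
        excl = parent_w if parent_w is not None else 0.0
        skip_px = excl / graph.spacing
        try:
            d_dirs = []
            for s in daughters:
                w_px = (s.median_width() or 0.0) / graph.spacing
                d_dirs.append(
                    fit_direction(s.polyline, skip_px, max(float(fit_px), w_px))
                )
            angle = bifurcation_angle(*d_dirs)
        except ValueError:
            continue
        w1 = _daughter_width(daughters[0], excl)
        w2 = _daughter_width(daughters[1], excl)
        if not w1 or not w2:
            continue
        out.append(
            BifurcationMeasure(
                node=node.position,
                angle=angle,
                asymmetry=bifurcation_asymmetry(w1, w2),
                parent_width=parent_w,
                daughter_widths=(w1, w2),
            )
        )
    return out


def _is_disc_rooted(component: VesselGraph, annuli: ZoneAnnuli, root_margin_dd: float) -> bool:
    center = np.asarray(annuli.disc.center)
    limit = annuli.disc.radius + root_margin_dd * annuli.disc.diameter
    for seg in component.segments:
        d = np.hypot(*(seg.polyline - center).T)
        if d.min() <= limit:
            return True
    return False


def _reaches_zone_c(component: VesselGraph, annuli: ZoneAnnuli) -> bool:
    center = np.asarray(annuli.disc.center)
    inner = annuli.disc.radius + annuli.radii_dd[1] * annuli.disc.diameter
    for seg in component.segments:
        d = np.hypot(*(seg.polyline - center).T)
        if d.max() > inner:
            return True
    return False


def zone_c_branch_stats(
    graph: VesselGraph,
    annuli: ZoneAnnuli,
    fit_px: int = 5,
    include_crossings: bool = False,
    branch_avg_mode: str = "per_tree",
    root_margin_dd: float = 0.25,
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """(angle_avg, asymmetry_avg, branch_avg) over Zone C bifurcations.

    angle_avg and asymmetry_avg are arithmetic means over all accepted
    bifurcations whose node lies in Zone C. branch_avg is, by default,
    the mean count of Zone C bifurcations per disc-rooted connected tree
    that reaches Zone C ('per_tree'); 'total' reports the whole-image
    count instead. All three are ``None`` when Zone C holds no
    bifurcation, mirroring the blank-cell convention of the output table.
    """
    all_measures = []
    per_tree_counts = []
    for comp in graph.component_subgraphs():
        measures = bifurcation_measures(
            comp, fit_px, include_crossings, disc_center=annuli.disc.center
        )
        in_c = [m for m in measures if zone_of(m.node, annuli) == "C"]
        all_measures.extend(in_c)
        if _is_disc_rooted(comp, annuli, root_margin_dd) and _reaches_zone_c(comp, annuli):
            per_tree_counts.append(len(in_c))
    if not all_measures:
        return None, None, None
    angle_avg = float(np.mean([m.angle for m in all_measures]))
    asymmetry_avg = float(np.mean([m.asymmetry for m in all_measures]))
    if branch_avg_mode == "total":
        branch_avg = float(len(all_measures))
    else:
        branch_avg = float(np.mean(per_tree_counts)) if per_tree_counts else float(len(all_measures))
    return angle_avg, asymmetry_avg, branch_avg


def segment_tortuosity(polyline, smooth_window: int = 1) -> Optional[float]:
    """Arc-chord tortuosity of a centerline polyline.

    Ratio of the integrated centerline length to the straight-line
    distance between the endpoints; 1 for a straight vessel, larger for
    more tortuous ones. Returns ``None`` (with a warning) for closed
    polylines, whose chord is zero.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or len(poly) < 2:
        raise ValueError("polyline needs at least 2 points")
    chord = float(np.hypot(*(poly[-1] - poly[0])))
    arc = polyline_length(smooth_polyline(poly, smooth_window))
    if chord <= max(1e-9, 1e-6 * arc):  # closed (or numerically closed) loop
        logger.warning("coincident endpoints: tortuosity undefined")
        return None
    return max(arc / chord, 1.0)


def zone_c_segments(graph: VesselGraph, annuli: ZoneAnnuli) -> List[np.ndarray]:
    """Maximal Zone C sub-polylines (>= 2 points) of every segment."""
    out = []
    for seg in graph.segments:
        labels = zone_of_points(seg.polyline, annuli)
        idx = np.flatnonzero(labels == "C")
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            lo, hi = idx[s], idx[e]
            if hi - lo + 1 >= 2:
                out.append(seg.polyline[lo : hi + 1])
    return out


def zone_c_length_stats(
    graph: VesselGraph,
    annuli: ZoneAnnuli,
    spacing: float,
    smooth_window: int = 1,
) -> LengthStats:
    """Mean length (µm) and mean tortuosity of Zone C centerline segments."""
    polys = zone_c_segments(graph, annuli)
    if not polys:
        return LengthStats(None, None, 0)
    lengths = [polyline_length(smooth_polyline(p, smooth_window)) * spacing for p in polys]
    torts = [segment_tortuosity(p, smooth_window) for p in polys]
    torts = [t for t in torts if t is not None]
    return LengthStats(
        length_avg=float(np.mean(lengths)),
        curvature_avg=float(np.mean(torts)) if torts else None,
        n_segments=len(polys),
    )


def densities(
    artery_mask: np.ndarray,
    vein_mask: np.ndarray,
    artery_skeleton: np.ndarray,
    vein_skeleton: np.ndarray,
    annuli: Optional[ZoneAnnuli] = None,
    region: str = "image",
) -> Tuple[float, float]:
    """(vessel_length_density, vessel_density) over the analysis region.

    vessel_density is the foreground fraction of the artery|vein union
    mask; vessel_length_density the fraction occupied by the union of the
    centerlines. ``region='image'`` uses the whole raster; ``'2dd'``
    restricts to the disk reaching 2 DD beyond the disc edge (requires
    ``annuli``).
    """
    vessel = np.asarray(artery_mask, dtype=bool) | np.asarray(vein_mask, dtype=bool)
    skel = np.asarray(artery_skeleton, dtype=bool) | np.asarray(vein_skeleton, dtype=bool)
    if vessel.shape != skel.shape:
        raise ValueError("masks and skeletons must share one shape")
    if region == "2dd":
        if annuli is None:
            raise ValueError("region='2dd' requires zone annuli")
        rr, cc = np.mgrid[0 : vessel.shape[0], 0 : vessel.shape[1]]
        d = np.hypot(rr - annuli.disc.center[0], cc - annuli.disc.center[1])
        sel = d <= annuli.outer_radius_px
    else:
        sel = np.ones(vessel.shape, dtype=bool)
    denom = int(sel.sum())
    if denom == 0:
        raise ValueError("empty analysis region")
    vessel_density = float(vessel[sel].sum()) / denom
    vessel_length_density = float(skel[sel].sum()) / denom
    return vessel_length_density, vessel_density
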