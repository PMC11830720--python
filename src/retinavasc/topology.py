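"""Vessel mask -> centerline graph.

The binary mask of one vessel class is thinned to a one-pixel skeleton;
skeleton pixels with one 8-neighbor become endpoints and pixels with
three or more become junction pixels. Adjacent junction pixels are merged
into a single node, and junction nodes closer than a width-scaled
threshold are merged again, because the skeleton of a thick vessel smears
one anatomical bifurcation over several pixels. Degree-4 nodes are
flagged as crossing suspects (artery/vein crossings project onto each
other in a fundus photograph) rather than counted as bifurcations.

Per-point vessel width is the classical caliber proxy: twice the
Euclidean distance transform of the mask sampled on the centerline,
scaled to µm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "Node",
    "Segment",
    "VesselGraph",
    "skeletonize",
    "extract_graph",
    "prune_spurs",
    "smooth_polyline",
    "polyline_length",
]

logger = logging.getLogger(__name__)

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Node:
    id: int
    position: Tuple[float, float]  # (row, col)
    kind: str  # endpoint | bifurcation | crossing-suspect | through | cycle


@dataclass
class Segment:
    """Centerline polyline between two nodes (or a flagged cycle)."""

    polyline: np.ndarray  # (n, 2) float pixel coords
    widths: Optional[np.ndarray]  # per-point caliber, µm
    vessel_class: str
    node_ids: Tuple[Optional[int], Optional[int]]  # ids at polyline[0], polyline[-1]
    is_cycle: bool = False

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise ValueError("polyline needs at least 2 points")
        if self.widths is not None:
            self.widths = np.asarray(self.widths, dtype=float)
            if self.widths.shape[0] != self.polyline.shape[0]:
                raise ValueError("widths must match polyline length")

    @property
    def length_px(self) -> float:
        return polyline_length(self.polyline)

    def arc_length_um(self, spacing: float, smooth_window: int = 1) -> float:
        poly = smooth_polyline(self.polyline, smooth_window)
        return polyline_length(poly) * spacing

    def median_width(self) -> Optional[float]:
        if self.widths is None or self.widths.size == 0:
            return None
        return float(np.median(self.widths))

    def reversed(self) -> "Segment":
        widths = None if self.widths is None else self.widths[::-1].copy()
        return Segment(
            self.polyline[::-1].copy(),
            widths,
            self.vessel_class,
            (self.node_ids[1], self.node_ids[0]),
            self.is_cycle,
        )


def polyline_length(polyline: np.ndarray) -> float:
    """Euclidean chain length of an ordered point sequence (pixels)."""
    poly = np.asarray(polyline, dtype=float)
    if len(poly) < 2:
        return 0.0
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


def smooth_polyline(polyline: np.ndarray, window: int) -> np.ndarray:
    """Endpoint-preserving moving average along a polyline.

    Digital centerlines follow pixel staircases, which inflates chain
    length (up to ~8% on oblique straight lines); a short moving average
    removes the staircase while keeping the endpoints fixed so chord
    lengths are untouched. Near the ends the window shrinks symmetrically.
    """
    poly = np.asarray(polyline, dtype=float)
    n = len(poly)
    if window <= 1 or n < 3:
        return poly
    half = window // 2
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(poly, axis=0)])
    out = poly.copy()
    for i in range(1, n - 1):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


class VesselGraph:
    """Centerline graph of one vessel class (multigraph of segments)."""

    def __init__(self, vessel_class: str = "vessel", spacing: float = 1.0):
        self.vessel_class = vessel_class
        self.spacing = float(spacing)
        self._g = nx.MultiGraph()
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_node(self, position, kind: str = "endpoint") -> int:
        nid = self._next_id
        self._next_id += 1
        self._g.add_node(nid, position=(float(position[0]), float(position[1])), kind=kind)
        return nid

    def add_segment(self, u: int, v: int, polyline, widths=None, is_cycle: bool = False) -> None:
        seg = Segment(polyline, widths, self.vessel_class, (u, v), is_cycle)
        self._g.add_edge(u, v, segment=seg)

    def add_free_segment(self, polyline, widths=None, end_kinds=("endpoint", "endpoint")) -> None:
        poly = np.asarray(polyline, dtype=float)
        u = self.add_node(poly[0], end_kinds[0])
        v = self.add_node(poly[-1], end_kinds[1])
        self.add_segment(u, v, poly, widths)

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> List[Node]:
        return [
            Node(nid, data["position"], data["kind"])
            for nid, data in self._g.nodes(data=True)
        ]

    @property
    def segments(self) -> List[Segment]:
        return [data["segment"] for _, _, data in self._g.edges(data=True)]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_segments(self) -> int:
        return self._g.number_of_edges()

    def degree(self, nid: int) -> int:
        return self._g.degree(nid)

    def node_kind(self, nid: int) -> str:
        return self._g.nodes[nid]["kind"]

    def node_position(self, nid: int) -> Tuple[float, float]:
        return self._g.nodes[nid]["position"]

    def incident_segments(self, nid: int) -> List[Segment]:
        """Segments at a node, each oriented to start at that node."""
        out = []
        for u, v, data in self._g.edges(nid, data=True):
            seg = data["segment"]
            out.append(seg if seg.node_ids[0] == nid else seg.reversed())
        return out

    def bifurcation_nodes(self, include_crossings: bool = False) -> List[Node]:
        kinds = {"bifurcation"} | ({"crossing-suspect"} if include_crossings else set())
        return [n for n in self.nodes if n.kind in kinds]

    def component_subgraphs(self) -> List["VesselGraph"]:
        out = []
        for comp in nx.connected_components(self._g):
            sub = VesselGraph(self.vessel_class, self.spacing)
            sub._g = self._g.subgraph(comp).copy()
            sub._next_id = self._next_id
            out.append(sub)
        return out

    def copy(self) -> "VesselGraph":
        g = VesselGraph(self.vessel_class, self.spacing)
        g._g = self._g.copy()
        g._next_id = self._next_id
        return g

    def total_length_um(self, smooth_window: int = 1) -> float:
        return sum(s.arc_length_um(self.spacing, smooth_window) for s in self.segments)

    # -- maintenance ---------------------------------------------------
    @staticmethod
    def _kind_for_degree(degree: int, self_loop: bool = False) -> str:
        if self_loop:
            return "cycle"
        if degree <= 1:
            return "endpoint"
        if degree == 2:
            return "through"
        if degree == 3:
            return "bifurcation"
        return "crossing-suspect"

    def recompute_kinds(self) -> None:
        for nid in self._g.nodes:
            self_loop = self._g.has_edge(nid, nid)
            self._g.nodes[nid]["kind"] = self._kind_for_degree(
                self._g.degree(nid), self_loop
            )

    def splice_through_nodes(self) -> None:
        """Remove degree-2 nodes by concatenating their two segments."""
        changed = True
        while changed:
            changed = False
            for nid in list(self._g.nodes):
                if self._g.degree(nid) != 2 or self._g.has_edge(nid, nid):
                    continue
                edges = list(self._g.edges(nid, keys=True, data=True))
                if len(edges) != 2:
                    continue  # parallel pair forming a loop; leave as is
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                s1 = d1["segment"] if d1["segment"].node_ids[1] == nid else d1["segment"].reversed()
                s2 = d2["segment"] if d2["segment"].node_ids[0] == nid else d2["segment"].reversed()
                far1 = s1.node_ids[0]
                far2 = s2.node_ids[1]
                poly = np.vstack([s1.polyline, s2.polyline[1:]])
                widths = None
                if s1.widths is not None and s2.widths is not None:
                    widths = np.concatenate([s1.widths, s2.widths[1:]])
                self._g.remove_node(nid)
                if far1 == far2:
                    seg = Segment(poly, widths, self.vessel_class, (far1, far2), is_cycle=True)
                else:
                    seg = Segment(poly, widths, self.vessel_class, (far1, far2))
                self._g.add_edge(far1, far2, segment=seg)
                changed = True
                break
        self.recompute_kinds()

    def merge_junction_pair(self, u: int, v: int) -> None:
        """Contract the edge between two junction nodes into one node."""
        pos_u = np.asarray(self._g.nodes[u]["position"])
        pos_v = np.asarray(self._g.nodes[v]["position"])
        new_pos = tuple((pos_u + pos_v) / 2.0)
        # drop all parallel connecting segments, reattach the rest
        while self._g.has_edge(u, v):
            self._g.remove_edge(u, v)
        for _, w, key, data in list(self._g.edges(v, keys=True, data=True)):
            seg = data["segment"]
            a, b = seg.node_ids
            seg.node_ids = (u if a == v else a, u if b == v else b)
            self._g.remove_edge(v, w, key)
            target = u if w == v else w
            self._g.add_edge(u, target, segment=seg)
        self._g.remove_node(v)
        self._g.nodes[u]["position"] = new_pos
        # close the geometric gap the removed bridge leaves: extend every
        # incident polyline to the merged node position
        new_pt = np.asarray(new_pos)
        for _, _, data in self._g.edges(u, data=True):
            seg = data["segment"]
            if seg.node_ids[0] == u and not np.allclose(seg.polyline[0], new_pt):
                seg.polyline = np.vstack([new_pt, seg.polyline])
                if seg.widths is not None:
                    seg.widths = np.concatenate([seg.widths[:1], seg.widths])
            if seg.node_ids[1] == u and not np.allclose(seg.polyline[-1], new_pt):
                seg.polyline = np.vstack([seg.polyline, new_pt])
                if seg.widths is not None:
                    seg.widths = np.concatenate([seg.widths, seg.widths[-1:]])

    def drop_artifact_loops(self, merge_factor: float) -> None:
        """Remove tiny cycles the thinning step leaves at junctions.

        A self-loop, or the shorter of two parallel segments between one
        node pair, is an artifact when its arc is below ``merge_factor``
        x the local vessel width.
        """
        def local_width_px(nid: int) -> float:
            ws = [
                float(np.max(d["segment"].widths))
                for _, _, d in self._g.edges(nid, data=True)
                if d["segment"].widths is not None and d["segment"].widths.size
            ]
            return (max(ws) / self.spacing) if ws else 2.0

        changed = True
        while changed:
            changed = False
            for u, v, key, data in list(self._g.edges(keys=True, data=True)):
                seg = data["segment"]
                threshold = merge_factor * max(local_width_px(u), 2.0)
                if u == v and seg.length_px < threshold:
                    self._g.remove_edge(u, v, key)
                    changed = True
                    break
                if u != v and self._g.number_of_edges(u, v) >= 2:
                    parallel = sorted(
                        self._g.get_edge_data(u, v).items(),
                        key=lambda kv: kv[1]["segment"].length_px,
                    )
                    if parallel[0][1]["segment"].length_px < threshold:
                        self._g.remove_edge(u, v, parallel[0][0])
                        changed = True
                        break
        self.recompute_kinds()

    def merge_close_junctions(self, merge_factor: float) -> None:
        """Merge junction nodes linked by a bridge shorter than
        ``merge_factor`` x the local vessel width (in pixels)."""
        changed = True
        while changed:
            changed = False
            for nu, nv, key, data in list(self._g.edges(keys=True, data=True)):
                if nu == nv:
                    continue
                if self._g.degree(nu) < 3 or self._g.degree(nv) < 3:
                    continue
                seg = data["segment"]
                if seg.widths is not None and seg.widths.size:
                    local_w_px = float(np.max(seg.widths)) / self.spacing
                else:
                    local_w_px = 2.0
                if seg.length_px < merge_factor * max(local_w_px, 2.0):
                    self.merge_junction_pair(nu, nv)
                    changed = True
                    break
        self.recompute_kinds()


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a binary mask to 1-px centerlines."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _skimage_skeletonize(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    counts = ndi.convolve(skel.astype(int), kernel, mode="constant")
    return counts * skel


def extract_graph(
    skeleton: np.ndarray,
    mask: np.ndarray,
    spacing: float,
    vessel_class: str = "vessel",
    junction_merge_factor: float = 1.5,
) -> VesselGraph:
    """Trace a one-pixel skeleton into a node/segment graph.

    Widths are attached to every polyline point as
    ``2 * EDT(mask) * spacing`` (µm). Isolated skeleton pixels are
    dropped. Junction-pixel clusters collapse to centroid nodes and
    near-coincident junctions are merged width-aware; remaining degree-2
    nodes are spliced away.
    """
    skel = np.asarray(skeleton, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    graph = VesselGraph(vessel_class, spacing)
    if not skel.any():
        return graph

    counts = _neighbor_counts(skel)
    isolated = skel & (counts == 0)
    n_isolated = int(isolated.sum())
    if n_isolated:
        logger.info("dropping %d isolated skeleton pixel(s)", n_isolated)
        skel = skel & ~isolated
        if not skel.any():
            return graph
        counts = _neighbor_counts(skel)

    # caliber proxy: twice the distance transform at the centerline. The
    # EDT runs on a 2x-upsampled mask to halve the lattice quantization
    # of distances, and is ridge-sampled with a local maximum because the
    # thinned centerline can sit slightly off the medial axis.
    up = np.repeat(np.repeat(mask, 2, axis=0), 2, axis=1)
    edt = ndi.maximum_filter(ndi.distance_transform_edt(up) / 2.0, size=3)

    def widths_for(path_pixels: np.ndarray) -> np.ndarray:
        rr = np.clip(path_pixels[:, 0].astype(int), 0, mask.shape[0] - 1)
        cc = np.clip(path_pixels[:, 1].astype(int), 0, mask.shape[1] - 1)
        return np.maximum(2.0 * edt[2 * rr, 2 * cc], 1.0) * spacing

    node_pixel = skel & ((counts == 1) | (counts >= 3))
    labels, n_clusters = ndi.label(node_pixel, structure=np.ones((3, 3), dtype=int))
    cluster_of = {}  # pixel -> cluster label
    node_of_cluster = {}
    if n_clusters:
        rs, cs = np.nonzero(labels)
        for r, c in zip(rs, cs):
            cluster_of[(int(r), int(c))] = int(labels[r, c])
        for lab in range(1, n_clusters + 1):
            pix = np.argwhere(labels == lab)
            node_of_cluster[lab] = graph.add_node(pix.mean(axis=0), kind="endpoint")

    skel_set = set(map(tuple, np.argwhere(skel)))
    visited = set()  # regular pixels already traced
    done_pairs = set()  # direct cluster-to-cluster adjacencies already added

    def neighbors(p):
        r, c = p
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in skel_set:
                yield q

    # trace outward from every node pixel
    for start in sorted(cluster_of):
        lab0 = cluster_of[start]
        for q in neighbors(start):
            if q in cluster_of:
                lab1 = cluster_of[q]
                if lab1 == lab0:
                    continue
                pair = frozenset((start, q))
                if pair in done_pairs:
                    continue
                done_pairs.add(pair)
                poly = np.array([start, q], dtype=float)
                graph.add_segment(
                    node_of_cluster[lab0], node_of_cluster[lab1], poly, widths_for(poly)
                )
                continue
            if q in visited:
                continue
            # walk through regular pixels until the next node pixel
            path = [start, q]
            visited.add(q)
            prev, cur = start, q
            end_cluster = None
            while True:
                nxts = [
                    p for p in neighbors(cur) if p != prev and not (
                        p in cluster_of and cluster_of[p] == cluster_of.get(prev, -2)
                    )
                ]
                node_nxts = [p for p in nxts if p in cluster_of]
                reg_nxts = [p for p in nxts if p not in cluster_of and p not in visited]
                if node_nxts:
                    end = node_nxts[0]
                    path.append(end)
                    end_cluster = cluster_of[end]
                    break
                if not reg_nxts:
                    # dead end without a node pixel (should not happen on a
                    # proper skeleton); close the path here
                    break
                prev, cur = cur, reg_nxts[0]
                path.append(cur)
                visited.add(cur)
            poly = np.array(path, dtype=float)
            if end_cluster is None:
                end_node = graph.add_node(poly[-1], kind="endpoint")
            else:
                end_node = node_of_cluster[end_cluster]
            graph.add_segment(node_of_cluster[lab0], end_node, poly, widths_for(poly))

    # leftover regular pixels form node-free cycles
    remaining = [p for p in skel_set if p not in cluster_of and p not in visited]
    remaining_set = set(remaining)
    while remaining_set:
        start = min(remaining_set)
        path = [start]
        remaining_set.discard(start)
        prev, cur = None, start
        while True:
            nxts = [p for p in neighbors(cur) if p != prev and p in remaining_set]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            path.append(cur)
            remaining_set.discard(cur)
        path.append(start)  # close the loop
        poly = np.array(path, dtype=float)
        if len(poly) >= 3:
            nid = graph.add_node(poly[0], kind="cycle")
            graph.add_segment(nid, nid, poly, widths_for(poly), is_cycle=True)
            logger.info("traced a node-free cycle of %d pixels", len(path) - 1)

    graph.recompute_kinds()
    graph.drop_artifact_loops(junction_merge_factor)
    graph.merge_close_junctions(junction_merge_factor)
    graph.splice_through_nodes()
    return graph


def prune_spurs(
    graph: VesselGraph,
    min_length_um: Optional[float] = None,
    spur_factor: float = 3.0,
) -> VesselGraph:
    """Remove terminal skeleton spurs.

    A terminal segment (at least one endpoint of degree 1) is dropped when
    shorter than ``min_length_um``; when no explicit length is given the
    threshold is ``spur_factor`` x the local vessel width, since thinning
    artifacts scale with caliber. Idempotent.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for u, v, key, data in list(g._g.edges(keys=True, data=True)):
            if u == v:
                continue
            deg_u, deg_v = g._g.degree(u), g._g.degree(v)
            if deg_u != 1 and deg_v != 1:
                continue
            seg = data["segment"]
            length = seg.length_px * g.spacing
            if min_length_um is not None:
                threshold = min_length_um
            else:
                if seg.widths is not None and seg.widths.size:
                    threshold = spur_factor * float(np.median(seg.widths))
                else:
                    threshold = spur_factor * g.spacing
            # only prune spurs hanging off a junction, or floating short paths
            attached_to_junction = deg_u >= 3 or deg_v >= 3
            floating = deg_u == 1 and deg_v == 1
            if length < threshold and (attached_to_junction or floating):
                g._g.remove_edge(u, v, key)
                for nid in (u, v):
                    if g._g.degree(nid) == 0:
                        g._g.remove_node(nid)
                changed = True
                break
    g.recompute_kinds()
    g.splice_through_nodes()
    return g
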