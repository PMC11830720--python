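"""End-to-end measurement: segmentation map -> morphometry record."""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np

from . import caliber as _caliber
from . import fractal as _fractal
from . import morphometry as _morph
from . import topology as _topo
from .config import RunConfig
from .io import MorphometryRecord, SegmentationMap, validate_quality
from .zones import ZoneAnnuli, fit_disc

__all__ = ["measure_map", "build_graphs"]

logger = logging.getLogger(__name__)


def build_graphs(
    segmap: SegmentationMap, config: RunConfig
) -> Tuple[Dict[str, _topo.VesselGraph], Dict[str, np.ndarray]]:
    """Skeletonize both vessel classes and extract pruned centerline graphs."""
    graphs, skeletons = {}, {}
    for cls, mask in (("artery", segmap.artery_mask), ("vein", segmap.vein_mask)):
        skel = _topo.skeletonize(mask)
        graph = _topo.extract_graph(
            skel,
            mask,
            segmap.pixel_spacing,
            vessel_class=cls,
            junction_merge_factor=config.junction_merge_factor,
        )
        graph = _topo.prune_spurs(graph, spur_factor=config.spur_factor)
        graphs[cls] = graph
        skeletons[cls] = skel
    return graphs, skeletons


def measure_map(segmap: SegmentationMap, config: RunConfig) -> MorphometryRecord:
    """Compute the full parameter panel of one eye.

    Zone-restricted branch/length statistics, box-counting fractal
    spectra of the two centerline images, densities, and the Knudtson
    caliber panel; parameters whose measurement zone is empty stay
    missing (blank in the CSV).
    """
    for w in validate_quality(segmap, config.min_vessel_fraction):
        logger.warning("%s: %s", segmap.source_id, w)

    disc = fit_disc(segmap.disc_mask)
    annuli = ZoneAnnuli(disc, config.zone_radii_dd)
    graphs, skeletons = build_graphs(segmap, config)

    values: dict = {"source_id": segmap.source_id}

    for cls, suffix in (("artery", "_a"), ("vein", "_v")):
        graph = graphs[cls]
        angle, asym, branch = _morph.zone_c_branch_stats(
            graph,
            annuli,
            fit_px=config.direction_fit_px,
            include_crossings=config.count_crossings_as_bifurcations,
            branch_avg_mode=config.branch_avg_mode,
            root_margin_dd=config.root_margin_dd,
        )
        values[f"angle_avg{suffix}"] = angle
        values[f"asymmetry_avg{suffix}"] = asym
        values[f"branch_avg{suffix}"] = branch
        lstats = _morph.zone_c_length_stats(
            graph, annuli, segmap.pixel_spacing, config.smooth_window_px
        )
        values[f"length_avg{suffix}"] = lstats.length_avg
        values[f"curvature_avg{suffix}"] = lstats.curvature_avg

    vld, vd = _morph.densities(
        segmap.artery_mask,
        segmap.vein_mask,
        skeletons["artery"],
        skeletons["vein"],
        annuli=annuli,
        region=config.density_region,
    )
    values["vessel_length_density"] = vld
    values["vessel_density"] = vd

    spectra = _fractal.fractal_panel(
        skeletons["artery"],
        skeletons["vein"],
        sizes=config.box_sizes,
        q_values=np.arange(config.q_min, config.q_max + 1e-9, config.q_step),
        r2_floor=config.r2_floor,
    )
    values.update(spectra["artery"].as_dict("_a"))
    values.update(spectra["vein"].as_dict("_v"))

    panel = _caliber.caliber_panel(
        graphs["artery"], graphs["vein"], annuli, n_use=config.knudtson_n
    )
    values["crae"] = panel.crae
    values["crve"] = panel.crve
    values["avr"] = panel.avr

    return MorphometryRecord(**values)
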