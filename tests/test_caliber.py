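import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinavasc import simulate as sim
from retinavasc.caliber import (
    KNUDTSON_COEFFICIENTS,
    caliber_panel,
    central_equivalent,
    knudtson_combine,
)
from retinavasc.topology import extract_graph, prune_spurs, skeletonize


def brute_force_equivalent(widths, vessel_class, n_use=6):
    """Independent reimplementation of the iterative pairing protocol:
    keep the n_use largest, then repeatedly sort ascending, combine the
    extremes pairwise, carry the odd middle element."""
    c = {"artery": 0.88, "vein": 0.95}[vessel_class]
    vals = sorted(widths)[-n_use:]
    while len(vals) > 1:
        vals = sorted(vals)
        out = []
        while len(vals) >= 2:
            lo = vals.pop(0)
            hi = vals.pop(-1)
            out.append(c * math.sqrt(lo**2 + hi**2))
        out.extend(vals)  # odd middle carried unchanged
        vals = out
    return vals[0]


class TestKnudtsonCombine:
    @pytest.mark.parametrize(
        "w1, w2, cls, expected",
        [
            (1.0, 1.0, "artery", 0.88 * math.sqrt(2)),
            (3.0, 4.0, "vein", 0.95 * 5.0),
            (0.0, 0.0, "artery", 0.0),
            (0.0, 0.0, "vein", 0.0),
        ],
    )
    def test_printed_formula(self, w1, w2, cls, expected):
        assert knudtson_combine(w1, w2, cls) == pytest.approx(expected, abs=1e-12)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            knudtson_combine(-1.0, 2.0, "artery")

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            knudtson_combine(1.0, 1.0, "capillary")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        w1=st.floats(0.0, 400.0),
        w2=st.floats(0.0, 400.0),
        cls=st.sampled_from(["artery", "vein"]),
    )
    def test_symmetry(self, w1, w2, cls):
        assert knudtson_combine(w1, w2, cls) == knudtson_combine(w2, w1, cls)


class TestCentralEquivalent:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        widths=st.lists(st.floats(20.0, 300.0), min_size=1, max_size=12),
        cls=st.sampled_from(["artery", "vein"]),
    )
    def test_matches_brute_force_pairing(self, widths, cls):
        assert central_equivalent(widths, cls) == pytest.approx(
            brute_force_equivalent(widths, cls), rel=1e-12
        )

    def test_single_width_identity(self):
        assert central_equivalent([123.4], "vein") == 123.4

    def test_empty_missing(self):
        assert central_equivalent([], "artery") is None

    def test_only_six_largest_used(self):
        widths = [200, 190, 180, 170, 160, 150, 10, 5]
        assert central_equivalent(widths, "artery") == pytest.approx(
            central_equivalent(widths[:6], "artery"), rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        widths=st.lists(st.floats(20.0, 300.0), min_size=1, max_size=6),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_equivariance(self, widths, k):
        base = central_equivalent(widths, "vein")
        scaled = central_equivalent([k * w for w in widths], "vein")
        assert scaled == pytest.approx(k * base, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        widths=st.lists(st.floats(20.0, 300.0), min_size=2, max_size=6),
        idx=st.integers(0, 5),
        bump=st.floats(0.1, 50.0),
    )
    def test_monotone_in_each_width(self, widths, idx, bump):
        idx = idx % len(widths)
        bigger = list(widths)
        bigger[idx] += bump
        assert central_equivalent(bigger, "artery") >= central_equivalent(
            widths, "artery"
        ) - 1e-9


def _six_vessel_image(widths_a, widths_v, geom):
    center = np.asarray(geom.center)
    masks = {}
    for cls, widths, offset in (("artery", widths_a, 0.0), ("vein", widths_v, 0.5)):
        m = np.zeros((geom.canvas_px, geom.canvas_px), bool)
        for k, w in enumerate(widths):
            az = 2 * math.pi * (k + offset) / len(widths)
            d = np.array([math.cos(az), math.sin(az)])
            t = np.linspace(geom.disc_radius_px * 0.9, 3.4 * geom.disc_radius_px, 600)
            poly = center + t[:, None] * d[None, :]
            sim._stamp_polyline(m, poly, w / geom.pixel_spacing_um / 2)
        masks[cls] = m
    return masks


class TestCaliberPanel:
    def test_crae_recovers_known_widths(self, sim_geometry):
        widths_a = [100, 95, 90, 85, 105, 98]
        widths_v = [130, 140, 125, 135, 128, 122]
        masks = _six_vessel_image(widths_a, widths_v, sim_geometry)
        graphs = {}
        for cls in masks:
            g = extract_graph(
                skeletonize(masks[cls]),
                masks[cls],
                sim_geometry.pixel_spacing_um,
                vessel_class=cls,
            )
            graphs[cls] = prune_spurs(g)
        panel = caliber_panel(graphs["artery"], graphs["vein"], sim_geometry.annuli())
        assert panel.crae == pytest.approx(
            brute_force_equivalent(widths_a, "artery"), rel=0.10
        )
        assert panel.crve == pytest.approx(
            brute_force_equivalent(widths_v, "vein"), rel=0.10
        )
        assert panel.avr == pytest.approx(panel.crae / panel.crve, rel=1e-12)

    def test_identical_geometry_avr_below_one(self, sim_geometry):
        widths = [110, 105, 100, 95, 115, 108]
        masks = _six_vessel_image(widths, widths, sim_geometry)
        # use the artery mask for both classes: identical geometry
        g = extract_graph(
            skeletonize(masks["artery"]),
            masks["artery"],
            sim_geometry.pixel_spacing_um,
        )
        g = prune_spurs(g)
        panel = caliber_panel(g, g, sim_geometry.annuli())
        assert panel.avr < 1.0
        # the ratio of the 0.88- and 0.95-coefficient reductions is nearly
        # width-independent; compare against the brute-force pairing oracle
        expected = brute_force_equivalent(widths, "artery") / brute_force_equivalent(
            widths, "vein"
        )
        assert panel.avr == pytest.approx(expected, abs=0.02)

    def test_missing_class_missing_values(self, sim_geometry):
        widths = [110, 105, 100, 95, 115, 108]
        masks = _six_vessel_image(widths, widths, sim_geometry)
        g = extract_graph(
            skeletonize(masks["artery"]),
            masks["artery"],
            sim_geometry.pixel_spacing_um,
        )
        empty = extract_graph(
            np.zeros_like(masks["artery"]),
            np.zeros_like(masks["artery"]),
            sim_geometry.pixel_spacing_um,
        )
        panel = caliber_panel(g, empty, sim_geometry.annuli())
        assert panel.crae is not None
        assert panel.crve is None and panel.avr is None
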