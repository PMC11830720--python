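"""Run-wide configuration.

Every numeric choice in the pipeline that is not dictated by the
measurement definitions themselves (zone radii, coefficients) lives here,
so a run can be reproduced from the resolved config file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: Zone edges in disc-diameter units measured from the disc EDGE:
#: Zone A (0, 0.5], Zone B (0.5, 1], Zone C (1, 2].
DEFAULT_ZONE_RADII_DD = (0.5, 1.0, 2.0)


@dataclass
class RunConfig:
    """Configuration for a measurement run.

    Attributes
    ----------
    pixel_spacing_um:
        Physical size of one pixel in micrometers. Mandatory for any
        measurement; there is no meaningful default because it depends on
        the camera/eye pairing.
    rgb_tolerance:
        Maximum Chebyshev distance (0-255) between a pixel and a pure
        channel color for the RGB input dialect (red=artery, blue=vein,
        yellow=disc).
    min_vessel_fraction:
        Quality floor: a warning is issued when the vessel foreground
        fraction of the image falls below this.
    zone_radii_dd:
        Outer edges of zones A, B, C in disc diameters from the disc edge.
    spur_factor:
        Terminal skeleton branches shorter than ``spur_factor`` x local
        width are treated as skeletonization artifacts and pruned.
    junction_merge_factor:
        Junction nodes closer than this multiple of the local vessel width
        are merged into one bifurcation (thick vessels smear one junction
        over several skeleton pixels).
    smooth_window_px:
        Moving-average window (pixels, odd) applied to centerline
        polylines before arc-length and tortuosity evaluation; corrects
        the stair-step overestimate of digital path length.
    direction_fit_px:
        Minimum arc (pixels) over which a daughter direction is fitted at
        a bifurcation; the actual arc is max(direction_fit_px, local width).
    count_crossings_as_bifurcations:
        Degree-4 nodes are artery/vein crossing suspects and excluded from
        branch statistics unless this is set.
    branch_avg_mode:
        'per_tree' (mean Zone C bifurcation count per disc-rooted tree) or
        'total' (whole-image count).
    root_margin_dd:
        A connected component counts as disc-rooted when it approaches the
        disc edge closer than this many disc diameters.
    density_region:
        Denominator for the density measures: 'image' (whole raster) or
        '2dd' (disk out to 2 DD beyond the disc edge).
    box_sizes:
        Box-counting edge lengths (pixels). None selects the dyadic ladder
        from min(height, width)//4 down to 4.
    q_min, q_max, q_step:
        Moment orders for the multifractal spectrum.
    r2_floor:
        Minimum regression R^2 for a mass-exponent fit to enter the
        singularity spectrum.
    grid_offsets:
        Number of random grid origins averaged in box counting; 0 keeps a
        single origin-anchored grid (deterministic).
    knudtson_n:
        Number of largest Zone B trunks entering the CRAE/CRVE iterative
        combination.
    """

    pixel_spacing_um: Optional[float] = None
    rgb_tolerance: int = 100
    min_vessel_fraction: float = 0.01
    zone_radii_dd: Sequence[float] = DEFAULT_ZONE_RADII_DD
    spur_factor: float = 3.0
    junction_merge_factor: float = 1.5
    smooth_window_px: int = 7
    direction_fit_px: int = 5
    count_crossings_as_bifurcations: bool = False
    branch_avg_mode: str = "per_tree"
    root_margin_dd: float = 0.25
    density_region: str = "image"
    box_sizes: Optional[Sequence[int]] = None
    q_min: float = -3.0
    q_max: float = 3.0
    q_step: float = 0.5
    r2_floor: float = 0.90
    grid_offsets: int = 0
    knudtson_n: int = 6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pixel_spacing_um is not None and self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        if self.smooth_window_px < 1 or self.smooth_window_px % 2 == 0:
            raise ValueError("smooth_window_px must be a positive odd integer")
        if self.branch_avg_mode not in ("per_tree", "total"):
            raise ValueError("branch_avg_mode must be 'per_tree' or 'total'")
        if self.density_region not in ("image", "2dd"):
            raise ValueError("density_region must be 'image' or '2dd'")
        radii = tuple(float(r) for r in self.zone_radii_dd)
        if len(radii) != 3 or not (0 < radii[0] < radii[1] < radii[2]):
            raise ValueError("zone_radii_dd must be three increasing positives")
        self.zone_radii_dd = radii

    @property
    def spacing(self) -> float:
        if self.pixel_spacing_um is None:
            raise ValueError("pixel_spacing_um is required but was not set")
        return float(self.pixel_spacing_um)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_radii_dd"] = list(self.zone_radii_dd)
        if d["box_sizes"] is not None:
            d["box_sizes"] = [int(s) for s in d["box_sizes"]]
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
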