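"""Box-counting fractal dimensions and the multifractal singularity length.

The capacity (D0), entropy (D1), and correlation (D2) dimensions of a
binary centerline raster are estimated from per-box pixel masses over a
dyadic ladder of grid sizes:

  D0: slope of log N(eps)       vs log(1/eps)
  D1: slope of sum p log p      vs log eps      (the q->1 limit)
  Dq: tau(q)/(q-1), tau(q) = slope of log sum p^q vs log eps   (q != 1)

The singularity length SL is the width alpha_max - alpha_min of the
singularity spectrum, obtained by Legendre transform of tau(q) over a
finite q window (default q in [-3, 3] in steps of 0.5). Negative-q
moments use the masses of occupied boxes only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FractalSpectrum",
    "default_box_sizes",
    "box_counts",
    "generalized_dimension",
    "singularity_width",
    "singularity_length",
    "fractal_panel",
]


@dataclass
class FractalSpectrum:
    """Generalized dimensions and spectrum width of one vessel class."""

    d0: Optional[float]
    d1: Optional[float]
    d2: Optional[float]
    sl: Optional[float]
    fit_diagnostics: dict = field(default_factory=dict)

    def as_dict(self, suffix: str = "") -> dict:
        return {
            f"d0{suffix}": self.d0,
            f"d1{suffix}": self.d1,
            f"d2{suffix}": self.d2,
            f"sl{suffix}": self.sl,
        }


def default_box_sizes(shape: Tuple[int, int]) -> List[int]:
    """Dyadic ladder from min(h, w)//4 down to 4 pixels."""
    upper = min(shape) // 4
    sizes = []
    s = 4
    while s <= upper:
        sizes.append(s)
        s *= 2
    return sizes[::-1]


def box_counts(
    centerline: np.ndarray, sizes: Sequence[int], origin: Tuple[int, int] = (0, 0)
) -> Dict[int, np.ndarray]:
    """Per-box foreground pixel counts for each box size.

    The grid is anchored at ``origin`` (top-left); the raster is
    zero-padded to a multiple of each box size. Returns, per size, the
    counts of the occupied boxes only.
    """
    img = np.asarray(centerline) != 0
    if not img.any():
        raise ValueError("no foreground: cannot box-count an empty raster")
    h, w = img.shape
    out: Dict[int, np.ndarray] = {}
    for size in sizes:
        size = int(size)
        if size < 1 or size > min(h, w):
            raise ValueError(f"box size {size} outside [1, {min(h, w)}]")
        r0, c0 = (int(origin[0]) % size, int(origin[1]) % size)
        ph = (-(h + r0)) % size
        pw = (-(w + c0)) % size
        padded = np.pad(img, ((r0, ph), (c0, pw)))
        hh, ww = padded.shape
        counts = (
            padded.reshape(hh // size, size, ww // size, size)
            .sum(axis=(1, 3))
            .ravel()
        )
        out[size] = counts[counts > 0].astype(np.int64)
    return out


def _linfit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares slope, intercept, R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def _moment_curve(occupancies: Dict[int, np.ndarray], q: float) -> Tuple[np.ndarray, np.ndarray]:
    """x = log eps and the q-moment response per box size."""
    sizes = np.array(sorted(occupancies), dtype=float)
    ys = []
    for size in sizes:
        counts = occupancies[int(size)].astype(float)
        p = counts / counts.sum()
        if abs(q - 1.0) < 1e-12:
            ys.append(float(np.sum(p * np.log(p))))
        else:
            ys.append(float(np.log(np.sum(p**q))))
    return np.log(sizes), np.asarray(ys)


def generalized_dimension(
    occupancies: Dict[int, np.ndarray], q: float
) -> Tuple[float, float]:
    """Order-q generalized dimension estimate and its regression R^2.

    q = 0 gives the capacity dimension (box count scaling), q = 1 the
    entropy (information) dimension, q = 2 the correlation dimension.
    """
    if len(occupancies) < 4:
        raise ValueError("need at least 4 box sizes for a dimension fit")
    x, y = _moment_curve(occupancies, q)
    slope, _, r2 = _linfit(x, y)
    if abs(q - 1.0) < 1e-12:
        return slope, r2  # sum p log p ~ D1 * log eps
    tau = slope  # log sum p^q ~ tau(q) * log eps
    return tau / (q - 1.0), r2


def _tau_spectrum(
    occupancies: Dict[int, np.ndarray],
    q_values: np.ndarray,
    r2_floor: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mass exponents tau(q) with unstable fits dropped."""
    qs, taus = [], []
    for q in q_values:
        if abs(q - 1.0) < 1e-12:
            # tau(1) = 0 identically (masses are normalized)
            qs.append(1.0)
            taus.append(0.0)
            continue
        x, y = _moment_curve(occupancies, q)
        slope, _, r2 = _linfit(x, y)
        if r2 < r2_floor:
            continue
        qs.append(float(q))
        taus.append(slope)
    return np.asarray(qs), np.asarray(taus)


def singularity_width(
    occupancies: Dict[int, np.ndarray],
    q_values: Sequence[float],
    r2_floor: float = 0.90,
) -> Tuple[Optional[float], dict]:
    """Spectrum width alpha_max - alpha_min from per-size box masses."""
    qs, taus = _tau_spectrum(occupancies, np.asarray(q_values, dtype=float), r2_floor)
    diag = {"q": qs.tolist(), "tau": taus.tolist(), "sizes": sorted(occupancies)}
    if len(qs) < 3:
        return None, diag
    alpha = np.gradient(taus, qs)
    diag["alpha"] = alpha.tolist()
    return max(float(alpha.max() - alpha.min()), 0.0), diag


def singularity_length(
    centerline: np.ndarray,
    q_values: Optional[Sequence[float]] = None,
    sizes: Optional[Sequence[int]] = None,
    r2_floor: float = 0.90,
) -> Tuple[Optional[float], dict]:
    """Width of the multifractal singularity spectrum.

    alpha(q) = d tau / d q is evaluated numerically on the retained q
    grid; SL = max alpha - min alpha. A q whose tau fit falls below
    ``r2_floor`` in R^2 is dropped; if fewer than 3 orders survive the
    result is missing.
    """
    img = np.asarray(centerline) != 0
    if q_values is None:
        q_values = np.arange(-3.0, 3.0 + 1e-9, 0.5)
    if sizes is None:
        sizes = default_box_sizes(img.shape)
    occ = box_counts(img, sizes)
    if len(occ) < 4:
        raise ValueError("need at least 4 box sizes")
    return singularity_width(occ, q_values, r2_floor)


def _spectrum_for(
    centerline: np.ndarray,
    sizes: Optional[Sequence[int]],
    q_values: Optional[Sequence[float]],
    r2_floor: float,
) -> FractalSpectrum:
    img = np.asarray(centerline) != 0
    if not img.any():
        return FractalSpectrum(None, None, None, None, {"empty": True})
    use_sizes = list(sizes) if sizes is not None else default_box_sizes(img.shape)
    occ = box_counts(img, use_sizes)
    dims = {}
    diags = {"sizes": sorted(occ), "n_boxes": {s: int(len(occ[s])) for s in occ}}
    for q in (0, 1, 2):
        d, r2 = generalized_dimension(occ, q)
        dims[q] = d
        diags[f"r2_q{q}"] = r2
    sl, sl_diag = singularity_length(img, q_values, use_sizes, r2_floor)
    diags["sl"] = sl_diag
    return FractalSpectrum(dims[0], dims[1], dims[2], sl, diags)


def fractal_panel(
    artery_centerline: np.ndarray,
    vein_centerline: np.ndarray,
    sizes: Optional[Sequence[int]] = None,
    q_values: Optional[Sequence[float]] = None,
    r2_floor: float = 0.90,
) -> Dict[str, FractalSpectrum]:
    """Fractal spectra of the artery and vein centerline rasters.

    A class with an empty centerline yields a spectrum of missing values.
    """
    return {
        "artery": _spectrum_for(artery_centerline, sizes, q_values, r2_floor),
        "vein": _spectrum_for(vein_centerline, sizes, q_values, r2_floor),
    }
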