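"""Cell-cycle summaries from per-nucleus fluorescence intensity.

Two independent readouts are computed from the same list of integrated
densities (a.u., proportional to DNA content):

1. **Phase allocation rule.**  With cut-offs ``c1 < c2 < c3``
   (defaults 100/400/600 a.u.), the G1 fraction is the proportion of
   nuclei below ``c1`` plus half of those in ``[c1, c2)``; the S
   fraction is half of those in ``[c2, c3)``; G2 is the complement —
   the other halves of both middle bands plus everything at or above
   ``c3``.  Band membership is left-closed/right-open, so a value at
   exactly a cut falls in the upper band.

2. **Five-class DNA-content distribution.**  After calibrating the
   intensity of a 2C nucleus, intensities are expressed in C-doublings
   ``x = intensity / scale`` (x = 1 at 2C, x = 2 at 4C) and classified
   into hypoploid (< 2C), 2C, S (2-4C), 4C and endopolyploid (> 4C)
   using symmetric bands of half-width ``band_halfwidth`` (default
   0.25) around x = 1 and x = 2.

The two schemes are reported side by side and never reconciled: the
allocation rule is tied to an instrument's a.u. scale, the class scheme
to the 2C calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .synthetic import PLOIDY_CLASSES

__all__ = [
    "PhaseFractions",
    "PloidyFractions",
    "PloidyHistogram",
    "CellCycleProfile",
    "allocate_phases",
    "calibrate_2c",
    "classify_ploidy",
    "build_histogram",
    "profile_sample",
    "DEFAULT_CUTS",
]

DEFAULT_CUTS = (100.0, 400.0, 600.0)


@dataclass(frozen=True)
class PhaseFractions:
    g1: float
    s: float
    g2: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"G1": self.g1, "S": self.s, "G2": self.g2}


@dataclass(frozen=True)
class PloidyFractions:
    hypoploid: float
    c2: float
    s: float
    c4: float
    endopolyploid: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PLOIDY_CLASSES,
                        (self.hypoploid, self.c2, self.s, self.c4,
                         self.endopolyploid)))


@dataclass(frozen=True)
class PloidyHistogram:
    edges: np.ndarray   # bin edges, a.u., strictly increasing
    counts: np.ndarray  # per-bin counts, sum == n
    n: int


@dataclass(frozen=True)
class CellCycleProfile:
    phases: PhaseFractions
    classes: PloidyFractions
    cuts: tuple[float, float, float]
    scale_2c: float
    band_halfwidth: float
    n: int


def _as_intensities(intensities) -> np.ndarray:
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity list")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")
    return x


def allocate_phases(intensities, cuts=DEFAULT_CUTS) -> PhaseFractions:
    """Apply the banded G1/S/G2 allocation rule.

    G1 = f(x < c1) + f(c1 <= x < c2) / 2
    S  = f(c2 <= x < c3) / 2
    G2 = 1 - G1 - S
    """
    x = _as_intensities(intensities)
    c1, c2, c3 = (float(c) for c in cuts)
    if not c1 < c2 < c3:
        raise ValueError(f"cuts must be strictly increasing, got {cuts}")
    n = x.size
    n_low = int(np.count_nonzero(x < c1))
    n_mid1 = int(np.count_nonzero((x >= c1) & (x < c2)))
    n_mid2 = int(np.count_nonzero((x >= c2) & (x < c3)))
    g1 = (n_low + 0.5 * n_mid1) / n
    s = 0.5 * n_mid2 / n
    g2 = 1.0 - g1 - s
    return PhaseFractions(g1=g1, s=s, g2=g2, n=n)


def calibrate_2c(reference_intensities, min_n: int = 20,
                 median_factor: float = 1.5,
                 grid_points: int = 2048) -> float:
    """Estimate the a.u. intensity of a 2C (G1) nucleus.

    The 2C population is the dominant low-intensity mode of an
    interphase intensity distribution.  A Gaussian kernel-density
    estimate is evaluated on a fixed grid and the peak below
    ``median_factor`` x the overall median is returned.  Deterministic
    for fixed input.
    """
    x = _as_intensities(reference_intensities)
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} reference nuclei, got {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)
    lo, hi = float(x.min()), float(x.max())
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    bound = median_factor * float(np.median(x))
    window = grid <= bound
    if not window.any():
        window = np.ones_like(grid, dtype=bool)
    dens = kde(grid[window])
    return float(grid[window][int(np.argmax(dens))])


def classify_ploidy(intensities, scale: float,
                    band_halfwidth: float = 0.25) -> PloidyFractions:
    """Classify intensities into the five DNA-content classes.

    With ``x = intensity / scale`` (C-doublings; x = 1 at 2C):
    hypoploid x < 1-hw; 2C x in [1-hw, 1+hw]; S x in (1+hw, 2-hw);
    4C x in [2-hw, 2+hw]; endopolyploid x > 2+hw.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    hw = float(band_halfwidth)
    if not 0 < hw < 0.5:
        raise ValueError("band_halfwidth must be in (0, 0.5)")
    x = _as_intensities(intensities) / float(scale)
    n = x.size
    hypo = np.count_nonzero(x < 1 - hw)
    c2 = np.count_nonzero((x >= 1 - hw) & (x <= 1 + hw))
    s = np.count_nonzero((x > 1 + hw) & (x < 2 - hw))
    c4 = np.count_nonzero((x >= 2 - hw) & (x <= 2 + hw))
    endo = np.count_nonzero(x > 2 + hw)
    return PloidyFractions(
        hypoploid=hypo / n, c2=c2 / n, s=s / n, c4=c4 / n,
        endopolyploid=endo / n, n=n,
    )


def build_histogram(intensities, bin_width: float) -> PloidyHistogram:
    """Fixed-width intensity histogram covering the data range.

    Edges start at ``floor(min / bin_width) * bin_width``; the
    rightmost bin is closed so counts always sum to n.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = _as_intensities(intensities)
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = max(int(np.ceil((x.max() - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= x.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return PloidyHistogram(edges=edges, counts=counts, n=x.size)


def profile_sample(intensities, cuts=DEFAULT_CUTS, scale: float | None = None,
                   band_halfwidth: float = 0.25) -> CellCycleProfile:
    """Full cell-cycle profile of one sample.

    When ``scale`` is None the 2C calibration is estimated from the
    sample itself via :func:`calibrate_2c`.
    """
    x = _as_intensities(intensities)
    if scale is None:
        scale = calibrate_2c(x)
    phases = allocate_phases(x, cuts=cuts)
    classes = classify_ploidy(x, scale, band_halfwidth=band_halfwidth)
    return CellCycleProfile(
        phases=phases, classes=classes,
        cuts=tuple(float(c) for c in cuts), scale_2c=float(scale),
        band_halfwidth=float(band_halfwidth), n=x.size,
    )
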