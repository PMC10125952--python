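"""ROI densitometry shared by all stain channels.

One quantifier serves Aniline Blue (callose), chloro-tetracycline
(calcium) and Evans Blue absorbance; channel semantics live in the
calling configuration, not in code paths.  Signals are reported both as
mean and integrated above-background intensity so either convention can
be compared downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionSignal",
    "quantify_region",
    "nuclear_cytoplasmic_split",
    "cross_wall_profile",
    "signals_frame",
]

REGION_CLASSES = ("whole_cell", "nucleus", "cytoplasm", "cross_wall")


@dataclass(frozen=True)
class RegionSignal:
    region_id: int
    region_class: str
    mean_au: float
    integrated_au: float
    area_px: int


def _background(raster: np.ndarray, mask: np.ndarray, rule) -> float:
    if rule == "median_outside":
        outside = raster[~mask]
        return float(np.median(outside)) if outside.size else 0.0
    return float(rule)


def quantify_region(raster: np.ndarray, mask: np.ndarray,
                    background: str | float = 0.0,
                    region_id: int = 1,
                    region_class: str = "whole_cell") -> RegionSignal:
    """Mean and integrated above-background intensity over a mask.

    ``integrated = sum(pixel - background)`` over the mask (no floor, so
    integrated signal is exactly additive over disjoint regions);
    ``mean = integrated / area``.
    """
    raster = np.asarray(raster, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape != mask.shape:
        raise ValueError("raster and mask shapes differ")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    bg = _background(raster, mask, background)
    integrated = float(raster[mask].sum()) - bg * area
    return RegionSignal(
        region_id=int(region_id), region_class=region_class,
        mean_au=integrated / area, integrated_au=integrated, area_px=area,
    )


def nuclear_cytoplasmic_split(raster: np.ndarray, cell_mask: np.ndarray,
                              nucleus_mask: np.ndarray,
                              background: str | float = 0.0,
                              region_id: int = 1):
    """Quantify whole cell, nucleus and cytoplasm (= cell minus nucleus).

    The nucleus mask must be nested in, and strictly smaller than, the
    cell mask.  Integrated signal is conserved:
    whole_cell = nucleus + cytoplasm.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask must be nested inside the cell mask")
    cyto_mask = cell_mask & ~nucleus_mask
    if not cyto_mask.any():
        raise ValueError("cytoplasm region is empty (nucleus fills the cell)")
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    raster = np.asarray(raster, dtype=float)
    bg = _background(raster, cell_mask, background)
    whole = quantify_region(raster, cell_mask, bg, region_id, "whole_cell")
    nuc = quantify_region(raster, nucleus_mask, bg, region_id, "nucleus")
    cyto = quantify_region(raster, cyto_mask, bg, region_id, "cytoplasm")
    return whole, nuc, cyto


def cross_wall_profile(raster: np.ndarray, wall_labels: np.ndarray,
                       background: str | float = 0.0) -> list[RegionSignal]:
    """Per-wall signal from a cross-wall label mask, sorted by wall id."""
    wall_labels = np.asarray(wall_labels)
    ids = [int(i) for i in np.unique(wall_labels) if i > 0]
    if not ids:
        raise ValueError("no cross-wall regions in mask")
    raster = np.asarray(raster, dtype=float)
    bg = _background(raster, wall_labels > 0, background)
    return [
        quantify_region(raster, wall_labels == i, bg, i, "cross_wall")
        for i in sorted(ids)
    ]


def signals_frame(signals, field: str = "field0",
                  channel: str = "signal") -> pd.DataFrame:
    rows = [
        dict(field=field, channel=channel, region_id=s.region_id,
             region_class=s.region_class, mean_au=s.mean_au,
             integrated_au=s.integrated_au, area_px=s.area_px)
        for s in signals
    ]
    return pd.DataFrame(rows, columns=[
        "field", "channel", "region_id", "region_class",
        "mean_au", "integrated_au", "area_px",
    ])
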