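"""Synthetic micrograph phantoms and trait tables with known ground truth.

Every downstream stage of the pipeline (segmentation, DNA-content
profiling, viability staging, ROI densitometry, network construction)
is exercised against phantoms generated here.  The generators plant
explicit per-object truths — DNA content, death stage, stain level,
correlation structure — and return them as sidecar records, so tests
never have to reverse-engineer the rendered pixels.

The emulated populations
------------------------
* **Nuclear DNA content.**  DAPI-stained interphase nuclei whose total
  above-background fluorescence is proportional to DNA content.  DNA
  contents are drawn from a mixture over five ploidy classes —
  hypoploid (< 2C), 2C (G1), 2–4C (S), 4C (G2) and endopolyploid
  (> 4C).  The default calibration renders a 2C nucleus at 200 a.u. of
  integrated density, so that the classic 100/400/600 a.u. cell-cycle
  cut-offs bracket the 2C and 4C populations plausibly.
* **Viability staging.**  Acridine-Orange / Ethidium-Bromide double
  staining: membrane-intact cells take up only AO (green); as membranes
  permeabilise, EB (red) enters the nucleus and finally the nucleolus.
  Each phantom cell is planted into one of four stages — alive,
  dying I (red nucleus signal intermediate, nucleolus spared),
  dying II (nucleolus stained too), dead (red dominant) — encoded as
  the red/green ratio of nucleus and nucleolus.
* **Stain fields.**  Callose bands at cross walls, cytoplasmic vs
  nuclear calcium signal, and Evans-Blue absorbance for mortality
  scoring.
* **Trait tables.**  Multivariate samples over named physiological
  traits with a planted correlation matrix and planted control-vs-
  kinetin shifts, feeding the correlation-network stage.

Geometry is deliberately simple — axis-aligned elliptical nuclei,
concentric disc nucleoli, rectangular cells and walls — so that areas
and planted signals have exact analytic bookkeeping.  Noise is i.i.d.
Gaussian clipped at zero; with ``noise_sd=0`` every rendered object's
summed above-background signal equals its planted value exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .io import Micrograph, write_mask, write_micrograph

__all__ = [
    "PLOIDY_CLASSES",
    "STAGES",
    "PhantomSpec",
    "GroundTruth",
    "TraitSimSpec",
    "PackingError",
    "gen_nuclei_field",
    "gen_aoeb_field",
    "gen_signal_field",
    "gen_trait_table",
    "sample_dna_contents",
    "sample_intensities",
    "DEFAULT_TRAITS",
]

PLOIDY_CLASSES = ("hypoploid", "2C", "S", "4C", "endopolyploid")
STAGES = ("alive", "dying_I", "dying_II", "dead")

#: Trait set of the kinetin study: calcium pools, callose, death-stage
#: frequencies and DNA-content class frequencies.
DEFAULT_TRAITS = (
    "cytosolic_ca",
    "nuclear_ca",
    "callose",
    "alive",
    "dying_I",
    "dying_II",
    "dead",
    "lt2C",
    "2C",
    "2_4C",
    "4C",
    "gt4C",
)

# DNA-content draw ranges per ploidy class, in C units.  Each range sits
# strictly inside the corresponding classifier band (half-width 0.25
# C-doublings around 2C and 4C), so planted class labels remain
# recoverable ground truth under small measurement noise.
_DNA_RANGES_C = {
    "hypoploid": (0.8, 1.4),
    "2C": (1.6, 2.4),
    "S": (2.6, 3.4),
    "4C": (3.6, 4.4),
    "endopolyploid": (4.8, 8.0),
}

# Red/green ratio draw ranges per death stage, for (nucleus, nucleolus).
# Alive cells exclude EB entirely; dying stages show an intermediate
# nuclear ratio; the dead band dominates.  Chosen well clear of the
# default staging thresholds (t_alive=0.2, t_dead=1.5, t_nco=0.2).
_STAGE_RATIOS = {
    "alive": ((0.0, 0.0), (0.0, 0.0)),
    "dying_I": ((0.5, 1.1), (0.0, 0.0)),
    "dying_II": ((0.5, 1.1), (0.5, 1.2)),
    "dead": ((1.8, 2.8), (1.8, 2.8)),
}


class PackingError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of a rendered phantom field.

    Attributes
    ----------
    image_shape : (h, w)
        Field size in pixels.
    n_cells : int
        Number of objects to render.
    ploidy_mixture : fractions over :data:`PLOIDY_CLASSES`
        Must sum to 1.  Default is the control-at-subcultivation
        population: 60% 2C, 30% S, 10% 4C.
    stage_mixture : fractions over :data:`STAGES`
        Must sum to 1.  Default is a kinetin-style end-of-cycle
        population: 40% alive, 45% dying I, 12% dying II, 3% dead.
    intensity_scale : float
        Integrated density (a.u.) of a 2C nucleus, before noise.
    noise_sd : float
        Standard deviation of additive Gaussian pixel noise (a.u.).
    background : float
        Uniform background level (a.u.).
    min_separation : float
        Minimum pixel gap enforced between object bounding circles.
    nucleus_axes : (lo, hi)
        Range from which the semi-axes of a 2C nucleus are drawn (px).
        In DAPI fields each nucleus's axes are additionally scaled by
        sqrt(C / 2), so nuclear area grows linearly with DNA content at
        constant stain density -- the per-pixel amplitude is then
        uniform across ploidy classes while total signal stays
        proportional to C.
    aoeb_green_rfi : float
        Planted above-background green (AO) level inside nuclei (a.u.).
    seed : int
        Root seed; identical spec + seed gives bit-identical output.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 30
    ploidy_mixture: tuple[float, ...] = (0.0, 0.60, 0.30, 0.10, 0.0)
    stage_mixture: tuple[float, ...] = (0.40, 0.45, 0.12, 0.03)
    intensity_scale: float = 200.0
    noise_sd: float = 0.0
    background: float = 100.0
    min_separation: float = 4.0
    nucleus_axes: tuple[float, float] = (9.0, 12.0)
    aoeb_green_rfi: float = 100.0
    seed: int = 0

    def noise_sd_for_snr(self, snr: float) -> float:
        """Noise sd giving pixel signal-to-noise *snr* for the dimmest
        nucleus (the largest 2C footprint at constant stain density)."""
        min_amplitude = self.intensity_scale / (np.pi * max(self.nucleus_axes) ** 2)
        return min_amplitude / snr

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")
        for name, mix, k in (
            ("ploidy_mixture", self.ploidy_mixture, len(PLOIDY_CLASSES)),
            ("stage_mixture", self.stage_mixture, len(STAGES)),
        ):
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (k,):
                raise ValueError(f"{name} must have {k} entries")
            if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        lo, hi = self.nucleus_axes
        if not (0 < lo <= hi):
            raise ValueError("nucleus_axes range invalid")


@dataclass
class GroundTruth:
    """Planted per-object truth plus label-mask rasters.

    ``objects`` has one row per rendered object (id, class labels,
    planted values, geometry).  ``masks`` maps object-class name
    (``nucleus``, ``nucleolus``, ``cell``, ``cross_wall``) to a uint16
    label raster in which object k carries label k.
    """

    objects: pd.DataFrame
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, directory: str | Path, field_name: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.objects.to_csv(directory / f"{field_name}_truth.csv", index=False)
        for name, mask in self.masks.items():
            write_mask(mask, directory / f"{field_name}_mask_{name}.tif")


# ---------------------------------------------------------------------------
# geometry helpers


def _place_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    axes_range: tuple[float, float],
    min_separation: float,
    scales: Sequence[float] | None = None,
    max_tries: int = 200,
) -> list[tuple[float, float, float, float]]:
    """Draw n non-overlapping axis-aligned ellipses (cy, cx, a, b).

    ``scales`` multiplies both drawn semi-axes per object (used to grow
    nuclear area with ploidy).  Overlap is excluded conservatively on
    bounding circles inflated by ``min_separation``; objects are kept
    clear of the image border.  Raises :class:`PackingError` after
    ``max_tries`` rejections per object.
    """
    h, w = shape
    placed: list[tuple[float, float, float, float]] = []
    for i in range(n):
        sc = 1.0 if scales is None else float(scales[i])
        for attempt in range(max_tries):
            a = sc * rng.uniform(*axes_range)  # semi-axis along rows
            b = sc * rng.uniform(*axes_range)  # semi-axis along cols
            r = max(a, b)
            margin = r + 2.0
            if 2 * margin >= min(h, w):
                raise PackingError("objects too large for the field")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = True
            for (py, px, pa, pb) in placed:
                pr = max(pa, pb)
                if np.hypot(cy - py, cx - px) < r + pr + min_separation:
                    ok = False
                    break
            if ok:
                placed.append((cy, cx, a, b))
                break
        else:
            raise PackingError(
                f"could not place object {len(placed) + 1}/{n} after "
                f"{max_tries} tries; reduce n_cells or min_separation"
            )
    return placed


def _finish(spec: PhantomSpec, rng: np.random.Generator, *planes: np.ndarray) -> np.ndarray:
    """Add background and clipped Gaussian noise; stack channels."""
    out = []
    for plane in planes:
        img = plane + spec.background
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)
        out.append(img)
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# DNA-content sampling (shared by the renderer and large-n cytometry
# simulations that do not need pixels)


def sample_dna_contents(
    rng: np.random.Generator, n: int, mixture: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-nucleus (class label, DNA content in C units)."""
    mix = np.asarray(mixture, dtype=float)
    labels = rng.choice(len(PLOIDY_CLASSES), size=n, p=mix)
    contents = np.empty(n)
    for k, cls in enumerate(PLOIDY_CLASSES):
        sel = labels == k
        lo, hi = _DNA_RANGES_C[cls]
        contents[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    return np.array([PLOIDY_CLASSES[k] for k in labels]), contents


def sample_intensities(
    spec: PhantomSpec, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (labels, integrated densities in a.u.) without rendering.

    The intensity of a nucleus with DNA content ``C`` is
    ``(C / 2) * intensity_scale`` plus Gaussian noise of sd
    ``noise_sd`` (here acting on the integrated density directly).
    Used for image-free cytometry simulations at large n.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells if n is None else n
    labels, contents = sample_dna_contents(rng, n, spec.ploidy_mixture)
    intens = contents / 2.0 * spec.intensity_scale
    if spec.noise_sd > 0:
        intens = np.clip(intens + rng.normal(0, spec.noise_sd, n), 0, None)
    return labels, intens


# ---------------------------------------------------------------------------
# field generators


def gen_nuclei_field(spec: PhantomSpec) -> tuple[Micrograph, GroundTruth]:
    """Render a DAPI-like field of elliptical nuclei.

    Each nucleus is filled uniformly so that its total above-background
    signal equals ``(C / 2) * intensity_scale`` exactly before noise.
    Nuclear area scales with DNA content (axes x sqrt(C / 2)), keeping
    the per-pixel amplitude uniform across ploidy classes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    signal = np.zeros((h, w))
    nucleus_labels = np.zeros((h, w), dtype=np.uint16)

    labels, contents = sample_dna_contents(rng, spec.n_cells, spec.ploidy_mixture)
    ellipses = _place_ellipses(
        rng, (h, w), spec.n_cells, spec.nucleus_axes, spec.min_separation,
        scales=np.sqrt(contents / 2.0),
    )

    rows = []
    for i, (cy, cx, a, b) in enumerate(ellipses):
        rr, cc = ellipse(cy, cx, a, b, shape=(h, w))
        area = rr.size
        total = contents[i] / 2.0 * spec.intensity_scale
        signal[rr, cc] += total / area
        nucleus_labels[rr, cc] = i + 1
        rows.append(
            dict(
                object_id=i + 1,
                ploidy_class=labels[i],
                dna_content_c=contents[i],
                integrated_au=total,
                area_px=area,
                centroid_row=float(rr.mean()),
                centroid_col=float(cc.mean()),
                semi_axis_row=a,
                semi_axis_col=b,
            )
        )

    data = _finish(spec, rng, signal)
    img = Micrograph(data, ("dapi",))
    truth = GroundTruth(
        objects=pd.DataFrame(
            rows,
            columns=[
                "object_id", "ploidy_class", "dna_content_c", "integrated_au",
                "area_px", "centroid_row", "centroid_col",
                "semi_axis_row", "semi_axis_col",
            ],
        ),
        masks={"nucleus": nucleus_labels},
    )
    return img, truth


def gen_aoeb_field(spec: PhantomSpec) -> tuple[Micrograph, GroundTruth]:
    """Render a two-channel AO/EB field encoding planted death stages.

    Green (AO) is uniform at ``aoeb_green_rfi`` above background inside
    every nucleus.  Red (EB) above background equals the planted
    nucleus ratio x green over the nucleus outside the nucleolus, and
    the planted nucleolus ratio x green inside the nucleolus, so the
    viability stager's red/green ratios recover the planted values
    exactly in the noise-free case.  Nucleoli are concentric discs at
    30% of the nuclear minor semi-axis.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    nucleus_labels = np.zeros((h, w), dtype=np.uint16)
    nucleolus_labels = np.zeros((h, w), dtype=np.uint16)

    ellipses = _place_ellipses(
        rng, (h, w), spec.n_cells, spec.nucleus_axes, spec.min_separation
    )
    stage_idx = rng.choice(len(STAGES), size=spec.n_cells, p=np.asarray(spec.stage_mixture))

    rows = []
    g = spec.aoeb_green_rfi
    for i, (cy, cx, a, b) in enumerate(ellipses):
        stage = STAGES[stage_idx[i]]
        (nuc_lo, nuc_hi), (nco_lo, nco_hi) = _STAGE_RATIOS[stage]
        rho_nuc = rng.uniform(nuc_lo, nuc_hi) if nuc_hi > nuc_lo else nuc_lo
        rho_nco = rng.uniform(nco_lo, nco_hi) if nco_hi > nco_lo else nco_lo

        rr, cc = ellipse(cy, cx, a, b, shape=(h, w))
        r_nco = max(0.3 * min(a, b), 1.0)
        rr2, cc2 = disk((cy, cx), r_nco, shape=(h, w))

        green[rr, cc] += g
        red[rr, cc] += rho_nuc * g
        # overwrite the nucleolus with its own ratio
        red[rr2, cc2] += (rho_nco - rho_nuc) * g
        nucleus_labels[rr, cc] = i + 1
        nucleolus_labels[rr2, cc2] = i + 1

        rows.append(
            dict(
                object_id=i + 1,
                stage=stage,
                rho_nucleus=rho_nuc,
                rho_nucleolus=rho_nco,
                green_rfi=g,
                centroid_row=cy,
                centroid_col=cx,
            )
        )

    data = _finish(spec, rng, green, red)
    img = Micrograph(data, ("green", "red"))
    truth = GroundTruth(
        objects=pd.DataFrame(
            rows,
            columns=[
                "object_id", "stage", "rho_nucleus", "rho_nucleolus",
                "green_rfi", "centroid_row", "centroid_col",
            ],
        ),
        masks={"nucleus": nucleus_labels, "nucleolus": nucleolus_labels},
    )
    return img, truth


_SIGNAL_KINDS = ("callose", "calcium", "evans_blue")


def gen_signal_field(
    kind: str,
    spec: PhantomSpec,
    region_params: Mapping[str, object] | None = None,
) -> tuple[Micrograph, GroundTruth]:
    """Render a stain field of the requested *kind*.

    kind = "callose"
        Bright bands at cross walls between adjacent cells of a file.
        ``region_params``: ``wall_means`` (explicit per-wall means,
        a.u. above background) or ``n_walls``/``wall_mean``/``wall_sd``.
        Defaults emulate the control-culture scale (mean 150, sd 30).
    kind = "calcium"
        Rectangular cells with elliptical nuclei; cytoplasm and nucleus
        carry planted mean levels (``cyto_mean``, ``nuc_mean``; a.u.
        above background; defaults 100 and 200).
    kind = "evans_blue"
        Per-cell absorbance; a planted fraction of cells
        (``stained_fraction``, default 0.60) is stained at
        ``stained_mean`` (default 0.8), the rest at ``unstained_mean``
        (default 0.05), on an absorbance scale with zero background.
    """
    if kind not in _SIGNAL_KINDS:
        raise ValueError(f"unknown signal kind {kind!r}; expected one of {_SIGNAL_KINDS}")
    spec.validate()
    params = dict(region_params or {})
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    if kind == "callose":
        return _gen_callose(spec, params, rng)
    if kind == "calcium":
        return _gen_calcium(spec, params, rng)
    return _gen_evans_blue(spec, params, rng)


def _cell_file_layout(
    rng: np.random.Generator, shape: tuple[int, int], n_cells: int
) -> list[tuple[int, int, int, int]]:
    """Lay rectangular cells in horizontal files (BY-2 cells grow in
    chains); returns (row0, row1, col0, col1) per cell."""
    h, w = shape
    cell_h = int(rng.integers(36, 48))
    cell_w = int(rng.integers(48, 64))
    gap = 6
    cells = []
    r0 = gap
    while len(cells) < n_cells and r0 + cell_h < h - gap:
        c0 = gap
        while len(cells) < n_cells and c0 + cell_w < w - gap:
            cells.append((r0, r0 + cell_h, c0, c0 + cell_w))
            c0 += cell_w + 2  # adjacent in the file, sharing a cross wall
        r0 += cell_h + gap
    if len(cells) < n_cells:
        raise PackingError(f"field too small for {n_cells} cells")
    return cells


def _gen_callose(spec, params, rng):
    h, w = spec.image_shape
    if "wall_means" in params:
        wall_means = [float(v) for v in params["wall_means"]]
        n_walls = len(wall_means)
    else:
        n_walls = int(params.get("n_walls", max(spec.n_cells - 1, 1)))
        mu = float(params.get("wall_mean", 150.0))
        sd = float(params.get("wall_sd", 30.0))
        wall_means = np.clip(rng.normal(mu, sd, n_walls), 0, None).tolist()

    cells = _cell_file_layout(rng, (h, w), n_walls + 1)
    signal = np.zeros((h, w))
    wall_labels = np.zeros((h, w), dtype=np.uint16)
    wall_half = 2  # wall band half-thickness, px
    rows = []
    for k in range(n_walls):
        r0, r1, c0, c1 = cells[k]
        nr0, nr1, nc0, nc1 = cells[k + 1]
        if nr0 == r0:  # same file: wall at the shared vertical edge
            wc = (c1 + nc0) // 2
            sl = (slice(r0 + 2, r1 - 2), slice(wc - wall_half, wc + wall_half + 1))
        else:  # file wrapped: place wall at the right edge of cell k
            sl = (slice(r0 + 2, r1 - 2), slice(c1 - wall_half * 2, c1))
        signal[sl] = wall_means[k]
        wall_labels[sl] = k + 1
        rows.append(dict(object_id=k + 1, mean_au=wall_means[k],
                         area_px=int(wall_labels[sl].size)))

    data = _finish(spec, rng, signal)
    truth = GroundTruth(
        objects=pd.DataFrame(rows, columns=["object_id", "mean_au", "area_px"]),
        masks={"cross_wall": wall_labels},
    )
    return Micrograph(data, ("aniline_blue",)), truth


def _gen_calcium(spec, params, rng):
    h, w = spec.image_shape
    cyto_mean = float(params.get("cyto_mean", 100.0))
    nuc_mean = float(params.get("nuc_mean", 200.0))
    cyto_sd = float(params.get("cyto_sd", 0.0))
    nuc_sd = float(params.get("nuc_sd", 0.0))

    cells = _cell_file_layout(rng, (h, w), spec.n_cells)[: spec.n_cells]
    signal = np.zeros((h, w))
    cell_labels = np.zeros((h, w), dtype=np.uint16)
    nucleus_labels = np.zeros((h, w), dtype=np.uint16)
    rows = []
    for i, (r0, r1, c0, c1) in enumerate(cells):
        cm = max(rng.normal(cyto_mean, cyto_sd), 0.0) if cyto_sd else cyto_mean
        nm = max(rng.normal(nuc_mean, nuc_sd), 0.0) if nuc_sd else nuc_mean
        cell_sl = (slice(r0, r1), slice(c0, c1))
        signal[cell_sl] = cm
        cell_labels[cell_sl] = i + 1
        cy, cx = (r0 + r1) / 2.0, (c0 + c1) / 2.0
        a = (r1 - r0) * 0.22
        b = (c1 - c0) * 0.22
        rr, cc = ellipse(cy, cx, a, b, shape=(h, w))
        signal[rr, cc] = nm
        nucleus_labels[rr, cc] = i + 1
        rows.append(dict(object_id=i + 1, cyto_mean_au=cm, nuc_mean_au=nm))

    data = _finish(spec, rng, signal)
    truth = GroundTruth(
        objects=pd.DataFrame(rows, columns=["object_id", "cyto_mean_au", "nuc_mean_au"]),
        masks={"cell": cell_labels, "nucleus": nucleus_labels},
    )
    return Micrograph(data, ("ctc",)), truth


def _gen_evans_blue(spec, params, rng):
    h, w = spec.image_shape
    frac = float(params.get("stained_fraction", 0.60))
    stained_mean = float(params.get("stained_mean", 0.8))
    unstained_mean = float(params.get("unstained_mean", 0.05))
    if not 0.0 <= frac <= 1.0:
        raise ValueError("stained_fraction must be in [0, 1]")

    cells = _cell_file_layout(rng, (h, w), spec.n_cells)[: spec.n_cells]
    # exact planted count, randomly assigned
    n_stained = int(round(frac * spec.n_cells))
    stained = np.zeros(spec.n_cells, dtype=bool)
    stained[rng.permutation(spec.n_cells)[:n_stained]] = True

    signal = np.zeros((h, w))
    cell_labels = np.zeros((h, w), dtype=np.uint16)
    rows = []
    for i, (r0, r1, c0, c1) in enumerate(cells):
        ab = stained_mean if stained[i] else unstained_mean
        signal[r0:r1, c0:c1] = ab
        cell_labels[r0:r1, c0:c1] = i + 1
        rows.append(dict(object_id=i + 1, stained=bool(stained[i]), absorbance=ab))

    # absorbance scale: background 0, noise still applies
    eb_spec = dataclasses.replace(spec, background=0.0)
    data = _finish(eb_spec, rng, signal)
    truth = GroundTruth(
        objects=pd.DataFrame(rows, columns=["object_id", "stained", "absorbance"]),
        masks={"cell": cell_labels},
    )
    return Micrograph(data, ("evans_blue",)), truth


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitSimSpec:
    """Specification of a simulated control-vs-kinetin trait table.

    ``corr`` is the planted Pearson correlation matrix over ``traits``
    (symmetric, unit diagonal, positive semidefinite).  ``effects``
    maps trait name to the kinetin-group shift in SD units.  Samples
    are assigned round-robin to ``timepoints`` (days after
    subcultivation) within each group, emulating a daily time course
    with replicate cultures.
    """

    traits: tuple[str, ...] = DEFAULT_TRAITS
    n_samples: int = 24
    corr: np.ndarray | None = None
    effects: Mapping[str, float] = field(default_factory=dict)
    timepoints: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    seed: int = 0

    def validate(self) -> np.ndarray:
        p = len(self.traits)
        if len(set(self.traits)) != p:
            raise ValueError("trait names must be unique")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        corr = np.eye(p) if self.corr is None else np.asarray(self.corr, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"corr must be {p}x{p}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("corr must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"corr not positive semidefinite (min eigenvalue {eigvals.min():.3g})"
            )
        unknown = set(self.effects) - set(self.traits)
        if unknown:
            raise ValueError(f"effects for unknown traits: {sorted(unknown)}")
        return corr


def gen_trait_table(spec: TraitSimSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a trait table with planted correlation and group effects.

    Returns ``(table, planted_corr)``.  The table has columns
    ``sample_id``, ``group`` (control/kinetin), ``timepoint_d`` and one
    column per trait.  Trait values are standard-normal deviates
    correlated through the planted matrix; kinetin rows are shifted by
    the planted per-trait effect (in SD units).
    """
    corr = spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = len(spec.traits)
    n = spec.n_samples

    # PSD square root via eigendecomposition (tolerates singular matrices,
    # e.g. a planted r = 1 pair)
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    z = rng.standard_normal((2 * n, p))
    x = z @ factor.T

    shifts = np.array([float(spec.effects.get(t, 0.0)) for t in spec.traits])
    x[n:] += shifts  # kinetin rows

    tp = np.resize(np.asarray(spec.timepoints, dtype=float), n)
    df = pd.DataFrame(x, columns=list(spec.traits))
    df.insert(0, "timepoint_d", np.concatenate([tp, tp]))
    df.insert(0, "group", ["control"] * n + ["kinetin"] * n)
    df.insert(0, "sample_id", np.arange(2 * n))
    return df, corr.copy()
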