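# Methods

This note documents the models implemented in `phytocyto`, the
parameter choices that matter, what the synthetic phantoms do and do
not emulate, and the numerical conventions used throughout.

## The measurement model

All quantification rests on one assumption: fluorescence is additive,
so the summed above-background pixel intensity over an object
(*integrated density*, a.u.) is proportional to the amount of stained
material — DNA for DAPI, callose for Aniline Blue, membrane-associated
calcium for chloro-tetracycline.  Background is estimated as the
median of non-object pixels by default (a fixed level can be supplied
instead); whether an instrument's integrated densities should be
background-subtracted at all is exposed as a choice because both
conventions are in use.

## Synthetic phantoms

The generators plant explicit truths and return them as sidecar
records (CSV + label-mask TIFFs), so validation never reverse-engineers
pixels.

**Geometry.**  Nuclei are axis-aligned ellipses with uniform fill;
nucleoli are concentric discs at 30% of the nuclear minor semi-axis;
cells and cross walls are rectangles laid out in files, as BY-2 cells
grow in chains.  Simple shapes give exact analytic bookkeeping of area
and signal.

**DNA content.**  Per-nucleus DNA content is drawn from a mixture over
five ploidy classes.  Within each class the C-value is drawn uniformly
from a range that sits strictly inside the corresponding classifier
band (e.g. 2C nuclei from 1.6–2.4 C against the band 1.5–2.5 C), so the
planted class label remains recoverable ground truth under small
measurement noise.  The default calibration renders a 2C nucleus at an
integrated density of 200 a.u.; real microscopes produce arbitrary
a.u., which is why both the calibration and the allocation cut-offs
are configurable.  There is no published magnitude for this
calibration — 200 a.u. per 2C is a modelling choice selected so that
the classic 100/400/600 a.u. cut-offs bracket the 2C and 4C
populations plausibly.

**Ploidy–size scaling.**  Nuclear area scales linearly with DNA
content (semi-axes × √(C/2)) at constant stain density.  This mirrors
the well-known nuclear-size/ploidy relationship and has a practical
consequence: the per-pixel amplitude above background is uniform
across ploidy classes (≈ 0.4–0.8 a.u. at default geometry), which
keeps the image histogram cleanly bimodal.  Automatic (Otsu)
thresholding needs a foreground fraction of at least a few percent to
beat the degenerate background split; 30 default-size nuclei occupy
≈ 5% of a 512×512 field, which is sufficient (verified over seeded
fields in the test suite).

**Noise.**  Pixel noise is i.i.d. Gaussian, clipped at zero.  Poisson
shot noise, point-spread blur, illumination gradients, photobleaching
and cell-shape realism are deliberately not modelled: the downstream
stages use only thresholds and region sums, so these effects would
change difficulty, not correctness.  Passing tests on phantoms
therefore demonstrate the *estimators* are right; they do not
demonstrate robustness to real-microscope artefacts.  Pixel SNR is
defined as the dimmest object's above-background amplitude divided by
the noise SD (`PhantomSpec.noise_sd_for_snr`).

**Images** are single-plane float32 TIFFs, one file per channel
(`<field>_<channel>.tif`); label masks are uint16.  Float storage keeps
the conservation property exact — with `noise_sd=0` every object's
summed above-background signal equals its planted value to float
precision — and permits sub-unit noise levels that integer DN would
quantise away at the 200 a.u. = 2C scale.

**AO/EB encoding.**  Green is uniform inside nuclei (default 100 a.u.
above background).  Red encodes the planted stage through the
red/green ratio: alive cells carry no red at all (EB fully excluded),
dying cells an intermediate nuclear ratio drawn from 0.5–1.1 with the
nucleolus either spared (dying I) or stained at 0.5–1.2 (dying II),
dead cells 1.8–2.8 throughout.  Draw ranges sit well clear of the
staging thresholds so planted labels are exact ground truth.

**Trait tables** are multivariate standard-normal samples with a
planted correlation matrix (any PSD matrix; the bundled study uses a
single-factor structure corr = λλᵀ + diag(1 − λ²), PSD by
construction) plus per-trait control-vs-kinetin mean shifts in SD
units.  Samples are assigned round-robin to timepoints (days 0–7,
three replicates per day per group by default, matching a daily
sampling design).  Trait values are abstract z-scores, not simulated
through the imaging stages; the table feeds the network stage only.

## Cell-cycle profiling

**Allocation rule.**  With cut-offs c1 < c2 < c3 on integrated density,
G1 receives everything below c1 plus half of [c1, c2); S receives half
of [c2, c3); G2 is the complement, i.e. the two unallocated halves plus
everything at or above c3.  Sending the unallocated halves to G2 via
the complement is an interpretation of the verbal "divided by two …
remaining cells" rule; it is the only reading in which the three
fractions partition the population.  Bands are left-closed/right-open:
a value at exactly a cut falls in the upper band.  The rule is applied
to integrated density (the measured quantity), not mean intensity.

**2C calibration** takes the kernel-density peak of the intensity
distribution below 1.5× the median — the dominant low mode of an
interphase population is G1/2C.  The KDE (Gaussian, Scott bandwidth) is
evaluated on a fixed 2048-point grid, making the estimate
deterministic; a zero-variance input returns its value directly; at
least 20 reference nuclei are required.

**Five-class scheme.**  In C-doubling units x = I/scale, classes are
hypoploid x < 1−h, 2C [1−h, 1+h], S (1+h, 2−h), 4C [2−h, 2+h],
endopolyploid x > 2+h with half-width h = 0.25.  No published border
exists for these classes; symmetric bands with no gaps or overlaps are
the minimal complete choice.  The 2C/4C bands are closed and the
S/extreme regions open so boundary values resolve to the named ploidy
class.

The allocation rule and the five-class scheme answer different
questions (fixed instrument-scale banding vs calibrated DNA content)
and are reported side by side, never reconciled.

## Viability staging

The verbal green → yellow → red progression is operationalised as the
red/green RFI ratio with three thresholds: t_alive = 0.2 (below:
alive), t_dead = 1.5 (at or above: dead), t_nco = 0.2 separating
dying I (nucleolus ratio below) from dying II.  The decision is a total
ordering, so every finite ratio pair receives exactly one stage, and
increasing nuclear redness can never move a cell to an earlier stage.
Nucleus RFI is computed over nucleus-minus-nucleolus so the two ratios
are independent readouts.  The thresholds are calibrated on phantoms
only; real instruments need recalibration against visually staged
reference cells.  On real images without a nucleolus mask,
`detect_nucleolus` finds the largest connected green-intensity
depression (< 60% of the nuclear median) — the unstained nucleolus
appears as a green hole.

Evans-Blue mortality is the fraction of cells whose mean absorbance
reaches the stain threshold (default 0.5 on the phantom's 0–1
absorbance scale).

## ROI densitometry

`quantify_region` reports mean and integrated above-background signal.
The integrated value is the raw sum of (pixel − background) without
flooring, so integration is exactly additive over disjoint regions and
whole-cell = nucleus + cytoplasm holds to rounding.  (Per-object
segmentation measurements floor the total at zero instead, since a
negative DNA amount is meaningless.)  Cross-wall and cell masks come
from the phantom sidecar or user-supplied ROIs; automatic wall
detection is out of scope.  Whether a published per-wall intensity is
a mean or an integral is often unstated; the mean is the primary
readout here and both are reported.

## Statistics and network

**Group comparison.**  The Mann–Whitney U statistic is computed from
midranks (ties count half).  For combined n ≤ 12 the two-sided P is
exact: all C(n, n1) assignments of the pooled values are enumerated
and P is the fraction with |U − n1·n2/2| at least the observed
distance.  This enumeration tolerates ties, which off-the-shelf exact
implementations refuse.  Larger samples use the tie-corrected normal
approximation with continuity correction.  Degenerate input (all
values identical) yields P = 1 with a warning.  Student's t is always
reported alongside; the screen's decision uses the Mann–Whitney P.

**Window regression.**  Time-course traits are fitted by least squares
(linear by default, quadratic optional) per group over a day window
(default days 4–7, the expansion/death phase), with R² = 1 − SSres/SStot
and R² ≡ 0 for constant data.  When two groups are present the window
values are additionally compared via the group tests.

**Correlations and bands.**  Pearson r with pairwise deletion
(minimum 3 complete pairs); zero-variance traits are flagged missing,
not zero.  Band cuts: |r| < 0.3 none, 0.3 ≤ |r| ≤ 0.8 moderate,
|r| > 0.8 strong — the boundary values 0.3 and 0.8 are assigned to the
moderate band (closed on both ends), matching the strict reading of
"above 0.8" for strong.  Correlations pool both groups across the time
course by default (the treatment response is part of the signal); a
per-group analysis can be run by subsetting the table.  No
multiple-testing correction is applied across pairs, by design.

**Network.**  Nodes are the traits passing the step-1 screen, in
lexicographic order; edges are pairs reaching at least the moderate
band, attributed with r, sign and band.  Node ordering makes the
GraphML byte-deterministic.

## Pipeline and reproducibility

A run is a declarative YAML config.  All randomness derives from one
root seed via fixed per-stage offsets (every derived seed < 2³¹); the
manifest records the package version, root seed, a SHA-256 hash of the
config and a checksum per output file.  Identical config + seed
reproduce every output byte — verified by running the bundled study
twice in the test suite.  `run_pipeline` drives simulated studies;
file-based inputs go through the per-stage CLI subcommands
(`segment`, `stage`, `quantify`, `network`), which accept TIFFs and
label masks directly.

## Problem sizes

The validation suite and the acceptance script use: 1,000 random
intensity lists for the allocation oracle; 100 seeded 512×512 fields of
30 nuclei at pixel SNR 5 for segmentation recovery; 50 populations of
700 nuclei for mixture recovery (noise 5% of the 2C scale), with the
day-0 profile averaged over six replications of 700 nuclei; 20 seeded
AO/EB fields of 40 cells, noise-free and at SNR 5, for staging; every
two-group partition shape with combined n ≤ 10 for Mann–Whitney
exactness; 100 trait tables of n = 100 with a two-block (r = 0.9)
structure for network recovery.

## Known limitations

* Touching or overlapping nuclei are not split (no watershed); the
  phantoms guarantee separation, real clumped cultures would need
  pre-separation or manual ROIs.
* Otsu thresholding degrades when objects cover well under a few
  percent of the field; supply a fixed threshold or a label mask in
  that regime.
* Staging thresholds and the 2C calibration are phantom-calibrated
  defaults, not instrument constants.
* The trait simulator plants correlations directly rather than
  deriving them mechanistically from the imaging phantoms; network
  tests validate the statistical machinery, not a biological model.
* CTC calcium readouts are relative (a.u.), never molar.
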