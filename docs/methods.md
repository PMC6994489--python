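# Methods

## Scope

`traquant` scores three-channel epifluorescence images of blood mononuclear
cells for a rare TRA-1-60+/CD45-low population and summarises each patient
by three measurements plus ROC diagnostics between cohort groups. Because
no real images ship with the package, a synthetic-slide generator provides
inputs with exact per-cell ground truth; every claim the test-suite makes
is a claim about recovery of that known truth.

## Image model of the synthetic generator

A field is a `height_px × width_px` raster at 0.65 µm/px (defaults
512 × 512; full-scale sensor fields of 2560 × 2160 are available by
configuration but are not the testing default). Per channel

```
I(x, y) = (B + S(x, y)) · shade(x) + ε,   shade(x) = 1 + g·(x/(W−1) − ½),
ε ~ N(0, σ²)
```

with background `B = 100 AU`, noise `σ = 10 AU` and illumination gradient
`g = 0.05`. Images are quantised to 16-bit, the format the pipeline reads.

Cells are round nuclei (radius ~N(6, 0.7²) px clipped to [5, 7.5]) painted
as disks and smoothed with a σ = 1 px Gaussian; surface markers (CD45,
TRA-1-60) are painted on a disk 5 px larger than the nucleus, matching the
mask dilation the pipeline applies. Default amplitudes (AU, 10% CV):
DAPI 1000; TRA-1-60 500 on TRA+ cells, exactly 0 before noise on TRA−
cells; CD45 1100 for the "high" (normal leukocyte) class and 10 — one
noise SD — for the "low" class, i.e. barely above background. TRA+ cells
drawn from the high-CD45 class get a ×1.3 CD45 boost, reproducing the
healthy-donor pattern in which TRA+ cells stain *brighter* for CD45 than
the leukocyte average; this is what makes the CD45-difference measure
positive in healthy-like patients and negative in metastatic-like ones
without any change to the analysis code.

**Placement.** Nucleus centres are dart-thrown with a minimum
centre-to-centre distance of `r_i + r_j + min_gap_px`. The default gap of
14 px is deliberate: the rendered surface stain of a cell extends to about
`r + 5 + 1.5` px once smoothing and the detection threshold are accounted
for, and the gap keeps that footprint on the cell's own side of the
nearest-seed bisector. Without it, a TRA+ cell's surface signal spills
into the mask of an adjacent cell and creates false positive calls — a
genuine property of surface-marker assays at high confluency, but one that
would confound truth-recovery testing. Dense or touching layouts
(`min_gap_px` small, or explicit cell lists) are used where that regime is
itself under test (watershed splitting, the all-positive validation
slide). Impossible densities raise `PlacementError`.

**Negative controls** contain nuclei in DAPI and pure background + noise
in CD45 and TRA-1-60, emulating secondary-antibody-only staining.

**Seeds.** One master seed deterministically spawns per-patient and
per-field seeds (`numpy` `SeedSequence`); identical seeds give
byte-identical images and truth tables.

## Default cohort

57 patients mirroring the study population: 17 healthy, 26 metastatic,
13 localized, 1 progressor. Designed TRA+ fractions sit on jittered
log-spaced grids spanning each group's reported range — healthy 0–2.3%
(five patients exactly zero), metastatic 0.2–13.6%, localized 0.002–3.1% —
so a generated cohort covers its range at any seed. CD45-low propensity
among TRA+ cells (`cd45low_given_tra`) is zero for healthy, 0.2–0.75 for
metastatic (paired inversely with the TRA+ fraction so that even the
lowest-burden metastatic patient carries an expected ≥ 1 TRA+/CD45-low
cell at desk-scale cell counts), 0.03 for exactly two localized patients,
and 0.2 for the progressor.

Cohort presets trade cell numbers for runtime; sizes are package choices:

| preset | field | stained/control fields | cells/field | cells/patient |
|--------|-------|------------------------|-------------|---------------|
| full   | 512²  | 20 / 10                | ~120        | ~2400         |
| desk   | 384²  | 10 / 4                 | ~90         | ~900          |
| mini   | 224²  | 4 / 2                  | ~30         | ~120          |

The test-suite and the acceptance script use `desk` for cohort-level
experiments and full-geometry single fields (512², ~100 nuclei) for
segmentation recovery.

## Pipeline

**Preprocessing.** DAPI → float, Gaussian smoothing (σ = 1 px), background
subtraction by grey-scale top-hat: an opening with a decomposed-disk
footprint of radius 50 px (≫ nucleus radius), subtracted and clipped at 0.
The opening removes flat offsets exactly and linear shading in the
interior; the residual at the image border is bounded by
(gradient slope × footprint radius), < 1 AU under default conditions.

**Thresholds.** Both histogram thresholds are implemented from first
principles because the detection method is built on their exact behaviour.

* *Otsu*: the split minimising within-class variance, equivalently
  maximising `S₀²/w₀ + S₁²/w₁` over split points; for integer images with
  ≤ 4096 distinct values the maximisation is carried out in exact rational
  arithmetic, so results are bit-identical to exhaustive search. Ties go
  to the lowest candidate. Float images use a 256-bin histogram and return
  the best bin centre.
* *Rosin (unimodal)*: chord from the histogram's highest peak to its last
  non-empty bin; the threshold is the bin at maximal perpendicular
  distance, compared via integer cross products. Defined for
  background-dominated decaying histograms (the shape background-subtracted
  DAPI produces, where it falls at the noise/foreground elbow, below the
  Otsu value); a peak at the upper end raises `ValueError`.

Foreground is strictly `> T` everywhere.

**Nuclei.** Otsu mask → 8-connected components (4-connectivity is a
config option). Components with area strictly greater than the median
component area are candidates for splitting: markers are local maxima of
the (σ = 1-smoothed) Euclidean distance transform with a minimum
separation of 0.9 × the median-equivalent radius, and a watershed on the
negated smoothed EDT, restricted to the component, separates touching
nuclei. A candidate yielding one marker passes through unchanged. Labels
are relabelled contiguously in row-major component/marker order.

**Cell masks.** Rosin mask of the same preprocessed image, dilated
isotropically by 5 px (an EDT-based dilation whose pixel set equals a
radius-5 disk footprint — "5 px" is read as one radius-5 dilation, not
five unit dilations), united with the seed pixels. Every mask pixel takes
the label of the Euclidean-nearest seed region; distances are compared as
exact integer squares and ties go to the lowest label (deterministic). The
implementation queries a KD-tree with k = 4 and widens to k = 64 for the
rare pixels whose whole candidate set ties.

**Calibration.** Per patient, from its negative controls. Default
(`pixel` mode): the threshold is the maximum TRA-1-60 value inside any
control cell mask, so no control pixel survives it. `detection` mode — the
smallest threshold at which the full calling rule yields zero control
detections, i.e. the largest 5th-greatest per-cell value — is also
implemented; it is the weakest admissible threshold, but because it is the
maximum of an iid per-cell statistic, roughly
`n_patient_cells / n_control_cells` patient cells exceed it by order
statistics alone, producing a floor of false calls (~2–3 per patient at
default field counts) that is independent of the intensity distribution.
The pixel rule has no such leak (a false detection then needs ≥ 5
independent ~10⁻⁵ pixel events inside one cell) and reproduces healthy
samples scoring exactly 0%. A saturated control TRA channel is rejected.

**Calling and CD45.** TRA+ ⇔ ≥ 5 strictly suprathreshold pixels inside the
cell mask (`min_tra_pixels`, configurable). CD45 per cell is the mean raw
intensity in the mask; no background subtraction is applied — the CD45
staining background (pooled per-cell mean over controls) is reported
separately in the calibration record. Exposure is assumed constant across
fields and controls, so no inter-field normalisation is applied.

**Patient measures.** (1) per-field % TRA+, mean and SD over fields (SD
over n fields, i.e. population SD, matching an error bar over the imaged
areas; `pct_sd_ddof=1` switches to the sample estimator). (2) normalised
CD45 = cell mean ÷ patient's TRA− mean (so TRA− cells average exactly 1;
patients with no TRA− cells are rejected loudly — they cannot occur in
PBMC data); TRA+ cells with normalised CD45 strictly below 0.3 are
CD45-low, reported as a count and per 1000 analysed cells. (3) mean
normalised CD45 of TRA+ minus TRA− cells, computed only when the patient
has ≥ 3 TRA+ cells; excluded patients carry an explicit flag and an empty
value. Expressing both classes on the normalised scale puts measure 3 in
the same unit system as the CD45-low cutoff.

**ROC.** AUC by the Mann–Whitney identity with half-credit ties, oriented
so AUC ≥ 0.5. CI (95%) and two-sided p-value against AUC = 0.5 use the
Hanley–McNeil standard error with a normal approximation, CI clipped to
[0, 1]; the DeLong variance is available via `roc_method="delong"`. When
the SE is zero (complete separation) the p-value is reported as 0 and the
CI collapses. The default comparison plan tests measure 1 for
healthy-vs-metastatic and localized-vs-metastatic, and measure 3 for all
three group pairs; measure-3 comparisons use only included patients and
require at least two per group. No multiple-testing correction is applied
across the plan. The progressor patient is a single-sample group and is
summarised but not entered into ROC comparisons.

## What passing tests show — and what they do not

The generator emulates: field geometry and channel structure, dense round
nuclei with touching pairs on demand, additive Gaussian noise over a
linear illumination gradient, per-patient frequency spectra spanning the
reported cohort ranges, and a CD45-low subpopulation essentially confined
to the metastatic-like group. It does **not** emulate realistic optics
(PSF, chromatic shift), nuclear texture or shape irregularity, cell
clumps beyond pairwise touching, autofluorescence, bleed-through, or
staining artefacts. Recovery results therefore validate the *logic and
numerics* of the pipeline (thresholding, splitting, propagation,
calibration, bookkeeping, statistics) — not its robustness to real-slide
pathology, which would require annotated real images.

## Numerical and degenerate-input choices

* Coordinates are row-major, 0-based; pixel centres at integer positions.
* Threshold ties resolve to the lowest candidate; label-propagation ties
  to the lowest label; marker order is row-major — all outputs are
  reproducible bit-for-bit.
* Empty Otsu mask → zero-label map (not an error); empty seed map → empty
  cell map; constant rasters raise for thresholds.
* An all-zero control TRA channel calibrates to T = 0, which under the
  strict `>` rule already yields zero control detections.
* The pipeline is RNG-free; all randomness lives in the generator and is
  seed-derived.

## Known limitations

* Per-field segmentation treats fields independently; no stitching.
* The nearest-seed partition ignores intensity valleys between adjacent
  cells; at very high confluency masks can annex background or neighbour
  territory (mitigated in the generator by the placement gap, see above).
* The CD45-low cutoff (0.3) and the 5-pixel rule are taken as fixed assay
  constants, not fitted.
* Hanley–McNeil p-values are asymptotic; at the smallest group sizes in
  the default plan (n = 4 included healthy patients) they are indicative
  only, as the permutation-calibration test shows for moderate n only.
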