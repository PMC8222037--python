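# Methods

## Problem and approach

Inhaled corticosteroids such as budesonide (BUD) ionize poorly under
MALDI and are therefore hard to image directly in tissue.  On-tissue
chemical derivatization with Girard's reagent P converts the C3 ketone
into a pre-charged pyridinium hydrazone, which is detected with high
sensitivity.  Quantification on tissue then proceeds by (i) extracting
narrow-window ion images for the analyte, a structurally matched
internal standard (triamcinolone acetonide, TA, co-sprayed with the
derivatization reagent), and two marker channels; (ii) segmenting
tissue sections (endogenous heme B) and deposited calibration spots
(tiotropium added to every dilution solution); (iii) normalizing the
analyte to the internal standard per pixel; and (iv) regressing per-spot
median ratios on deposited amount, with the tissue's surfactant
(phospholipid) level as a covariate to quantify ion suppression.

`msiquant` implements this workflow as a library plus a thin CLI, and
ships a synthetic-slide generator with full ground truth so every stage
is testable without instrument data.

## Mass arithmetic

Monoisotopic masses are sums of most-abundant-isotope atomic masses
(IUPAC values via pyteomics' element table).  All ion m/z values are
electron-mass corrected:

* Girard hydrazone (single condensation, singly charged):
  `m/z = M(steroid) + M(reagent cation) − M(H2O) − m_e`.
  The shift is a constant per reagent (GirP: 134.07127 Da), a useful
  cross-check when assigning peaks.
* Protonated ions: `(M + m_proton)/z`; radical cations and pre-charged
  cations: `(M − z·m_e)/z`.

Vendor software and much of the literature label pre-charged species
"[M + H]+"; the computed values here make the distinction explicit.
Heme B is modeled as a radical cation M+•.  One known discrepancy is
retained rather than hidden: the conventional ferulic-acid lock-mass
value 195.0657 corresponds to adding a neutral hydrogen atom to
C10H10O4, whereas the protonated ion computes to 195.0652; the package
computes the protonated value and treats the 0.0005 Da difference as an
accepted convention gap (asserted within 0.001 Da).

## Ion images

A pixel's value is the sum of centroid intensities inside a closed,
symmetric window `target ± tolerance` (default tolerance 0.005 Da, the
workflow's standard).  Sum, not max, is the default aggregation — robust
when a centroid splits — and "max" is available.  A centroid lying
exactly on the window edge is included.  Unscanned raster positions are
NaN ("missing"), deliberately distinct from 0 ("scanned, nothing in the
window").  The log10 transform maps 0 to missing with a
"below detection" flag instead of pseudo-counting; ratios are always
computed on the linear scale, so the choice of pseudo-count never enters
the statistics.

Lock-mass recalibration (optional, off by default since instruments
usually apply it online) shifts each pixel's axis additively so the
ferulic-acid matrix peak lands on its reference value.  An additive
shift fully corrects a constant mass-axis offset; a *multiplicative*
ppm-scale drift is only partially corrected away from the lock mass —
a known limitation of single-point recalibration.

## Segmentation

The recipe is fixed and deterministic so results are reproducible from
parameters alone:

* Tissue: Otsu threshold on the log10 heme-B image, 3×3 binary opening,
  3×3 binary closing, 8-connected components, area filter, labels
  ordered row-major by rounded centroid (ties: larger first).  Scanned
  pixels with no heme centroid enter the Otsu histogram as a floor class
  one log-decade below the dimmest detected pixel — without them the
  histogram would contain only tissue and Otsu would split the tissue
  itself.  The opening step matters: a single chance background hit in
  the heme window can otherwise pass Otsu (with two near-point-mass
  classes, the between-class variance is flat over the gap and the
  lowest maximizing threshold is returned) and, after closing, bridge
  two adjacent sections.
* Spots: fixed threshold (default 5.6) on the log10 tiotropium image,
  interpreted on the log scale because all signals in this workflow are
  log10-transformed before analysis; then the same component/area/label
  machinery.  An empty result is a valid outcome, not an error.
* Annotation replaces manual labeling: detected spots are matched to the
  design layout (expected row/col per spot) by optimal bipartite
  assignment; two spots sharing a nearest design cell is an explicit
  ambiguity error, and under the strict policy a count mismatch names
  the missing design cells.

## Calibration model

Per calibration spot the response is the median of the per-pixel
analyte/IS ratio (median commutes with monotone transforms, so working
on the linear scale is equivalent rank-wise to subtracting logs).  The
model is ordinary least squares,

    median_ratio ~ amount_ng * C(lipid_level)

i.e. one line per surfactant level with shared structure, reporting
per-level intercept/slope with standard errors, global R², and two
suppression tests: lipid main effect (intercept) and lipid × amount
interaction (slope), at α = 0.05.

Inference uses HC3 heteroscedasticity-robust covariance.  The pixel
noise is multiplicative, so spot-summary variance grows with the
response, and classical F-tests on the slope terms are anti-conservative
in exactly that situation (empirically ~11% rejections at nominal 5% in
the generator's recovery study; HC3 restores the nominal rate).  Point
estimates are unchanged.  On a numerically perfect (noise-free) fit the
Wald statistics are 0/0; the implementation then reports p = 1 when the
effect estimates are zero at machine precision and p = 0 otherwise.

Inverse prediction is `(ratio − intercept)/slope` at the chosen lipid
level, with a first-order delta-method interval combining the
coefficient covariance and the ROI's own median sampling noise
(IQR-based).  Ratios below the intercept report 0 with a
below-calibration flag.  Spiking arithmetic assumes unit density
(1 g/mL), which reproduces the reference 14.2/7.1 μg/g tissue
concentrations from the stated surfactant-budesonide recipe.

## Synthetic slides

The generator renders rectangular tissue sections and circular
calibration spots on a 400 μm raster into centroided spectra over
m/z 185–650, with ground truth for every pixel.  Default design — the
study's quantification conditions: dilution series 0.2, 2, 5, 20,
40 ng/μL × 500 nL drops (0.1–20 ng deposited), four replicates, three
surfactant levels (0/4/8 mg/g), and an ion-suppression effect injected
as a +10% intercept shift at 8 mg/g (+5% at 4 mg/g, interpolated) with
no slope change.  The full-slide layout adds one treated sample section
and two control sections at 2.5 and 10 ng, mirroring the slide design
the workflow targets.

Signal model per pixel: expected ratio `r = α(lipid) + β·amount`; the
internal standard is emitted everywhere on tissue/spots, heme only on
tissue, tiotropium only on spots (intensity 1e7, so log10 ≈ 7 clears the
5.6 threshold comfortably), the analyte at `r × IS`.  Noise is
multiplicative lognormal, split into a shared per-pixel factor
(σ_shared = 0.30) that multiplies all channels — this is the
pixel-to-pixel ionization variability that internal-standard
normalization exists to cancel, and the package tests that it does
cancel exactly — and an independent per-channel factor (σ = 0.15) that
survives the ratio.  Noise factors have median 1, so per-spot median
ratios are unbiased for `r`; their mean exceeds `r` by the lognormal
factor `exp(σ²)`, which the noise-model test verifies analytically.
Peak positions get 2 ppm Gaussian jitter; background peaks arrive at
Poisson rate 5 per pixel, uniform in m/z; a scanned pixel never returns
an empty peak list (a one-peak noise floor is emitted if needed, since
imzML cannot encode empty spectra).

Free parameters were set by a design calculation, not by instrument
fitting: with spot radius 2.5 px (≈2 mm drop at the 400 μm raster,
~21 pixels per spot), response α = 1.0, β = 0.025 per ng and σ = 0.15,
the variance algebra gives a calibration R² ≈ 0.88 — the goodness of fit
the real on-tissue curves exhibit — and ≈0.92 analytic power to detect
the 10% intercept shift at α = 0.05 in the 5 × 4 × 3 design.  The
recovery study (200 seeds) measures slope bias ≈ 0%, power ≈ 0.95 and
false slope-effect rate ≈ 0.05.

What the generator does *not* emulate: isotope envelopes, profile
spectra, chromatographic-like spot edge effects (uniform discs by
default), desorption physics, matrix clusters, and spatially correlated
biology inside a section.  Passing tests therefore demonstrate the
correctness of the pipeline's arithmetic and statistics under the
declared noise model, not instrument-level realism.

The treated/untreated contrast is modeled by giving untreated sections
no analyte channel at all: the calibration intercept α represents
deposition/derivatization background associated with treatment and
spotting, not a universal background at the analyte m/z.  The
separation between a treated section's median raw analyte intensity and
an untreated section's (zero, measured against a 1-count floor) is
≥3 orders of magnitude, mirroring the selectivity the workflow is
designed to demonstrate.

## Determinism and reproducibility

All randomness flows from one integer seed through a single
`numpy.random.Generator` in a fixed pixel order; identical spec + seed
yields identical spectra, and the ibd binary payloads are bit-identical
after their 16-byte UUID header (the imzML standard assigns each file a
fresh UUID, so whole-file byte equality is deliberately not the
criterion — array equality and post-UUID payload equality are).  The
file pipeline writes a manifest with SHA-256 checksums of every output;
two runs with the same config and seed produce byte-identical
calibration-fit JSON.  `SpectrumGrid.pixel_size` is carried in memory
and in the run config; the imzML writer does not persist raster pitch.

## Problem sizes

The shipped recovery studies use: 200 seeds for the Monte-Carlo
calibration study (60 spots each, 34×122 px slides), 20 seeds for
segmentation/spot-recovery (64×84 px slides, 4 sections + 20 spots),
1000 random mini-grids for the extraction oracle equivalence, and
10⁴ pixels for the noise-model mean check.  These sizes give binomial /
Monte-Carlo error comfortably below the asserted margins (e.g. the
false-positive envelope is nominal 0.05 + 2.58·√(0.05·0.95/200)).

## Known limitations

* Single condensation, singly charged derivatives only; no
  isotope-pattern simulation.
* Profile-mode imzML is rejected, not peak-picked.
* Lock-mass correction is additive (single-point).
* OLS on spot medians; no weighted regression or LOD/LOQ formalism.
* Inverse-prediction intervals are first-order (delta method), not
  profile-likelihood.
* Tissue inverse prediction applies the spot-derived calibration to
  embedded analyte; spotting-vs-embedding recovery differences are a
  real-world caveat the synthetic model does not attempt to capture.
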