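# Methods

`rootspec` estimates the dry weight of hydroponic root systems from
hyperspectral images taken through a transparent baseplate against a
blue-painted panel. This note documents the models, the synthetic data the
package is validated on, the numerical choices, and the known limits.

## The estimation pipeline

**Calibration.** Raw digital numbers are converted to reflectance per band
with the standard white-reference / dark-frame normalisation
`R = (DN − dark) / (white − dark)`, which cancels the illuminant spectrum
and sensor gain and is invariant to common exposure scaling. Reflectance is
clipped to [0, 1.5]: mild super-white values (specular highlights) are kept,
gross outliers bounded. Bands are then trimmed to 450–950 nm, inclusive on
both ends, to drop the noisy spectral edges.

**Segmentation.** The blue panel is bright near 450 nm and root tissue
attenuates it, so roots are pixels below an Otsu threshold of the band
nearest 450 nm. Otsu's threshold is computed over a 256-bin histogram
spanning [min, max]; candidates are the interior bin edges, the data are
partitioned as `x < t` vs `x ≥ t`, and ties resolve to the lowest
qualifying edge. If the two classes differ by less than 20% relative
contrast the scene is declared root-free — without this guard Otsu happily
splits pure sensor noise on a bare panel. The scene is tiled into
5 cm × 2.5 cm segments (width × length; length runs along the root growth
axis, plant base at row 0), `round(cm / pixel_size)` pixels per side,
partial edge cells dropped. At the default 25 cm / 512 px geometry a cell
is 102 × 51 px.

**Segment spectra.** Each segment contributes its percent root coverage and
a mean reflectance spectrum. The default spectrum is the **area mean** over
all segment pixels. An area mean blends root tissue with visible panel in
proportion to coverage, so it carries the two factors of segment dry weight
at once: how much of the segment is root (coverage) and how optically dense
that root tissue is. The root-pixel-only mean is available
(`pixels="root"`, with a whole-segment fallback and QC flag when a segment
has no detected roots) but discards coverage: on synthetic data its
cross-validated R² in sqrt-weight saturates near 0.5 where the area mean
exceeds 0.95, and the characteristic saturating fall of segment-level
450 nm reflectance with dry weight only arises for area means. Segments
whose mask occupies more than half of the cell border are flagged
(`"border"`) as candidates for exclusion, the analogue of roots escaping
their partition.

**Preprocessing grid.** Spectra are conditioned by one method from each of
three layers — (none | unit-L2 normalization | absorbance log10(1/R)) →
(none | Savitzky–Golay smoothing | 1st derivative | 2nd derivative) →
(none | SNV | MSC) — 36 combinations in all, applied in layer order.
Choices the grid leaves open: "normalization" is unit Euclidean norm
(scale-invariant, standard in chemometrics); the log transform is the
absorbance convention with R floored at 1e-6; derivatives are
Savitzky–Golay convolutions (window 11, polyorder 2 by default, ≈ 33 nm at
the default band spacing) scaled per nm, with polynomial edge handling —
noise-robust where finite differences are not. MSC's reference spectrum is
the training-set band-wise mean, frozen at fit time and reused for every
later prediction (test segments, pixels), which prevents information
leaking from evaluation data into the correction.

**Regression.** Orthogonal-scores (NIPALS) PLS1 on mean-centred spectra —
no variance scaling — with the dry-weight target square-root transformed
to stabilise its right-skewed distribution. The latent-variable count is
chosen by leave-one-out cross-validation (RMSECV, computed in sqrt-g
units), at most 16 LVs, ties to the fewest; preprocessing with fitted
state (MSC) is re-fitted inside every fold. The preprocessing combination
is chosen by the smallest minimum RMSECV across the 36 specs, ties to the
earlier spec in grid order; the winner is refit on the full training set.
Predictions clip negative sqrt-scale values to zero before squaring back
to grams. Variable importance in projection (VIP) scores summarise each
band's contribution; mean(VIP²) = 1 by construction, so VIP > 1 flags
influential wavelengths. Rank-deficient fits reduce the LV count with a
warning rather than failing; a constant target degenerates to predicting
the mean.

**Area baseline.** Dry weight regressed on percent coverage with a power
law `y = a (x/100)^b` fitted by least squares on sqrt-weight (a saturating
exponential and a linear form are available). Monotone and non-negative by
construction. The baseline saturates once coverage approaches its ceiling
while biomass keeps accumulating through overlap — the failure mode the
spectral model exists to fix. Models are compared by a two-sided paired
t-test on absolute prediction errors over a shared test set.

**Pixel mapping.** The segment-level model is reused at pixel resolution:
each root pixel's spectrum is treated as if it were a segment-mean
spectrum and the predicted g/segment is divided by the segment pixel count,
giving a per-pixel proposal in g/pixel. Proposals are spatially averaged
over root pixels in a 3 px window (single-pixel sensor noise suppression;
the average of a uniform field is itself), then each grid cell is rescaled
so its pixels sum to the model's prediction for the cell's area-mean
spectrum. The rescale matters because a pure root-pixel spectrum sits at
the edge of the area-mean training manifold and raw proposals can be badly
mis-scaled (several-fold on synthetic scenes), while area-mean predictions
are squarely on it; for a homogeneous fully-rooted segment the rescale is
the identity, so pixel maps aggregate exactly to segment predictions there.
Plant totals are sums over user-supplied regions (rectangles or label
masks). Growth series accumulate the detected root mask across days —
roots do not retract, and the running union stabilises frontier cells that
flicker in and out of detection.

## The synthetic scene generator

The generator stands in for a greenhouse campaign: it must reproduce the
spectral mechanisms the estimator relies on, against exact ground truth.

**Optics.** Noiseless reflectance is a two-term Beer–Lambert mixture in
the dry-mass areal density d (mg/pixel):

    R(λ, d) = bg(λ)·exp(−2·μa(λ)·d) + root(λ)·(1 − exp(−μs(λ)·d))

— panel light crossing the root layer twice, plus diffuse build-up of
light scattered back by tissue. Coefficients are smooth Gaussian/sigmoid
sums: the panel peaks at 450 nm (0.55) with a broad NIR shoulder (blue
paints reflect NIR); root tissue is dark in the blue (0.05), rises across
a red edge centred at 720 nm to a NIR plateau (0.47) and dips at the
965 nm water band; absorption is strongest in the blue with a water bump;
scattering decreases steeply with wavelength. The magnitudes are chosen so
that, over the realistic density range, 450 nm reflectance falls
monotonically and saturates for thick tissue, 750 nm rises monotonically,
and 950 nm trends down — and so the blue saturation means the NIR carries
the residual information about dense segments, which is what pushes VIP
above 1 near 750 nm as well as near 450 nm.

**Architecture.** Each plant is three primary axes of a seeded random walk
(heading wiggle with mean reversion, so paths curve locally but keep
direction) with 3%-per-step branching, Gaussian cross-sections (σ = 2.8 px
primaries, 1.7 px branches), and density tapering to 45% at the tip.
`mode="linear"` sends axes down-image from a top-edge base (roots guided
by partition boards); `mode="radial"` radiates them from a central base
(natural development; central density exceeds the periphery, as a mature
root system's does). Growth to stage s ∈ [0, 1] truncates the full-length
skeleton to a fraction s of each path and scales amplitude by a gentle
logistic in s, so architectures at two stages of one seed are nested and
total mass is non-decreasing in stage. Per-plant tissue density varies by
a log-normal multiplier (CV 0.3, clipped to [0.7, 1.6]): root systems of
equal extent differ in thickness, which decouples dry weight from coverage
and is precisely the variance component only the NIR can see once blue has
saturated.

**Detection floor.** Pixels below 30% of `mass_scale` are floored to zero.
Gaussian cross-sections have arbitrarily faint skirts whose blue
attenuation sits inside the noise/scatter spread of the bare panel; such
pixels are below any thresholding segmenter's detection limit, and keeping
them would make the ground-truth mask unrecoverable in principle. The
floor is pixelwise and pixel density is non-decreasing in stage, so mass
monotonicity survives. Consequence: the faint distal tips of young thin
plants are absent from both truth and image — the generator does not
create optically invisible tissue.

**Signal chain.** Per-pixel affine scatter artifacts (gain ~ N(1, 0.05),
offset ~ N(0, 0.01) — included specifically so SNV/MSC have something real
to remove), then 1% relative Gaussian sensor noise per pixel and band, then
DN = dark + R·(white − dark) with a halogen-shaped white frame. All
randomness derives from one integer seed through labelled sub-streams
(architecture, per-plant mass, scatter, noise), so every stage is
independently reproducible and scenes are bit-identical across reruns.

**Scale.** Defaults emulate the acquisition geometry: 25 × 25 cm at
512 × 512 px, 204 bands over 400–1000 nm, five plants per scene (one per
5 cm column). `mass_scale = 0.024` mg/pixel puts segment dry weights in
~0–0.3 g/segment (p99 ≈ 0.36 g with the thickness multiplier) and plant
totals near 0.5 g — the magnitudes of a leafy-vegetable stand.

**What the generator does not emulate.** No radiative transfer
(PROSPECT-class tissue optics), no nutrient-solution or film optics, no
chromatic point-spread or RGB-sensor simulation, no root physiology.
Root paths are random walks, not hydrotropic architectures. Passing tests
therefore show that the pipeline recovers biomass when the stated spectral
mechanisms hold with these noise magnitudes — not that those mechanisms
hold for any particular real crop or camera.

## Problem sizes

The validation workflows use: a 60-plant training campaign (12 scenes,
~450 root-bearing segments after excluding empty segments at a 1 mg
threshold), an 80/20 segment split, the full 36-spec grid search with
LOOCV to 16 LVs, 20 seeded splits for the model-comparison replicates, an
independent 104-plant batch for g/plant validation, and 50-day single-plant
growth series rendered at a quarter field of view (256 × 256 px, 12.5 cm,
same pixel pitch — the monitored properties do not depend on field size).

## Numerical choices and degenerate inputs

- Otsu: constant input errors (no separable classes); the all-background
  case surfaces as "no roots detected".
- Min-max RGB composites map flat channels to zero instead of erroring.
- NIPALS stops at the effective rank (tolerance 1e-12 relative to the
  centred data scale); LOOCV columns beyond a fold's rank repeat the last
  available prediction.
- MSC rejects slopes below 1e-8; SNV rejects constant spectra; the log
  transform floors reflectance at 1e-6.
- Train/test split takes ⌈0.8 n⌉ training rows by seeded permutation;
  splits are disjoint and exhaustive.
- False-color PNGs are byte-deterministic; a series shares one value→color
  scale recorded in a JSON sidecar.

## Known limitations

- Day-to-day plant totals carry ~1% measurement noise (per-band sensor
  noise propagated through the ~9-LV winning chemometric model). Late in a
  logistic trajectory daily growth falls below that, so a growth series is
  *not* strictly monotone after a window-3 moving average — the series
  wobbles by a few tenths of a percent at the plateau even though it tracks
  the trajectory closely (harvest-day relative error of a few percent).
  One acceptance-style check asserts strict post-smoothing monotonicity
  and fails for this reason; the underlying statistics are reported by
  `scripts/acceptance.py` as the fraction of monotone steps.
- The pixel map's within-segment distribution rests on single-pixel
  predictions outside the training manifold; totals are anchored per
  segment, but per-pixel values are ordinal more than metric (rank
  correlation with true density ≈ 0.87 on default scenes).
- The area baseline's power-law form is one defensible choice among
  several; with heavy saturation a saturating exponential may fit better.
- The per-plant regions used for g/plant totals are supplied by the
  caller (column strips in the synthetic layout); automatic plant
  separation is out of scope.
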