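# rootspec

Non-destructive estimation of root dry weight from hyperspectral images of
hydroponic root systems.

Root biomass is a central indicator of crop status, but roots are normally
invisible; weighing them is destructive and ends the experiment. When a
nutrient-film hydroponic bed is fitted with a transparent baseplate and a
blue-painted panel, the whole root system can be imaged from below — and a
hyperspectral camera turns those images into quantitative biomass maps.
`rootspec` implements that pipeline for researchers in plant phenotyping:
radiometric calibration, root segmentation, chemometric preprocessing,
partial least squares regression with wavelength-importance analysis, an
area-coverage baseline, and pixel-level biomass mapping over time. A
synthetic scene generator with exact per-pixel ground truth makes the whole
chain testable end to end.

## The model

Segments of the root image (5 × 2.5 cm tiles, the unit whose dry weight is
measured at harvest) contribute a mean reflectance spectrum **x** over
450–950 nm. Dry weight y (g/segment) is modelled by orthogonal-scores PLS1
on the square-root-transformed target,

    √y = (x − x̄)ᵀ b + q̄ ,

with the latent-variable count A ≤ 16 chosen by leave-one-out
cross-validation (minimum RMSECV) and the spectra conditioned by the best
of 36 preprocessing combinations — one method from each of three layers:

| layer 1 | layer 2 | layer 3 |
|---|---|---|
| none | none | none |
| normalization (unit L2) | Savitzky–Golay smoothing | SNV |
| log absorbance log10(1/R) | 1st derivative | MSC |
| | 2nd derivative | |

Variable importance in projection (VIP) scores, normalised so
mean(VIP²) = 1, identify the wavelengths driving the fit: the blue panel
contrast near 450 nm (light returning from the background dims as roots
overlap) and tissue scattering near 750 nm (NIR reflectance rises with
biomass even after the blue has saturated). Two spectral mechanisms, two
VIP peaks. Accuracy is reported as R², RMSE and MAE, against an
area-coverage power-law baseline y = a·(coverage/100)^b, with paired
t-tests on absolute errors.

Because a fitted model is linear in the preprocessed spectrum, it can be
applied to individual pixels: each root pixel is scored as if it were a
segment mean, scaled to g/pixel, and anchored so segment totals match —
yielding false-color biomass maps, per-plant totals (g/plant), and daily
growth curves.

## Worked example

`examples/04_train_and_evaluate.py` simulates a 60-plant campaign,
grid-searches the 36 preprocessing combinations and evaluates on a held-out
20% split:

```
476 segments -> 381 train / 95 test
best preprocessing: log/savgol/snv with 9 latent variables (RMSECV 0.0104 sqrt-g)
model               R2      RMSE       MAE     n  (g/segment)
plsr             0.970    0.0178    0.0069    95
area             0.676    0.0581    0.0414    95
paired t-test |err plsr| vs |err area|: t = -8.327, df = 94, p = 6.539e-13
VIP near 450 nm: max 2.83
VIP near 750 nm: max 1.15
```

Read: the spectral model explains 97% of the held-out variance in segment
dry weight with an error under 0.02 g/segment, while the coverage baseline
saturates (R² 0.68) once segments fill with overlapping roots — a
difference the paired t-test calls decisive — and VIP exceeds the
importance threshold of 1 at both mechanistic wavelengths. The other
examples cover scene simulation and calibration (01), segmentation and
feature extraction (02), the preprocessing grid (03), and pixel-level
mapping plus a 20-day growth series (05).

A thin CLI wraps the same library calls:

```bash
rootspec simulate --out scene/ --seed 4 --stage 0.8
rootspec calibrate --raw scene/ --out cube
rootspec segment --cube cube --out segments.csv
rootspec train --segments segments.csv --out model.json --ranking ranking.csv
rootspec demo --seed 1 --out demo_out/
```

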