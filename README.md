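# sscmap

Shape-aware hyperspectral mapping of fruit soluble-solids content (SSC,
Brix%) with a pixel-wise imaging-reliability index.

Curved fruit distorts near-infrared reflectance: pixel intensity falls with
surface tilt (Lambertian cosine) and with distance to the source and lens
(inverse square). `sscmap` corrects raw hyperspectral cubes for both
effects, calibrates PLS regression models on region-of-interest (ROI)
averaged spectra, applies them pixel-wise to produce SSC maps, and — because
pixel spectra can drift far from the calibration cloud even when global
accuracy metrics look fine — scores every pixel's squared Mahalanobis
distance in PLS score space against a chi-square threshold at k-sigma
coverage. The fraction of inlier pixels is the map's reliability index.

Since no real acquisition data ships with the package, a phantom module
generates synthetic strawberry-like scenes with known ground truth (true
reflectance with SSC-coupled absorption features, apex-to-base Brix
gradient, achene speckles, ellipsoidal height field) by forward-applying
exactly the distortions the correction chain inverts.

## Modules

| module        | what it does |
|---------------|--------------|
| `phantom`     | synthetic scenes + reference Brix tables, batch generation, scene I/O |
| `geometry`    | reflectance calibration, height / angle / combined corrections, white-stack interpolation, height-map alignment |
| `roi`         | background threshold → per-pixel PC1 score → Otsu binarization → flesh mask; section-mean spectra |
| `preprocess`  | the 8-pattern battery: none, smoothing, 1st/2nd Savitzky–Golay derivative (window 9, polyorder 2), SNV and SNV combinations |
| `plsr`        | NIPALS PLS1, SSC-stratified 7:3 split, fruit-level 5-fold CV, one-standard-error LV selection, the 4×8 = 32-configuration sweep |
| `reliability` | score projection T = (X − x̄)W*, manifold fit (μ, Σ, τ = χ²_A at α = erf(k/√2)), D² maps, reliability index, k-sensitivity |
| `imaging`     | pixel-wise SSC maps, section imaging means, r\*, line-scan and rotation-scan 3D fusion, ASCII PLY export |
| `envi`        | minimal ENVI-convention cube reader/writer (BSQ float32 + text header) |
| `cli`         | `sscmap` command with per-stage subcommands and an end-to-end pipeline |

## CLI

```bash
# generate a 6-fruit synthetic batch
sscmap phantom --n-fruits 6 --seed 3 --out runs/data

# correct one scene and segment its flesh ROI
sscmap correct --scene-dir runs/data/fruit-000 --mode height_angle --out runs/corrected
sscmap roi --cube runs/corrected --preset preset_linescan --out runs/flesh.csv

# the full 32-configuration sweep, then compare the two selection rules
sscmap sweep --data-dir runs/data --seed 3 --out runs/sweep.csv
sscmap report --sweep-csv runs/sweep.csv

# train one configuration, score per-sample reliability, fuse a 3D cloud
sscmap train --data-dir runs/data --mode height --pattern snv --out runs/model.json
sscmap reliability --data-dir runs/data --model runs/model.json --k 3
sscmap fuse --map runs/map.csv --height runs/data/fruit-000/height.csv --out runs/cloud.ply

# everything at once
sscmap pipeline --n-fruits 8 --seed 1 --out runs/full
```

Phantom/pipeline configs are flat `key = value` files (`grid_shape = 48x48`,
`n_bands = 60`, `noise_sd = 10.0`, ...). Every run writes a `manifest.json`
with the seed and file checksums.

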