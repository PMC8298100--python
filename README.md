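# vesiquant

Quantitative analysis toolkit for live-cell studies of intracellular
nanovesicle trafficking. It implements, as a tested reusable package, the
full measurement stack of such a study:

- **`vesiquant.stvariance`** — spatiotemporal variance scoring of time-lapse
  movies: per-frame mean normalization, per-pixel temporal variance over
  ROIs, pooled per-cell score. Distinguishes association with fast-moving
  subresolution vesicles from diffuse localization.
- **`vesiquant.mito`** — mitochondrial aggregation scoring after vesicle
  capture: segmentation, per-object area/perimeter, circularity
  `4*pi*A/P^2`, per-cell median over objects > 0.2 µm².
- **`vesiquant.screen`** — vesicle-capture screen statistics: per-cell
  F_post/F_pre mitochondrial intensity ratios, Dunnett many-to-one tests,
  BCa bootstrap effect-size intervals, z-scored screen matrices,
  hierarchical clustering and marker-set membership classes.
- **`vesiquant.migration`** — 2D migration track statistics: speeds,
  cumulative distance, directionality ratio, time-averaged MSD, direction
  autocorrelation, turning angles, fastest 25-µm segment, and
  replicate-aware superplot summaries (t test / Dunnett on experiment
  means). Reads Fiji Manual Tracking exports and a native tidy dialect.
- **`vesiquant.shape`** — cell-outline descriptors from closed polygons:
  exact area/perimeter/moments, equivalent-ellipse axes, mirror symmetry
  about the major axis (polygon clipping), convexity metrics, centroid
  distances.
- **`vesiquant.assays`** — invasion depth fraction (≥ 45 µm) with
  control normalization, liposome-binding densitometry correction, and
  the 2×2 amplification co-occurrence statistic (log2 odds ratio +
  Fisher exact).
- **`vesiquant.synth`** — synthetic-data generators for every input:
  diffusing-puncta movies (Gaussian PSF, Brownian walk, periodic wrap),
  network/aggregated mitochondrial masks, persistent-random-walk tracks
  with per-experiment effects, perturbed-ellipse contours with tunable
  asymmetry, and screen measurement tables with planted effect sizes.
  Everything is bit-reproducible for a fixed seed, so the whole pipeline
  runs without any external data.

## CLI

The `vesiquant` entry point exposes one subcommand per stage:

```sh
# generate synthetic inputs from a config file
cat > movie.yaml <<EOF
kind: movie
params: {frames: 30, field_size: [128, 128], diffusion_coeff: 0.5}
EOF
vesiquant simulate --config movie.yaml --seed 1 --out movie.tif

# spatiotemporal variance (5 auto-selected 20x20 ROIs by default)
vesiquant stvar movie.tif --roi-size 20 --n-roi 5 --out scores.csv

# mitochondrial aggregation from a (post-rerouting) image
vesiquant mito mask.tif --pixel-size 0.065 --out mito.csv

# screen statistics from a tidy measurement table
vesiquant screen screen.csv --control-label control --n-boot 100000 \
    --seed 1 --out-dir screen_out/

# migration statistics from Manual Tracking exports or tidy tables
vesiquant migrate tracks.csv --frame-interval 10 --pixel-size 0.32 \
    --out-dir migrate_out/

# shape descriptors, invasion, liposome binding, co-occurrence
vesiquant shape contours.csv --out shape.csv
vesiquant invade profiles.csv --control siCtrl --out invasion.csv
vesiquant liposome gel.csv --efficiencies eff.yaml --out binding.csv
vesiquant cooccur --n-total 398 --n-a 29 --n-b 20 --n-ab 7
```

Simulator config kinds: `movie`, `mito_masks`, `tracks`, `contours`,
`screen`; `params` maps directly onto the corresponding `*Params`
dataclass in `vesiquant.synth` (`--seed` overrides `params.seed`).

## Conventions

- Units: µm and minutes for tracks/contours, seconds for movie frame
  intervals; pixel sizes in µm/px. 0-based, half-open pixel indexing.
- Temporal variance uses the unbiased (T−1) estimator by default
  (`ddof` switchable); per-frame normalization divides by the whole-frame
  mean.
- The mask perimeter estimator is a smoothed marching-squares contour
  length (window 3), pinned by disc/square accuracy tests.
- Dunnett uses pooled variance and the equicorrelated multivariate-t
  adjustment (single-comparison case computed exactly as a pooled t test).
- BCa intervals resample both arms independently; acceleration comes from
  the pooled per-arm jackknife.
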