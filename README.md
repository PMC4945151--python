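# borderstereo

Line-intercept stereology of fiber confinement at cortical functional
borders, exercised end-to-end on a synthetic generator of
boundary-confined fiber morphologies.

The package quantifies how filamentous processes (astrocyte-like
arbors) respect planar region borders, the way classical barrel-field /
areal-border studies do it: oriented test lines are placed on and
around borders, fiber crossings are counted, perpendicular density
bands profile the drop across a border, and a small statistical battery
(pooled t, log-ratio ANOVA + Tukey, Pearson r) runs on the pooled
tables.  Because no raw tracing data are available for such studies,
the package ships a first-class synthetic module: labeled region
mosaics (barrel core/septum grids, a disc in a surround, laminar
strips, periodic blob mosaics), persistent-random-walk arbors whose
growth terminates at borders with a tunable crossing probability
`p_cross`, border-indifferent capillary segment processes, shared
landmark points for rigid alignment, and section-thickness thinning.

The stereological bridge is the isotropic line-intercept relation
`E[crossings] = 2 L rho / pi`, inverted to calibrate per-class fiber
length densities to target per-line crossing means.

## Layout

- `borderstereo.core` — planar domain types (`RegionMap`, `CurveSet`,
  `MeasurementLine`), µm coordinates, x right / y up.
- `borderstereo.synthetic` — region layouts, arbor growth with border
  confinement, capillary processes, thinning, Buffon calibration,
  optional rasterization.
- `borderstereo.geometry` — border extraction with tangents, septal/core
  line matrices, offset lines, blob lines, density bands, landmark
  rigid/similarity registration.
- `borderstereo.crossings` — exact segment-crossing counts (side-change
  rule), band density profiles, percent drop, septa/core ratios,
  paired series for correlation.
- `borderstereo.stats` — pooled two-sample t, one-way ANOVA on log
  ratios with Tukey HSD, Pearson r, group summaries.
- `borderstereo.pipeline` — six experiment presets
  (`barrel_layer4`, `barrel_layer3_5`, `auditory_A1A2`,
  `human_IIIaIIIb`, `human_blobs`, `thickness_4v8`), scene simulation,
  reports, confinement sweep.  Calibration constants live in
  `src/borderstereo/calibration.yaml`.
- `borderstereo.cli` — `generate` / `measure` / `stats` / `run` /
  `sweep` subcommands.

Scenes serialize as GeoJSON FeatureCollections (regions as Polygons,
fibers as LineStrings, landmarks as Points), crossing tables as CSV,
reports as JSON, rasters as multi-page TIFF.

## CLI

```sh
# generate a synthetic scene and write it as GeoJSON
borderstereo generate --preset barrel_layer4 --seed 1 --out-dir out/

# place this preset's measurement lines on a stored scene and count
borderstereo measure --preset barrel_layer4 \
    --scene out/barrel_layer4_scene0.geojson --out-dir out/

# statistics on a crossing table
borderstereo stats --table out/crossings.csv --out-dir out/

# a full preset end-to-end (scenes -> lines -> counts -> tests -> report)
borderstereo run --preset auditory_A1A2 --seed 1 --out-dir out/

# septa/core ratio as a function of the border crossing probability
borderstereo sweep --grid 0,0.25,0.5,0.75,1.0 --replicates 50 --seed 1 --out-dir out/
```

Every command is deterministic given `--seed`; components draw from
independent named RNG streams, so adding one component never perturbs
the draws of another.

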