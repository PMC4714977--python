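# polarprof

Quantitative single-cell image analysis for asymmetrically dividing
bacteria, built around the question of how *Bacillus subtilis* confines a
regulatory protein — and the transcription factor it activates — to the
small daughter cell (the forespore) created by polar division.

During sporulation, the membrane phosphatase SpoIIE moves from the polar
septum to the adjacent cell pole, escapes proteolysis there, and activates
σ^F only in the forespore. Testing that model quantitatively requires a
chain of image measurements that this package implements as a reusable,
fully tested pipeline:

- **synthgen** — a synthetic-micrograph generator: rod-shaped cells
  (straight capsules, 2–5 µm × 0.8–1 µm) with membrane-shell staining,
  optional polar or midcell septa, five reporter localization classes
  (uniform cytoplasmic, uniform membrane, divisome ring, polar cap,
  compartment-restricted membrane), Gaussian PSF, Poisson + Gaussian
  camera noise, and complete ground truth. Every downstream stage is
  validated against planted values, so no external image data is needed.
- **segment** — cell masks from the phase-like channel, with optional
  subtraction of the membrane channel so chained cells split at their
  shared septum; principal-axis centerline meshes (length, width, axial
  coordinate) per cell.
- **axialprofile** — the core observable: per-cell profiles of
  reporter ÷ membrane-stain signal in bins along the long axis
  (the membrane stain corrects for local membrane area), septum detection
  from the membrane profile, orientation of each divided cell with the
  forespore pole at the origin, population-average profiles on an absolute
  µm grid, random-pole control averages, and kymograph extraction.
- **compartment_stats** — per-cell compartmentalization calls from the
  forespore/mother density ratio ρ (ρ ≥ 2 forespore-specific, ρ ≤ 0.5
  mother-cell, otherwise both; inactive below an activity floor), and the
  minicell enrichment rule: a cell is "enriched" when its mean reporter
  intensity exceeds the population mean by more than two population
  standard deviations.
- **kinetics** — least-squares fits of N(t) = N₀·e^(−kt) (half-life
  t½ = ln2/k) for translation-shutoff chases, and of
  v = V_max·S/(K_m + S) for multiple-turnover phosphatase assays, with
  grid-search oracles in the test suite and optional bootstrap errors.
- **pipeline / CLI** — one-config orchestration
  (simulate → segment → profile → classify → summarize) with deterministic,
  checksummed outputs; `polarprof` exposes `simulate`, `segment`,
  `profile`, `enrich`, `fit-decay`, `fit-mm`, and `run` subcommands.

The `analysis/` scripts are thin narrative drivers over the library that
reproduce the shape of the study's main analyses on synthetic data.

## Worked example

Simulate a sporulating population in which 2% of divided cells fail to
confine the reporter to the forespore, then run the full pipeline:

```python
from polarprof import synthgen as sg
from polarprof.pipeline import analyze_scene

spec = sg.PopulationSpec(n_cells=300, mis_fraction=0.02, seed=17)
scene, truth = sg.simulate_population(spec)
res = analyze_scene(scene.channels, scene.pixel_size_um)
print(res["summary"]["categories"])
print("mis-compartmentalized: "
      f"{res['summary']['miscompartmentalized_pct']:.1f}%")
```

Output:

```
                        count    percent
forespore_specific        296  98.666667
mother_cell                 0   0.000000
both                        4   1.333333
inactive                    0   0.000000
predivisional_active        0   0.000000
predivisional_inactive      0   0.000000
mis-compartmentalized: 1.3%
```

All 300 cells are segmented, their septa detected from the membrane
channel, each cell oriented with the forespore pole at s = 0, and the
reporter classified by the forespore/mother density ratio. At this seed
the 2% mis-compartmentalization rate realized as 4 planted cells, and all
4 are recovered (ratio ≈ 1 falls in the "both" band) with no false calls.
The same run builds the population-average localization profile —
mean ± SEM of the membrane-normalized ratio versus distance from the
forespore pole — which for this forespore-restricted reporter peaks at
≈4.6× the cell mean near the pole and falls to ≈0.24× beyond the septum.

The equivalent file-based run is:

```sh
polarprof run --config experiment.yaml --seed 17 --out results/run1
```

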