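# foramshift

Analysis of fossil plankton assemblage change across the last
deglaciation: how marine zooplankton communities reorganized as the
climate warmed out of the last ice age, and whether the assemblages that
emerged in the current warm period still have counterparts in the
glacial ocean.

The package is built for sample-by-species census tables of planktonic
foraminifera — calcifying zooplankton with an excellent deep-sea fossil
record — with per-sample metadata (site, latitude, longitude, calibrated
age in kyr BP; 0 ka = 1950 CE). It targets the study design of
North Atlantic time-series compilations: ~25 sites along the latitudinal
gradient, 0–24 ka at sub-millennial resolution, 41 harmonized species,
and a 19–23 ka Last Glacial Maximum (LGM) reference pool. A bundled
synthetic generator produces data with the same structure (plus ground
truth), so every estimator is testable end to end; real and synthetic
data share one CSV schema and are interchangeable.

## What it computes

- **Compositional dissimilarity.** Morisita-Horn index between
  compositions x, y: `C = 1 − 2Σxᵢyᵢ / (Σxᵢ² + Σyᵢ²)`, 0 = identical,
  1 = no shared species. The full pairwise matrix is reduced by PCA
  (rows as feature vectors) and the first three axes are mapped to RGB
  (PC1 blue, PC2 red, PC3 green), then gridded on a 1 kyr × 2.5°
  time–latitude (Hovmöller) grid.
- **Per-site trends.** PC1 of each site's composition matrix, polarity
  aligned across sites, interpolated at 0.5 kyr over 2.5–23 ka, stacked
  with a LOESS fit (span 0.75, local quadratic) and 95% band, and
  compared against a temperature forcing curve.
- **Gains/losses rates.** Identity-aware species gains and losses of
  every sample against the oldest sample of its series, normalized by
  the pooled species set, plus OLS rates (per kyr, positive = increase
  towards the present) for richness, gains and losses.
- **No-analogue detection.** Distance of every sample to its nearest
  LGM analogue, judged against a self-referential null: the 95th/99th
  percentile of nearest (and 2nd-, 3rd-nearest) non-self analogue
  distances *within* the LGM reference. Strictly exceeding the
  threshold flags an assemblage as having no glacial analogue.
- **Latitudinal diversity gradient.** Richness and Shannon entropy
  `H = −Σ pᵢ log pᵢ` per sample, per-millennium LOESS gradients against
  latitude, and anomalies relative to each site's LGM mean, gridded.

See `docs/methods.md` for the full account of the models, parameter
defaults and numerical choices.

## Worked example

```python
from foramshift import (simulate_dataset, DatasetConfig, null_thresholds,
                        classify, series_pc1, align_polarity,
                        interpolate_trend, stack_loess, compare_to_forcing,
                        site_rates)

series, reference, truth = simulate_dataset(
    DatasetConfig(secondary_enabled=True), seed=1)
thr = null_thresholds(reference).get(percentile=99, rank=1)
samples = [s for sr in series for s in sr.samples]
result = classify(samples, reference, thr)

trends = align_polarity([series_pc1(sr) for sr in series])
stacked = stack_loess([interpolate_trend(t) for t in trends])
comp = compare_to_forcing(stacked, truth.forcing)
```

printing the pieces gives:

```
25 sites, 1025 samples, 175 glacial reference samples
99th-percentile nearest-analogue null threshold: 0.051
no-analogue flagged fraction: 15.2%
stacked PC1 trend vs forcing correlation: 0.979
site SYN-19 (51.5 N): richness +0.717/kyr, gains +0.0250/kyr, losses +0.0022/kyr
```

Reading: coeval glacial assemblages differ from their nearest analogue
by at most ~0.05 just by chance, so that is the novelty threshold.
With the Holocene-only secondary driver switched on at mid-latitude
sites, 15% of all site–age samples exceed it — the driver's footprint
(with it off, the rate sits at the nominal ~1–3% false-positive level).
The stacked compositional trend tracks the temperature forcing at
r ≈ 0.98, and the example site at 51.5° N gains species towards the
present (+0.7 species/kyr) with colonizations outpacing losses — the
warming-driven poleward-expansion signature the rate estimators are
designed to expose.

The same chain runs from the shell, driven by one TOML config:

```
foramshift all --config run.toml
foramshift simulate --seed 7 --out outdir
foramshift no-analogue --input samples.csv --percentile 99 --rank 1 --out outdir
```

Each run writes diff-able CSVs plus `manifest.json` with the seed and a
SHA-256 of every artifact; identical config + seed reproduces identical
bytes. Real census tables use the schema
`site_id, latitude, longitude, age_ka, <taxon>, ...` with counts,
percentages or proportions (declared by a flag).

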