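# Methods

`foramshift` analyses sample-by-species census tables of planktonic
foraminifera (or any comparable community census data) with per-sample
metadata: site, latitude, longitude and calibrated age in kyr BP
(0 ka = 1950 CE). This note documents the models and procedures, the
parameters that matter, the synthetic data generator, and the numerical
choices made where the design was genuinely open.

## Harmonized taxonomy

All computations run on a fixed, ordered list of 41 canonical taxa.
Input tables may report any subset of taxa, under source labels covered
by merge rules; merged columns are summed (total abundance is conserved)
and unreported taxa are zero — an unreported species is treated as
absent, not missing. Two merges reflect common reporting practice: the
*Globigerinoides ruber* chromotypes are combined into one taxon, and
P/D intergrades are assigned to *Neogloboquadrina incompta*. Unknown
labels are a hard error by default (`on_unknown="drop"` discards them
with a warning); silent misassignment would corrupt every identity-aware
statistic downstream. Tables may carry counts, percentages (row sums
must lie in [99, 101]) or proportions; a flag declares which, and
everything is renormalized to proportions before analysis.

## Compositional dissimilarity

Dissimilarity between two compositions x, y (relative abundances) is the
Morisita-Horn index

    C = 1 − 2 Σᵢ xᵢyᵢ / (Σᵢ xᵢ² + Σᵢ yᵢ²)  ∈ [0, 1],

0 for identical compositions, 1 for disjoint species sets. The index is
abundance-weighted and dominated by common species, which makes it
robust to unequal census sizes and to under-counting of rare taxa — the
property that matters when combining census data from many studies.
Tests verify the implementation against a naive transcription of the
formula and against R `vegan::vegdist(method = "horn")`, which reduces
to the same index on proportion data.

The full pairwise matrix is reduced by PCA applied to the matrix itself:
each sample's row of distances is its feature vector, column-centred,
covariance-based, no unit-variance scaling (distances already share a
scale). This is deliberately *not* PCoA; the rows-as-features reading is
the pinned default and a metric-scaling alternative is one flag away for
anyone who wants it. The first three axes map to colour channels (axis 1
→ blue, axis 2 → red, axis 3 → green), each min-max rescaled over the
sample set, so similar compositions get similar colours; a constant axis
is uninformative and pinned at 0.5. Axis signs are arbitrary, so colours
are identifiable only within one run.

## Hovmöller gridding

Spatio-temporal fields use time × latitude bins of 1 kyr × 2.5°,
left-closed ([t, t+1) kyr, [l, l+2.5)°) and anchored at 0 ka / 0°, so
every sample lands in exactly one cell deterministically. Empty cells
are missing (NaN), never zero. The default cell aggregate is the mean;
the no-analogue stage exposes `min` as an alternative because gridding
minima of nearest-analogue distances is an equally defensible display
choice.

## Per-site trends and the stacked curve

Each site's dominant mode of compositional change is PC1 of its
samples × taxa proportion matrix (covariance PCA, no scaling). PCA
leaves the axis sign arbitrary; polarities are aligned by the sign of a
linear fit of score on age, with the convention that scores increase
towards the present (an exactly zero slope is left alone with a
warning). Aligned trends are linearly interpolated at 0.5 kyr steps and
restricted to 2.5–23 ka — the window all default series cover — to avoid
edge effects; interpolation never extrapolates beyond a series' own
support. "Interpolate at 0.5 kyr bins" could also be read as
bin-averaging; linear interpolation at grid points is the default and
bin-averaging is available behind a flag.

The pooled (age, score) cloud is smoothed by LOESS. "Standard settings"
are pinned as span 0.75, local quadratic, tricube weights — the
conventional defaults of the original implementation. The smoother is
implemented in-package because the stack needs degree-2 fits with
pointwise uncertainty on arbitrary grids; it reproduces R
`stats::loess(..., surface = "direct")` to machine precision on frozen
fixtures. The 95% band is pointwise, from the equivalent-kernel standard
error (fit = l·y, var = σ²‖l‖², σ² from the smoother's residuals and
approximate residual degrees of freedom) under approximate normality;
it is a large-sample approximation, slightly anti-conservative at the
window edges, and the tests treat it as such.

For comparison with a temperature forcing, the stacked fit and the
forcing anomaly are min-max rescaled to [0, 1] on their overlapping age
support; the pointwise difference and the Pearson correlation of the two
rescaled curves summarize (mis)match. No formal lag estimation is
attempted.

## Richness, gains and losses

Richness counts taxa with abundance strictly greater than zero: one
counted individual is presence. A configurable minimum-proportion
threshold exists for sensitivity analysis and is off by default. For
each site the *oldest sample* is the baseline (deliberately not the
19–23 ka mean, which the diversity-anomaly stage uses instead — both
conventions are implemented where each belongs). For every sample,

    gains  = |present now, absent in baseline| / |union|
    losses = |absent now, present in baseline| / |union|

with the union pooling both samples' species. The integer identity
richness(sample) − richness(baseline) = (gains − losses) × union_size is
exact and is enforced by tests on random presence patterns.

Rates are unweighted OLS slopes of richness, gains and losses against
time-towards-the-present (−age) over the full series, so positive =
increase through time; at least 3 time points are required. Across-site
summaries use a Gaussian KDE with Scott's-rule bandwidth (the pinned
default; the display bandwidth is not a scientific claim) plus the
overall mean.

## No-analogue detection

Every sample's M-H distance to all members of the glacial reference
(19–23 ka window, closed interval; duplicates by (site, age rounded to
10⁻⁶ kyr) removed, the same key used to exclude self-matches) gives its
nearest-, 2nd- and 3rd-nearest-analogue distances. The null threshold is
self-referential: for each reference sample, its rank-r non-self
analogue distance within the reference; the 95th/99th percentiles of
those distributions (linear interpolation between order statistics —
the pinned quantile rule) are the distances that coeval assemblages
reach by chance. A sample is flagged no-analogue when its nearest
distance is *strictly greater* than the threshold. By construction, at
most ~1% of the reference itself exceeds its own 99th-percentile
threshold (the leave-self-out audit reports the realized rate). Grid
cells are flagged by comparing the cell mean (default; min by flag) of
nearest distances to the same threshold; per-sample flags are always
emitted as well.

## Diversity gradients

Shannon entropy H = −Σ pᵢ log pᵢ is computed on relative abundances as
given — no rarefaction or coverage correction — in natural log (nats) by
default with log2/log10 conversions available. Samples are pooled in
left-closed millennial bins; each millennium with at least `min_points`
samples (default 10) gets a LOESS curve of metric vs latitude with the
same smoother settings as the trend stack; sparse millennia are skipped
with a warning, never fabricated. Diversity anomalies subtract each
site's own 19–23 ka mean from every sample of that site (sites with no
glacial-window sample are excluded with a warning) and are gridded at
1 kyr × 2.5°.

## The synthetic generator

The generator produces data with the statistical structure the analyses
assume, plus a ground-truth record for recovery tests. It is a
statistical stand-in, not an ecological reconstruction.

**Forcing.** Global mean temperature anomaly: glacial plateau (−6 °C)
before 17 ka, smooth half-cosine warming across the 11–17 ka
deglaciation, flat Holocene, re-referenced so the 0–2 ka mean is exactly
zero.

**Sites.** 25 sites at equal latitude steps over 0–65° N. Modern SST
falls linearly from 29 °C (equator) to 3 °C (65° N). Local temperature
is modern SST + scale × global anomaly, with polar-amplified scale
3.3·(lat/65)²: essentially no tropical glacial cooling, ~20 °C of
nominal cooling at the highest latitudes, floored at −2 °C (freezing
point — the one deviation from a purely linear local response, since
unbounded cooling is unphysical and would pin every polar assemblage to
the coldest species). The near-zero tropical cooling matters
structurally: it makes the glacial reference span the full temperature
range any later sample experiences, so under pure habitat tracking every
unaffected assemblage has a glacial analogue somewhere, as in the real
ocean. Mid-latitude sites (38–52° N) get a −4 °C Heinrich-like
excursion at 15–17 ka by default.

**Species.** 41 Gaussian thermal niches, optima evenly spaced over −2 to
30 °C, tolerances widening from 3 °C (cold end) to 5.5 °C (warm end) so
warm waters support more and more-even species — producing a
latitudinal diversity gradient. Expected proportions at temperature T:
pᵢ ∝ amplitudeᵢ · exp(−(T − optimumᵢ)²/2τᵢ²) · exp(sᵢ·secondary).

**Counts.** Multinomial draws of 300 individuals per census (a typical
micropaleontological counting effort), every 0.6 kyr over 0–24 ka. At
this depth and evenness, chance alone produces nearest-analogue
distances of a few hundredths — the regime in which a self-referential
null threshold is meaningful rather than trivially zero.

**No-analogue regime.** An optional second environmental axis activates
at 11 ka at mid-latitude sites (30–50° N) and saturates towards
strength 2 with a 1 kyr e-folding. Species sensitivities to it are a
fixed ±(0.4–1.0) pattern uncorrelated with thermal optimum, so the axis
*reshuffles* compositions into states no temperature can produce —
novelty arises mechanistically, not by hard-coding the detector's
answer. The strength and timescale were set so the imposed regime is
well separated from the sampling-noise null (the detectability the
generator is designed to provide), while leaving the no-driver
false-positive rate at its nominal level.

**Determinism.** All randomness flows from one integer seed; per-site
streams derive from (seed, CRC32(site_id)), so adding or reordering
sites does not perturb other sites' draws.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: age-model uncertainty,
uneven and site-specific sampling resolution, spatially correlated
oceanographic noise, dispersal limitation or response lags (a lag
parameter would be an extension, deliberately not included), taphonomic
loss, and real niche geometry. Recovery results demonstrate the
*estimators*, under a data-generating process that satisfies their
assumptions.

## Problem sizes and runtime choices

The default synthetic design (25 sites × 41 samples, 1 025 samples,
~175-sample reference) runs every stage in seconds; the bundled
whole-method checks use 20 seed replicates for detection scoring and 100
series for rate recovery, sizes at which the scored proportions are
stable to a few percent across seeds.

## Known limitations

- The LOESS confidence band is pointwise and approximate; simultaneous
  coverage is not claimed.
- PCA-on-the-dissimilarity-matrix mixes metric information nonlinearly
  (the classic horseshoe); along a smooth one-dimensional gradient the
  leading axis carries most but not all variance. This is a property of
  the pinned method, preserved on purpose.
- Percent-unit inputs tolerate row sums in [99, 101] and renormalize;
  badly closed census rows outside that range are rejected rather than
  guessed at.
- The no-analogue threshold inherits the composition of the reference
  pool: a sparse or biased glacial reference inflates novelty rates, and
  no correction for reference density is attempted.
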