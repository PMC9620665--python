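# Methods

## Data model and conventions

The atomic datum is one segmented NFT: a continuous centroid in level-0
pixel coordinates (origin top-left, x rightward, y downward) and an area in
pixels². The default scale is 0.5066 µm per pixel (100 px = 50.66 µm),
overridable per slide. Region annotations are simple polygons (GeoJSON
interchange); the hippocampus-proper and entorhinal polygons of a slide
must be disjoint (intersection below 0.1% of the smaller area). Region
assignment is point-in-polygon on the centroid with *inclusive* boundaries,
so a centroid exactly on an edge is deterministically inside. NFTs in
neither polygon are labeled `unassigned` and excluded from all regional
metrics; the count of such exclusions is logged.

Instance extraction from per-pixel NFT probability maps binarises at a
threshold (default 0.5), labels connected components (8-connectivity by
default, configurable to 4 — 8-connectivity is the more inclusive choice
for blob-like tangles), and discards components under `min_size_px`
(default 20 px², i.e. ~5 µm² at scale, suppressing speckle). There is no
canonical reduction from soft segmentation output to discrete tangles;
these three knobs are explicit, exposed in the pipeline config, and the
defaults are stand-ins rather than fitted values.

Cognitive status (NCI vs CI) is derived per subject: CDR ≥ 0.5 or
MMSE < 26 means impaired; with both scores present the more recently
assessed wins; on the same date — or when a date is missing (logged) — CDR
takes precedence; with neither score, the chart-review impairment flag
decides; with nothing available the subject has no status and is excluded
from group statistics (logged).

## Burden metrics

Per region (hippocampus, entorhinal, and `combined`):

* count density = NFT count / region area, reported per mm²
  (area = shoelace polygon area × (µm/px / 1000)²);
* NFT pixel density = Σ tangle area / region area, a dimensionless
  fraction, invariant to the pixel scale;
* positive-pixel burden = positive / total pixel counts from an external
  stain-intensity pipeline, normalised to 0–1. The proprietary
  hue/intensity positive-pixel algorithm is not reimplemented; the counts
  are inputs (`method=external`) or may come from a plain intensity
  threshold on supplied rasters (`method=threshold`).

`combined` pools objects and sums areas — never the mean of the two
regional densities. Density units cancel downstream because every model
standardizes its predictor; units affect reporting only.

## The spatial clustering statistic

Tangle centroids form a random-geometric graph: edge (i, j) iff
‖pᵢ − pⱼ‖ < r. The boundary rule is strict `<`; ties at exactly r are
measure-zero for continuous centroids and resolved as non-edges. Neighbour
search is an exact kd-tree fixed-radius query; candidate pairs are
re-checked with an exact squared-distance comparison, so the strict rule
holds regardless of the tree's internal tolerance. Triangle counting goes
through a dense boolean adjacency product for graphs up to 2048 nodes and
neighbour-set intersection beyond, both exact.

The slide statistic is the arithmetic mean of the local clustering
coefficient Cᵢ = 2Tᵢ/(kᵢ(kᵢ−1)) over *all* nodes, with degree-<2 nodes
contributing 0 (the dominant convention; excluding them is a config
switch). Slides with fewer than 3 NFTs have no defined value: the
functions return NaN, the sweep propagates it as missing (never 0), and
such subjects drop out of clustering-based regressions with a logged
count. The sweep runs over r = 100…5000 px in 100 px steps (50 radii,
both endpoints included) on all slide NFTs pooled across regions, and the
total NFT count travels with the sweep as the nuisance covariate for every
regression on the metric.

## Statistical battery

* **Contingency tests.** Pearson chi-square; Yates continuity correction
  for 2×2 tables (this choice reproduces published 2×2 p-values computed
  from cohort counts, e.g. 0.9766 for a sex table and 0.019 for an ARTAG
  table), no correction for r×c.
* **Logistic odds ratios.** Maximum-likelihood logistic fits of the binary
  cognition outcome on one standardized measure at a time, so odds ratios
  are per SD — burden measures live on incomparable native scales
  (counts/mm² vs 0–1 fractions). Wald 95% CIs and two-sided Wald p-values
  match the OR-with-CI reporting style. Age-adjusted fits add standardized
  age; the clustering measure always carries total NFT count. Perfect or
  quasi-complete separation raises a named error rather than returning a
  divergent estimate (detected via the optimizer's convergence flag and a
  |β| > 50 guard).
* **FDR families.** Benjamini–Hochberg step-up, applied (a) across the
  measure battery within each adjustment condition and (b) across the
  radius grid within the OR curve. Note BH adjustment is not idempotent:
  re-adjusting an adjusted vector re-multiplies by m/rank.
* **CMH.** Mantel–Haenszel pooled OR Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) over 2×2
  strata with the continuity-corrected CMH chi-square; the two age strata
  default to a median split (cut point configurable).
* **Group tests.** Welch (unequal-variance) t-test by default with a
  pooled-variance switch; Spearman (average ranks) and Pearson
  correlations; fixed-effects two-way ANOVA with interaction using Type-I
  sums of squares, intended for balanced region × status designs where the
  decomposition is unambiguous.
* **Missing data.** Listwise deletion per fit, with logged exclusion
  counts.

The pipeline report has one row per measure — Braak stage, three regions ×
{positive-pixel burden, count density, NFT pixel density}, and the mean
clustering coefficient at r = 800 px (the battery's default radius) — in
unadjusted and age-adjusted blocks, plus the full OR-vs-r curve with its
FDR-corrected band.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
the scale of a ~700-subject autopsy series:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 706 | cohort size |
| age | TruncNormal(85, 10²) on [55, 110] | age at death (years) |
| `mean_count` | 100 | baseline expected NFTs per slide |
| `count_age_slope` | 0.29 | log-intensity slope per SD of age |
| `count_dispersion` | 0.70 | lognormal frailty SD (overdispersion) |
| `clustered_fraction` | 0.5 | share of subjects with clustered patterns |
| `thomas_mu`, `thomas_sigma_px` | 20, 400 px | offspring per cluster, cluster scale (~203 µm) |
| `beta_burden` | ln 1.40 | per-SD log-odds of impairment on NFT count |
| `beta_age` | 0.40 | per-SD log-odds on age |
| `label_noise` | 0.10 | symmetric misclassification of the recorded status |

Counts are lognormal-mixed Poisson: N ~ Poisson(mean_count ·
exp(γ·z_age + ε)), ε ~ N(0, τ²). γ and τ were calibrated once by
simulation so that default cohorts show a count–age Pearson correlation
near 0.3 with realistic overdispersion; β_age and the intercept −0.05 were
set the same way to give a ≈4.5-year CI/NCI age gap and ≈49% impairment
prevalence. The outcome model standardizes with *population* moments of
the count distribution (truncated-normal expectations evaluated by
quadrature), so subjects are mutually independent given the master seed.
The cluster spatial scale σ = 400 px is a construction choice — the true
length scale of NFT clusters is unknown — placed inside the radius band
where the clustering metric is most informative.

Spatial placement conditions on the drawn count: CSR subjects get exactly
N uniform points (rejection sampling in the polygon); clustered subjects
get Thomas-style placement (Poisson parents in a dilated window, each
offspring assigned a uniform parent and displaced by an isotropic Gaussian,
re-drawn until inside). The unconditional `simulate_csr` / `simulate_thomas`
processes are also provided and tested against their moment formulas.
Clinical draws and spatial draws use separate derived seed streams, so the
tabular cohort is bit-identical whether or not patterns are placed — the
statistical calibrations run in tabular mode for speed.

What the generator does *not* emulate: tissue anisotropy and laminar
structure, staining batch effects, segmentation errors correlated with
burden, per-slide region-shape variation (one fixed template), or any
biological claim about true NFT cluster geometry. Passing calibration
tests therefore shows the estimators are correct and calibrated under the
assumed data-generating process, not that the effect sizes transfer to
real tissue.

A consequence worth knowing: with the default age effect and 10% label
noise, the *crude* per-SD odds ratio on NFT count averages ≈1.41–1.43 —
upward confounding through age and downward attenuation from label noise
nearly cancel — while the age-adjusted estimate is attenuated to ≈1.27.
The recovery simulation therefore targets the crude estimate.

## Numerical choices and test design

* Sweep exactness is verified against an O(n³) dense-matrix oracle to
  1e-12 on seeded point sets up to n = 300, and against networkx as an
  independent implementation.
* The null-cohort type-I check for the radius curve averages significance
  fractions over independent null-outcome redraws within each cohort: the
  50 per-radius tests are almost perfectly correlated, so cohort-level
  fractions alone would carry Monte-Carlo error too large to verify the
  nominal 5% rate; the tolerance is three MC standard errors of the
  redraw-level estimate.
* Simulation sizes in the test suite (e.g. 100 recovery replicates at
  n = 700 in tabular mode, 20 null cohorts with full spatial placement,
  50 paired discrimination draws) are chosen so the whole suite completes
  in minutes while keeping each check's Monte-Carlo error well below its
  tolerance.
* Determinism: every stochastic component takes an explicit seed;
  per-subject generators derive from `SeedSequence([master, index,
  stream])`; pipeline outputs are byte-identical across reruns.

## Known limitations

* The positive-pixel burden consumes externally computed counts; no stain
  deconvolution or batch normalisation is attempted.
* Whole-slide pyramid formats are out of scope: inputs are object tables
  or pre-extracted rasters.
* The Type-I ANOVA is only unambiguous on balanced designs; unbalanced
  data should use the logistic battery instead.
* Absolute density values depend on annotation magnification and are not
  comparable across datasets without a shared pixel scale.
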