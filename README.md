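# nftburden

Quantitative clinicopathologic analysis of neurofibrillary-tangle (NFT)
burden from AI segmentation outputs on digitized hippocampal sections.

Neurofibrillary tangles — intraneuronal aggregates of hyperphosphorylated
tau — are the defining lesion of primary age-related tauopathy (PART) and
related tauopathies. Classical Braak staging records only the neuroanatomical
spread of tau pathology, not its magnitude, and predicts antemortem cognition
poorly in amyloid-negative subjects. Given per-slide NFT segmentations
(centroid + area of every tangle, in level-0 pixel coordinates) and manual
region annotations of the hippocampus proper and entorhinal cortex, this
package computes:

* **Regional burden metrics** — NFT count density (tangles/mm²), NFT
  positive-pixel density (summed tangle area over region area), and the
  normalised 0–1 positive-pixel burden from conventional stain-intensity
  counts;
* **A spatial clustering statistic** — the mean clustering coefficient
  `C̄(r) = (1/n) Σᵢ 2Tᵢ / (kᵢ(kᵢ−1))` of the geometric graph that joins two
  tangle centroids when their Euclidean distance is below a radius `r`
  (`kᵢ` = degree, `Tᵢ` = triangles through node *i*; nodes with `kᵢ < 2`
  contribute 0), swept over `r` = 100…5000 px in 100 px steps
  (50.66–2533 µm at the 0.5066 µm/px scanner scale);
* **The statistical battery** — cohort descriptives with Yates-corrected
  chi-square and Welch t-tests, logistic models of cognitive impairment on
  each standardized burden measure (odds ratios per SD, Wald 95% CIs,
  Benjamini–Hochberg FDR, unadjusted and age-adjusted blocks, with the
  total NFT count as a nuisance covariate for the clustering metric), the
  Cochran–Mantel–Haenszel age-stratified pooled odds ratio for categorical
  associations, rank/product correlations, and two-way ANOVA;
* **A synthetic-cohort generator** — truncated-normal ages, lognormal-mixed
  Poisson NFT counts correlated with age, Thomas-process (clustered) vs
  homogeneous-Poisson (random) point patterns inside a fixed two-region
  slide template, and a binary cognition outcome with a configurable per-SD
  burden odds ratio — so the full pipeline is testable and calibratable
  without any imaging data.

Intended users: neuropathology and digital-pathology groups relating
CNN-derived lesion maps to antemortem clinical status.

## Worked example

```python
import nftburden as nb

params = nb.CohortSimParams(n_subjects=200, seed=7)
bundle = nb.simulate_cohort(params)
report = nb.analyze_cohort(
    bundle.records, bundle.slides,
    positive_pixels={s.subject.subject_id: s.positive_pixels
                     for s in bundle.subjects},
)
print(report.or_report[~report.or_report.adjusted_for_age].round(3))
```

prints the unadjusted odds-of-impairment block (one row per burden
measure; `odds_ratio` is per SD of the measure):

```
                          measure  odds_ratio  ci95_low  ci95_high  p_raw  p_fdr
                      braak_stage       0.956     0.724      1.263  0.753  0.753
 positive_pixel_burden_entorhinal       1.048     0.794      1.385  0.739  0.753
positive_pixel_burden_hippocampus       1.295     0.961      1.747  0.090  0.447
   positive_pixel_burden_combined       1.154     0.868      1.534  0.324  0.447
     nft_count_density_entorhinal       1.158     0.872      1.536  0.311  0.447
    nft_count_density_hippocampus       1.139     0.860      1.508  0.365  0.447
       nft_count_density_combined       1.151     0.868      1.527  0.328  0.447
     nft_pixel_density_entorhinal       1.154     0.870      1.530  0.320  0.447
    nft_pixel_density_hippocampus       1.162     0.876      1.541  0.298  0.447
       nft_pixel_density_combined       1.158     0.873      1.536  0.308  0.447
      mean_clustering_coefficient       1.173     0.884      1.558  0.269  0.447
```

At this small n (200 subjects) the per-SD odds ratios scatter around the
generating value 1.40 with wide intervals; at the default cohort size (706)
they tighten around it. The same report carries the radius curve — here the
clustering odds ratio peaks at 1.21 at r = 1200 px (607.92 µm) — and the
descriptives (CI subjects are 5.3 years older, Welch p = 1.7e-4), mirroring
the age confounding the age-adjusted block then removes.

The command line wraps the same stages:

```sh
nftburden simulate --seed 1 --out cohort/
nftburden run --config config.yaml       # metrics, sweep, stats, report
```

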