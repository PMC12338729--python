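# cofluct

Amplitude-stratified edge co-fluctuation analysis of parcellated BOLD fMRI
timeseries.

Static functional connectivity (FC) between two brain regions is the Pearson
correlation of their timeseries — a single number that hides *when* the two
regions co-fluctuate. `cofluct` unwraps FC into its frame-wise components and
asks how each region's contribution to whole-brain co-fluctuation changes
with the brain's momentary global co-fluctuation amplitude. It is aimed at
researchers working with parcellated resting-state or naturalistic fMRI who
want amplitude-resolved network analyses without event thresholds.

## The method

For z-scored regional timeseries `z_i(t)`, the **edge timeseries** of a pair
(i, j) is `E_ij(t) = z_i(t) · z_j(t)`; its temporal mean is exactly the
pair's Pearson FC. Per frame, co-fluctuation amplitudes are root sums of
squares (RSS) over edges:

    RSS_GLOBAL(t)    = sqrt( Σ_{i<j} E_ij(t)² )
    RSS_REGION_i(t)  = sqrt( Σ_{j≠i} E_ij(t)² )

both evaluated through closed forms in the z-values, so the N(N−1)/2 edge
matrix is never materialized. Retained (low-motion) frames are sorted by
`RSS_GLOBAL` and split into 20 quantile bins (5% of timepoints per bin); a
region's **co-fluctuation score** in bin m is the ratio of within-bin means

    score_{i,m} = mean_{t∈T_m} RSS_REGION_i(t) / mean_{t∈T_m} RSS_GLOBAL(t),

its relative contribution to whole-brain co-fluctuation at that amplitude
stratum. Downstream analyses:

* **Trajectories** — per region, a penalized-spline GAM
  `score ~ f(amplitude) + β·sex + β·meanFD` (REML smoothing selection).
  The *primary amplitude effect* is the smooth's partial R² signed by the
  averaged first derivative; the *second amplitude effect* is the averaged
  second derivative (negative ⇒ inverted-U).
* **Spatial alignment** — Pearson similarity and 2-cluster structure of bin
  score maps; Spearman alignment of each bin map with a reference cortical
  axis (e.g. sensorimotor–association rank), with parcel-level spin-test
  significance (mirrored-hemisphere sphere rotations, nearest-neighbour
  reassignment).
* **Cohort statistics** — smooth age effects on bin-averaged scores, and
  paired rest-vs-movie regional contrasts with Benjamini–Hochberg FDR.

Because the matched empirical datasets are access-controlled, the package
ships a seeded synthetic cohort generator whose amplitude-dependent
co-fluctuation structure is known by construction (three region classes
with increasing / inverted-U / decreasing amplitude engagement), so the full
pipeline is verifiable end to end.

## Worked example

```python
from collections import Counter
import numpy as np
import cofluct as cf

cohort = cf.generate_cohort(cf.SyntheticCohortSpec(seed=1))   # 20 subjects
mats = [cf.score_scan(scan) for scan in cohort.scans]         # 20-bin scores
fits, _ = cf.fit_all_regions(mats, cohort.covariates)

cls = dict(zip(cohort.geometry["region_id"], cohort.geometry["region_class"]))
for want in ("S", "A", "L"):
    regimes = Counter(f.regime for f in fits if cls[f.region_id] == want)
    label, count = regimes.most_common(1)[0]
    print(f"{want}: {label} {count}/{sum(regimes.values())}")

group = cf.group_average_scores(mats)
sa = cohort.geometry["sa_rank"].to_numpy(float)
top = np.mean([cf.map_alignment(group.scores[:, m], sa) for m in (18, 19)])
mid = np.mean([cf.map_alignment(group.scores[:, m], sa) for m in (8, 9, 10, 11)])
print(f"SA-axis alignment: top bins rho {top:+.2f}, mid bins rho {mid:+.2f}")
```

prints

```
S: increasing 20/20
A: inverted-U 20/20
L: decreasing 20/20
SA-axis alignment: top bins rho -0.67, mid bins rho +0.88
```

All three planted amplitude regimes are recovered region by region, and the
group score maps align negatively with the synthetic
sensorimotor–association axis at the highest amplitude bins but positively
at intermediate bins — the characteristic amplitude-dependent reversal of
hierarchical alignment.

The same pipeline is scriptable from the shell:

```bash
cofluct simulate --out sim/ --seed 1
cofluct score --scan sim/scan_S000_rest.tsv --out scores.tsv
cofluct run --config pipeline.yaml --seed 1
```

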