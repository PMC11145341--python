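# percept-scaling

P-value based effect-size scaling for small-n omics and imaging data.

Binary p-value thresholding ("p < 0.05") discards every measurement that
fails the cut, which is especially punishing for omics studies with few
replicates and high variability. PERCEPT (P-value Enhanced Rescaling for
Comprehensive Exploration and Preservation of Trends) keeps every
measurement and instead scales it by its confidence: given a replicate
mean *m₁*, a hypothetical mean *m₀* (the ground truth, 0 for log2 ratios),
a p-value *p* from a one-sample t-test of the replicates against *m₀*, and
a tunable penalty factor *F* > 0, the scaled value is

```
V = m₀ + (m₁ − m₀) · F^(−p)
```

A high-confidence effect (p → 0) is preserved (V → m₁); a noisy,
low-confidence one (p → 1) is pulled toward the hypothetical mean
(V → m₀ + (m₁ − m₀)/F). F = 10·n, with n the replicate count, is the
recommended starting point for tuning. For example, with a ground truth
of 600 and a measured mean of 400 at n = 3 (so F = 30), p = 0.5 scales
the measurement to 563 (mostly suppressed) while p = 0.02 keeps it at 413
(mostly preserved). Because F^(−p) ≥ 500^(−0.05) ≈ 0.73 for any
significant p, confident effects are never flattened by more than ~30%
even at extreme penalties.

The package is aimed at proteomics/metabolomics practitioners and
provides, beyond the transform itself:

- **cohort** operations: per-donor log2 abundance ratios against the
  control-cohort mean, data-driven effect thresholds from a pseudo-control
  (label-randomized) distribution, volcano categorization (S/A, NS/A,
  NS/NA, S/NA), and table-wide scaling;
- **imaging** demonstration: noised replicate stacks of a binary ground
  truth, mean smoothing vs per-pixel scaling, line scans;
- **evaluation** machinery: small-n donor subsampling, distance to the
  population, normalized distances, nearest-method CDF interpolation on a
  fixed cumulative grid, Bland–Altman limits of agreement, cross-dataset
  Pearson correlation;
- **synthetic** generators for cohorts and images with known ground truth,
  so everything runs with no downloads.

## Worked example

```python
from percept import ScalingConfig, percept_from_replicates, percept_scale

percept_scale(m1=400, m0=600, p=0.5, F=30)    # 563.48... -> reported as 563
percept_scale(m1=400, m0=600, p=0.02, F=30)   # 413.15... -> reported as 413

out = percept_from_replicates([1, 2, 3], ScalingConfig(m0=0, F=30))
# PerceptOutcome(feature_id='', n=3, m1=2.0, p=0.0742, s=0.777, V=1.554)
```

The t-test p-value of [1, 2, 3] against 0 is 0.0742, giving a scaling
factor 30^(−0.0742) = 0.777, so the mean of 2.0 is softened to 1.554.

End-to-end from the shell (a synthetic 500-feature cohort, 20 control +
40 case donors, 20% of features carrying a true |log2 effect| of 1.5):

```sh
percept synth cohort --features 500 --control 20 --case 40 \
    --affected 0.2 --effect 1.5 --noise 0.35 --seed 7 --out demo.csv
percept scale --table demo.csv --groups demo.groups.csv \
    --penalty 20 --seed 7 --out demo_scaled
```

prints (abridged):

```json
{
  "category_counts": {"NS/NA": 297, "S/A": 100, "S/NA": 103},
  "thresholds": {"lower": -0.6017, "upper": 0.5166},
  "penalty": 20.0, "n_features": 500
}
```

The pseudo-control thresholds (−0.60, 0.52) bracket 90% of the
control-vs-control ratio distribution, and the 100 S/A features are
exactly the 20% truly affected ones. `demo_scaled/scaled_features.csv`
holds the per-feature table (`n, m1, p, s, V, category`), e.g. a null
feature with mean 0.005 at p = 0.92 is scaled by 20^(−0.92) = 0.063
down to 0.0003.

The other workflows run the imaging demonstration and the small-n
subsampling evaluation:

```sh
percept simulate-image --height 64 --width 64 --n 100 --small-n 5 \
    --penalty 20 --seed 1 --out img_demo
percept evaluate --table demo.csv --groups demo.groups.csv \
    --k 5 --trials 100 --penalty 20 --seed 7 --out eval_demo
```

`evaluate` reports the mean normalized distance of raw and scaled
five-donor summaries to the population values (raw is 1 by construction;
scaled below 1 means the scaled summaries sit closer to the population)
plus Bland–Altman agreement for both.

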