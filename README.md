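# icitau

Information-content-informed Kendall-tau (ICI-Kt) correlation for omics
abundance data with left-censored missing values.

## The problem

In metabolomics and proteomics, a large share of missing values are not
missing at random: the analyte fell below the instrument's limit of
detection (LOD). Its absence therefore *says something* — the true value is
small. Standard practice either drops such points (pairwise-complete
correlation) or imputes them, and in both cases the information carried by
the missingness is discarded or distorted.

ICI-Kt folds that information into the Kendall tau-b rank correlation. The
concordant/discordant pair definitions are extended so that a
present-vs-missing comparison carries ordering information: a missing value
ranks below every observed value, and two missing values tie. With
n<sub>c</sub>, n<sub>d</sub> the concordant/discordant pair counts,
n<sub>tot</sub> = n(n−1)/2, and n<sub>xtie</sub>, n<sub>ytie</sub> the tied
pair counts (missing-vs-missing included),

τ<sub>b</sub> = (n<sub>c</sub> − n<sub>d</sub>) / √((n<sub>tot</sub> − n<sub>xtie</sub>)(n<sub>tot</sub> − n<sub>ytie</sub>))

Points missing in *both* vectors are either dropped (**local** perspective,
natural for one two-sample comparison) or kept as ties in both variables
(**global** perspective, so every pair of samples over the same feature set
sees the same number of pair comparisons). Alongside τ the package reports:

- **τ<sub>max</sub>** = (n<sub>tot</sub> − n<sub>xtie</sub> − n<sub>ytie</sub> + n<sub>tie</sub>) / √((n<sub>tot</sub> − n<sub>xtie</sub>)(n<sub>tot</sub> − n<sub>ytie</sub>)) —
  the largest τ<sub>b</sub> the pair's tie structure allows, usable to
  rescale a whole dataset;
- **completeness** — the fraction of features missing in neither vector,
  multiplied with τ to form a quality-sensitive composite;
- a two-sided **Mann–Kendall p-value** with tie-corrected variance.

The fast path substitutes missing values with a sentinel below every
observed value and counts exchanges with an O(n log n) mergesort — exactly
equivalent to the extended pair definitions (the test suite proves the
equivalence against an O(n²) rule-based census).

Built on top of the correlation:

- a **binomial test for left-censorship** (are values of partially-missing
  features concentrated below their sample medians?) plus median-rank vs
  N-missing diagnostics — use these to check that ICI-Kt's premise holds
  for your dataset;
- **sample outlier detection** from within-group median correlations via
  the score log(1 − cor<sub>median</sub>) and an upper Tukey fence;
- **feature–feature networks**: shrinkage-regularized partial
  correlations, 2.5% tail edge selection, and a modularity-style
  partitioning ratio Q scored against annotation sets;
- a **simulation module** generating all the synthetic benchmarks (perfect
  and realistic log-normal pairs, outlier points, low-end and random
  censoring, dynamic-range cohorts, half-minimum imputation).

## Worked example

```python
import numpy as np
from icitau import ici_kt_fast
from icitau.simulate import gen_realistic_pair, censor_by_cutoff

x, y = gen_realistic_pair(seed=42)          # log-normal base + N(0, 0.2) noise
out = ici_kt_fast(x, y, perspective="global")
print(f"no censoring : tau = {out.tau:.4f}  completeness = {out.completeness:.3f}")

xc, yc = censor_by_cutoff(x, y, cutoff=1.0)  # values below 1.0 become missing
out_c = ici_kt_fast(xc, yc, perspective="global")
print(f"cutoff 1.0   : tau = {out_c.tau:.4f}  completeness = {out_c.completeness:.3f}")
```

prints

```
no censoring : tau = 0.8995  completeness = 1.000
cutoff 1.0   : tau = 0.8996  completeness = 0.963
```

Left-censoring removed ~4% of the points, yet ICI-Kt barely moves (0.8995 →
0.8996): the censored points were the lowest-ranked ones, and treating them
as "lowest" preserves — slightly reinforces — the rank agreement. Random
missingness of the same magnitude would instead drop the correlation
sharply, which is the desired sensitivity.

The same pipelines are scriptable from the shell:

```bash
icitau simulate --dataset lod --seed 7 --n 400 --n-samples 6 \
    --censor-max-level 1.0 --out demo.tsv
icitau censor-test --input demo.tsv --groups groups.tsv --out censor.tsv
# -> successes=726 failures=533 estimate=0.5766 p=2.96e-08
```

The one-sided binomial p-value of 3e-08 says the missing values in this
cohort are exactly where left-censorship puts them: features with
missingness have their observed values concentrated below the per-sample
medians. Subcommands: `simulate`, `correlate`, `censor-test`, `outliers`,
`network`; every run writes a JSON config sidecar for provenance.

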