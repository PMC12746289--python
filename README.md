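# betascape

Beta-diversity homogenization analysis for paired land-use soil community
surveys.

Converting natural landscapes to cropland is widely expected to
*homogenize* soil life: agricultural management flattens the environmental
mosaic, and soil taxa, functional gene assemblages, and microbial
life-history strategies all become more alike — within a field, between
fields, or both. Testing that claim from sequencing data takes a fairly
long statistical pipeline, and `betascape` implements it end to end for
the standard paired design (each site contributes an agricultural plot,
AS, and a natural plot, NS, with replicate soil cores):

- **Multivariate dispersion** (`betadisper`-style): embed a Bray–Curtis
  distance matrix by principal coordinates (keeping the imaginary axes
  that non-Euclidean distances produce), measure every sample's distance
  `z` to its group centroid, and compare AS vs NS by Wilcoxon rank-sum or
  a permutation-F, at the *regional* scale (groups = land use) and the
  *local* scale (groups = site × land use). Smaller dispersion = more
  homogeneous.
- **Distance–decay relationships**: OLS of community similarity
  (1 − Bray–Curtis) on geographic distance per land use, with a
  label-permutation test for the slope difference.
- **Spatial vs environmental structure**: PCNM spatial eigenvectors,
  max-F forward selection, variation partitioning into pure
  environmental / shared / pure spatial / residual adjusted-R² fractions,
  and PERMANOVA.
- **Assembly processes**: the Sloan neutral community model
  (occurrence frequency predicted as `1 − BetaCDF(1/N; Nmp, Nm(1−p))`,
  migration rate `m` fit by bounded least squares), Levins niche breadth
  `B = 1/Σ P²` with community mean `Bcom`, and the normalized
  stochasticity ratio (NST) against a proportional-occupancy /
  fixed-richness / fixed-depth null model, with 50% as the
  deterministic/stochastic boundary.
- **Co-occurrence networks**: Pearson correlation networks (mean relative
  abundance > 0.01%, prevalence ≥ 25%, |r| > 0.7, P < .01), modularity
  modules, Zi/Pi node roles (thresholds 2.5 / 0.62), top-5% network hubs,
  and stability metrics (robustness under random or hub-targeted removal,
  vulnerability from global efficiency, natural connectivity).
- **Y-A-S life-history profiling**: aggregate CPM-normalized gene tables
  into growth **Y**ield / resource **A**cquisition / **S**tress-tolerance
  shares via a gene→category trait map, compare them between land uses,
  and screen features against environmental covariates with BH control.

A first-class synthetic-data generator (`betascape.simulate`) emulates the
paired design — 27 sites × 2 land uses × 5 replicate cores along a 900 km
transect by default — with explicit knobs for within-plot noise,
between-site heterogeneity, spatial autocorrelation, environmental
filtering, and neutral migration, so every statistic in the pipeline can
be validated against known ground truth.

## Worked example

```python
from betascape import (SimConfig, simulate_paired_design, simulate_neutral,
                       two_scale_homogeneity, ncm_fit)

# a survey where agriculture homogenizes only the local scale
cfg = SimConfig(n_sites=12, n_replicates=3, n_features=150, depth=1000, seed=0)
table, metadata = simulate_paired_design(cfg)
report = two_scale_homogeneity(table, metadata)
print(f"local:    mean z AS={report.local_test['mean_a']:.3f} "
      f"NS={report.local_test['mean_b']:.3f} p={report.local_test['p_value']:.2e}")
print(f"regional: mean z AS={report.regional_test['mean_a']:.3f} "
      f"NS={report.regional_test['mean_b']:.3f} p={report.regional_test['p_value']:.3f}")

# neutral-model parameter recovery on neutral data
neutral = simulate_neutral(SimConfig(n_features=300, depth=1000,
                                     migration=0.1, seed=0), n_samples=100)
fit = ncm_fit(neutral)
print(f"NCM: m={fit.m:.3f}  R2={fit.r2:.3f}")
```

Output:

```
local:    mean z AS=0.071 NS=0.233 p=4.62e-11
regional: mean z AS=0.656 NS=0.657 p=0.740
NCM: m=0.095  R2=0.983
```

The AS cores sit three times closer to their plot centroids than the NS
cores (local homogenization, p ≈ 5e-11), while the two land uses are
indistinguishable at the regional scale (p = 0.74) — the generator was
configured with reduced within-plot noise in AS but equal between-site
effects. The neutral fit recovers the true migration rate m = 0.1 from
data generated under the model's own beta approximation.

## Command line

Every stage is also a subcommand:

```bash
betascape simulate --seed 1 --out-dir run/
betascape dispersion --table run/counts.tsv --metadata run/metadata.tsv --out-dir run/disp
betascape ddr --table run/counts.tsv --metadata run/metadata.tsv --out-dir run/ddr
betascape nst --table run/counts.tsv --metadata run/metadata.tsv --n-null 1000 --seed 1 --out-dir run/nst
betascape network roles --table run/counts.tsv --out run/roles.tsv
betascape run-all --seed 1 --out-dir run/full   # whole pipeline + manifest
```

`run-all` writes every figure-backing table as tidy TSV/JSON plus a
`manifest.yaml` echoing the resolved configuration, seed, and package
version, so any artifact can be regenerated from its manifest alone.

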