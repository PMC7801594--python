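# oveseg

Detection of **subtype-specific differentially expressed genes (SDEGs)**
among K ≥ 2 purified tissue or cell subtypes, using the One-Versus-Everyone
fold change (OVE-FC) and its scaled statistic (OVE-sFC) with a
posterior-weighted nested-permutation mixture null.

## The problem

A gene is an SDEG when it is most-upregulated in exactly **one** subtype —
higher than in *every* other subtype, not merely higher than the average of
the rest. Such genes are the markers that drive supervised deconvolution of
bulk tissue and subtype characterization. The usual screens do not match
this definition: ANOVA fires on any between-subtype difference, and
one-versus-rest comparisons fire on genes shared by several subtypes. With
log2 subtype means `mu_k(j)` the OVE statistics target the definition
directly:

    d_j = min_{l != (K)} { mu_(K)(j) - mu_l(j) }                  (OVE-FC)

    t_j = min_{l != (K)} (mu_(K)(j) - mu_l(j))
          / ( sigma_tilde(j) sqrt(1/n_(K) + 1/n_l) )              (OVE-sFC)

where `(K)` is the subtype with the largest mean and `sigma_tilde(j)` an
empirical-Bayes moderated standard deviation (prior
`sigma^2 ~ nu0 sigma0^2 / chi2_nu0`, fitted from all genes). The null
hypothesis `d_j = 0` covers a *mixture* of non-SDEG patterns — housekeeping
genes and genes upregulated equally in any subset of ≥ 2 subtypes — so the
null distribution of `t_j` is estimated as a (K−1)-component mixture. Each
component `H0,m` is sampled by a nested permutation that shuffles labels
only within each gene's top K−m subtypes, and genes enter each component
with posterior weights given by local false discovery rates of nested ANOVA
tests. p-values are the weighted exceedance fraction over all components,
genes, and permutations; q-values come from a Grenander tail-area estimator.

See `docs/methods.md` for the full model, estimation details, and the
simulators used for validation.

## Worked example

Simulate a 4-subtype dataset (3 replicates each) with 30 spiked SDEGs among
1,000 genes, and test it:

```python
import oveseg

cfg = oveseg.PowerSimConfig(n_genes=1000, n_sdegs=30, fc_range=(5, 20),
                            K=4, n_k=(3, 3, 3, 3), seed=42)
data, truth = oveseg.simulate_power(cfg)

model = oveseg.OVESFC(data)           # or OVESFC.from_dataframe(frame, design)
res = model.fit(permutations=999, seed=7)
print(res.summary(top=5))
```

```
OVE-sFC subtype-specific DEG test
================================================================
genes: 1000    samples: 12    subtypes (K): 4
samples per subtype: S0=3, S1=3, S2=3, S3=3
variance prior: nu0 = 48.3, sigma0^2 = 0.2537    residual df = 8
permutations P = 999    p lower bound = 5.88e-19
mixture component priors: H0,0: 0.148, H0,1: 0.385, H0,2: 0.466
genes with q < 0.05: 33
----------------------------------------------------------------
gene_id winner  ove_fc_log2  ove_sfc  p_overall  q_overall
   g879     S3        4.605    11.11  5.884e-19  5.314e-16
   g319     S2        4.322       11  1.198e-16   4.57e-14
   g333     S2        4.517    10.75   1.75e-16  5.268e-14
   g129     S2        4.307    10.58  5.312e-16  1.037e-13
   g253     S0        4.234     10.4  6.134e-16  1.108e-13
```

Reading the output: `nu0` and `sigma0^2` are the fitted variance-prior
degrees of freedom and scale (moderation strength); the component priors say
how the null mass splits between "flat in all 4 subtypes" (H0,0) and
"equally up in the top 3 / top 2" (H0,1 / H0,2); `ove_fc_log2` is the
top-two gap in log2 units (g879 is ~24-fold above the runner-up subtype);
`p_overall` is the mixture-null permutation p-value, floored at the printed
lower bound (genes whose observed statistic exceeds every permuted value are
reported at the attainable minimum, which depends on the smallest per-gene
weight). At q < 0.05 the test reports 33 genes; checking against the
simulation truth:

```python
print(oveseg.empirical_fdr(res, truth, 0.05))
# FDR 0.0909, TPR 1.0 — 33 discoveries, all 30 true SDEGs recovered
# with the correct subtype call, plus 3 false positives
```

The same pipeline is scriptable from the shell:

```sh
oveseg test --matrix expr.tsv --design design.tsv \
    --permutations 999 --seed 1 --out results.tsv
oveseg simulate-null  --config null.yaml  --out-prefix sim/
oveseg simulate-power --config power.yaml --out-prefix sim/
oveseg evaluate --matrix sim/matrix.tsv --design sim/design.tsv \
    --truth sim/truth.tsv --methods ove_sfc,ovo_t --out metrics.tsv
```

Input formats: expression matrix as TSV/CSV (header = sample ids, first
column = gene ids; `--input-scale linear` applies log2(x+1)); design as a
two-column table (sample_id, subtype).

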