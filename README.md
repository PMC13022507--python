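# breedmix

Supervised estimation of **global breed admixture** from genotype data,
built for cohorts like domestic dogs where the number of source
populations is large (dozens of breeds rather than a handful of
continental groups).

Given a reference cohort of purebred individuals, the package

1. filters variants the way a reference panel is normally constructed
   (minor-allele frequency ≥ 0.01, genotyping rate ≥ 20%, greedy LD
   pruning at 250 kb / 50 variants / r² 0.8);
2. selects **breed-informative markers** with the Weir–Cockerham (1984)
   FST estimator — the top-K sites per breed in one-vs-rest mode (the
   breed against all others pooled) unioned with every site whose global
   multi-breed FST exceeds 0.350;
3. derives breed-stratified allele frequencies *P* (sites × breeds) and
   estimates each query individual's breed proportions *q* under the
   linear model **F̂ = PQ**, where F̂ holds individual allele
   frequencies: *q* minimizes Σₘ (gₘ/2 − (Pq)ₘ)² over the probability
   simplex (non-negative, summing to one), solved by accelerated
   projected gradient with an active-set polish and a KKT certificate;
4. places **bootstrap error bounds** on estimates by repeatedly removing
   a few random reference individuals (default 6 samples × 100
   iterations), recomputing frequencies, and re-estimating;
5. provides cohort-structure diagnostics: standardized relationship
   (GRM) and allele-count Hamming matrices, unrooted neighbor-joining
   trees, PCA embeddings, and a sample-to-breed-centroid score for
   comparing marker panels.

Because a multi-hundred-dog sequencing cohort cannot ship with a
package, `breedmix` includes a first-class **simulator**: breeds drift
from a common ancestor under the Balding–Nichols model (per-breed drift
F, so realized FST is tunable per breed), purebred genotypes are
Binomial(2, p) draws, admixed individuals are built haplotype by
haplotype from exponential-length ancestry blocks with the block map
returned as ground truth, and low coverage is emulated with Poisson
zero-coverage genotype missingness. Every generator is bit-reproducible
given a seed.

## Worked example

```python
import numpy as np
from breedmix import (SimulationConfig, simulate_reference,
                      simulate_admixed_cohort, one_vs_rest_tables, wc_fst,
                      select_panel, breed_allele_freqs, estimate_q_matrix,
                      recovery_metrics)

cfg = SimulationConfig(n_breeds=5, n_sites=2000, samples_per_breed=6,
                       breed_drift=0.2, seed=1)
panel_truth, G_ref, labels = simulate_reference(cfg)

sel = select_panel(one_vs_rest_tables(G_ref, labels), wc_fst(G_ref, labels),
                   top_k=100, global_threshold=0.35)
P = breed_allele_freqs(G_ref, labels, sel)

G_q, truth, _ = simulate_admixed_cohort(panel_truth, 10, cfg,
                                        np.random.default_rng(7))
fit = estimate_q_matrix(P, G_q.subset_site_ids(sel.site_ids))
print(recovery_metrics(fit.q, truth)[["rmse", "pearson_r"]].mean())
```

prints (panel of 511 markers, 10 two-breed mixtures):

```
rmse         0.102851
pearson_r    0.960837
```

i.e. at this deliberately tiny scale the estimated proportion vectors
correlate with the truth at r ≈ 0.96 with a mean per-breed error of
about 0.10; at the study scale used in `analysis/` (20 breeds, 20,000
sites, ~8,400-site panel) the same pipeline reaches mean RMSE ≈ 0.037
and r ≈ 0.996.

## Analysis scripts

The `analysis/` directory holds numbered drivers that reproduce the
package's validation experiments end to end and write their tables under
`results/`:

| script | what it does |
|---|---|
| `01_simulate_and_filter.py` | simulate the 20-breed cohort, apply MAF/call-rate/LD filters |
| `02_build_panels.py` | build top-K FST panels, compare centroid tightness vs random panels |
| `03_purebred_recovery.py` | re-estimate every reference dog, bootstrap error bars |
| `04_admixed_recovery.py` | recover 50 known two-breed mixtures (RMSE, Pearson r) |
| `05_downsampling.py` | repeat recovery at 75/50/25/10/5% read fractions of a 2.5× query |
| `06_structure_diagnostics.py` | GRM, Hamming, NJ tree, PCA, centroid scores |

A `breedmix` CLI exposes the same stages (`simulate`, `filter`, `panel`,
`freqs`, `estimate`, `bootstrap`, `structure`, `evaluate`, `run`); see
`breedmix --help`.

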