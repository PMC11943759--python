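# soilnet

Grouped OTU-table analysis for soil (and other) microbiome studies: from a
samples × taxa count matrix with group labels and environmental covariates
to alpha/beta diversity, constrained ordination, and per-group microbial
co-occurrence networks with topology, node-role and stability metrics.

The package targets the common land-use comparison design — several
treatment groups (e.g. forestland, arable land, wetland), replicated
samples per group, 16S-style OTU/ASV counts, and a panel of soil
covariates (pH, SOM, TN, TP, TK, AN, AP, AK, C:N, NO3-N, NH4-N, enzyme
activities, functional-gene abundances) — and answers the questions such
studies ask: do the groups differ in diversity and composition, which
covariates structure the community, and how complex, modular and stable is
each group's co-occurrence network?

## What it computes

**Diversity.** Rarefaction to a fraction of the minimum depth (default
90 %), then Sobs, Shannon (−Σ pᵢ ln pᵢ), Simpson (Σ pᵢ², convention
configurable), bias-corrected Chao1 (S + F₁(F₁−1)/(2(F₂+1))), ACE (rare
cutoff 10) and Good's coverage (1 − F₁/N); shared/unique OTU partitions
per group (Venn regions); rank-level relative-abundance aggregation; and
per-variable one-way ANOVA with Tukey HSD and a compact letter display.

**Ordination.** Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ),
PCoA, seeded PERMANOVA (pseudo-F from within/total pairwise distances,
free label permutation), redundancy analysis (Hellinger-transformed
community regressed on standardised covariates, PCA of the fitted values)
and taxa × covariate correlation screens (Pearson/Spearman, optional BH).

**Networks.** Per group: dominance filter (mean relative abundance and
prevalence), all-pairs correlation on relative abundances, edges where
|r| ≥ r_min and (BH-adjusted) p ≤ p_max, then node/edge counts,
characteristic path length, clustering, density, mean degree, Newman
(CNM greedy) modularity Q = Σ(eᵢᵢ − aᵢ²), and the Guimerà–Amaral Zi–Pi
node roles (module hub / connector / network hub / peripheral at
Zi = 2.5, Pi = 0.62).

**Stability.** Natural connectivity λ̄ = ln((1/N) Σⱼ exp(λⱼ)) of the
adjacency spectrum (log-sum-exp, overflow-safe); robustness as the mean
retained λ̄ fraction after removing a random 10 % of nodes (100
replicates); vulnerability as the worst single-node relative drop in
global efficiency E = (1/(N(N−1))) Σ 1/d(i,j); and keystone redundancy
(1 − mean λ̄ impact of hub/connector removal).

A synthetic-cohort generator (latent-Gaussian copula → softmax →
multinomial, with planted correlation blocks, group effects and covariate
effects) makes every stage testable against ground truth without any data
download.

## Worked example

```python
import soilnet as sn

otu, tax, env, truth = sn.simulate_counts(sn.SimSpec(seed=1))
bundle = sn.run_pipeline(sn.RunConfig(seed=1), otu, tax, env)

print(bundle.permanova)
# {'pseudo_F': 7.8335, 'p': 0.001, 'n_permutations': 999,
#  'n_groups': 3, 'n_samples': 30}

print(bundle.alpha_compare.letters.loc[["sobs", "shannon"]])
#          arable forest wetland
# sobs          a      c       b
# shannon       a      b       b
```

The three simulated land-use groups separate cleanly in composition
(PERMANOVA p = 0.001) and the letter display recovers the planted richness
ordering (arable 700 > wetland 500 > forest 400 OTUs: groups that share no
letter differ at p < 0.05 by Tukey HSD).

Correlation networks need more replication than the default 10 samples
per group (with ~10⁵ BH-corrected tests, n = 10 leaves almost no
detectable edge); at 30 samples per group the per-group stability report
looks like:

```text
  group  nodes  edges  natural_connectivity  robustness_mean  vulnerability  modularity
 arable     67    126                3.8865           0.7594         0.0835      0.7778
 forest     50     95                3.6976           0.7703         0.1397      0.7105
wetland     59    131                5.3708           0.7893         0.0533      0.7419
```

Reading one row: the arable network keeps 76 % of its natural
connectivity after a random 10 % node loss (robustness), its worst
single-node removal costs 8.4 % of global efficiency (vulnerability), and
its detected module structure has Q = 0.78.

The same pipeline runs from the shell:

```bash
soilnet simulate --seed 1 --outdir cohort/
soilnet all --otu cohort/otu_counts.tsv --env cohort/env.tsv \
            --taxonomy cohort/taxonomy.tsv --seed 1 --outdir results/
```

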