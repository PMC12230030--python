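# ccmicro

Analysis pipeline for soil-microbiome succession along a continuous-cropping
gradient: how does year after year of the same crop reshape bacterial and
fungal communities, and is that reshaping driven by deterministic selection
or by stochastic assembly?

The package is aimed at microbial ecologists working with genus- or
phylum-level amplicon abundance tables sampled along a cropping-year (CCY)
gradient — here a 7-level design (1, 2, 5, 10, 15, 20, 25 years × 4
replicates = 28 samples) with a short-term (2–10 y) vs long-term (15–25 y)
contrast. It implements, as one tested library plus CLI:

- **Diversity and trends** — bias-corrected Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon entropy (nats), Bray–Curtis
  dissimilarity, principal coordinates analysis, one-way ANOVA / t-tests /
  Fisher's LSD with compact letter displays, and OLS trend fits of any
  metric against CCY.
- **Signed co-occurrence networks** — per duration class: mean-relative-
  abundance floor (0.1%), all-pairs Pearson r with t-distribution p-values,
  Benjamini–Hochberg adjustment, edges at |r| ≥ 0.7 and q < 0.05, and
  topology (density, Louvain modularity Q, clustering, path length, signed
  edge percentages).
- **Network robustness** — natural connectivity
  λ̄ = ln((1/N) Σᵢ exp(λᵢ)) of the adjacency spectrum, tracked while nodes
  are removed highest-degree-first, with Wilcoxon signed-rank comparison of
  the resulting attack curves.
- **Sloan neutral community model** — occurrence frequency vs mean relative
  abundance, Freq(p) = 1 − BetaCDF(1/N; Nm·p, Nm·(1−p)); least-squares
  migration estimate m, fit R², bootstrap CIs, and the three-fraction
  partition of taxa against the 95% band.
- **Assembly inference** — abundance-weighted βMNTD on a user-supplied
  phylogeny, βNTI via taxa-shuffling null models (999 randomizations), and
  classification of pairs into heterogeneous selection (βNTI > +2),
  homogeneous selection (< −2) or stochastic assembly.
- **Synthetic data** — coalescent trees, Sloan-type neutral tables with a
  known migration parameter, Brownian-trait niche-filtered tables, and the
  full 28-sample gradient fixture, so every stage is testable end to end
  without any download.

## Worked example

```python
from ccmicro import simulate, network, neutral, assembly
from ccmicro.io import LONG_TERM

table, md, tree = simulate.simulate_ccy_dataset(1)
sub = table.subset_samples(list(md.index[md["duration_class"] == LONG_TERM]))

net = network.cooccurrence_network(sub, r_min=0.7, alpha=0.05, floor=0.001)
topo = network.topology(net, seed=0)
print(f"long-term network: {topo.n_nodes} nodes, {topo.n_edges} edges, "
      f"Q={topo.modularity:.3f}, {topo.pct_negative_edges:.1f}% negative")

fit = neutral.fit_ncm(sub, n_boot=1000, seed=0)
above, within, below = neutral.summarize_fractions(fit)
print(f"NCM: Nm={fit.nm:.0f}, Rsqr={fit.rsqr:.3f}, "
      f"{within:.1f}% of genera within the 95% band")

res = assembly.beta_nti(table, tree, n_null=999, seed=0)
summ = assembly.summarize_assembly(res, md, "between")
print(f"betaNTI between classes: {summ.pct_heterogeneous:.1f}% heterogeneous "
      f"selection, {summ.pct_stochastic:.1f}% stochastic over {summ.n_pairs} pairs")
```

prints

```
long-term network: 80 nodes, 95 edges, Q=0.119, 43.2% negative
NCM: Nm=2256, Rsqr=0.859, 71.2% of genera within the 95% band
betaNTI between classes: 0.0% heterogeneous selection, 100.0% stochastic over 144 pairs
```

Reading: the 12 long-term samples yield a network of 80 genera whose strong
correlations are roughly half negative; neutral immigration with
Nm ≈ 2256 explains the occupancy–abundance relation well (R² = 0.86) with
71% of genera inside the model's 95% band; and the between-class turnover of
this mostly neutral synthetic community is, correctly, classified as
stochastic rather than selection-driven. The same stages run from the shell:

```sh
ccmicro simulate --seed 1 --out synthetic/
ccmicro all --seed 1 --out results/
```

(`diversity`, `network`, `robustness`, `ncm`, `bnti` run single stages; a
YAML file passed via `--config` overrides any threshold in
`ccmicro.pipeline.RunConfig`.)

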