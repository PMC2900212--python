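# promselnet

Genome-scale detection of positive selection in **human proximal promoters**
(the ~1 kb upstream of the TSS), and analysis of how those genes sit in the
human protein-interaction network — for molecular evolutionists and systems
biologists who want the full chain, from triplet alignments to network
association statistics, in one tested toolkit.

## What it computes

**The selection test.** For each gene, a human/chimp/macaque promoter
alignment is compared against the gene's own intronic reference under an
HKY85 substitution model on the three-taxon star tree. The intron calibrates
the neutral branch lengths (t_h, t_c, t_m) and κ; the promoter receives
branch-specific rate multipliers ζ = (ζ_h, ζ_c, ζ_m). Two nested models are
fitted by maximum likelihood:

* null — ζ_h ∈ [0, 1] (constraint, drift, or *relaxation* of constraint),
* alternative — ζ_h ∈ [0, ∞) (acceleration allowed).

Only positive selection can push the human-branch rate above neutral, so the
likelihood-ratio statistic Λ = 2(lnL₁ − lnL₀), referred to the boundary
mixture ½χ²₀ + ½χ²₁, is specific to adaptive acceleration. Genes with
p < 0.05 are called positively selected. Alignments first pass three QC
filters: a 50-bp sliding-window divergence screen (>12 human–chimp or >17
human–macaque differences rejects), a 10% gap-column ceiling, and an
intronic neutrality screen (human-specific substitution ratio inside
0.0053 ± 2·0.0022 per site).

**The systemic analyses.** On the largest component of a protein-interaction
network: degree, betweenness (unnormalized Brandes), average shortest path
length, and eigenvector centrality (max-scaled); one-tailed
Wilcoxon–Mann–Whitney comparisons of selected vs reference genes; logistic
regression of selection status on (log-)EVC with quantile-bin summaries;
hypergeometric category enrichment (`phyper`-style over/under-representation);
and DATA1/DATA2 expression summaries with Kendall τ-b correlations against
centrality. A synthetic-data module generates alignments, heavy-tailed
networks, planted labels, expression and annotations with the statistical
structure every stage assumes, so the whole pipeline runs and is validated
without any external download.

## Worked example

```python
from promselnet import PromoterSelectionModel
from promselnet.simulate import SimulationConfig, simulate_gene_case

cfg = SimulationConfig()                       # 1-kb promoter, 4-kb intron
prom, intron = simulate_gene_case(cfg, zeta_h=5.0, seed=7)   # accelerated gene
res = PromoterSelectionModel(prom, intron, gene_id="demo").fit()
print(res.summary())
```

```
Promoter selection likelihood-ratio test
========================================================
gene:                 demo
promoter sites used:  1000
intron sites used:    4000
--------------------------------------------------------
neutral kappa:            3.9062
neutral branches:     t_h=0.00470  t_c=0.00768  t_m=0.03009
promoter scalers:     z_h=6.3560  z_c=0.0000  z_m=0.8139
--------------------------------------------------------
lnL (null, z_h<=1):       -8103.6559
lnL (alt,  z_h free):     -8084.6766
LRT statistic:               37.9586
p-value (mixture):         3.613e-10
status (alpha=0.05):  positive
========================================================
```

The human-branch scaler is fitted at ẑ_h ≈ 6.4 against a true simulated
value of 5 (the human branch carries only ~5 neutral substitutions per kb,
so individual estimates are noisy; the median across replicates is on
target), and the boundary-mixture p-value rejects the no-acceleration null
decisively, so the gene is flagged `positive`. With ~1 kb of promoter the
chimp scaler is weakly determined and can sit at its boundary; the macaque
scaler, informed by a branch six times longer, stays near 1.

A full synthetic cohort end to end:

```bash
promselnet simulate --out fixture/ --seed 3 --n-genes 20 --n-positive 2
promselnet report --fixture fixture/ --seed 3 --out-dir results/
```

writes per-gene QC and LRT tables, the centrality table, and an
`association.json` report (WMW p-values, logistic coefficients, quantile
bins, enrichment, expression correlations).

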