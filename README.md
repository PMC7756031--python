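# mirsubpath

Identification of miRNA-mediated disease subpathways and survival-biomarker
modules from two-condition expression studies.

## The problem

In many cancers, localized *subregions* of signaling pathways — rather than
whole pathways — are dysregulated, and miRNAs act on those subregions by
repressing their target genes. This package implements a complete pipeline
for finding such regions and turning them into prognostic biomarkers:

1. **Differential expression.** A SAM-style relative-difference statistic
   d&nbsp;=&nbsp;(x̄₁ − x̄₂)/(s + s₀) with a permutation-estimated FDR calls
   differentially expressed (DE) genes (FDR &lt; 0.001) and miRNAs
   (FDR &lt; 0.05).
2. **UPEM construction.** Each pathway becomes an undirected gene graph;
   every miRNA with a validated target inside the pathway is embedded as an
   extra node linked to its contained targets (an *Undirected Pathway graph
   Embedded by MiRNA*).
3. **Subpathway mining.** DE genes and miRNAs are mapped onto each UPEM as
   signature nodes. Signature nodes at shortest-path distance ≤ *n* (default
   1) are grouped together with the interior nodes of their shortest paths;
   merged groups of ≥ *s* (default 10) nodes become subpathways. Each is
   scored by the joint gene/miRNA hypergeometric upper tail

   P = 1 − Σ<sub>x&lt;r<sub>g</sub>+r<sub>mir</sub></sub>
   C(t<sub>g</sub>+t<sub>mir</sub>, x)·
   C(m<sub>g</sub>+m<sub>mir</sub>−t<sub>g</sub>−t<sub>mir</sub>, n<sub>g</sub>+n<sub>mir</sub>−x) /
   C(m<sub>g</sub>+m<sub>mir</sub>, n<sub>g</sub>+n<sub>mir</sub>)

   with Benjamini–Hochberg correction (significant at FDR &lt; 0.001).
4. **CMGN.** Significant subpathways are merged into a Comprehensive
   MiRNA-Gene Network; miRNA–gene edges with Pearson r &lt; −0.7 are marked;
   degree, normalized betweenness, a log-log power-law fit and a
   known-disease-node comparison characterize the topology.
5. **Modules.** Overlapping communities are mined by clique percolation
   (k = 4); communities with both a miRNA and a gene, not contained in a
   larger such community, are the miRNA-mRNA modules, annotated back to
   subpathways by a hypergeometric overlap test (p &lt; 10⁻⁴, annotation
   proportion ≥ 70%).
6. **Survival.** Per-molecule univariate Cox coefficients b<sub>i</sub>
   weight a per-sample risk score Σ b<sub>i</sub>·Exp(i); the cohort is
   median-split and the arms compared by Kaplan–Meier curves with a
   two-tailed log-rank test (α = 0.05), including an exhaustive search over
   gene combinations for the most compact prognostic signature.

A seeded synthetic-data generator produces all inputs with planted ground
truth (DE-dense pathway subregions, anticorrelated miRNA-target pairs,
prognostic hazard structure), so every stage can be validated end to end
without any external databases.

## Worked example

```python
from mirsubpath import SubpathwayModel
from mirsubpath.synth import test_scale_spec

model = SubpathwayModel.from_synthetic(test_scale_spec(seed=1))
results = model.fit()
print(results.summary())
```

prints

```
miRNA-mediated subpathway biomarker analysis
====================================================
DE genes (signature)                           18
DE miRNAs (signature)                           4
pathways (UPEMs)                                6
subpathways extracted                           2
subpathways significant                         2
network nodes (genes/miRNAs)              18/4
network edges                                  84
anticorrelated edges                           13
modules (all / miRNA-mRNA)                 2/2
prognostic modules (log-rank p<alpha)           2
degree power-law slope / R^2              0.188/0.044
====================================================
```

(The power-law fit is meaningless on a 22-node toy network; at the
genome-magnitude preset the slope is negative, as expected of a
hub-dominated network.)

The cohort planted two DE-dense subregions of 10 genes each (18 distinct
genes) and three anticorrelated miRNAs; the pipeline recovers both regions
as its two significant subpathways, flags their anticorrelated edges,
finds both as clique-percolation modules, and both modules split the cohort
into high/low-risk arms with log-rank p &lt; 0.05.
`results.recovery()` scores this against the generator's ground truth
(all entries 1.0 here), and `results.plot_km("M1")` /
`results.plot_degree_distribution()` draw the usual figures.

The same run is available from the shell:

```bash
mirsubpath synth --scale test --seed 1 --out data/      # inputs + ground truth
mirsubpath run   --scale test --seed 1 --out out/       # full pipeline + report
```

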