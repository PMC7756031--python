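# Methods

## Differential expression

The two-class statistic is the relative difference
d_i = (x̄_case − x̄_control) / (s_i + s0), where s_i is the pooled
two-sample standard-error term and s0 is a fudge factor that prevents
molecules with near-zero variance from dominating the ranking. s0 defaults
to the 5th percentile of the {s_i}; the full exhaustive s0 optimization of
the original SAM procedure is intentionally not implemented — the
percentile rule captures its damping behaviour with far less machinery and
is configurable for users who want a different choice (including s0 = 0,
which reduces d to the ordinary two-sample t form; this identity is tested).

The FDR is estimated by relabeling: group-size-preserving label
assignments are enumerated exhaustively when there are at most `n_perm`
distinct assignments (results are then seed-independent) and otherwise
sampled without replacement under the seed. For every candidate threshold
on |d| (the observed |d| values), FDR(t) = median over permutations of
#{|d*| ≥ t} divided by the observed #{|d| ≥ t}, clipped to [0, 1]; a
molecule's q-value is the minimum FDR over thresholds at or below its own
|d|, which makes q monotone non-increasing in |d| by construction. The s0
computed from the observed data is reused for all permutations.

Signature thresholds follow the study design: genes at FDR < 0.001, miRNAs
at FDR < 0.05. Externally computed DE lists can be supplied directly
(`signature_from_lists`) when DE calling happens outside the package.

## UPEM construction and mining

Pathways are undirected simple gene graphs; directed input edges are
symmetrized and self-loops dropped on read. A miRNA is embedded into a
pathway iff at least one of its validated targets is a gene node there,
with one edge per contained target; the gene-gene subgraph is never
modified, so stripping miRNA nodes recovers the pathway exactly and
re-embedding is idempotent. miRNA identifiers are matched
case-insensitively with mature-arm suffixes preserved. Both the full
validated-target table and its low-throughput subset are accepted
(`evidence` flag); the default uses all pairs.

Lenient-distance mining: for every pair of signature nodes at unweighted
shortest-path distance ≤ n, the endpoints and the interior nodes of *all*
shortest paths between them form a candidate set; sets sharing any node
merge transitively (element-level union-find); isolated signature nodes
remain singletons. With the default n = 1 this is provably the connected
components of the signature-induced subgraph, and the equivalence is
asserted on random graphs in the test suite. Including all shortest paths
(rather than an arbitrary one) keeps the rule deterministic; it is
irrelevant at n = 1. Candidate sets with ≥ s nodes (default 10) become
subpathways — the induced subgraphs of the UPEM — with ordinals assigned by
decreasing size, ties broken by the lexicographically smallest node.

## Enrichment

Genes and miRNAs are pooled into a single hypergeometric tail:
population m_g + m_mir (genome totals), successes t_g + t_mir (subpathway
molecules), draws n_g + n_mir (signature totals), observation r_g + r_mir.
The tail P(X ≥ r) is computed as a log-space sum of pmf terms via gammaln
and logsumexp; the test suite checks every instance with population ≤ 12
against exact rational arithmetic (max error < 1e-12), and far-tail values
(~1e-16) against published count columns. Benjamini–Hochberg correction is
applied over all extracted subpathways; the default significance rule is
FDR < 0.001. The source study states a raw-p rule in its methods text and
an FDR rule in its results; the FDR rule matches its printed tables and is
the default here, with `use_raw_p=True` available. BH is used because no
specific step-up procedure was named; any monotone alternative can be
plugged in upstream of the threshold.

## CMGN

The network is the union of nodes and edges over significant subpathways;
each edge records its origin subpathways, making the merge
order-independent. Pearson correlations are computed only for miRNA-gene
edges already present in the network, over the intersection of the two
matrices' samples — restricting to network edges yields identical flags on
those edges at a fraction of the cost, and the full miRNA-by-gene matrix
remains available via `correlation_matrix`. Edges with r < −0.7 are
flagged; zero-variance profiles leave r undefined and the edge unflagged.
Expression is used as read (log scale assumed); Pearson r is invariant to
positive affine transforms, so no further normalization is applied.

Topology: degree and normalized betweenness (unweighted, undirected); the
degree distribution is summarized by a least-squares line of
log10(count) on log10(degree) over raw, unbinned degrees ≥ 1 — a
descriptive fit chosen to match how slope and R² are conventionally
reported, not a rigorous Clauset-style power-law inference. Known-disease
nodes (supplied as a plain id list) are compared to the rest by mean ± SEM
of degree and betweenness with a two-sided rank-sum p-value.

## Modules

k-clique communities (default k = 4): two k-cliques are adjacent iff they
share k−1 nodes, and a community is a connected chain of adjacent
k-cliques; nodes may belong to several communities. The implementation
delegates to networkx's maximal-clique-based percolation, which is
contractually identical to exhaustive k-subset enumeration — the test
suite asserts equality against a brute-force oracle on 500 random graphs.
Communities with at least one miRNA and one gene are kept; any whose node
set is contained in another kept community is dropped (the larger module
is retained). Module-to-subpathway annotation reuses the hypergeometric
tail with universe m = all significant-subpathway nodes; a module is
annotated when p < 1e-4 and at least 70% of its nodes lie in the
subpathway. (The source again states p < 0.001 in its methods but applies
p < 0.0001 with the 70% rule in its results; the results-rule is the
default, both are configurable.) The redundancy filter runs after the
miRNA-mRNA restriction, matching the reported workflow.

## Survival

Univariate Cox PH fits use lifelines (Newton-Raphson, Efron tie handling —
chosen because the source is silent on ties and Efron is the modern
default). Non-convergent fits (monotone likelihood) are reported with
`converged=False` and dropped from risk models. The risk score is
Σ b_i·Exp(i); samples strictly above the median score are the high-risk
arm, ties go to the low arm (a fixed deterministic convention). Log-rank
is the standard two-group (O−E)²/V chi-square with 1 df, two-tailed;
significance at p < 0.05. Coefficients are re-fitted on the evaluation
cohort itself, mirroring the study design (an optional
`coefficients=` argument supports a train/apply split). Modules with less
than 60% of molecules matched to the expression profile trigger a warning,
mirroring the exclusion rule of the study. The combination search
enumerates every non-empty subset of a module's coding genes (miRNAs by
flag), re-fits coefficients per subset, and ranks by log-rank p with ties
broken by fewer molecules then lexicographic ids; searches above 10^7
subsets are refused unless bounded.

## Synthetic data generator

The generator emulates a two-condition (tumor vs. normal) expression study:

- **Pathways** are connected Watts–Strogatz small-world graphs over genes
  drawn from the genome pool, so genes recur across pathways. A fraction
  of pathways receives a *planted subregion*: 10 contiguous nodes
  densified with extra edges (probability 0.6) so the region is clique-rich
  and can be found by k = 4 percolation, then verified connected.
- **Expression** is baseline N(8, 1) per molecule plus N(0, noise_sd)
  per sample (log2-microarray-like units). Planted subregion genes get a
  case-mean shift `de_effect` (default 2.0 at noise 0.5 with 20+20
  samples — strong but realistic microarray effect sizes).
- **Anticorrelated miRNAs** mirror their partner gene's profile around
  their own baseline with 10% relative noise, guaranteeing Pearson
  r ≈ −1 without tuning, and are each given a target triangle inside a
  planted subregion so they participate in 4-cliques. Their inherited
  −de_effect shift makes them the planted DE miRNAs.
- **Targets** are Poisson(target_density) per miRNA, biased 80:20 toward
  pathway genes; planted pairs are always included.
- **Survival** is exponential proportional hazards with baseline median
  24 months; the linear predictor is `survival_beta` times the summed
  z-scored expression of the planted prognostic molecules (z-scoring keeps
  the hazard scale independent of the arbitrary log-expression baseline).
  Censoring is independent exponential with rate tuned (via the geometric
  mean hazard) to the requested censored fraction, default 0.3.

Two presets are provided: a test scale (60 genes, 12 miRNAs, 6 pathways,
20+20 samples) used throughout the tests, and a genome-magnitude scale
(6,000 genes, 400 miRNAs, 343 pathways, ~100 planted subregions) whose
pipeline counts land in the magnitude of a real genome-wide study.

What the generator does **not** emulate: microarray normalization
artifacts, batch effects, probe-level duplication, correlated background
co-expression, non-proportional hazards, and the imperfect overlap between
expression platforms and pathway annotation. Passing recovery tests
therefore demonstrate the pipeline's correctness and calibration under the
assumed model, not its field performance on real cohorts.

## Numerical choices and degenerate inputs

- All randomness flows from one root seed through fixed per-stage
  sub-seeds (`numpy.random.default_rng((seed, stage))`); reports are
  byte-identical under identical config + seed.
- Hypergeometric tails short-circuit to 1.0 at or below the support lower
  bound; counts are validated (r ≤ min(t, n), t + n bounds).
- d statistics with zero numerator and zero denominator are defined as 0.
- Median-split ties always fall to the low arm; an all-tied split raises.
- Writers sort rows lexicographically; GraphML list attributes are
  '|'-joined strings.
- Pipeline problem sizes in tests and the acceptance script (test-scale
  cohorts, 20–100 replicate seeds, 100 permutations) are chosen so the
  whole suite completes in well under a minute while keeping binomial
  noise on the asserted rates far from the thresholds.

## Known limitations

- The permutation FDR is the SAM-flavored median-ratio estimator, not a
  full plug-in q-value procedure; with few distinct permutations its
  granularity is coarse (q can be exactly 0, as in published FDR = 0 rows).
- The power-law fit is descriptive least squares on the degree histogram.
- The combination search refits coefficients on the same cohort it
  evaluates, as in the emulated design; its p-values are optimistically
  biased and should be read as ranking scores, not inference.
- KGML parsing, probe-to-gene mapping, GO/hallmark enrichment and disease
  database curation are out of scope; pathway inputs must be gene-resolved
  and known-disease labels arrive as a plain id list.
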