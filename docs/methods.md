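# Methods

## Over-representation model

The core statistic treats the interaction database as an urn of *M*
interactions. For a candidate item (a miRNA when the input is a gene list,
a gene when the input is a miRNA list) with *K* interactions, of which *X*
touch the *N*-item input list, the p-value is the hypergeometric upper tail
P(count ≥ X). It is computed by summing the tail of the pmf in log space
(log-binomials via `gammaln`), which keeps relative error near 1e−8 for M
up to ~1e6. The tail is always summed directly on the upper side:
computing 1 − (lower tail) would amplify the absolute error of
large-argument log-binomials into percent-level relative error whenever the
tail probability is tiny.

Two urn conventions are offered:

* **interactions** (default, the tool's native convention): M = total
  interactions, N = input-list length. This mixes interaction counts with
  gene counts: for a gene list drawn uniformly from the DB's genes, a
  candidate miRNA's expected overlap is K·N/G (G = number of distinct
  genes), while the urn's null expects K·N/M. Since M > G whenever genes
  carry more than one interaction each, the default urn is structurally
  anticonservative by roughly M/G for *every* miRNA. We keep it as the
  default for fidelity and expose the behaviour rather than hide it.
* **entities** (`universe="entities"`): M = distinct genes in the DB,
  K = distinct targets of the miRNA — a self-consistent urn for users who
  want calibrated p-values.

Multiple testing uses Benjamini–Hochberg (the ecosystem default when only
"FDR" is specified), adjusted over **all** candidates with K ≥ 1 in the
database, not only those overlapping the input — restricting the family to
X ≥ 1 items would be anti-conservative. Rows with X = 0 are dropped from
the report after adjustment. Default filter: FDR ≤ 0.05, overlap ≥ 1.

Identifier conventions: miRNA IDs are case-sensitive (miRBase
capitalisation is meaningful), gene symbols are upper-cased on input.
Duplicate (miRNA, gene) pairs collapse to the best score (predicted; more
negative = stronger predicted repression, the context++ convention) or the
strongest evidence (validated). miRTarBase support-type strings containing
"(Weak)" map to the *weak* evidence category; all others to *strong*.
"Top K targets" ranks predicted interactions by ascending score; validated
interactions, which carry no score, rank by the number of supporting
evidence rows before deduplication, ties broken lexicographically.

## Network topology

The filtered interactions form a bipartite graph. Metrics are computed per
connected component (filtered enrichment networks are routinely
disconnected): eccentricity, closeness ((n_c − 1)/Σd within the component)
and average shortest path use unweighted BFS distances to reachable nodes
only; betweenness is reported unnormalized by default (flag for the
2/((n−1)(n−2)) normalisation). The triangle-based clustering coefficient is
identically zero on any bipartite graph; it is reported anyway because it
belongs to the standard panel, and a square-clustering (4-cycle) alternative
is available behind a flag for users who want a non-degenerate bipartite
analogue.

The power-law fit is ordinary least squares of log10 P(k) on log10 k over
the degrees observed with nonzero probability — exactly the straight line
drawn on a log-log degree plot — rather than a Clauset-style discrete MLE.
This estimator is faithful to the plot but sensitive to sparsely observed
high-degree bins: bins observed once sit far above the true pmf and flatten
the slope, so recovery experiments bound the degree support where each bin
is estimable (see tests). At least two distinct positive degrees are
required; a regular graph raises a degeneracy error.

## Synthetic interaction generator

`generate_synthetic_db` emulates a predicted interaction table: each of
`n_mirnas` synthetic miRNAs draws its target count from a bounded discrete
power law P(k) ∝ k^−γ on [min_targets, max_targets] and samples that many
distinct targets uniformly from `n_genes` gene symbols, with i.i.d.
negative exponential scores standing in for ranking scores. Defaults
(γ = 1.8, k ∈ [20, 2000]) give per-miRNA target counts spanning tens to
thousands with a heavy upper tail, comparable in spread to genome-scale
predicted-target tables, and leave roughly a tenth of miRNAs with ≥ 500
targets so that the top-target budgets of the detection benchmark are
satisfiable by a comfortable margin. The generated degree law is verified
by a bounded-power-law maximum-likelihood fit (grid-refined), since OLS on
a bounded discrete law's histogram is biased.

What the generator does **not** emulate: correlated target sets between
miRNAs of the same family, seed-type structure in scores, expression–
connectivity correlation, and gene-level covariates. Conclusions from
synthetic benchmarks therefore speak to the pipeline's statistical
behaviour, not to biological recovery rates on real databases.

## Detection benchmark

The simulator plants miRNA activity in a 100-sample expression matrix
(50 affected / 50 unaffected by default): baseline E(g,s) ~ N(0,1) i.i.d.;
the j-th active miRNA represses its top `target_counts[j]` targets
(budgets 100, 200, …, 1000 for ten active miRNAs at reference scale) in
every affected sample by α + ε, ε ~ N(0,1), so a repressed entry is
N(0,1) − (α + N(0,1)) with expectation −α and variance 2. A gene targeted
by several active miRNAs is repressed once. The activity grid is
α ∈ {0.30, 0.35, …, 1.00}.

The input gene list at each α is derived by a per-gene one-sided Welch
t-test (affected < unaffected) at BH FDR ≤ 0.05 — the simplest defensible
reading of "repression reduces expression"; method and threshold are
configurable. A miRNA counts as detected when it survives the default
enrichment filter. TPR is the detected fraction of active miRNAs, FPR the
detected fraction of inactive ones; one (FPR, TPR) point per α, and the
ROC is the staircase through the sorted unique points anchored at (0,0)
and (1,1), with trapezoidal AUC.

The active set is drawn once per evaluation (uniformly among miRNAs with
at least `max(target_counts)` targets — a "top 500 targets" budget
presupposes 500 targets) and held fixed across the sweep; each α level
then receives independent noise, seeded from the master seed by a fixed
per-level offset, so runs are reproducible and levels are uncoupled.

Desk-scale conditions used throughout tests and the acceptance script:
200 miRNAs × 5000 genes, 5 active miRNAs with budgets 100…500, the full
α-grid, 10 replicate seeds. A sweep takes ~1.5 s, the whole benchmark
under half a minute on one CPU; at this scale the mean AUC sits near 0.97.
At high α the FPR also grows — a direct consequence of the
anticonservative interaction universe described above, visible as
large detected sets once the input list is big.

## Tissue-style precision harness

`select_representative_mirnas` mirrors profiling practice: repeat
measurements of a profile are averaged, then miRNAs strictly above the
75th percentile (linear-interpolation quantile) of the profile's values
are taken as representative. `ppv_evaluation` feeds a representative
protein list to the gene-list enrichment under defaults and scores
PPV = TP/(TP + FP) of the detected miRNAs against the representative set
(undefined, not zero, when nothing is detected).

The acceptance script's synthetic stand-in assigns 50 of 200 miRNAs a
high expression profile, lets 10 of them define the protein list via their
top-30 targets, and scores PPV. Because the synthetic DB has no
expression–connectivity correlation and the default urn flags most
well-connected miRNAs once the list is a few hundred genes, the synthetic
PPV lands near the representative base rate (~0.3) rather than the high
precision reachable on real tissue data — a property of the stand-in, not
of the harness.

## Numerical and design choices

* BH adjustment delegates to `statsmodels`; graph metrics delegate to
  `networkx`; both are verified against from-scratch oracles
  (min-over-suffix step-up; pairwise BFS with path counting) in the tests.
* Percentile selection uses the linear-interpolation quantile and a
  *strict* inequality, so a constant profile selects nothing.
* `filter_results` rejects a zero threshold (it would silence everything);
  empty filtered results produce an empty network with a warning, not an
  error.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  derived seeds come from `SeedSequence` composition and stay below 2^31.

## Known limitations

* The interaction-universe p-values are not calibrated (see above); use
  the entity universe when calibration matters.
* The OLS power-law exponent is biased when high-degree bins are observed
  ~once; it is a descriptive fit of the log-log plot, not an estimator of
  choice for tail inference.
* Validated-interaction ranking by support count is a surrogate; real
  effect sizes are not modelled.
* Species handling is a tag, not an orthology mapping; identifier
  conversion beyond case normalisation is out of scope.
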