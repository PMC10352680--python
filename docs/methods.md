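# Methods

## Scope and model

`keygenet` implements a consensus hub-detection analysis for two-group
transcriptomic studies: differential expression seeds a confidence-filtered
PPI subnetwork, seven node-centrality algorithms score the subnetwork's
core, and the genes common to all seven top-10 lists are nominated as key
genes; a bipartite drug–key-gene ranking then proposes repurposing
candidates. The statistical model is deliberately plain: expression values
are treated as approximately Gaussian on the log2 scale (normalized
microarray intensities or log-transformed counts), the two groups are
independent with possibly unequal variances, and the interactome is an
undirected simple graph whose integer confidence scores are comparable
across edges.

## Differential expression

Per gene, the effect is the case-minus-control difference of means on the
log2 scale and significance is a two-sided Welch t-test. A gene is a DEG
when *p* < 0.05 **and** |log2FC| > log2(1.2) ≈ 0.2630344, both strict
inequalities. No multiple-testing correction enters the call: the screening
criterion is intentionally liberal, as is common for network-seeding DEG
lists; a Benjamini–Hochberg column is emitted for information. Moderated
(empirical-Bayes) variance estimation is not implemented — with 10 samples
per group the Welch test is adequately powered for the effect sizes of
interest, and the package's contribution lies downstream of the DE call.
Degenerate genes with zero variance in both groups get *p* = 0 when the
means differ and *p* = 1 otherwise (the limit of the test statistic);
groups with fewer than two samples are rejected.

Calibration is tested: on ≥ 2500 simulated null genes the empirical
*p* < 0.05 rate must lie within three binomial standard errors of 0.05, and
exchanging the group labels must negate every log2FC while leaving every
p-value unchanged.

## Network construction

Edges with combined score strictly greater than 900 (a stringent
high-confidence cutoff on the 0–1000 scale) are kept; the graph is induced
on the DEG set; DEGs with no retained edge are counted but excluded.
"Removing scatters" is interpreted as keeping the largest connected
component — removing only isolated nodes cannot delete edges, whereas
dropping minor components does, which matches how core networks shrink in
practice. A `min_component_size` alternative is exposed for users who
prefer a size cutoff; the default remains the largest component, with ties
broken toward the component containing the lexicographically smallest gene
id. Gene identifiers are matched as exact strings; alias resolution is out
of scope.

## Centrality algorithms

All eleven algorithms operate on the simple undirected core graph.
Numerical and convention choices that the formulas alone do not fix:

- **EPC** (threshold 0.5, 1000 replicates, seeded): each replicate deletes
  every edge independently with probability 0.5; a node's per-replicate
  statistic is the size of its connected component, itself included
  (δ_xx = 1, which makes the edgeless graph well defined at score 1/|V|).
  Scores are averaged over replicates and divided by |V|; the raw
  sum-over-replicates variant is available behind `normalized=False` and is
  an exact monotone rescaling, so rankings — the only downstream use — are
  unaffected. The Monte-Carlo estimator is validated against exhaustive
  enumeration over all 2^|E| edge subsets on every non-isomorphic graph
  with ≤ 5 nodes and ≤ 6 edges.
- **Katz** uses α = 0.1 and includes the length-zero walk (the summation
  starts at k = 0), computed as row sums of (I − αA)^{-1}; a requested α
  at or above 1/λ_max raises an error naming the admissible bound. The
  closed form is checked against a 200-term truncated power series to
  1e−10.
- **Laplacian centrality** is evaluated by the degree formula and verified
  exactly (integer arithmetic) against the energy-drop definition
  E(G) − E(G − x) with E = Σ deg² + 2|E|.
- **Radiality**, closeness, betweenness, stress and reciprocal eccentricity
  require a connected graph; the pipeline guarantees this via core
  extraction, and the functions refuse disconnected input rather than
  inventing an unreachable-pair convention. Reciprocal eccentricity
  (1/max_y s(x,y)) is the eccentricity-based variant consistent with
  published score tables (values like 0.125 = 1/8 and 0.111 ≈ 1/9).
  Betweenness and stress count each unordered endpoint pair once.
- Ranking ties are broken lexicographically by gene id everywhere, so all
  outputs are deterministic; a tie crossing the top-k boundary is flagged
  in the provenance JSON rather than silently resolved.

## Consensus

`top_k` defaults to k = 10; the key-gene set is the intersection of the
seven top-10 lists, which is monotonically non-increasing in the number of
algorithms intersected. Include-first lexicographic tie handling at rank k
was chosen over include-all-ties to keep list lengths fixed; the flag in
the provenance lets users audit any affected run. Co-expression of the key
genes is summarized as per-group Pearson correlation matrices (Spearman is
a trivial substitution via pandas but Pearson matches the log-scale
Gaussian working model); no formal test of between-group correlation
differences is performed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
at the default study design: 10 vs 10 samples, 1000 genes, 100 planted DEGs
with |log2FC| = 1 (signs random per gene) and i.i.d. Gaussian noise with
SD 0.5 on the log2 scale; a Barabási–Albert backbone (m = 2) over all genes
with scores uniform on [400, 1000] so the 900 filter is non-trivial; and a
hub module overlaid at scores in (901, 1000]. `noise_sd = 0` is accepted as
the degenerate deterministic limit used by exactness tests.

The hub module contains, besides the four mutually connected hubs (each
wired to ≥ 15 planted DE genes, with satellite counts decreasing across
hubs so hub degrees differ), two structurally distinct **decoy families**:
eight *connectors* adjacent to every hub (globally central, locally
sparse) and an eight-gene *spike* clique attached to the last hub (locally
dense, globally peripheral). Degree-driven measures (degree, MNC, EPC)
admit spikes into their top-10 but exclude connectors; distance- and
neighbour-quality-driven measures (radiality, Laplacian, Katz, SLC) do the
reverse. Only the hubs survive the seven-way intersection, so exact hub
recovery genuinely exercises the consensus rather than any single
algorithm. A pre-build Monte-Carlo calibration over 200 seeds put exact
recovery at ≈ 95–96%; the residual failures are almost entirely runs in
which one hub misses the *p* < 0.05 cutoff (per-gene Welch power ≈ 0.99 at
effect size 2, so all four hubs pass in ≈ 0.99⁴ ≈ 96% of runs) — an
irreducible property of the study design, not of the consensus.

Not emulated: probe-level structure and triplicate-array averaging, batch
effects, heavier-tailed noise, correlated expression outside the planted
key-gene factors, score-dependent edge densities, and identifier aliasing.
Passing tests therefore demonstrate correctness of the algorithms and the
recoverability of planted structure under the stated noise model — not
robustness to the full messiness of real array data.

Drug–target tables assign nervous-system ATC codes (plus a few non-N decoy
drugs to exercise the filter) and fix the number of drugs hitting exactly
4/3/2/1 key genes at 14/8/19/35 by construction, with `candidate_min = 3`
flagging 22 candidates; bucket sizes are configurable, and buckets
requiring more hits than there are key genes are rejected (the pipeline
clips them when a simulation plants fewer hubs).

## Reproducibility and problem sizes

A single pipeline seed fans out by fixed offsets (simulation: seed; EPC:
seed + 10; generator sub-streams: +1/+2), so identical configurations give
byte-identical manifests and adding stages never perturbs existing ones.
The test suite validates oracle equivalence on graphs of ≤ 8 nodes (100
random connected graphs), EPC on the ≤ 5-node atlas graphs, and hub
recovery over 200 full pipeline runs at the default design; the acceptance
script uses 100 runs for its recovery rate and 2500 genes for calibration.
These sizes give binomial standard errors of ~2% on recovery-type rates
while keeping a full run in the tens of seconds on one core.

## Known limitations

- Welch testing without variance moderation loses a little power at very
  small sample sizes relative to empirical-Bayes approaches.
- The consensus depends on k: smaller k approaches the top-degree gene,
  larger k dilutes toward the whole core; k = 10 is convention, not
  optimum.
- EPC rankings inherit Monte-Carlo noise; near-tied nodes can swap ranks
  across seeds (the recorded seed makes any run reproducible).
- Exact-string gene matching will silently drop interactions whose
  identifiers differ in case or aliasing from the expression matrix.
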