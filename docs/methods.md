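# Methods

## Scope and model

`hsnet` implements the network half of a systems-level analysis of heat shock
response (HSR) regulation in *C. elegans*. The inputs are (i) the hit lists
of a genome-wide RNAi screen — 7 positive regulators whose knockdown blocks
heat-shock induction of an HSF1-dependent reporter, and 52 negative
regulators whose knockdown constitutively activates it, each scored for
reporter induction in spermatheca, intestine, and muscle — and (ii) a
background interactome given as an undirected edge list pooling physical,
genetic, and predicted interactions. The analysis asks three questions:

1. **Connectivity.** Do the screen hits interact with each other more than
   random gene sets do? The regulator-induced subgraph is extracted
   (hits absent from the interactome are retained as isolated nodes, so the
   "k of n connected" accounting keeps the full hit list in its
   denominator), its components are summarised, and the induced edge
   density is compared with densities of uniformly drawn node sets of the
   same size.
2. **Modularity.** Does the regulator subnetwork decompose into modules?
   Newman–Girvan modularity `Q = Σ_s (e_ss − a_s²)` is maximized on the
   largest connected component, and the observed maximal `Q` is compared
   with maximal `Q` values of degree-preserving randomizations.
3. **Tissue concordance.** Do the interaction-derived modules line up with
   the tissue-selective induction patterns? Module assignments are compared
   against per-gene S/I/M categories with the adjusted Rand index, purity,
   and a label-permutation test.

## Modularity maximization

Three optimizers share one scoring function (each edge counted once, no
resolution parameter; a one-module partition scores exactly 0):

* **Simulated annealing** (default). Moves are single-node reassignments to
  a neighbouring module or a fresh singleton, plus collective moves that
  merge two random modules or split one by random bisection; acceptance is
  Metropolis on ΔQ, computed incrementally in O(degree). The initial
  temperature is calibrated from a sample of proposed moves so that the
  median worsening move would be accepted with probability ½; cooling is
  geometric with factor 0.95 per temperature stage; each stage performs n²
  node moves and n collective moves. A stage counts as *stale* only when the
  chain is effectively frozen (under 5 % of proposals accepted) and the best
  `Q` did not improve; the run stops after 5 consecutive stale stages
  (hard cap 500 stages). Each of 3 restarts ends with a deterministic
  zero-temperature hill climb on its best partition; the best restart wins
  and is never worse than the one-module baseline (`Q = 0`).

  The stop rule deserves a note: a literal "5 temperatures without
  improvement" criterion, combined with very slow cooling, terminates while
  the chain is still hot — on 39-node planted benchmarks it returned 8–13
  fragmented modules at `Q ≈ 0.30` against a true optimum of `0.63`. Tying
  staleness to the frozen regime and adding the final hill climb fixes
  this; with the settings above the annealer matches the exhaustive optimum
  on 50/50 random graphs with n ≤ 8 and recovers planted partitions with
  ARI 1.0 on 20/20 default-condition benchmarks.

* **Greedy agglomeration.** Starting from singletons, repeatedly merge the
  connected pair of modules with the largest ΔQ (ties broken
  lexicographically by smallest member), tracking the best partition along
  the whole merge path. Fully deterministic, which makes it the optimizer
  of choice inside Monte Carlo nulls.

* **Exhaustive enumeration.** All set partitions, feasible to n = 10
  (Bell(10) = 115 975); serves as ground truth in tests.

Partitions are reported in canonical form — modules numbered by decreasing
size, ties by lexicographically smallest member — so equal groupings compare
equal. All randomness flows from one integer seed; identical seeds reproduce
identical results bit for bit.

## Null models and p-values

**Degree-preserving rewiring.** Realizations are produced by accepted
double-edge swaps (10 per edge, a standard mixing heuristic); proposals
creating self-loops or duplicate edges are rejected without counting, so the
node-wise degree sequence and simplicity are exact invariants. Graphs with
no valid swap (e.g. stars) are returned unchanged with a warning after a
bounded proposal budget. A count-preserving G(n, m) null is available as an
option for the looser "same number of nodes and connections" reading.

**Null statistic.** Each realization is re-optimized with the *same*
optimizer and budget as the observed graph; realizations that disconnect
are scored on their largest component. Re-optimizing (rather than re-scoring
the observed partition) is the conservative choice.

**Empirical p-values** use the +1 pseudocount, `p = (1 + k)/(1 + N)` with
ties counted as exceedances, hence `1/(N+1) ≤ p ≤ 1` and never exactly zero.
The library default is N = 10⁴ realizations (minimum attainable p below
10⁻⁴); the pipeline and the reproduction script run N = 999 with the greedy
optimizer on both sides of the comparison, which keeps a full run under two
minutes on one core while leaving the calibration and floor behaviour
unchanged. Under the null (a rewired graph tested against its own rewiring
null) the p-value distribution is approximately uniform; tests check the
median over 20 repeats lies in [0.2, 0.8] and apply a coarse
Kolmogorov–Smirnov bound.

## Tissue-pattern concordance

Module/label agreement is quantified by the adjusted Rand index between the
module assignment of the largest component and each gene's tissue category
(the raw S/I/M triple, one of 8 categories, uncollapsed), with purity (the
fraction of genes carrying their module's majority category) as a
descriptive companion, and a permutation test that shuffles labels across
nodes. ARI is the standard chance-corrected choice when neither grouping is
privileged; purity alone would reward fragmenting modules.

## Synthetic interactomes

The background interactome used in the original analysis is not
redistributable, so the generator emulates its relevant statistics:

* **Background:** a preferential-attachment graph (heavy-tailed degrees)
  with 2 000 genes and mean degree ≈ 4 by default — large enough for
  realistic density nulls, small enough for second-scale runs. Heavy tails
  matter because they are what the degree-preserving null must cope with.
* **Planted regulator modules:** 52 regulators in q = 3 near-equal modules;
  within-module edges Bernoulli(p_in = 0.6), between-module
  Bernoulli(p_out = 0.02). A `connect_fraction` (default 39/52) share of
  each module is wired into the regulator subnetwork; the rest receive no
  regulator–regulator edges, emulating screen hits absent from interaction
  data. Because `connect_fraction` *targets* the giant-component size, the
  generator adds the minimal number of random between-component links when
  the Bernoulli draws happen to leave wired clusters mutually disconnected
  (never when p_out = 0, preserving the disjoint-clique limit case).
  Regulator–background attachment is sparse: Poisson(mean degree × p_out)
  partners per regulator, so it scales with p_out and never swamps the
  planted structure.
* **Tissue labels:** each module gets a distinct canonical category (the
  first three echo the observed correspondence: spermatheca+intestine,
  muscle-only, intestine-only); each gene keeps its module's category with
  probability 1 − flip_rate (default 0.1), otherwise drawing uniformly from
  the *other* categories. One consequence worth knowing: with only two
  labels, flip_rate = 1 is the deterministic complement bijection and ARI
  stays 1; the chance-level baseline occurs at the uniformizing rate ½.
* **Determinism:** every stage draws from its own substream derived from
  the single seed by fixed offsets.

The defaults echo the observed geometry of the real regulator network
(3 modules, 39 of 52 hits connected). They are echoes, not claims: passing
tests on synthetic data show the machinery recovers planted structure under
interactome-like sparsity and degree heterogeneity, not that any particular
real interactome yields the same modules. Reproducing the real 39/52
component, the exact module composition, or the original p < 10⁻⁴ requires
the original background network, which users can supply as an edge list.

When the pipeline simulates a background for the packaged negative-regulator
table, planted modules follow the observed tissue-pattern classes collapsed
onto three anchors (S+I, M-only, I-only; the two genes inducing in all three
tissues join S+I by Hamming distance), so the synthetic mode exercises the
module/tissue concordance stage with realistic label structure.

## Numerical and degenerate-input choices

* Node IDs are case-sensitive strings; cosmids are the canonical key for
  joining tables to networks (several screen hits have no gene name); an
  optional two-column alias map translates gene names to cosmids.
* Tie-breaks are lexicographic on node ID everywhere (canonical module
  labels, largest-component selection, greedy merges).
* `modularity` refuses edgeless graphs (undefined); the SA and the
  rewiring null refuse disconnected inputs and direct the caller to the
  largest component; exhaustive search refuses n > 10; ARI refuses single
  items; the permutation test refuses degenerate (single-module or
  single-label) inputs.
* Density enrichment drops gene IDs missing from the background with a
  warning and requires at least two mapped genes; the enrichment ratio is
  undefined (NaN) when the background density is zero.
* Floating-point ties in empirical p-values are counted as exceedances
  (tolerance 10⁻¹²), keeping p-values valid under ties.

## Problem sizes used in tests and the reproduction script

Unit and acceptance tests run on graphs of 3–45 nodes; Monte Carlo checks
use N = 49–999 realizations; planted-recovery and calibration statements
aggregate 20 independent seeds. The reproduction script
(`scripts/acceptance.py`) runs the full pipeline at the default generator
scale (2 052 nodes) with N = 999 for each null and 20 seeds for the
recovery and calibration summaries. These sizes were chosen so a complete
run finishes in about a minute on a single core while every Monte Carlo
floor (1/(N+1)) remains well below the decision thresholds it supports.

## Known limitations

* The synthetic background reproduces sparsity and heavy-tailed degrees but
  not the correlation structure of real interactomes (clustering, date/party
  hub distinctions, study-bias toward well-known complexes).
* Modularity maximization inherits the resolution limit of plain
  Newman–Girvan `Q`; very small modules attached to large ones may be
  absorbed.
* The annealer's guarantees are empirical (oracle battery, planted
  recovery), not worst-case; pathological graphs may require more restarts.
* Interaction evidence types are pooled; no weighting of physical vs
  predicted edges is attempted.
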