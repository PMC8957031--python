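# Methods

## Signatures and symbol handling

A `GeneSignature` is an ordered, deduplicated gene set with optional up/down
direction split and species/tissue/dose/duration metadata. All matching is
case-insensitive: human symbols are conventionally uppercase and rodent
symbols capitalized, and case-sensitive matching silently destroys
cross-species overlaps. Internally every comparison uses uppercased symbols;
outputs preserve the casing of the first occurrence. Up and down halves must
be disjoint; a gene appearing in both is a data error and raises.

Ortholog translation expands many-to-many mappings to the union of all
targets (the mapping tables give no basis for choosing one), drops unmapped
genes, and records both counts on the returned signature so silent shrinkage
is visible. Signatures larger than the 500-gene cap are truncated to the
genes with the smallest ranking statistic (FDR or p), pooled across both
directions, with ties broken by symbol order so truncation is deterministic.

Cross-tissue/species comparison reports pairwise overlap percentages on
direction-pooled sets. The denominator is configurable (union, smaller set,
or mean size); the default is the union (Jaccard percentage), since the
union is the only choice that is simultaneously symmetric, bounded by 100,
and insensitive to which signature is listed first. Exclusive
intersection-region counts (UpSet semantics: every gene of the overall
union is assigned to exactly one subset combination) accompany the table,
and their sum always equals the union size.

## Overlap scoring

For a drug set A and query set B in a universe of U genes, the one-sided
Fisher's exact test of the 2×2 table gives the enrichment p-value, the
sample odds ratio is reported (infinite for saturated tables), and fold
enrichment is (|A∩B|/|A|)/(|B|/U). The universe defaults to the union of
all library genes plus the query — the smallest set every tested gene
demonstrably belongs to — and can be overridden when a platform-specific
roster is known. The signed Jaccard score treats an empty-union term as 0,
so one-directional signatures degrade gracefully instead of erroring.
p-values are BH-adjusted across the drugs scored in a single run (per-query
semantics), and drugs with adjusted p < 0.05 are flagged.

## Network proximity and the degree-matched null

Distances are unweighted shortest paths on the undirected projection of the
input network. Edge direction encodes inferred regulatory orientation and
edge weights encode confidence; neither is a travel cost, and proximity —
not causality — is what is being measured. The observed statistic is the
mean over drug genes of the distance to the nearest query gene, computed by
one multi-source BFS from the query set. Drug genes with no finite path are
excluded from the mean and counted rather than assigned an arbitrary
penalty. Signatures need strictly more than 10 genes in the network to be
scored (the variance of the mean over fewer genes is too high); the filter
is overridable.

The null redraws gene sets preserving degree profiles. Candidates come from
exact-degree pools; any pool with fewer than 10 nodes is merged with the
nearest-degree pools until it has at least 10, so that rare-degree genes
(hubs, typically) are not resampled deterministically. Both the drug and
the query set are permuted per replicate by default, since hub bias affects
both sides; a drug-only mode exists. The z-score standardizes the observed
distance by the null sample's mean and standard deviation (the sample sd is
the conventional permutation-test scale), the empirical p uses the +1
correction, and significance is called at z < −2.33 (one-sided 0.01).

A known property of degree-matched nulls on scale-free graphs: when the
observed query contains unique hubs, the merged pools substitute somewhat
less central nodes in the permuted sets, which biases z slightly negative
(about −0.2 to −0.4 on the default fixture) even for random drug sets under
the default both-sets permutation. The calibration check therefore uses the
exact self-consistency construction — the observed drug set is itself drawn
by the null sampler and only the drug set is permuted — under which z is
standard normal to within sampling error. Interpreting z-scores near the
cutoff for hub-rich queries should keep this conservatism in mind.

Drug ranking spawns one child seed per signature from a root seed
(`numpy.random.SeedSequence`), so results are bit-reproducible and
independent of scoring order. The attached percentile is the fraction of
competitor drugs with strictly worse (higher) z, in [0, 1]; a single drug
gets 1.0 by convention.

## Meta-signatures (robust rank aggregation)

Each dataset contributes a normalized rank vector per direction (rank /
roster size, in (0, 1]). The default ranker orders genes by a standardized
mean difference between treated and control groups — a deliberately simple,
documented stand-in; any external ranker producing normalized ranks plugs
in unchanged. For one gene with order statistics r(1) ≤ … ≤ r(k) across k
lists, the score is rho = min_j P(Beta(j, k−j+1) ≤ r(j)); the per-gene
p bound is min(k·rho, 1), and gene calls apply a further Bonferroni factor
for the per-direction roster size, at threshold 0.01. Genes absent from a
list carry the worst rank 1.0, the standard convention for partial lists.
Up and down directions aggregate independently; a gene significant in both
is assigned to the direction with the smaller corrected p and flagged
ambiguous. Species-level aggregation pools all of a drug's lists across
tissues and reruns the aggregation (a union-of-tissue-calls mode exists).

The double correction is deliberately conservative and has a hard
combinatorial consequence worth knowing: with k = 3 lists and a 500-gene
roster, a gene must rank within the top ~9 of every list to clear the 0.01
threshold (3·(m/500)³·500 < 0.01 ⇒ m ≤ 9.4), so if 10 genes share the top
of all lists, at most ~9 — typically ~7 — can ever be called. The planted-
signal tests assert recovery at this attainable level.

## Toxicity subnetworks

The subgraph induced by the toxicity genes present in the network is
partitioned by Louvain modularity optimization at resolution 1.0 (no
evidence favors another value; the seed is explicit and fixed).
Communities under 10 genes are discarded and counted; retained plus
filtered genes always partition the toxicity genes in the network. Each
retained community then serves as an independent query for either scoring
engine, which lets a drug's signal concentrate in one mechanism-specific
subnetwork instead of being diluted by the full set.

## Benchmarking

AUROC uses the midrank formula (ties count half), with a one-sided
normal-approximated Mann–Whitney p for separation. Balanced accuracy is
100·(sensitivity + specificity)/2 from the confusion counts of a
significance cutoff. Two-group comparisons use the Wilcoxon signed-rank
test when paired and the Mann–Whitney rank-sum test when independent (the
report names which ran); Kruskal–Wallis covers more than two groups.

The masking experiment subsamples the query signature at each proportion
(20 seeded repeats by default), reruns repositioning, and records the
AUROC. Subsampling uses independent child seeds per repeat while the
scoring itself uses one seed shared across all repeats and proportions;
this isolates the effect of masking from permutation noise and makes the
proportion-1.0 repeats reproduce the unmasked AUROC exactly. Proportions
leaving fewer than 5 genes are skipped with a warning.

## Synthetic fixtures

The default benchmark emulates the study conditions of the retrieval
experiments at desk scale: a 200-node Barabási–Albert network (m = 2) —
preferential attachment supplies the heavy-tailed degree distribution that
makes degree matching non-trivial — a 30-gene connected disease module
grown by BFS from a random start, and 20 drug signatures of 30 genes, 5 of
them positive. Positive drugs draw 80% of their genes (proximity level 0.8)
from the module first, spilling into first neighbors only when the module
is exhausted, and the rest uniformly from the whole network; negative drugs
are degree-matched redraws of the positives' degree profiles, so retrieval
cannot ride on a degree confound. An Erdős–Rényi topology exists for
calibration studies. All generators are pure functions of (spec, seed).

What the fixtures do not emulate: real drug signatures share genes across
drugs, carry platform- and batch-structured noise, and live on networks
with community structure and measurement bias far richer than a BA graph.
Passing the synthetic benchmark shows the machinery is correct and
calibrated — it does not certify retrieval performance on real libraries.

## Problem sizes and numerical choices

The bundled test and acceptance runs use 150-1,000 permutations, 200-node
networks, 200 calibration replicates, and 20 masking repeats per
proportion — sizes chosen so the full suite exercises every stage at
meaningful statistical resolution while remaining quick on one CPU; the
library defaults (1,000 permutations) apply to real analyses. Empirical
p-values are +1-corrected and never zero; Fisher p-values are clamped to
(0, 1]; a degenerate null (sd = 0) yields z = 0 when the observed distance
equals the null mean and signed infinity otherwise. Ties everywhere break
by canonical (uppercased) symbol order or drug id, so every ranking is
deterministic.

## Limitations

- Shortest-path proximity ignores edge direction and weight by design;
  regulatory cascades with strong directionality may be misrepresented.
- Degree-pool merging makes the null slightly conservative for hub-rich
  queries (see above).
- The RRA threshold inherits the double-Bonferroni conservatism; large
  consensus sets across few lists are structurally capped.
- The default ranker is a univariate standardized mean difference; it does
  not model gene-gene covariance as multivariate direction methods do.
- Louvain is a stochastic heuristic: partitions are deterministic only
  under a fixed seed, and near-degenerate modularity landscapes can split
  differently across seeds.
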