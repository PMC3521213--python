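# Methods

## The model

A miRNA cluster analysis involves three linked layers: a set of miRNAs, the
genes they are predicted to target, and the GO terms annotating those
genes. For a cluster *C* and a term *t* with annotated gene set *A*, three
2×2 contingency tables are derived from the same topology:

| measure | "in-set" margin (i + j)              | universe (i+j+k+l)           |
|---------|--------------------------------------|------------------------------|
| ρ       | target gene cluster of *C*           | genes with ≥ 1 link          |
| τ       | links leaving members of *C*         | all links                    |
| μ       | members of *C* (in the universe)     | all miRNAs with ≥ 1 link     |

with *i* counting the annotated portion (genes in *A*; links ending in *A*;
members targeting ≥ 1 gene of *A*) and *k*, *l* the same split outside the
cluster. Significance is the one-sided hypergeometric upper tail
P(X ≥ i), X ~ Hypergeom(N = i+j+k+l, K = i+k, n = i+j), computed through
`scipy.stats.hypergeom.sf` — log-space internally, so genome-scale counts
(N ≈ 1.5 million links) cannot overflow. The test suite verifies agreement
with exact rational enumeration to < 1e−12 relative error over every
quartet with N ≤ 40.

Two deliberate counting conventions:

* **The enrichment gene universe is the network's gene universe** (genes
  with at least one predicted link), not the whole annotation corpus. The
  benchmark quartets only reproduce under this convention (their ρ rows sum
  to 17,636 — the linked-gene count of the underlying target-pair
  variation — not to the GOA gene count).
* **Links are unweighted, deduplicated pairs**; several algorithms
  predicting the same pair yield one link. Cluster members absent from the
  miRNA universe are dropped (with a warning) before the μ margins are
  formed, keeping i + j equal to the effective cluster size.

Why three measures: ρ is invariant under any rewiring of links that
preserves the target gene cluster, so topologically different clusters can
be indistinguishable to it. τ separates sparse from dense wiring onto the
same genes; μ separates many members each contributing a little from one
hub member contributing everything. The hand-wired fixtures in
`mirtrigo.synthetic.make_discriminability_fixtures` encode exactly these
contrasts (equal ρ quartets with τ quartets 8 vs 22 links; equal ρ and τ
with μ membership 6 vs 3); the published wiring they emulate is not fully
recoverable, so the fixtures reproduce the qualitative contrast, not
specific p-values.

## Combining and ranking

Fisher's combined probability method: S = −2 Σ ln p referred to χ² with 2k
degrees of freedom for k ∈ {2, 3} p-values. A non-standard variant
(S = Σ −ln p, df = k) is available behind `method="one_df"` for
comparability with analyses that treated −ln p itself as χ²(1); the
standard form is the default because it is the correct distributional
result and what established implementations compute. Inputs of exactly 0
are clamped to the smallest positive float
with a warning; `math.fsum` makes the combination exactly order-invariant.
Note the three p-values share one topology and are not independent; the
combined values are used for ranking, not as calibrated significance
levels.

Because the three measures have differently shaped null distributions,
cross-measure comparison is done on ranks, not raw p-values: within a GO
category each measure's p-values receive ascending competition ranks
(ties get the smallest rank of their block — deterministic and
inclusion-monotone), and S_θ(n) is the set of terms ranked ≤ n, boundary
ties included. Combination sets (S_ρ,τ(n) etc.) are intersections of the
single-measure sets by default (the consensus reading of "set operations");
union is available. No multiple-testing correction enters the method
itself; a Benjamini–Hochberg column (`scipy.stats.false_discovery_control`)
can be appended as a diagnostic.

## Ontology measures

Terms, `is_a` edges and per-category roots come from the OBO file (parsed
with `obonet`); only `is_a` edges define ancestry by default (`part_of`
optional). Annotations come from GAF 2.x; rows with ND/NR evidence or a
NOT qualifier are excluded, duplicate (gene, term) pairs collapse to one,
and gene identity is the DB object symbol (column 3) by default, matching
target-pair tables. The true-path rule (a gene annotated to *t* is
annotated to every ancestor of *t*) is applied before enrichment counting;
whether the original analysis propagated is not documented, so propagation
is the default with `propagate=False` available.

Term frequency follows the literal summation convention
freq(t) = n(annotate(t)) + Σ over all descendants c of n(annotate(c)) —
"children" read as the entire descendant subtree — so a gene annotated to
two descendants counts twice (`counting_mode="multiplicity_sum"`, which therefore
requires raw annotations). The standard union count is available as
`counting_mode="unique_genes"`. Information Content is
IC(t) = −log(freq(t)/freq(root)); the log base is configurable
({e, 2, 10}, natural log default — cross-measure comparisons are
base-invariant since a base change rescales every IC equally). Zero
frequency leaves IC undefined (an explicit error, not an infinity in
output tables). Resnik similarity takes the **maximum** IC over common
ancestors (the most-informative-common-ancestor reading of "lowest common
ancestor", which is ambiguous in a DAG).

Term-set scores: average IC (specificity) and semantic similarity density
(mean Resnik over all unordered distinct pairs; self-pairs excluded, so
sets smaller than two have no defined density rather than trivially
scoring their own IC).

## The synthetic generator

`generate_scenario` draws, from a single `numpy` generator seeded once: a
top-down DAG (Poisson branching, mean 3 children; ~15% of terms get a
second parent among earlier terms, so the graph is a DAG, not a tree);
per-gene annotations (1 + Poisson(density − 1) terms per gene, density 2
by default); and miRNA out-degrees from a discrete truncated Pareto
(minimum 5, exponent `degree_skew` = 2, capped at the gene count) —
emulating the very uneven link distributions of real target predictions.
A *planted term* is chosen among terms whose propagated gene set covers
0.5–5% of genes (closest to 2%); cluster members' links are steered to its
genes with probability `planted_term_fraction` (default 0.9), other links
are uniform. With the fraction at 0 the scenario is an exact null. Default
sizes — 200 miRNAs, 1000 genes, 150 terms, cluster of 6 — are the package's
scaled-down study conditions; they keep a full simulate → enrich → evaluate
round trip under a couple of seconds.

What the generator does **not** emulate: real GO topology (depth ~15,
45k terms, cross-category links), correlated annotations between related
genes, the extreme link density of permissive target predictions (~16% of
all genes per miRNA in the benchmark variation), or miRNA family structure.
Passing synthetic tests therefore demonstrates correctness of the
computations and calibration machinery, not biological performance on real
corpora.

Two calibration facts about the null, established with this generator and
worth knowing before interpreting μ p-values for small clusters:

* The planted term's null p-values are *super-uniform* (P(p ≤ t) ≤ t): with
  only 6 draws the hypergeometric support is tiny and the p-value
  distribution carries atoms of mass up to ~0.4, so distribution-distance
  comparisons against a continuous uniform are uninformative, and the
  pooled proportion of p < 0.05 over many terms sits near 0.017 rather
  than 0.05 — the test is conservative, never anti-conservative. Terms hit
  by more than ~60% of the miRNA universe can never reach p < 0.05 with a
  6-member cluster at all.
* Power is nonetheless high: with planting probability 0.9 the planted
  term is significant at 0.05 in 100/100 seeded replicates and in the μ
  top five in 100/100.

## Numerical and interface choices

* p-values are clamped into (tiny, 1]; quartet cells are validated
  non-negative; an empty target cluster raises `EmptyClusterError`, which
  the CLI converts into a logged skip (mirroring the exclusion of
  target-less clusters from real analyses).
* miRNA identifiers compare case-insensitively after trimming; no miRBase
  version mapping is attempted. Gene and term identifiers are opaque
  strings.
* Results TSVs print probabilities with 6 significant digits, fixed column
  order, `\n` endings; all writers are deterministic, and every CLI run
  writes a manifest with input/output SHA-256 checksums.
* The `evaluate` command takes `--obo`/`--gaf` in addition to the results
  files because IC and Resnik similarity are properties of the annotation
  corpus, not of the enrichment table.
* `scripts/acceptance.py` re-derives all reported numbers at run time; its
  exact-enumeration sweep uses universes ≤ 30 (≈ 46k quartets) to stay
  fast, while the test suite sweeps ≤ 40.

## Known limitations

* `multiplicity_sum` frequency double-counts multi-annotated genes by design
  (fidelity to the summation formula); use `unique_genes` for the standard
  convention. The two disagree more, the deeper and more multiply-annotated
  the DAG.
* Only `is_a` (optionally `part_of`) ancestry; no GO-slim mapping, no Lin
  or Jiang–Conrath similarity, no cross-category similarity.
* Combined p-values ignore the dependence between ρ, τ and μ.
* The vote-table reader loads the full table into memory; tables of a few
  million pairs are fine, but no streaming mode is provided.
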