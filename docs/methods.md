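# Methods

## Data model

A knowledge base is a signed directed multigraph. Nodes are typed entities
(`protein`, `transcript`, `compound`, `process`, `phenotype`, `other`);
only `transcript` nodes are comparable to expression data. Edges are causal
statements `source --sign--> target`, `sign ∈ {+1, −1}`, each carrying a
list of (citation, quote) evidence pairs. Duplicate `(source, sign,
target)` triples collapse with merged evidence; *contradictory* duplicates
(both signs between the same pair) are deliberately kept — they are what
produces ambiguous predictions. Self-loops are rejected at parse time.
Identifiers are opaque, case-sensitive strings; translating between
identifier namespaces belongs upstream of this tool.

The experiment side is an already-called differential-expression table. A
transcript is significant when `adj_p < 0.05` and `|fold change| ≥ 1.3`
(both configurable); its direction is the sign of the log2 fold-change.
Mapping intersects the measured universe with the knowledge base's
transcript index; the *mapping rate* is the mapped fraction of the
significant calls.

## Signed propagation and classification

A hypothesis `(entity, direction)` predicts, for every transcript reachable
by a statement chain of length ≤ `depth`, the sign `direction ×
∏(chain signs)`. Chains are simple paths — no node may repeat — which is
the conventional way to prevent unbounded sign flipping around feedback
loops. A transcript reached by chains whose products disagree is ambiguous.
Multiple concordant chains do not up-weight a prediction: counts are
per-gene, not per-assertion. Transcripts may serve as chain intermediates.
The default depth is 1 (direct regulator→transcript assertions), and depth
is capped at 3: deeper signed propagation through curated statements
compounds curation noise multiplicatively and is exposed as a flag rather
than silently applied.

Classification compares predictions with the mapped significant calls:
match → correct, mismatch → incorrect, ambiguous prediction → ambiguous;
predicted transcripts that are unmeasured or not significant are ignored.
Flipping the hypothesis direction exactly swaps correct and incorrect and
leaves ambiguity unchanged (tested as an invariant).

## Statistics

**Enrichment.** One-sided over-representation Fisher exact test on the 2×2
table (downstream of h × significantly changed) over the mapped universe,
computed as a hypergeometric survival function. Ambiguously predicted
transcripts are excluded from both the hit count and the downstream draw
size, because the score formula names only correct and incorrect calls;
the downstream set with no unambiguous member returns p = 1 with a warning.

**Correctness.** The score `S = #correct − #incorrect` is referred to its
exact null distribution under random re-assignment of the `G_up` up- and
`G_down` down-labels to distinct nodes of the universe. Writing `u±` for
labels landing in the predicted-up set (size `d_up`) and `v±` for the
predicted-down set (size `d_down`), `S = (u₊ + v₋) − (u₋ + v₊)` and
`(u₊, v₊, u₋, v₋)` is multivariate hypergeometric. The pmf is accumulated
by summing the exact log-binomial weights over the four counts —
`O(d_up² · d_down²)` work, independent of `N` — never by enumerating
assignments. The p-value is the upper tail `P(S ≥ s)`. Distributions are
memoised on their parameter tuple, which makes repeated scoring over one
experiment cheap. Numerics: log-space binomials via `gammaln`, so the pmf
is accurate to ~1e-14 relative; the test suite checks total variation
≤ 1e-12 against exhaustive enumeration for every parameter tuple with
N ≤ 12 and agreement with a 100,000-draw permutation estimate at N = 500.

The null universe `N` is the *mapped measured* transcript set, not all
knowledge-base nodes: re-assigning labels "to arbitrary nodes" is
interpreted over the nodes that could in fact have carried a label in this
experiment, so the margins match the data. No multiple-testing correction
is applied across hypotheses — the downstream filter acts on raw p-values —
and under the discrete null the p-value is conservative (empirical type-I
rate well below nominal; measured by the acceptance script).

**GO-style enrichment.** For comparison with gene-set methods, a two-sided
Fisher exact test per term over the mapped universe, reporting the sample
odds ratio (`ad/bc`; infinity when a term lies entirely inside the
significant set). Terms are ranked by a Derringer-type composite
desirability — the geometric mean of three [0,1] ramps: |log2 odds ratio|
saturating at 3, −log10 p saturating at 5, and a size component peaked at
20 genes (linear in log10 size between anchors 2 and 200). The anchor
values are conventions, chosen once and configurable; the literature on
this ranking does not fix them.

## Filtering, ranking, clustering, merging

Admission requires all four defaults: correctness p < 0.01, enrichment
p < 0.01, ≥ 3 correct, ≥ 60% correct (strict `<` on p-values, `≥` on
counts). Ranking uses ascending correctness p with competition ranking
(ties share the minimum rank); ties are ordered by enrichment p then entity
id. The ranking key is an interpretation — published hypothesis tables for
this method order broadly by correctness p within clusters but never state
the key.

Each hypothesis's evidence vector is the binary set of (transcript,
observed direction) pairs it *correctly* explains; incorrect and ambiguous
genes are not support (a flag admits incorrect explanations as signed
features). Similarity is binary cosine `|a∩b|/√(|a||b|)`; clustering is
average-linkage agglomeration that merges while the best pair's average
inter-cluster similarity is ≥ the user threshold (no fixed cluster count;
singletons allowed). Determinism and input-order invariance come from a
fixed tie-break: among equally similar pairs, merge the lexicographically
smallest pair of cluster keys. Hypotheses with empty evidence never merge.
`scipy.cluster.hierarchy` is intentionally not used: its dendrogram-cut
semantics differ from this threshold-stopped merge, and an independent
brute-force re-implementation serves as the test oracle instead.

Merging a subset reports the fraction of all significant mapped changes
explained by the union of correct sets, per-transcript overlap counts
(≥ 2 explaining members) plus a single overlap fraction, and contradictions
(transcripts correct for one member, incorrect for another — the published
displays print no formula for "overlap", so both granularities are
emitted). The evidence matrix is hypothesis × transcript with +1/−1/0 and
blank for no relation, columns ordered by how many members explain them.
Exports: SIF, GraphML and node/edge/matrix TSVs, with node attributes for
predicted direction and observed mRNA direction (the usual colour
semantics) and optional inter-hypothesis edges taken from the knowledge
base. Output is byte-stable for fixed input.

## Synthetic data

`simulate_kb` draws a regulator→transcript graph (Poisson out-degree,
optional regulator→regulator edges for depth testing), signs negative with
probability `p_negative_edge`, and gives each edge a contradictory twin
with probability `ambiguity_rate`. `simulate_experiment` picks `n_active`
regulators with random directions; each direct target responds consistently
with probability `tpr`, with flipped sign with probability `flip_rate`, and
unrelated transcripts are called significant at `background_rate`. When two
planted regulators share a target the first (in sorted order) wins — the
noiseless "every planted hypothesis is 100% correct" limit therefore holds
only when target sets do not collide. `unmapped_rate` appends significant
calls on identifiers absent from the knowledge base to emulate incomplete
mapping (e.g. a 0.76 mapping rate); otherwise mapping is 1.0 by
construction.

Defaults — 200 regulators, 2,000 transcripts, out-degree 15, 30% negative
edges, 2% ambiguity, 5 planted actives, tpr 0.8, flip 0.05, background
0.02 — are sized so a run resembles the regime of a few-hundred-gene
signature over a knowledge base that dwarfs it, at desk scale. Identical
seed and config give identical output; the knowledge base and the
experiment use independent child streams of the seed.

What the generator does *not* emulate: correlated co-regulation,
probe-level noise and the upstream testing pipeline, realistic scale-free
degree structure, or entity-type heterogeneity beyond
regulator/transcript. Passing recovery benchmarks therefore show the
machinery is correct and well-calibrated, not that real knowledge bases
have enough signal for any particular experiment.

## Benchmark and calibration sizes

The type-I calibration battery uses 10 knowledge bases (100 regulators,
400 transcripts, out-degree 8) × 100 null experiments (background rate
0.05, nothing planted), pooling all hypothesis p-values; the recovery
benchmark runs the default generator across 20 seeds and reports the
median planted rank after filtering and the fraction of seeds recovering
every planted direction. These sizes are the package's study conditions
for its own validation and are re-run from scratch by
`scripts/acceptance.py`.

## Known limitations

* Depth > 1 treats every chain as independent evidence of sign, with no
  attenuation; use with curated, high-precision statement collections only.
* The correctness null conditions on the predicted sets but not on the
  dependence between hypotheses; p-values are per-hypothesis and are not
  corrected across the hypothesis family (a Benjamini–Hochberg pass can be
  applied externally to the results table).
* Percent correct is undefined (NaN) when a hypothesis explains nothing;
  such rows never pass the filter.
* The exact null costs `O(d_up²·d_down²)`; hypotheses predicting thousands
  of transcripts in both directions would be slow (not the intended
  regime, where downstream sets are tens of genes).
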