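# crengine — causal reasoning over signed molecular networks

`crengine` infers **signed upstream molecular hypotheses** from
differential-expression calls. Given a knowledge base of curated causal
statements — signed edges of the form *increase of A increases/decreases B*
over typed biological entities (proteins, transcripts, compounds,
processes…) — every entity with an assumed direction of regulation is a
candidate *hypothesis* for what caused the observed transcriptional changes.
The engine propagates each hypothesis through statement chains, classifies
each significantly changed transcript downstream of it as **correct**
(predicted and observed directions agree), **incorrect** (they disagree) or
**ambiguous** (the literature contains contradictory statements), and
scores the hypothesis with two exact statistics:

* **Enrichment p-value** — one-sided Fisher exact (hypergeometric) tail for
  finding `#correct + #incorrect` significant transcripts among the
  hypothesis's downstream transcripts, within the mapped measured universe.
* **Correctness p-value** — the upper tail of the score
  `S = #correct − #incorrect` under the null model that re-assigns the
  `G_up` up- and `G_down` down-labels uniformly to distinct nodes of the
  `N`-transcript universe. With predicted-up/-down sets of sizes
  `d_up`/`d_down`, the counts of labels landing in those sets are jointly
  multivariate hypergeometric, and the exact pmf of `S` is computed in
  polynomial time by convolution over those counts (mean
  `(G_up−G_down)(d_up−d_down)/N`).

Surviving hypotheses (defaults: correctness p < 0.01, enrichment p < 0.01,
≥ 3 correct, ≥ 60% correct) are ranked, clustered by cosine similarity of
their supporting-evidence vectors (average linkage, threshold-stopped), and
merged into network models with coverage/overlap/contradiction statistics,
an evidence matrix, and SIF/GraphML/TSV exports for Cytoscape-style viewing.

A synthetic-data generator produces knowledge bases and expression profiles
with planted active regulators, so the entire pipeline is testable without
licensed knowledge-base content. It is aimed at computational biologists
who have differential-expression calls and a causal statement collection
and want mechanistic upstream hypotheses rather than gene-set labels; a
GO-style two-sided Fisher enrichment with desirability ranking is included
for comparison.

## Worked example

The packaged demo fixture is a toy knowledge base in which one regulator,
hypothesised to decrease, has 56 significant downstream genes in a measured
universe of 200:

```python
from crengine import map_changes, score_hypothesis
from crengine.datasets import demo_fixture

kg, oc, h = demo_fixture()
mapped = map_changes(kg, oc)
r = score_hypothesis(h, kg, mapped)
print(r.n_correct, r.n_incorrect, r.n_ambiguous)
print(r.score, r.percent_correct)
print(r.correctness_p, r.enrichment_p)
```

prints

```
36 14 6
22 0.72
3.796118841244013e-07 1.9546653683984077e-26
```

36 downstream genes change in the predicted direction, 14 contradict it and
6 are ambiguous due to contradictory literature; the score is
36 − 14 = 22 with 72% correct. The correctness p-value says a score of 22
is very unlikely under random re-assignment of the 80 up/down labels to the
200 measured transcripts; the enrichment p-value says 50 unambiguous hits
among 50 downstream transcripts is an extreme over-representation.

The same workflow from the shell, on simulated data with ~76% of
significant genes mapping to the knowledge base:

```sh
cre simulate --seed 7 --emulate-mapping 0.76 -o demo
cre run --kb demo/kb.tsv --expression demo/expression.tsv -o demo/out
```

logs `mapping rate 0.763; scored 400 hypotheses, kept 5 in 5 clusters` and
writes `hypotheses.tsv` (rank, cluster, counts, score, both p-values,
percent correct), `clusters.tsv`, merged-model exports
(`top_cluster_model.sif/.graphml/…`) and a `run.json` record. With the
default generator all five planted regulators survive filtering with the
correct direction.

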