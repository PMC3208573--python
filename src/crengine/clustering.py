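"""Group hypotheses by similarity of their supporting evidence.

Each hypothesis is represented by the binary set of (transcript, observed
direction) pairs it correctly explains; similarity between hypotheses is the
cosine of those binary vectors (1 = identical supporting evidence, 0 =
disjoint). Clusters form by average-linkage agglomeration: repeatedly merge
the pair of clusters with the highest average pairwise cosine similarity, as
long as that average is >= the user's cluster threshold. Merging is made
deterministic and order-independent by always picking, among tied best
pairs, the lexicographically smallest pair of cluster keys (a cluster's key
is the sorted tuple of its members' positions in the ranked input).

Hypotheses with empty evidence never merge: similarity to everything is 0
and a cluster of unsupported hypotheses is meaningless; they remain
singletons at every threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .types import DOWN, UP, HypothesisResult


@dataclass(frozen=True)
class HypothesisCluster:
    cluster_id: int
    members: tuple[HypothesisResult, ...]
    threshold: float

    @property
    def size(self) -> int:
        return len(self.members)


def evidence_features(r: HypothesisResult, signed: bool = False) -> frozenset:
    """Feature set of a hypothesis: correctly explained (transcript,
    direction) pairs; with ``signed`` incorrect explanations join as
    negatively tagged features."""
    feats = {(t, d, +1) for t, d in r.evidence}
    if signed:
        feats |= {(t, r.observed[t], -1) for t in r.classification.incorrect_set}
    return frozenset(feats)


def cosine_similarity(a: frozenset, b: frozenset) -> float:
    """|a n b| / sqrt(|a|·|b|) on binary feature sets; 0 when either is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def cluster_hypotheses(results: list[HypothesisResult], threshold: float,
                       signed_features: bool = False) -> list[HypothesisCluster]:
    """Threshold-stopped average-linkage agglomeration of hypothesis evidence.

    Clusters are numbered from 1 by descending size, then by the best member
    (lowest rank if ranks are assigned, else lowest correctness p). Each
    member's ``cluster_id`` is set accordingly.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("cluster threshold must lie in [0, 1]")
    feats = [evidence_features(r, signed_features) for r in results]
    n = len(results)
    # clusters keyed by sorted member-position tuples; only non-empty-evidence
    # hypotheses participate in merging
    clusters: dict[tuple[int, ...], list[int]] = {(i,): [i] for i in range(n)}
    sim = {}
    active = [(i,) for i in range(n) if feats[i]]
    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            a, b = active[ai], active[bi]
            sim[(a, b)] = cosine_similarity(feats[a[0]], feats[b[0]])

    def pair_key(a, b):
        return (a, b) if a < b else (b, a)

    while True:
        best = None
        for (a, b), s in sim.items():
            if s >= threshold and (best is None or s > best[0]
                                   or (s == best[0] and (a, b) < best[1:])):
                best = (s, a, b)
        if best is None:
            break
        _, a, b = best
        merged = tuple(sorted(clusters[a] + clusters[b]))
        na, nb = len(clusters[a]), len(clusters[b])
        clusters[merged] = clusters.pop(a) + clusters.pop(b)
        # Lance-Williams update for unweighted average linkage on similarities
        new_sim = {}
        for key, s in sim.items():
            if a in key or b in key:
                continue
            new_sim[key] = s
        for other in list(clusters):
            if other == merged or not feats[other[0]]:
                continue
            if len(other) == 1 and not feats[other[0]]:
                continue
            sa = sim.get(pair_key(a, other))
            sb = sim.get(pair_key(b, other))
            if sa is None or sb is None:
                continue
            new_sim[pair_key(merged, other)] = (na * sa + nb * sb) / (na + nb)
        sim = new_sim

    def best_key(members):
        rs = [results[i] for i in members]
        ranks = [r.rank for r in rs if r.rank is not None]
        if ranks:
            return min(ranks)
        return min(r.correctness_p for r in rs)

    ordered = sorted(clusters.values(), key=lambda m: (-len(m), best_key(m), min(m)))
    out = []
    for cid, members in enumerate(ordered, start=1):
        for i in members:
            results[i].cluster_id = cid
        out.append(HypothesisCluster(cid, tuple(results[i] for i in sorted(members)),
                                     threshold))
    return out


def cluster_table(clusters: list[HypothesisCluster]) -> pd.DataFrame:
    """Flat cluster table: hypothesis, rank, cluster id/size and the three
    quality columns."""
    rows = []
    for c in clusters:
        for r in c.members:
            rows.append({
                "hypothesis": r.hypothesis.entity,
                "direction": "+" if r.hypothesis.direction == UP else "-",
                "rank": r.rank,
                "cluster_id": c.cluster_id,
                "cluster_size": c.size,
                "correctness_p": r.correctness_p,
                "enrichment_p": r.enrichment_p,
                "percent_correct": r.percent_correct,
            })
    return pd.DataFrame(rows, columns=["hypothesis", "direction", "rank", "cluster_id",
                                       "cluster_size", "correctness_p", "enrichment_p",
                                       "percent_correct"])
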