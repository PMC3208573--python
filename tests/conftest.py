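"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from crengine import CausalStatement, Entity, KnowledgeGraph, ObservedChanges


def make_kg(statements, kinds=None):
    """Build a KnowledgeGraph from (source, sign, target[, evidence]) tuples.

    By default any id starting with 't' is a transcript; ``kinds`` overrides
    per id.
    """
    kinds = kinds or {}
    kg = KnowledgeGraph()
    ids = {s for st in statements for s in (st[0], st[2])}
    for i in sorted(ids):
        kind = kinds.get(i, "transcript" if i.startswith("t") else "protein")
        kg.add_entity(Entity(i, kind))
    for st in statements:
        evidence = tuple(st[3]) if len(st) > 3 else ()
        kg.add_statement(CausalStatement(st[0], st[1], st[2], evidence))
    return kg


def make_oc(direction, extra_universe=()):
    universe = frozenset(direction) | frozenset(extra_universe)
    return ObservedChanges(universe=universe, direction=dict(direction))


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def enumerate_null_oracle(N, G_up, G_down, d_up, d_down):
    """Exact null pmf of the correctness score by enumerating every placement
    of G_up up-labels and G_down down-labels on N distinct nodes.

    The predicted-up set is taken as nodes [0, d_up) and predicted-down as
    [d_up, d_up + d_down); uniform placement makes the choice irrelevant.
    """
    nodes = range(N)
    counts = Counter()
    total = 0
    for up in itertools.combinations(nodes, G_up):
        rest = [n for n in nodes if n not in up]
        for down in itertools.combinations(rest, G_down):
            s = (sum(1 for x in up if x < d_up)
                 + sum(1 for x in down if d_up <= x < d_up + d_down)
                 - sum(1 for x in down if x < d_up)
                 - sum(1 for x in up if d_up <= x < d_up + d_down))
            counts[s] += 1
            total += 1
    return {k: v / total for k, v in counts.items()}


def hypergeom_tail_oracle(hits, N, K, D):
    """Upper-tail hypergeometric sum by direct summation of binomials."""
    from math import comb
    denom = comb(N, D)
    return sum(comb(K, k) * comb(N - K, D - k) for k in range(hits, min(K, D) + 1)) / denom


def brute_force_predictions(kg, entity, direction, depth):
    """Exhaustive simple-path listing oracle for signed downstream prediction."""
    import networkx as nx
    transcripts = kg.transcript_index
    sign_sets = {}
    targets = set(kg.graph.nodes) - {entity}
    for path in nx.all_simple_edge_paths(kg.graph, entity, targets, cutoff=depth):
        prod = direction
        for (_, tgt, sign) in path:
            prod *= sign
        tgt = path[-1][1]
        if tgt in transcripts:
            sign_sets.setdefault(tgt, set()).add(prod)
    return {t: (next(iter(s)) if len(s) == 1 else 0) for t, s in sign_sets.items()}


def brute_force_average_linkage(features, threshold):
    """Reference threshold-stopped average-linkage agglomeration.

    Recomputes every cross-pair cosine from scratch at each step (no
    Lance-Williams update); empty feature sets never merge. Returns a sorted
    list of frozensets of item indices.
    """
    import math

    def cos(a, b):
        if not a or not b:
            return 0.0
        return len(a & b) / math.sqrt(len(a) * len(b))

    clusters = [frozenset([i]) for i in range(len(features))]
    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                if not any(features[x] for x in a) or not any(features[x] for x in b):
                    continue
                sims = [cos(features[x], features[y]) for x in a for y in b]
                avg = sum(sims) / len(sims)
                key = tuple(sorted((tuple(sorted(a)), tuple(sorted(b)))))
                if best is None or avg > best[0] or (avg == best[0] and key < best[1]):
                    best = (avg, key, i, j)
        if best is None or best[0] < threshold:
            break
        _, _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(clusters, key=lambda c: tuple(sorted(c)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def demo():
    from crengine.datasets import demo_fixture
    return demo_fixture()
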