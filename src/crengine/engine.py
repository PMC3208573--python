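"""Hypothesis engine: enumerate upstream candidates, propagate signs, classify.

A hypothesis (entity, direction) predicts, for every transcript reachable by
a causal-statement chain of length <= ``depth``, the sign
``direction x product(chain signs)``. Chains are simple paths (no node
revisited), which prevents unbounded sign flipping through cycles; a
transcript supported by chains whose products disagree is *ambiguous*.
Transcripts may appear as chain intermediates as well as endpoints.

Predictions are compared to the mapped significant calls: matching sign ->
correct, opposite -> incorrect, ambiguous prediction -> ambiguous;
transcripts that are unmeasured or not significant are ignored.
"""

from __future__ import annotations

from .knowledge import KnowledgeGraph
from .types import (AMBIGUOUS, DOWN, UP, Classification, Hypothesis,
                    MappedChanges, Prediction)

DEFAULT_DEPTH = 1
MAX_DEPTH = 3


def _collect_chains(kg: KnowledgeGraph, root: str, depth: int,
                    with_provenance: bool):
    """DFS over simple signed chains of length <= depth starting at root.

    Returns (sign_sets, chains): transcript id -> set of chain sign products,
    and (if requested) transcript id -> list of chains, each a tuple of
    (source, sign, target) statements.
    """
    g = kg.graph
    transcripts = kg.transcript_index
    sign_sets: dict[str, set[int]] = {}
    chains: dict[str, list] = {} if with_provenance else None
    path_nodes = {root}
    path_edges: list[tuple[str, int, str]] = []

    def visit(node: str, product: int, remaining: int) -> None:
        if remaining == 0:
            return
        for _, nxt, sign in sorted(g.out_edges(node, keys=True)):
            if nxt in path_nodes:
                continue
            prod = product * sign
            path_edges.append((node, sign, nxt))
            if nxt in transcripts:
                sign_sets.setdefault(nxt, set()).add(prod)
                if with_provenance:
                    chains.setdefault(nxt, []).append(tuple(path_edges))
            path_nodes.add(nxt)
            visit(nxt, prod, remaining - 1)
            path_nodes.discard(nxt)
            path_edges.pop()

    visit(root, 1, depth)
    return sign_sets, chains


def predict_downstream(h: Hypothesis, kg: KnowledgeGraph,
                       depth: int = DEFAULT_DEPTH,
                       with_provenance: bool = True) -> Prediction:
    """Predict signed downstream transcript changes for one hypothesis."""
    if h.entity not in kg:
        raise KeyError(f"hypothesis entity {h.entity!r} not in knowledge base")
    if not 1 <= depth <= MAX_DEPTH:
        raise ValueError(f"depth must be in [1, {MAX_DEPTH}], got {depth}")
    sign_sets, chains = _collect_chains(kg, h.entity, depth, with_provenance)
    signs = {t: (h.direction * next(iter(s)) if len(s) == 1 else AMBIGUOUS)
             for t, s in sign_sets.items()}
    return Prediction(hypothesis=h, signs=signs, provenance=chains)


def downstream_signatures(kg: KnowledgeGraph, depth: int = DEFAULT_DEPTH,
                          entities: list[str] | None = None) -> dict[str, dict[str, int]]:
    """Bulk signed reachability: entity -> {transcript -> sign for a +1 hypothesis}.

    Ambiguous transcripts carry sign 0. Signatures for the -1 hypothesis are
    obtained by flipping non-zero signs (sign antisymmetry).
    """
    if entities is None:
        entities = sorted(kg.graph.nodes)
    out = {}
    for ent in entities:
        sign_sets, _ = _collect_chains(kg, ent, depth, with_provenance=False)
        out[ent] = {t: (next(iter(s)) if len(s) == 1 else AMBIGUOUS)
                    for t, s in sign_sets.items()}
    return out


def enumerate_hypotheses(kg: KnowledgeGraph, depth: int = DEFAULT_DEPTH,
                         min_targets: int = 1) -> list[Hypothesis]:
    """Both directions of every entity with >= min_targets transcript
    descendants within ``depth``, ordered by entity id then direction (+ first)."""
    if depth < 1 or min_targets < 1:
        raise ValueError("depth and min_targets must be >= 1")
    hyps: list[Hypothesis] = []
    for ent, sig in downstream_signatures(kg, depth).items():
        if len(sig) >= min_targets:
            hyps.append(Hypothesis(ent, UP))
            hyps.append(Hypothesis(ent, DOWN))
    hyps.sort(key=lambda h: (h.entity, -h.direction))
    return hyps


def classify(pred: Prediction, mapped: MappedChanges) -> Classification:
    """Partition the predicted, significant, mapped transcripts into
    correct / incorrect / ambiguous against the observed directions."""
    correct, incorrect, ambiguous = set(), set(), set()
    direction = mapped.direction
    for t, p in pred.signs.items():
        obs = direction.get(t)
        if obs is None or t not in mapped.universe:
            continue
        if p == AMBIGUOUS:
            ambiguous.add(t)
        elif p == obs:
            correct.add(t)
        else:
            incorrect.add(t)
    return Classification(frozenset(correct), frozenset(incorrect), frozenset(ambiguous))
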