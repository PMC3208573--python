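"""Packaged synthetic demo fixture.

A toy knowledge base and expression call set built so that one regulator,
hypothesised to *decrease*, partitions its 56 significant downstream genes
into 36 correctly explained, 14 contradicted and 6 ambiguous (the ambiguous
genes carry contradictory duplicate statements) — the shape of a strong
upstream hypothesis subnetwork, with score 22 and 72% correct. The rest of
the measured universe supplies background: 24 significant genes not
downstream of the regulator and 120 unchanged genes, for a universe of 200
measured transcripts.

Everything is constructed programmatically and deterministically; the
fixture is synthetic and stands in for no real data set.
"""

from __future__ import annotations

from .knowledge import KnowledgeGraph
from .types import DOWN, UP, CausalStatement, Entity, Hypothesis, ObservedChanges

DEMO_REGULATOR = "REG1"

N_CORRECT, N_INCORRECT, N_AMBIGUOUS = 36, 14, 6
N_BACKGROUND_SIG, N_UNCHANGED = 24, 120


def demo_fixture() -> tuple[KnowledgeGraph, ObservedChanges, Hypothesis]:
    """Return (knowledge graph, observed changes, the planted hypothesis)."""
    kg = KnowledgeGraph()
    kg.add_entity(Entity(DEMO_REGULATOR, "protein"))
    h = Hypothesis(DEMO_REGULATOR, DOWN)
    direction: dict[str, int] = {}
    universe: set[str] = set()
    gid = 0

    def next_gene() -> str:
        nonlocal gid
        gid += 1
        return f"G{gid:03d}"

    # alternate edge signs for variety; observed = prediction for correct genes
    for i in range(N_CORRECT):
        g = next_gene()
        sign = UP if i % 2 == 0 else DOWN
        kg.add_entity(Entity(g, "transcript"))
        kg.add_statement(CausalStatement(DEMO_REGULATOR, sign, g,
                                         ((f"PMID:{1000 + i}", "curated assertion"),)))
        direction[g] = h.direction * sign
        universe.add(g)
    for i in range(N_INCORRECT):
        g = next_gene()
        sign = UP if i % 2 == 0 else DOWN
        kg.add_entity(Entity(g, "transcript"))
        kg.add_statement(CausalStatement(DEMO_REGULATOR, sign, g,
                                         ((f"PMID:{2000 + i}", "curated assertion"),)))
        direction[g] = -h.direction * sign
        universe.add(g)
    for i in range(N_AMBIGUOUS):
        g = next_gene()
        kg.add_entity(Entity(g, "transcript"))
        kg.add_statement(CausalStatement(DEMO_REGULATOR, UP, g,
                                         ((f"PMID:{3000 + i}", "supporting study"),)))
        kg.add_statement(CausalStatement(DEMO_REGULATOR, DOWN, g,
                                         ((f"PMID:{3500 + i}", "contradicting study"),)))
        direction[g] = UP if i % 2 == 0 else DOWN
        universe.add(g)
    for i in range(N_BACKGROUND_SIG):
        g = next_gene()
        kg.add_entity(Entity(g, "transcript"))
        direction[g] = UP if i % 2 == 0 else DOWN
        universe.add(g)
    for _ in range(N_UNCHANGED):
        g = next_gene()
        kg.add_entity(Entity(g, "transcript"))
        universe.add(g)

    oc = ObservedChanges(universe=frozenset(universe), direction=direction)
    return kg, oc, h
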