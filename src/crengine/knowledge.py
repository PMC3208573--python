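"""Knowledge base: parse, validate and index curated causal statements.

A knowledge base is a signed directed multigraph over typed entities. The
on-disk dialect is a UTF-8 TSV with header columns
``source_id  source_kind  sign  target_id  target_kind  citation  quote``;
the sign column accepts ``+``/``-`` or ``increases``/``decreases``.
Duplicate ``(source, sign, target)`` triples collapse into one statement with
merged evidence; contradictory duplicates (both signs present for the same
source/target pair) are both kept and surface as ambiguity at prediction
time. A row with empty sign and target declares a bare entity (used to keep
statement-less transcripts, and hence the measurable universe, stable across
write/parse round trips).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx

from .types import DOWN, UP, CausalStatement, Entity, MappedChanges, ObservedChanges

log = logging.getLogger(__name__)

KB_COLUMNS = ("source_id", "source_kind", "sign", "target_id", "target_kind", "citation", "quote")

_SIGN_TOKENS = {
    "+": UP, "-": DOWN, "−": DOWN,
    "increases": UP, "decreases": DOWN,
    "+1": UP, "-1": DOWN, "1": UP,
}


class KBParseError(ValueError):
    """Raised for malformed knowledge-base files; message carries the line number."""


@dataclass
class KBReport:
    """Parse summary: entity/statement/transcript counts and rejected lines."""

    n_entities: int = 0
    n_statements: int = 0
    n_transcripts: int = 0
    n_rejected: int = 0
    rejected_lines: list[tuple[int, str]] = field(default_factory=list)


class KnowledgeGraph:
    """Signed directed multigraph of causal statements with typed nodes.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are the
    statement signs (+1/-1), so at most two parallel edges exist per ordered
    entity pair; edge data carries the merged evidence list.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_entity(self, entity: Entity) -> None:
        existing = self.graph.nodes.get(entity.id)
        if existing is not None and existing["kind"] != entity.kind:
            raise ValueError(
                f"entity {entity.id!r} redeclared with kind {entity.kind!r} (was {existing['kind']!r})")
        self.graph.add_node(entity.id, kind=entity.kind, label=entity.label or entity.id)

    def add_statement(self, st: CausalStatement) -> None:
        """Add a statement; endpoints must already be entities. Duplicate
        triples collapse with merged evidence."""
        for end in (st.source, st.target):
            if end not in self.graph:
                raise ValueError(f"statement endpoint {end!r} is not a declared entity")
        if self.graph.has_edge(st.source, st.target, key=st.sign):
            self.graph[st.source][st.target][st.sign]["evidence"].extend(st.evidence)
        else:
            self.graph.add_edge(st.source, st.target, key=st.sign, evidence=list(st.evidence))

    # -- views ---------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_statements(self) -> int:
        return self.graph.number_of_edges()

    @property
    def transcript_index(self) -> frozenset[str]:
        return frozenset(n for n, k in self.graph.nodes(data="kind") if k == "transcript")

    def entities(self) -> list[Entity]:
        return [Entity(n, d["kind"], d.get("label")) for n, d in sorted(self.graph.nodes(data=True))]

    def statements(self) -> list[CausalStatement]:
        out = []
        for u, v, sign, data in sorted(self.graph.edges(keys=True, data=True)):
            out.append(CausalStatement(u, sign, v, tuple(data["evidence"])))
        return out

    def kind(self, entity_id: str) -> str:
        return self.graph.nodes[entity_id]["kind"]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
                and self.statements() == other.statements())


def parse_sign(token: str, lineno: int | None = None) -> int:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        where = f" at line {lineno}" if lineno is not None else ""
        raise KBParseError(f"unknown sign token {token!r}{where}; "
                           f"expected one of +, -, increases, decreases") from None


def parse_kb(path, strict: bool = True) -> KnowledgeGraph:
    """Parse a TSV knowledge-base file into a validated :class:`KnowledgeGraph`.

    With ``strict`` (default) any malformed line raises :class:`KBParseError`
    naming the line; otherwise bad lines are skipped and recorded. The parse
    summary is attached to the returned graph as ``kg.report``.
    """
    kg = KnowledgeGraph()
    report = KBReport()
    n_raw = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise KBParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header[:5]) != KB_COLUMNS[:5]:
            raise KBParseError(
                f"{path}: bad header {header!r}; expected columns {KB_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                if len(row) < 5:
                    raise KBParseError(f"line {lineno}: expected >=5 fields, got {len(row)}")
                src, src_kind, sign_tok, tgt, tgt_kind = (f.strip() for f in row[:5])
                citation = row[5].strip() if len(row) > 5 else ""
                quote = row[6].strip() if len(row) > 6 else ""
                if not sign_tok and not tgt:
                    # declaration-only row: registers an entity with no statement
                    kg.add_entity(Entity(src, src_kind or "other"))
                    continue
                sign = parse_sign(sign_tok, lineno)
                kg.add_entity(Entity(src, src_kind or "other"))
                kg.add_entity(Entity(tgt, tgt_kind or "other"))
                evidence = ((citation, quote),) if citation or quote else ()
                kg.add_statement(CausalStatement(src, sign, tgt, evidence))
                n_raw += 1
            except (ValueError, KBParseError) as exc:
                if strict:
                    if isinstance(exc, KBParseError):
                        raise
                    raise KBParseError(f"line {lineno}: {exc}") from exc
                report.n_rejected += 1
                report.rejected_lines.append((lineno, str(exc)))
    if n_raw == 0 and report.n_rejected == 0:
        raise KBParseError(f"{path}: no statements found")
    report.n_entities = kg.n_entities
    report.n_statements = kg.n_statements
    report.n_transcripts = len(kg.transcript_index)
    kg.report = report
    log.info("parsed %s: %d entities, %d statements (%d raw lines), %d transcripts, %d rejected",
             path, report.n_entities, report.n_statements, n_raw,
             report.n_transcripts, report.n_rejected)
    return kg


def write_kb(kg: KnowledgeGraph, path) -> None:
    """Write a knowledge graph in the TSV dialect :func:`parse_kb` reads.

    Statements with multiple evidence entries emit one row per entry so that
    a round trip preserves evidence exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(KB_COLUMNS)
        for ent in kg.entities():
            if kg.graph.degree(ent.id) == 0:
                writer.writerow([ent.id, ent.kind, "", "", "", "", ""])
        for st in kg.statements():
            sign_tok = "+" if st.sign == UP else "-"
            rows = st.evidence or (("", ""),)
            for citation, quote in rows:
                writer.writerow([st.source, kg.kind(st.source), sign_tok,
                                 st.target, kg.kind(st.target), citation, quote])


def map_changes(kg: KnowledgeGraph, oc: ObservedChanges) -> MappedChanges:
    """Restrict observed changes to transcripts known to the knowledge base.

    The mapped universe keeps measured transcripts present in
    ``kg.transcript_index``; the mapping rate is computed over the
    *significant* calls, mirroring how coverage of a knowledge base is
    usually reported.
    """
    if not oc.direction:
        raise ValueError("observed changes contain no significant transcripts")
    index = kg.transcript_index
    mapped_universe = frozenset(oc.universe & index)
    mapped_dir = {t: d for t, d in oc.direction.items() if t in index}
    if not mapped_dir:
        raise ValueError(
            "no significant transcript mapped to the knowledge base; "
            "check that expression and KB identifiers share a namespace")
    unmapped = tuple(sorted(set(oc.direction) - index))
    rate = len(mapped_dir) / len(oc.direction)
    log.info("mapped %d/%d significant transcripts (rate %.3f); universe %d -> %d",
             len(mapped_dir), len(oc.direction), rate, len(oc.universe), len(mapped_universe))
    return MappedChanges(universe=mapped_universe, direction=mapped_dir,
                         mapping_rate=rate, unmapped_significant=unmapped,
                         thresholds=oc.thresholds)


# -- raw KB network export ---------------------------------------------

def kb_to_sif(kg: KnowledgeGraph, path) -> None:
    """Write the raw KB as SIF: ``source <tab> increases|decreases <tab> target``."""
    with open(path, "w", encoding="utf-8") as fh:
        for st in kg.statements():
            rel = "increases" if st.sign == UP else "decreases"
            fh.write(f"{st.source}\t{rel}\t{st.target}\n")


def kb_to_graphml(kg: KnowledgeGraph, path) -> None:
    """Write the raw KB as GraphML with sign and evidence-count edge attributes."""
    g = nx.MultiDiGraph()
    for ent in kg.entities():
        g.add_node(ent.id, kind=ent.kind, label=ent.label or ent.id)
    for st in kg.statements():
        g.add_edge(st.source, st.target, key=str(st.sign), sign=st.sign,
                   n_evidence=len(st.evidence))
    nx.write_graphml(g, path)
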