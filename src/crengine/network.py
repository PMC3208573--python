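"""Merge hypotheses into network models: coverage statistics, the evidence
matrix, and headless SIF/GraphML/TSV exports.

A merged model summarises a selected hypothesis subset: the union of
correctly explained transcripts and the fraction of all significant mapped
changes it covers, the transcripts explained by two or more members
(overlap), and the transcripts one member explains correctly while another
contradicts (contradictions). The evidence matrix is the hypothesis x gene
heatmap with +1 correct, -1 incorrect, 0 ambiguous, blank for no relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .knowledge import KnowledgeGraph
from .types import AMBIGUOUS, DOWN, UP, HypothesisResult, MappedChanges

EXPORT_FORMATS = ("sif", "graphml", "tsv")


@dataclass(frozen=True)
class MergedModel:
    hypotheses: tuple[HypothesisResult, ...]
    union_correct: frozenset[str]
    pct_unique_correct: float
    overlap: dict[str, int]            # transcript -> #explaining members (>= 2 only)
    overlap_fraction: float            # fraction of union_correct explained by >= 2
    contradictions: frozenset[str]
    observed: dict[str, int]           # observed direction of every involved transcript


def merge_hypotheses(subset: list[HypothesisResult],
                     mapped: MappedChanges) -> MergedModel:
    """Compute coverage, overlap and contradiction statistics for a subset."""
    if not subset:
        raise ValueError("cannot merge an empty hypothesis subset")
    union_correct: set[str] = set()
    counts: dict[str, int] = {}
    incorrect_union: set[str] = set()
    observed: dict[str, int] = {}
    for r in subset:
        union_correct |= r.classification.correct_set
        incorrect_union |= r.classification.incorrect_set
        observed.update(r.observed)
        for t in r.classification.correct_set:
            counts[t] = counts.get(t, 0) + 1
    overlap = {t: c for t, c in counts.items() if c >= 2}
    n_sig = mapped.n_significant
    pct = len(union_correct) / n_sig if n_sig else 0.0
    return MergedModel(
        hypotheses=tuple(subset),
        union_correct=frozenset(union_correct),
        pct_unique_correct=pct,
        overlap=overlap,
        overlap_fraction=len(overlap) / len(union_correct) if union_correct else 0.0,
        contradictions=frozenset(union_correct & incorrect_union),
        observed=observed,
    )


def evidence_matrix(subset: list[HypothesisResult]) -> pd.DataFrame:
    """Hypothesis x transcript matrix: +1 correct, -1 incorrect, 0 ambiguous,
    NaN no relation. Columns ordered by descending number of explaining
    hypotheses, then transcript id; rows keep the subset order."""
    if not subset:
        raise ValueError("cannot build an evidence matrix for an empty subset")
    col_counts: dict[str, int] = {}
    for r in subset:
        for t in (r.classification.correct_set | r.classification.incorrect_set
                  | r.classification.ambiguous_set):
            col_counts[t] = col_counts.get(t, 0) + 1
    cols = sorted(col_counts, key=lambda t: (-col_counts[t], t))
    rows = [r.hypothesis.label for r in subset]
    mat = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    for r in subset:
        lbl = r.hypothesis.label
        for t in r.classification.correct_set:
            mat.loc[lbl, t] = 1.0
        for t in r.classification.incorrect_set:
            mat.loc[lbl, t] = -1.0
        for t in r.classification.ambiguous_set:
            mat.loc[lbl, t] = 0.0
    return mat


def model_graph(model: MergedModel, kg: KnowledgeGraph | None = None) -> nx.DiGraph:
    """Overview graph of a merged model.

    Hypothesis nodes carry their predicted direction; transcript nodes their
    observed mRNA direction (the usual colour semantics: predicted
    increase/decrease, observed up/down). Edges hypothesis -> transcript carry
    the predicted sign and the classification. When a knowledge graph is
    supplied, causal statements linking two member entities become
    inter-hypothesis edges with their sign.
    """
    g = nx.DiGraph()
    for r in model.hypotheses:
        g.add_node(r.hypothesis.label, node_type="hypothesis",
                   entity=r.hypothesis.entity,
                   predicted_direction="increase" if r.hypothesis.direction == UP else "decrease")
    for r in model.hypotheses:
        items = [(t, "correct") for t in sorted(r.classification.correct_set)]
        items += [(t, "incorrect") for t in sorted(r.classification.incorrect_set)]
        items += [(t, "ambiguous") for t in sorted(r.classification.ambiguous_set)]
        for t, klass in items:
            obs = model.observed[t]
            g.add_node(t, node_type="transcript",
                       observed_direction="up" if obs == UP else "down")
            if klass == "correct":
                pred = obs
            elif klass == "incorrect":
                pred = -obs
            else:
                pred = AMBIGUOUS
            g.add_edge(r.hypothesis.label, t,
                       predicted_sign={UP: "+", DOWN: "-", AMBIGUOUS: "0"}[pred],
                       classification=klass)
    if kg is not None:
        ents = {r.hypothesis.entity: r.hypothesis.label for r in model.hypotheses}
        for u, lu in ents.items():
            for v, lv in ents.items():
                if u == v or u not in kg or v not in kg:
                    continue
                for sign in (UP, DOWN):
                    if kg.graph.has_edge(u, v, key=sign):
                        g.add_edge(lu, lv, predicted_sign="+" if sign == UP else "-",
                                   classification="inter_hypothesis")
    return g


def export_model(model: MergedModel, out_prefix, fmt: str = "sif",
                 kg: KnowledgeGraph | None = None) -> list[Path]:
    """Export a merged model. ``fmt`` is one of sif, graphml, tsv.

    SIF rows use increases/decreases (ambiguous predictions export as
    ``associates``); TSV emits node/edge attribute tables plus the evidence
    matrix. Output is byte-stable for a fixed model.
    """
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = model_graph(model, kg)
    written: list[Path] = []
    if fmt == "sif":
        path = prefix.with_suffix(".sif")
        rel = {"+": "increases", "-": "decreases", "0": "associates"}
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{rel[data['predicted_sign']]}\t{v}\n")
        written.append(path)
    elif fmt == "graphml":
        path = prefix.with_suffix(".graphml")
        nx.write_graphml(g, path)
        written.append(path)
    else:
        nodes = pd.DataFrame(
            [{"node": n, **d} for n, d in sorted(g.nodes(data=True))])
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d} for u, v, d in sorted(g.edges(data=True))])
        npath = prefix.parent / (prefix.name + "_nodes.tsv")
        epath = prefix.parent / (prefix.name + "_edges.tsv")
        mpath = prefix.parent / (prefix.name + "_evidence_matrix.tsv")
        nodes.to_csv(npath, sep="\t", index=False)
        edges.to_csv(epath, sep="\t", index=False)
        evidence_matrix(list(model.hypotheses)).to_csv(mpath, sep="\t")
        written.extend([npath, epath, mpath])
    return written
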