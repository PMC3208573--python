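"""Synthetic knowledge bases and expression profiles with planted regulators.

The generator emulates the regime this class of analysis runs in — a curated
regulator->transcript knowledge base far larger than the set of responding
genes, a few truly active upstream regulators, and noisy direction calls —
at desk scale, so every pipeline stage is testable without licensed content.

The defaults describe the study conditions used throughout the test suite
and benchmarks: 200 regulators over 2,000 transcripts with mean out-degree
15 (about 3,000 causal statements), 30% repressive edges, 2% of edges
carrying a contradictory duplicate, 5 planted active regulators whose
targets respond consistently with probability 0.8 and with flipped sign with
probability 0.05, and a 2% background significance rate. Identical seed and
config yield identical outputs; the knowledge base and the experiment draw
from independent child streams of the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .knowledge import KnowledgeGraph
from .types import DOWN, UP, CausalStatement, Entity, Hypothesis, ObservedChanges


@dataclass(frozen=True)
class SimConfig:
    n_regulators: int = 200
    n_transcripts: int = 2000
    out_degree: float = 15.0          # mean transcript targets per regulator
    reg_out_degree: float = 0.0       # mean regulator->regulator edges (depth testing)
    p_negative_edge: float = 0.3
    n_active: int = 5                 # planted active hypotheses
    tpr: float = 0.8                  # target responds consistently
    flip_rate: float = 0.05           # target responds with opposite sign
    background_rate: float = 0.02     # unrelated transcript called significant
    ambiguity_rate: float = 0.02      # edges with a contradictory duplicate
    unmapped_rate: float = 0.0        # significant calls on ids absent from the KB
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.p_negative_edge, self.tpr, self.flip_rate,
                 self.background_rate, self.ambiguity_rate, self.unmapped_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.tpr + self.flip_rate > 1.0:
            raise ValueError("tpr + flip_rate must not exceed 1")
        if self.n_regulators <= 0 or self.n_transcripts <= 0:
            raise ValueError("counts must be positive")
        if self.n_active > self.n_regulators:
            raise ValueError("n_active exceeds n_regulators")
        if self.unmapped_rate >= 1.0:
            raise ValueError("unmapped_rate must be < 1")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def regulator_id(i: int) -> str:
    return f"R{i:04d}"


def transcript_id(i: int) -> str:
    return f"T{i:05d}"


def simulate_kb(cfg: SimConfig) -> KnowledgeGraph:
    """Random regulator->transcript (plus optional regulator->regulator)
    signed multigraph with contradictory duplicates at ``ambiguity_rate``."""
    rng = _rng(cfg, 0)
    kg = KnowledgeGraph()
    regs = [regulator_id(i) for i in range(cfg.n_regulators)]
    txs = [transcript_id(i) for i in range(cfg.n_transcripts)]
    for r in regs:
        kg.add_entity(Entity(r, "protein"))
    for t in txs:
        kg.add_entity(Entity(t, "transcript"))
    for r in regs:
        k = min(int(rng.poisson(cfg.out_degree)), cfg.n_transcripts)
        targets = rng.choice(cfg.n_transcripts, size=k, replace=False)
        for ti in sorted(targets):
            sign = DOWN if rng.random() < cfg.p_negative_edge else UP
            kg.add_statement(CausalStatement(r, sign, txs[ti]))
            if rng.random() < cfg.ambiguity_rate:
                kg.add_statement(CausalStatement(r, -sign, txs[ti]))
        if cfg.reg_out_degree > 0 and cfg.n_regulators > 1:
            kr = min(int(rng.poisson(cfg.reg_out_degree)), cfg.n_regulators - 1)
            others = [o for o in rng.choice(cfg.n_regulators, size=kr + 1, replace=False)
                      if regs[o] != r][:kr]
            for oi in sorted(others):
                sign = DOWN if rng.random() < cfg.p_negative_edge else UP
                kg.add_statement(CausalStatement(r, sign, regs[oi]))
    return kg


def simulate_experiment(kg: KnowledgeGraph, cfg: SimConfig
                        ) -> tuple[ObservedChanges, list[Hypothesis]]:
    """Plant ``n_active`` regulators with random directions and generate
    direction calls for their direct targets plus background noise.

    Targets reached through a contradictory duplicate statement respond
    according to the first-listed sign. When ``unmapped_rate`` > 0, extra
    significant calls on identifiers absent from the KB are appended so the
    mapping rate is approximately ``1 - unmapped_rate``.
    """
    rng = _rng(cfg, 1)
    regs = sorted(n for n, k in kg.graph.nodes(data="kind") if k != "transcript")
    txs = sorted(kg.transcript_index)
    active_idx = rng.choice(len(regs), size=cfg.n_active, replace=False) if cfg.n_active else []
    truth = [Hypothesis(regs[i], UP if rng.random() < 0.5 else DOWN)
             for i in sorted(active_idx)]
    direction: dict[str, int] = {}
    for h in truth:
        for _, t, sign in sorted(kg.graph.out_edges(h.entity, keys=True)):
            if kg.kind(t) != "transcript" or t in direction:
                continue
            u = rng.random()
            if u < cfg.tpr:
                direction[t] = h.direction * sign
            elif u < cfg.tpr + cfg.flip_rate:
                direction[t] = -h.direction * sign
    for t in txs:
        if t not in direction and rng.random() < cfg.background_rate:
            direction[t] = UP if rng.random() < 0.5 else DOWN
    universe = set(txs)
    if cfg.unmapped_rate > 0 and direction:
        n_extra = round(len(direction) * cfg.unmapped_rate / (1 - cfg.unmapped_rate))
        for i in range(n_extra):
            uid = f"U{i:05d}"
            universe.add(uid)
            direction[uid] = UP if rng.random() < 0.5 else DOWN
    return (ObservedChanges(universe=frozenset(universe), direction=direction),
            truth)


def write_expression_table(oc: ObservedChanges, path,
                           rng: np.random.Generator | None = None) -> None:
    """Write an expression TSV consistent with the observed calls.

    Significant transcripts get |log2FC| above the fold-change cutoff and a
    small adjusted p; non-significant ones fail both thresholds, so
    re-reading with the recorded thresholds reproduces ``oc`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    p_cut, fc_cut = oc.thresholds
    log2_cut = float(np.log2(fc_cut))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "log2fc", "adj_p"])
        for g in sorted(oc.universe):
            d = oc.direction.get(g)
            if d is None:
                lfc = float(rng.normal(0, 0.25 * log2_cut))
                p = float(rng.uniform(max(p_cut, 0.1), 1.0))
            else:
                lfc = d * (log2_cut + abs(float(rng.normal(0.5, 0.2))))
                p = float(10 ** -rng.uniform(2, 6))
            w.writerow([g, f"{lfc:.6g}", f"{p:.6g}"])


def write_truth(truth: list[Hypothesis], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["entity", "direction"])
        for h in truth:
            w.writerow([h.entity, "+" if h.direction == UP else "-"])


def read_truth(path) -> list[Hypothesis]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for entity, d in reader:
            out.append(Hypothesis(entity, UP if d == "+" else DOWN))
    return out
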