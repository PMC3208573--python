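"""Significance measures for upstream hypotheses.

Two metrics quantify how well a hypothesis explains the data:

* **Enrichment p-value** — a one-sided Fisher exact (hypergeometric) tail for
  finding ``#correct + #incorrect`` significantly changed transcripts among
  the hypothesis's downstream transcripts, drawn from the mapped measured
  universe. Direction of regulation plays no role here.

* **Correctness p-value** — the upper tail of the score
  ``S = #correct - #incorrect`` under a null model that re-assigns the
  observed up- and down-labels uniformly at random to distinct nodes of the
  measured universe. With ``G_up``/``G_down`` labels over ``N`` nodes and a
  hypothesis predicting ``d_up`` transcripts up and ``d_down`` down,
  ``S = (u+ + v-) - (u- + v+)`` where ``u±`` counts up/down labels landing in
  the predicted-up set and ``v±`` in the predicted-down set. The joint law of
  ``(u+, v+, u-, v-)`` is multivariate hypergeometric; the exact pmf of S is
  accumulated by a polynomial-time convolution over those four counts — never
  by enumerating label assignments.

Transcripts with ambiguous (self-contradictory) predictions are excluded
from the hit count, the downstream draw size and the null parameters: the
score's definition names only correct and incorrect calls.

The module also provides the GO-style gene-set enrichment used for
high-level comparison: a two-sided Fisher exact test per term with a
Derringer-type desirability ranking favouring large |odds ratio|, small
p-value and a target term size of 20 genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact, hypergeom

from .engine import DEFAULT_DEPTH, classify, downstream_signatures, predict_downstream
from .knowledge import KnowledgeGraph
from .types import (AMBIGUOUS, DOWN, UP, Classification, Hypothesis,
                    HypothesisResult, MappedChanges, Prediction)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# exact null distribution of the correctness score
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class NullDistribution:
    """Exact probability mass of the correctness score under label re-assignment.

    ``support`` and ``pmf`` are aligned arrays; ``params`` is
    ``(N, G_up, G_down, d_up, d_down)``.
    """

    support: np.ndarray
    pmf: np.ndarray
    params: tuple[int, int, int, int, int]

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))


def _log_binom(n, k):
    """Vectorised log C(n, k); -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    valid = (k >= 0) & (k <= n) & (n >= 0)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(valid, out, -np.inf)


@lru_cache(maxsize=200_000)
def _null_arrays(N: int, G_up: int, G_down: int, d_up: int, d_down: int):
    D = d_up + d_down
    R = N - D  # nodes outside both predicted sets
    pmf = np.zeros(2 * D + 1)
    log_den_up = float(_log_binom(N, G_up))
    log_den_down = float(_log_binom(N - G_up, G_down))
    c = np.arange(d_up + 1)
    d = np.arange(d_down + 1)
    cg, dg = np.meshgrid(c, d, indexing="ij")
    for a in range(min(d_up, G_up) + 1):          # up labels in predicted-up
        la = float(_log_binom(d_up, a))
        for b in range(min(d_down, G_up - a) + 1):  # up labels in predicted-down
            log_up = (la + float(_log_binom(d_down, b))
                      + float(_log_binom(R, G_up - a - b)) - log_den_up)
            if log_up == -np.inf:
                continue
            # down labels over remaining capacity
            log_down = (_log_binom(d_up - a, cg) + _log_binom(d_down - b, dg)
                        + _log_binom(R - (G_up - a - b), G_down - cg - dg)
                        - log_den_down)
            w = np.exp(log_up + log_down)
            scores = a + dg - cg - b + D  # index shift: S in [-D, D]
            np.add.at(pmf, scores, w)
    support = np.arange(-D, D + 1)
    nz = np.nonzero(pmf)[0]
    support, pmf = support[nz[0]:nz[-1] + 1], pmf[nz[0]:nz[-1] + 1]
    support.setflags(write=False)
    pmf.setflags(write=False)
    return support, pmf


def correctness_null(N: int, G_up: int, G_down: int,
                     d_up: int, d_down: int) -> NullDistribution:
    """Exact null pmf of S = #correct - #incorrect.

    ``G_up`` up-labels and ``G_down`` down-labels are placed uniformly on
    distinct nodes of an N-node universe containing disjoint predicted-up and
    predicted-down sets of sizes ``d_up`` and ``d_down``.
    """
    if min(N, G_up, G_down, d_up, d_down) < 0:
        raise ValueError("null parameters must be non-negative")
    if G_up + G_down > N:
        raise ValueError(f"G_up + G_down = {G_up + G_down} exceeds N = {N}")
    if d_up + d_down > N:
        raise ValueError(f"d_up + d_down = {d_up + d_down} exceeds N = {N}")
    support, pmf = _null_arrays(N, G_up, G_down, d_up, d_down)
    return NullDistribution(support, pmf, (N, G_up, G_down, d_up, d_down))


def correctness_pvalue(score: int, nd: NullDistribution) -> float:
    """Upper-tail probability P(S >= score) under the exact null."""
    if score <= nd.support[0]:
        return 1.0
    tail = float(nd.pmf[nd.support >= score].sum())
    return min(max(tail, 0.0), 1.0)


# ---------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------

def enrichment_pvalue(cls: Classification, pred: Prediction,
                      mapped: MappedChanges) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    downstream-of-h x significantly-changed over the mapped universe.

    The downstream set counts unambiguously predicted transcripts inside the
    universe; the hit count is ``n_correct + n_incorrect``.
    """
    N = len(mapped.universe)
    if N == 0:
        raise ValueError("mapped universe is empty")
    K = mapped.n_significant
    downstream = sum(1 for t, s in pred.signs.items()
                     if s != AMBIGUOUS and t in mapped.universe)
    if downstream == 0:
        warnings.warn("hypothesis has no unambiguous downstream transcript in "
                      "the measured universe; enrichment p = 1", stacklevel=2)
        return 1.0
    hits = cls.n_correct + cls.n_incorrect
    return float(hypergeom.sf(hits - 1, N, K, downstream))


# ---------------------------------------------------------------------
# composite scoring
# ---------------------------------------------------------------------

def _result_from_parts(h: Hypothesis, cls: Classification, pred: Prediction,
                       mapped: MappedChanges) -> HypothesisResult:
    d_up = sum(1 for t, s in pred.signs.items() if s == UP and t in mapped.universe)
    d_down = sum(1 for t, s in pred.signs.items() if s == DOWN and t in mapped.universe)
    nd = correctness_null(len(mapped.universe), mapped.n_up, mapped.n_down, d_up, d_down)
    observed = {t: mapped.direction[t]
                for t in (cls.correct_set | cls.incorrect_set | cls.ambiguous_set)}
    return HypothesisResult(
        hypothesis=h,
        classification=cls,
        score=cls.score,
        enrichment_p=enrichment_pvalue(cls, pred, mapped),
        correctness_p=correctness_pvalue(cls.score, nd),
        percent_correct=cls.percent_correct,
        evidence=frozenset((t, mapped.direction[t]) for t in cls.correct_set),
        observed=observed,
    )


def score_hypothesis(h: Hypothesis, kg: KnowledgeGraph, mapped: MappedChanges,
                     depth: int = DEFAULT_DEPTH) -> HypothesisResult:
    """Predict, classify and attach both p-values for one hypothesis."""
    pred = predict_downstream(h, kg, depth, with_provenance=False)
    cls = classify(pred, mapped)
    return _result_from_parts(h, cls, pred, mapped)


def score_hypotheses(kg: KnowledgeGraph, mapped: MappedChanges,
                     depth: int = DEFAULT_DEPTH, min_targets: int = 1,
                     signatures: dict[str, dict[str, int]] | None = None,
                     ) -> list[HypothesisResult]:
    """Score both directions of every entity with >= min_targets downstream
    transcripts, sharing one signed-reachability pass per entity.

    ``signatures`` (from :func:`crengine.engine.downstream_signatures`) can be
    supplied to amortise the graph traversal over repeated experiments on the
    same knowledge base.
    """
    if signatures is None:
        signatures = downstream_signatures(kg, depth)
    results: list[HypothesisResult] = []
    for ent in sorted(signatures):
        base = signatures[ent]
        if len(base) < min_targets:
            continue
        for direction in (UP, DOWN):
            h = Hypothesis(ent, direction)
            signs = {t: (direction * s if s != AMBIGUOUS else AMBIGUOUS)
                     for t, s in base.items()}
            pred = Prediction(h, signs)
            cls = classify(pred, mapped)
            results.append(_result_from_parts(h, cls, pred, mapped))
    return results


# ---------------------------------------------------------------------
# results table I/O
# ---------------------------------------------------------------------

RESULT_COLUMNS = ("hypothesis", "direction", "rank", "cluster_id", "n_correct",
                  "n_incorrect", "n_ambiguous", "score", "correctness_p",
                  "enrichment_p", "percent_correct", "correct_set",
                  "incorrect_set", "ambiguous_set")


def _encode_set(tids, observed) -> str:
    return ",".join(f"{t}:{'+' if observed[t] == UP else '-'}" for t in sorted(tids))


def _decode_set(cell: str) -> dict[str, int]:
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return {}
    out = {}
    for item in str(cell).split(","):
        t, _, s = item.rpartition(":")
        out[t] = UP if s == "+" else DOWN
    return out


def results_to_frame(results: list[HypothesisResult]) -> pd.DataFrame:
    """Results table with the classification sets encoded as ``tid:+,tid:-``
    strings so the table is fully re-loadable."""
    rows = []
    for r in results:
        rows.append({
            "hypothesis": r.hypothesis.entity,
            "direction": "+" if r.hypothesis.direction == UP else "-",
            "rank": r.rank,
            "cluster_id": r.cluster_id,
            "n_correct": r.n_correct,
            "n_incorrect": r.n_incorrect,
            "n_ambiguous": r.n_ambiguous,
            "score": r.score,
            "correctness_p": r.correctness_p,
            "enrichment_p": r.enrichment_p,
            "percent_correct": r.percent_correct,
            "correct_set": _encode_set(r.classification.correct_set, r.observed),
            "incorrect_set": _encode_set(r.classification.incorrect_set, r.observed),
            "ambiguous_set": _encode_set(r.classification.ambiguous_set, r.observed),
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[HypothesisResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results(path) -> list[HypothesisResult]:
    """Re-load a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"hypothesis": str})
    out = []
    for row in df.itertuples(index=False):
        correct = _decode_set(row.correct_set)
        incorrect = _decode_set(row.incorrect_set)
        ambiguous = _decode_set(row.ambiguous_set)
        observed = {**correct, **incorrect, **ambiguous}
        cls = Classification(frozenset(correct), frozenset(incorrect), frozenset(ambiguous))
        out.append(HypothesisResult(
            hypothesis=Hypothesis(row.hypothesis, UP if row.direction == "+" else DOWN),
            classification=cls,
            score=int(row.score),
            enrichment_p=float(row.enrichment_p),
            correctness_p=float(row.correctness_p),
            percent_correct=float(row.percent_correct),
            evidence=frozenset(correct.items()),
            observed=observed,
            rank=None if pd.isna(row.rank) else int(row.rank),
            cluster_id=None if pd.isna(row.cluster_id) else int(row.cluster_id),
        ))
    return out


# ---------------------------------------------------------------------
# GO-style gene-set enrichment with desirability ranking
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilityConfig:
    """Anchor points of the three Derringer-style desirability ramps.

    The printed sources of this method do not fix the anchors, so these are
    conventions: full desirability at |log2 odds ratio| >= 3, at
    p <= 1e-5, and at a term size of exactly ``size_target`` genes (ramping
    linearly in log10 size from ``size_min`` and back down to ``size_max``).
    """

    log2_or_saturation: float = 3.0
    neglog10_p_saturation: float = 5.0
    size_target: int = 20
    size_min: int = 2
    size_max: int = 200


def _desirability(odds_ratio: float, p: float, size: int,
                  cfg: DesirabilityConfig) -> float:
    if math.isnan(odds_ratio):
        d_or = 0.0
    elif odds_ratio in (0.0, math.inf):
        d_or = 1.0
    else:
        d_or = min(1.0, abs(math.log2(odds_ratio)) / cfg.log2_or_saturation)
    d_p = min(1.0, -math.log10(max(p, 1e-300)) / cfg.neglog10_p_saturation)
    ls, lt = math.log10(size), math.log10(cfg.size_target)
    if size <= cfg.size_min or size >= cfg.size_max:
        d_size = 0.0
    elif size <= cfg.size_target:
        d_size = (ls - math.log10(cfg.size_min)) / (lt - math.log10(cfg.size_min))
    else:
        d_size = (math.log10(cfg.size_max) - ls) / (math.log10(cfg.size_max) - lt)
    return (d_or * d_p * d_size) ** (1.0 / 3.0)


def go_enrichment(gene_sets: dict[str, set[str]] | pd.DataFrame,
                  mapped: MappedChanges,
                  desirability: DesirabilityConfig = DesirabilityConfig(),
                  ) -> pd.DataFrame:
    """Two-sided Fisher exact test per gene set over the mapped universe,
    ranked by composite desirability (descending).

    ``gene_sets`` is either ``{term: genes}`` or a long DataFrame with
    columns ``term`` and ``gene``. The odds ratio is the sample odds ratio of
    the 2x2 table; terms fully contained in the significant set report
    infinity. Terms with no gene in the universe are skipped with a warning.
    """
    if isinstance(gene_sets, pd.DataFrame):
        gene_sets = {t: set(g) for t, g in gene_sets.groupby("term")["gene"]}
    universe = mapped.universe
    sig = set(mapped.direction)
    N, S = len(universe), len(sig)
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & universe
        if not members:
            warnings.warn(f"gene set {term!r} has no gene in the universe; skipped",
                          stacklevel=2)
            continue
        size = len(members)
        a = len(members & sig)
        b = S - a
        c = size - a
        d = N - S - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"term": term, "p_value": float(p), "odds_ratio": float(odds),
                     "size": size, "hits": a,
                     "desirability": _desirability(float(odds), float(p), size,
                                                   desirability)})
    df = pd.DataFrame(rows, columns=["term", "p_value", "odds_ratio", "size",
                                     "hits", "desirability"])
    return df.sort_values(["desirability", "term"], ascending=[False, True],
                          ignore_index=True)
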