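"""Core domain types shared across the package.

The vocabulary follows the causal-reasoning literature: a *causal statement*
is a curated, signed assertion that an increase in one biological entity
increases (+1) or decreases (-1) another; a *hypothesis* is a candidate
upstream cause, i.e. an entity together with an assumed direction of
regulation; transcripts downstream of a hypothesis are classified as
*correct*, *incorrect* or *ambiguous* against the observed direction calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

UP = 1
DOWN = -1
AMBIGUOUS = 0

#: closed vocabulary of entity kinds
ENTITY_KINDS = frozenset({"protein", "transcript", "compound", "process", "phenotype", "other"})


@dataclass(frozen=True)
class Entity:
    """A typed node of the knowledge graph.

    ``id`` is an opaque, case-sensitive identifier; ``kind`` must come from
    :data:`ENTITY_KINDS`. Only ``kind == "transcript"`` nodes are comparable
    to expression data.
    """

    id: str
    kind: str = "other"
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("entity id must be non-empty")
        if self.kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}; expected one of {sorted(ENTITY_KINDS)}")


@dataclass(frozen=True)
class CausalStatement:
    """One signed, evidence-backed edge: increase of ``source`` causes
    ``sign``-signed change of ``target``.

    ``evidence`` is a tuple of ``(citation_id, quote)`` pairs, possibly empty.
    """

    source: str
    sign: int
    target: str
    evidence: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.sign not in (UP, DOWN):
            raise ValueError(f"statement sign must be +1 or -1, got {self.sign!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop statement rejected: {self.source!r}")


@dataclass(frozen=True)
class ObservedChanges:
    """The measured universe with per-transcript direction calls.

    ``universe`` holds every measured transcript id; ``direction`` maps the
    *significant* subset to +1 (up) or -1 (down). ``thresholds`` records the
    (adjusted-p cutoff, fold-change cutoff) that produced the calls.
    """

    universe: frozenset[str]
    direction: dict[str, int]
    thresholds: tuple[float, float] = (0.05, 1.3)

    def __post_init__(self) -> None:
        missing = set(self.direction) - self.universe
        if missing:
            raise ValueError(f"directed transcripts not in universe: {sorted(missing)[:5]}")
        bad = {d for d in self.direction.values() if d not in (UP, DOWN)}
        if bad:
            raise ValueError(f"direction values must be +1/-1, got {bad}")

    @property
    def n_significant(self) -> int:
        return len(self.direction)


@dataclass(frozen=True)
class MappedChanges:
    """Observed changes restricted to transcripts present in a knowledge base.

    ``mapping_rate`` = |mapped significant| / |significant| over the original
    calls; ``unmapped_significant`` lists the ids that were dropped.
    """

    universe: frozenset[str]
    direction: dict[str, int]
    mapping_rate: float
    unmapped_significant: tuple[str, ...] = ()
    thresholds: tuple[float, float] = (0.05, 1.3)

    @property
    def n_significant(self) -> int:
        return len(self.direction)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.direction.values() if d == UP)

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.direction.values() if d == DOWN)


@dataclass(frozen=True, order=True)
class Hypothesis:
    """A candidate upstream cause: an entity plus an assumed direction."""

    entity: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError("hypothesis direction must be +1 or -1")

    @property
    def label(self) -> str:
        return f"{self.entity}{'+' if self.direction == UP else '-'}"


@dataclass
class Prediction:
    """Signed downstream transcript predictions of one hypothesis.

    ``signs`` maps transcript id to +1, -1 or :data:`AMBIGUOUS` (0, used when
    chains supporting both signs exist). ``provenance`` optionally maps each
    transcript to the statement chains supporting it (each chain a tuple of
    (source, sign, target) triples); it is ``None`` when predictions were
    computed in bulk without provenance tracking.
    """

    hypothesis: Hypothesis
    signs: dict[str, int]
    provenance: dict[str, list[tuple[tuple[str, int, str], ...]]] | None = None


@dataclass(frozen=True)
class Classification:
    """Partition of the significant mapped transcripts a hypothesis predicts."""

    correct_set: frozenset[str]
    incorrect_set: frozenset[str]
    ambiguous_set: frozenset[str]

    def __post_init__(self) -> None:
        if (self.correct_set & self.incorrect_set or self.correct_set & self.ambiguous_set
                or self.incorrect_set & self.ambiguous_set):
            raise ValueError("classification sets must be disjoint")

    @property
    def n_correct(self) -> int:
        return len(self.correct_set)

    @property
    def n_incorrect(self) -> int:
        return len(self.incorrect_set)

    @property
    def n_ambiguous(self) -> int:
        return len(self.ambiguous_set)

    @property
    def score(self) -> int:
        return self.n_correct - self.n_incorrect

    @property
    def percent_correct(self) -> float:
        denom = self.n_correct + self.n_incorrect
        return self.n_correct / denom if denom else math.nan


@dataclass
class HypothesisResult:
    """A scored hypothesis: classification counts, score and both p-values.

    ``evidence`` is the supporting-evidence feature set used for clustering:
    the (transcript, observed direction) pairs the hypothesis correctly
    explains. ``observed`` retains the observed direction of every transcript
    in the three classification sets, for exports.
    """

    hypothesis: Hypothesis
    classification: Classification
    score: int
    enrichment_p: float
    correctness_p: float
    percent_correct: float
    evidence: frozenset[tuple[str, int]] = frozenset()
    observed: dict[str, int] = field(default_factory=dict)
    rank: int | None = None
    cluster_id: int | None = None

    @property
    def n_correct(self) -> int:
        return self.classification.n_correct

    @property
    def n_incorrect(self) -> int:
        return self.classification.n_incorrect

    @property
    def n_ambiguous(self) -> int:
        return self.classification.n_ambiguous


def sign_to_str(sign: int) -> str:
    return {UP: "+", DOWN: "-", AMBIGUOUS: "0"}[sign]


def str_to_sign(token: str) -> int:
    try:
        return {"+": UP, "-": DOWN, "0": AMBIGUOUS, "+1": UP, "-1": DOWN, "1": UP}[token]
    except KeyError:
        raise ValueError(f"unknown sign token {token!r}") from None
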