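"""Hypothesis admission cutoffs and competition ranking.

Default cutoffs follow common practice for this method: correctness
p < 0.01, enrichment p < 0.01, at least 3 correctly explained changes and at
least 60% correctly explained (strict inequality on the p-values, >= on the
counts/fractions). Ranking is by ascending correctness p-value with tied
values sharing the minimum rank (competition ranking, "1224"); rows with
equal rank are ordered by ascending enrichment p, then entity id.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .types import HypothesisResult


@dataclass(frozen=True)
class FilterConfig:
    max_correctness_p: float = 0.01
    max_enrichment_p: float = 0.01
    min_correct: int = 3
    min_percent_correct: float = 0.60

    def __post_init__(self) -> None:
        if not (0 < self.max_correctness_p <= 1 and 0 < self.max_enrichment_p <= 1):
            raise ValueError("p-value cutoffs must lie in (0, 1]")
        if self.min_correct < 0 or not 0 <= self.min_percent_correct <= 1:
            raise ValueError("count/fraction cutoffs out of range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**{k: d[k] for k in asdict(cls()) if k in d})

    def admits(self, r: HypothesisResult) -> bool:
        return (r.correctness_p < self.max_correctness_p
                and r.enrichment_p < self.max_enrichment_p
                and r.n_correct >= self.min_correct
                and r.percent_correct >= self.min_percent_correct)


def filter_hypotheses(results: list[HypothesisResult],
                      cfg: FilterConfig = FilterConfig()) -> list[HypothesisResult]:
    """Keep results meeting all four cutoffs; input order preserved."""
    return [r for r in results if cfg.admits(r)]


def rank_hypotheses(results: list[HypothesisResult]) -> list[HypothesisResult]:
    """Return results sorted and with competition ranks assigned in place.

    Rank key: correctness p ascending; ties share the minimum rank and are
    ordered among themselves by enrichment p, then entity id, then direction.
    """
    ordered = sorted(results, key=lambda r: (r.correctness_p, r.enrichment_p,
                                             r.hypothesis.entity,
                                             -r.hypothesis.direction))
    prev_p = None
    for i, r in enumerate(ordered, start=1):
        if prev_p is not None and r.correctness_p == prev_p:
            r.rank = rank
        else:
            rank = i
            r.rank = rank
        prev_p = r.correctness_p
    return ordered
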