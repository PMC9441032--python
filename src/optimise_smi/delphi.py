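"""Delphi consensus summarisation and classification.

An expert panel rates candidate prescribing indicators on a 5-point Likert
scale (1 = strongly agree ... 5 = strongly disagree).  Per item and per
round the engine computes the median, inter-quartile range and 75th
centile of the non-missing ratings, then classifies:

* **accept** — median <= 2 and 75th centile <= 2
* **reject** — median > 2
* **revise** — median <= 2 but 75th centile > 2 (carried into the next
  round after re-wording by the research team; re-wording itself is human
  work and out of scope)
* **drop** — a revise verdict at the configured final round, where a
  further round is judged unlikely to reach consensus

Quantiles use linear interpolation between closest order statistics
(numpy's default, R type 7).  The convention matters for the 75th centile
of small panels (it is what yields values such as 1.25 or 1.75 from 16-17
raters); the classification of every shipped indicator is robust to the
choice.  Missing ratings are dropped per item, so items can have
different numbers of ratings within one round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatingMatrix", "ConsensusSummary", "RoundResult", "DelphiOutcome",
    "summarize_ratings", "classify_indicator", "run_round", "run_delphi",
    "read_ratings_csv",
]

LIKERT_VALUES = (1, 2, 3, 4, 5)

Classification = Literal["accept", "reject", "revise", "drop"]


@dataclass(frozen=True)
class ConsensusSummary:
    """Per-item rating summary: median, IQR and 75th centile."""

    item_id: str
    n_ratings: int
    median: float
    q25: float
    p75: float

    def __post_init__(self) -> None:
        if not (1 <= self.q25 <= self.p75 <= 5):
            raise ValueError(f"{self.item_id}: quartiles outside the Likert range")
        if not (self.q25 <= self.median <= self.p75):
            raise ValueError(f"{self.item_id}: median outside the IQR")

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q25, self.p75)


@dataclass
class RatingMatrix:
    """Panellist x item Likert ratings for one round; NaN marks missing."""

    round_id: str
    ratings: pd.DataFrame  # index = panellist ids, columns = item ids

    def __post_init__(self) -> None:
        values = self.ratings.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if not np.isin(observed, LIKERT_VALUES).all():
            bad = sorted(set(observed) - set(LIKERT_VALUES))
            raise ValueError(f"round {self.round_id}: non-Likert ratings {bad}")
        if self.ratings.isna().all(axis=0).any():
            empty = list(self.ratings.columns[self.ratings.isna().all(axis=0)])
            raise ValueError(f"round {self.round_id}: items with no ratings: {empty}")

    @property
    def items(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def panellists(self) -> list[str]:
        return list(self.ratings.index)

    def item_ratings(self, item_id: str) -> list[int]:
        column = self.ratings[item_id]
        return [int(v) for v in column.dropna()]


@dataclass
class RoundResult:
    round_id: str
    accepted: list[str]
    rejected: list[str]
    revise: list[str]
    summaries: dict[str, ConsensusSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = self.accepted + self.rejected + self.revise
        if len(parts) != len(set(parts)) or set(parts) != set(self.summaries):
            raise ValueError(
                f"round {self.round_id}: accepted/rejected/revise must "
                "partition the round's items")


@dataclass
class DelphiOutcome:
    rounds: list[RoundResult]
    final_tool: list[str]
    dropped_after_final: list[str]


def summarize_ratings(values: Sequence[float | None],
                      item_id: str = "item") -> ConsensusSummary:
    """Summarise one item's ratings; missing entries (None/NaN) are dropped."""
    clean = [float(v) for v in values
             if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not clean:
        raise ValueError(f"{item_id}: no non-missing ratings")
    if not all(v in LIKERT_VALUES for v in clean):
        raise ValueError(f"{item_id}: ratings must be integers in 1..5")
    arr = np.asarray(clean)
    q25, median, p75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return ConsensusSummary(item_id=item_id, n_ratings=len(clean),
                            median=float(median), q25=float(q25), p75=float(p75))


def classify_indicator(summary: ConsensusSummary,
                       is_final_round: bool = False) -> Classification:
    """Apply the consensus acceptance rule to one summarised item."""
    if summary.median > 2:
        return "reject"
    if summary.p75 <= 2:
        return "accept"
    return "drop" if is_final_round else "revise"


def run_round(matrix: RatingMatrix, is_final_round: bool = False) -> RoundResult:
    """Summarise and classify every item of one Delphi round."""
    accepted, rejected, revise = [], [], []
    summaries = {}
    for item in matrix.items:
        summary = summarize_ratings(matrix.item_ratings(item), item_id=item)
        summaries[item] = summary
        verdict = classify_indicator(summary, is_final_round=is_final_round)
        {"accept": accepted, "reject": rejected,
         "revise": revise, "drop": revise}[verdict].append(item)
    return RoundResult(round_id=matrix.round_id, accepted=accepted,
                       rejected=rejected, revise=revise, summaries=summaries)


def run_delphi(rounds: Sequence[RatingMatrix],
               max_rounds: Optional[int] = None) -> DelphiOutcome:
    """Run an ordered multi-round Delphi flow.

    Every round after the first must rate exactly the previous round's
    revise items.  Items still unresolved at the last executed round are
    dropped from the final tool.
    """
    if not rounds:
        raise ValueError("at least one rating round is required")
    max_rounds = max_rounds if max_rounds is not None else len(rounds)
    results: list[RoundResult] = []
    expected_items: Optional[set[str]] = None
    for number, matrix in enumerate(rounds[:max_rounds], start=1):
        if expected_items is not None and set(matrix.items) != expected_items:
            raise ValueError(
                f"round {matrix.round_id} must contain exactly the prior "
                f"round's revise items {sorted(expected_items)}, "
                f"got {sorted(matrix.items)}")
        result = run_round(matrix, is_final_round=(number == max_rounds))
        results.append(result)
        expected_items = set(result.revise)
    final_tool = [item for r in results for item in r.accepted]
    assert len(final_tool) == len(set(final_tool)), "accepted sets must be disjoint"
    return DelphiOutcome(rounds=results, final_tool=final_tool,
                         dropped_after_final=list(results[-1].revise))


def read_ratings_csv(path: str | Path, round_id: Optional[str] = None) -> RatingMatrix:
    """Read a ratings CSV: rows = panellists (first column = panellist id),
    columns = item ids, cells 1-5 or blank for missing."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    return RatingMatrix(round_id=round_id or path.stem, ratings=frame)
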