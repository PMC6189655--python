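"""Disagreement scores: an external-consistency measure per rater.

If an optimization ran m recognition rounds, a rater first excluded in
round t receives score m - t + 1: the earlier a rater stood out from the
panel, the larger the score.  Raters never excluded score 0.  The score
complements intrarater (internal-consistency) agreement: a rater can be
perfectly self-consistent yet systematically disagree with the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .optimizer import OptimizationTrace


@dataclass(frozen=True)
class DisagreementScoreTable:
    """Per-rater integer disagreement scores for one feature."""

    feature_id: str
    m: int
    scores: dict[str, int]

    def to_dict(self) -> dict:
        return {"feature_id": self.feature_id, "m": self.m, "scores": dict(self.scores)}


def disagreement_scores(
    trace: OptimizationTrace, all_raters: Sequence[str]
) -> DisagreementScoreTable:
    """Score every rater in the original panel from an optimization trace.

    Raters identified in round t of m get m - t + 1; everyone else 0.  A
    rater listed in two rounds violates exclusion semantics and is a hard
    error, as is a round mentioning a rater outside ``all_raters``.
    """
    universe = list(all_raters)
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate rater ids in panel universe")
    m = trace.n_rounds
    scores = {rater: 0 for rater in universe}
    seen: set[str] = set()
    for rnd in trace.rounds:
        for rater in rnd.identified_raters:
            if rater in seen:
                raise ValueError(
                    f"rater {rater!r} identified in more than one round of "
                    f"{trace.feature_id}"
                )
            if rater not in scores:
                raise ValueError(
                    f"rater {rater!r} in trace {trace.feature_id} is not in the panel"
                )
            seen.add(rater)
            scores[rater] = m - rnd.round_index + 1
    return DisagreementScoreTable(feature_id=trace.feature_id, m=m, scores=scores)


def aggregate_scores(
    tables: Iterable[DisagreementScoreTable], method: str = "mean"
) -> dict[str, float]:
    """Aggregate per-feature scores into one value per rater (mean/sum/max)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no score tables to aggregate")
    universe = set(tables[0].scores)
    for t in tables[1:]:
        if set(t.scores) != universe:
            raise ValueError(
                f"score tables disagree on the rater universe (feature {t.feature_id})"
            )
    frame = pd.DataFrame({t.feature_id: t.scores for t in tables})
    if method == "mean":
        agg = frame.mean(axis=1)
    elif method == "sum":
        agg = frame.sum(axis=1)
    elif method == "max":
        agg = frame.max(axis=1)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return {str(r): float(v) for r, v in agg.items()}


def scores_frame(
    tables: Sequence[DisagreementScoreTable], aggregate: str = "mean"
) -> pd.DataFrame:
    """Raters x features score table with an aggregate column (CSV-ready)."""
    frame = pd.DataFrame({t.feature_id: t.scores for t in tables})
    frame.index.name = "rater"
    frame[f"aggregate_{aggregate}"] = pd.Series(aggregate_scores(tables, aggregate))
    return frame
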