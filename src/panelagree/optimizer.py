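"""Iterative optimization of interrater agreement by discordant-rater exclusion.

Each recognition round runs a leave-one-out pass over the current panel and
excludes, in one batch, every rater flagged discordant (Delta R < 0).  The
first round always runs; further rounds run only while the panel's AC1 is
still at or below the "substantial" threshold (0.6 on the Landis-Koch
benchmark), new discordant raters keep appearing, and the panel stays at or
above ``min_raters``.  Non-convergence is a valid outcome: some features
cannot be optimized past the threshold no matter how many raters go.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .agreement import InsufficientRatingsError, gwet_ac1
from .discordance import leave_one_out
from .ratings_io import RatingsMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecognitionRound:
    """One recognition-and-exclusion round."""

    round_index: int
    identified_raters: tuple[str, ...]
    n_remaining: int
    r_after: float

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "identified_raters": list(self.identified_raters),
            "n_remaining": self.n_remaining,
            "r_after": self.r_after,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecognitionRound":
        return cls(
            round_index=int(d["round_index"]),
            identified_raters=tuple(d["identified_raters"]),
            n_remaining=int(d["n_remaining"]),
            r_after=float(d["r_after"]),
        )


@dataclass(frozen=True)
class OptimizationTrace:
    """Full history of the optimization loop for one feature."""

    feature_id: str
    r_initial: float
    rounds: tuple[RecognitionRound, ...]
    r_final: float
    converged: bool
    threshold: float

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def excluded_raters(self) -> list[str]:
        """All raters excluded, in round order."""
        out: list[str] = []
        for r in self.rounds:
            out.extend(r.identified_raters)
        return out

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "r_initial": self.r_initial,
            "rounds": [r.to_dict() for r in self.rounds],
            "r_final": self.r_final,
            "converged": self.converged,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizationTrace":
        return cls(
            feature_id=str(d["feature_id"]),
            r_initial=float(d["r_initial"]),
            rounds=tuple(RecognitionRound.from_dict(r) for r in d["rounds"]),
            r_final=float(d["r_final"]),
            converged=bool(d["converged"]),
            threshold=float(d["threshold"]),
        )


def optimize_agreement(
    matrix: RatingsMatrix,
    threshold: float = 0.6,
    min_raters: int = 3,
    max_rounds: int = 50,
    ci_multiplier: float = 2.0,
) -> OptimizationTrace:
    """Run the recognition/exclusion loop on one feature's panel.

    ``converged`` is strict: the final AC1 must exceed ``threshold``.  If a
    round's full batch of discordant raters would shrink the panel below
    ``min_raters``, only the most negative-Delta-R raters are excluded so
    exactly ``min_raters`` remain (and the loop then stops).
    """
    if matrix.n_raters < min_raters:
        raise InsufficientRatingsError(
            f"{matrix.feature_id}: optimization needs >= {min_raters} raters"
        )
    current = matrix
    r_initial = gwet_ac1(current, compute_sd=False).coefficient
    rounds: list[RecognitionRound] = []
    r_current = r_initial
    while len(rounds) < max_rounds and current.n_raters >= max(min_raters, 3):
        records = leave_one_out(current, ci_multiplier=ci_multiplier)
        flagged = [rec for rec in records if rec.discordant]
        if not flagged:
            break
        capacity = current.n_raters - min_raters
        if len(flagged) > capacity:
            flagged = sorted(flagged, key=lambda rec: rec.delta_r)[:capacity]
        if not flagged:
            break
        excluded = tuple(rec.rater_id for rec in flagged)
        current = current.drop_raters(excluded)
        r_current = gwet_ac1(current, compute_sd=False).coefficient
        rounds.append(
            RecognitionRound(
                round_index=len(rounds) + 1,
                identified_raters=excluded,
                n_remaining=current.n_raters,
                r_after=r_current,
            )
        )
        logger.info(
            "%s round %d: excluded %s -> %d raters, AC1=%.4f",
            matrix.feature_id,
            len(rounds),
            ", ".join(excluded),
            current.n_raters,
            r_current,
        )
        if r_current > threshold:
            break
    r_final = rounds[-1].r_after if rounds else r_initial
    return OptimizationTrace(
        feature_id=matrix.feature_id,
        r_initial=r_initial,
        rounds=tuple(rounds),
        r_final=r_final,
        converged=bool(r_final > threshold),
        threshold=threshold,
    )


def optimize_all(
    features: list[RatingsMatrix], **kwargs
) -> tuple[dict[str, OptimizationTrace], dict[str, str]]:
    """Optimize every feature independently.

    Returns (traces by feature id, errors by feature id); a failing feature
    never aborts the batch.
    """
    traces: dict[str, OptimizationTrace] = {}
    errors: dict[str, str] = {}
    for matrix in features:
        try:
            traces[matrix.feature_id] = optimize_agreement(matrix, **kwargs)
        except (InsufficientRatingsError, ValueError) as exc:
            errors[matrix.feature_id] = str(exc)
            logger.warning("feature %s failed: %s", matrix.feature_id, exc)
    return traces, errors


def summarize_traces(traces: dict[str, OptimizationTrace]):
    """Per-feature summary: rounds run, raters left, AC1 before and after."""
    import pandas as pd

    rows = []
    for fid, t in traces.items():
        rows.append(
            {
                "feature": fid,
                "recognition_times": t.n_rounds,
                "n_excluded": len(t.excluded_raters()),
                "rest_of_raters": t.rounds[-1].n_remaining if t.rounds else None,
                "ac1_before": t.r_initial,
                "ac1_after": t.r_final,
                "converged": t.converged,
            }
        )
    return pd.DataFrame(rows)
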