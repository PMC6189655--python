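"""Reference worked example for the scoring rule.

An eight-round optimization of a 50-expert panel rating the "moderate
tongue texture" feature of a tongue-image collection: the recognition loop
excluded 34 discordant experts over eight rounds, raising interrater AC1
from 0.0948 to 0.6333 with 16 experts remaining.  The trace is used in the
documentation and tests to exercise the disagreement-scoring rule on a
realistic multi-round history.
"""

from __future__ import annotations

from .optimizer import OptimizationTrace, RecognitionRound

#: (identified experts, experts remaining, AC1 after the round), in round order
MODERATE_TEXTURE_ROUNDS: tuple[tuple[tuple[str, ...], int, float], ...] = (
    (("rater 45", "rater 49", "rater 32", "rater 42", "rater 34", "rater 40"), 44, 0.1674),
    (("rater 20", "rater 16", "rater 13", "rater 3"), 40, 0.2220),
    (("rater 5", "rater 43"), 38, 0.2470),
    (("rater 15", "rater 25"), 36, 0.2707),
    (("rater 29", "rater 39", "rater 33", "rater 47"), 32, 0.3247),
    (("rater 31", "rater 35", "rater 50", "rater 26", "rater 38"), 27, 0.4098),
    (("rater 41", "rater 17", "rater 1", "rater 10"), 23, 0.4890),
    (("rater 46", "rater 19", "rater 44", "rater 37", "rater 30", "rater 18", "rater 11"),
     16, 0.6333),
)

MODERATE_TEXTURE_R_INITIAL = 0.0948
MODERATE_TEXTURE_THRESHOLD = 0.6


def moderate_texture_panel() -> list[str]:
    """The 50-expert universe of the worked example."""
    return [f"rater {i + 1}" for i in range(50)]


def moderate_texture_trace() -> OptimizationTrace:
    """The eight-round optimization trace of the worked example."""
    rounds = tuple(
        RecognitionRound(
            round_index=t + 1,
            identified_raters=identified,
            n_remaining=n_rest,
            r_after=r_after,
        )
        for t, (identified, n_rest, r_after) in enumerate(MODERATE_TEXTURE_ROUNDS)
    )
    return OptimizationTrace(
        feature_id="moderate_texture",
        r_initial=MODERATE_TEXTURE_R_INITIAL,
        rounds=rounds,
        r_final=rounds[-1].r_after,
        converged=rounds[-1].r_after > MODERATE_TEXTURE_THRESHOLD,
        threshold=MODERATE_TEXTURE_THRESHOLD,
    )
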