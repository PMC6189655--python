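"""Synthetic rating panels with known ground truth.

The generator emulates a large expert-labelling study: a panel of raters
classifies a set of items into binary present/absent features, and a
smaller set of items is presented twice to every rater so that test-retest
(intrarater) agreement can be measured.  The generative model is latent
truth plus independent rater error:

* each feature has a latent binary truth per item, drawn at the feature's
  prevalence;
* a rater reports the truth with probability ``accuracy`` and otherwise
  errs -- symmetrically (the complement) or toward category "1" with a
  ``bias`` probability;
* the second presentation of a repeated item flips the rater's first
  answer independently with the rater's ``flip_prob`` (intrarater
  inconsistency).

Planted discordant raters are just profiles with low accuracy; their ids
are recorded in the ground truth so detection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ratings_io import RatingsMatrix, ReplicateTable

CATEGORIES = ("0", "1")


@dataclass(frozen=True)
class RaterProfile:
    """A block of raters sharing an error model."""

    count: int
    accuracy: float
    bias: float | None = None
    flip_prob: float = 0.05

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("profile count must be >= 0")
        for name in ("accuracy", "flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bias is not None and not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias must be in [0, 1], got {self.bias}")


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters for one synthetic panel.

    Defaults mirror a 50-expert study of 230 once-rated items plus 35
    twice-presented items across 25 binary features, with competent raters
    at accuracy 0.9 and ten planted discordant raters at accuracy 0.55.
    """

    n_raters: int = 50
    n_items: int = 230
    n_repeat_items: int = 35
    n_features: int = 25
    prevalence: float | Sequence[float] = 0.5
    good_accuracy: float = 0.9
    good_flip_prob: float = 0.05
    discordant_profiles: tuple[RaterProfile, ...] = (RaterProfile(10, 0.55),)
    seed: int = 0

    def __post_init__(self):
        if self.n_raters < 2 or self.n_items < 1 or self.n_features < 1:
            raise ValueError("need >= 2 raters, >= 1 item, >= 1 feature")
        if self.n_repeat_items < 0:
            raise ValueError("n_repeat_items must be >= 0")
        planted = sum(p.count for p in self.discordant_profiles)
        if planted > self.n_raters:
            raise ValueError(
                f"discordant profiles cover {planted} raters but the panel has "
                f"{self.n_raters}"
            )
        if not 0.0 <= self.good_accuracy <= 1.0 or not 0.0 <= self.good_flip_prob <= 1.0:
            raise ValueError("good rater probabilities must be in [0, 1]")
        for p in self.prevalences():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence must be in (0, 1), got {p}")

    def prevalences(self) -> tuple[float, ...]:
        if np.isscalar(self.prevalence):
            return (float(self.prevalence),) * self.n_features
        values = tuple(float(p) for p in self.prevalence)
        if len(values) != self.n_features:
            raise ValueError(
                f"prevalence list has {len(values)} entries for {self.n_features} features"
            )
        return values


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a generated panel."""

    truths: dict[str, np.ndarray]
    repeat_truths: dict[str, np.ndarray]
    discordant_ids: frozenset[str]
    accuracy: dict[str, float]
    flip_prob: dict[str, float]


def _rate(
    rng: np.random.Generator,
    truth: np.ndarray,
    accuracy: float,
    bias: float | None,
) -> np.ndarray:
    """One rater's binary ratings of items with the given latent truth."""
    correct = rng.random(truth.size) < accuracy
    if bias is None:
        reported = np.where(correct, truth, ~truth)
    else:
        erred = rng.random(truth.size) < bias
        reported = np.where(correct, truth, erred)
    return reported


def generate_panel(
    config: PanelConfig,
) -> tuple[list[RatingsMatrix], list[ReplicateTable], GroundTruth]:
    """Generate matrices, replicate tables and ground truth for one panel.

    Fully deterministic given ``config.seed``; per-feature random streams
    are spawned from the single root seed.
    """
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    rater_ids = [f"rater {i + 1}" for i in range(config.n_raters)]

    # deterministic random placement of the planted profiles in the panel
    order = assign_rng.permutation(config.n_raters)
    accuracy = {r: config.good_accuracy for r in rater_ids}
    flip = {r: config.good_flip_prob for r in rater_ids}
    bias_of = {r: None for r in rater_ids}
    discordant: set[str] = set()
    cursor = 0
    for profile in config.discordant_profiles:
        for k in range(profile.count):
            rid = rater_ids[order[cursor]]
            accuracy[rid] = profile.accuracy
            flip[rid] = profile.flip_prob
            bias_of[rid] = profile.bias
            discordant.add(rid)
            cursor += 1

    item_ids = [f"img{(i + 1):03d}" for i in range(config.n_items)]
    repeat_ids = [f"rep{(i + 1):02d}" for i in range(config.n_repeat_items)]
    feature_ids = [f"feature{(f + 1):02d}" for f in range(config.n_features)]
    feature_seeds = root.spawn(config.n_features)

    matrices: list[RatingsMatrix] = []
    replicates: list[ReplicateTable] = []
    truths: dict[str, np.ndarray] = {}
    repeat_truths: dict[str, np.ndarray] = {}
    for fid, prev, seed in zip(feature_ids, config.prevalences(), feature_seeds):
        rng = np.random.default_rng(seed)
        truth = rng.random(config.n_items) < prev
        truth_rep = rng.random(config.n_repeat_items) < prev
        truths[fid] = truth
        repeat_truths[fid] = truth_rep
        grid = {}
        for rid in rater_ids:
            ratings = _rate(rng, truth, accuracy[rid], bias_of[rid])
            grid[rid] = np.where(ratings, "1", "0")
            if config.n_repeat_items:
                occ1 = _rate(rng, truth_rep, accuracy[rid], bias_of[rid])
                flipped = rng.random(config.n_repeat_items) < flip[rid]
                occ2 = np.where(flipped, ~occ1, occ1)
                replicates.append(
                    ReplicateTable(
                        feature_id=fid,
                        rater_id=rid,
                        item_ids=tuple(repeat_ids),
                        occasion1=tuple(np.where(occ1, "1", "0")),
                        occasion2=tuple(np.where(occ2, "1", "0")),
                    )
                )
        frame = pd.DataFrame(grid, index=pd.Index(item_ids, name="item"), dtype=object)
        matrices.append(RatingsMatrix(fid, frame, CATEGORIES))

    truth = GroundTruth(
        truths=truths,
        repeat_truths=repeat_truths,
        discordant_ids=frozenset(discordant),
        accuracy=accuracy,
        flip_prob=flip,
    )
    return matrices, replicates, truth


def recovery_metrics(
    detected: set[str] | Sequence[str], truth: GroundTruth
) -> tuple[float | None, float]:
    """Sensitivity and specificity of discordant-rater detection.

    Sensitivity is None when no discordant raters were planted.
    """
    detected = set(detected)
    universe = set(truth.accuracy)
    unknown = detected - universe
    if unknown:
        raise ValueError(f"detected raters outside the panel: {sorted(unknown)}")
    planted = set(truth.discordant_ids)
    clean = universe - planted
    sensitivity = len(detected & planted) / len(planted) if planted else None
    specificity = len(clean - detected) / len(clean) if clean else 1.0
    return sensitivity, specificity
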