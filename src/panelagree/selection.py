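"""Expert-selection policies and comparison of the resulting panels.

Three inclusion policies build a curated panel per feature:

* **A** -- internal consistency: keep raters whose intrarater (test-retest)
  AC1 strictly exceeds a threshold (default 0.6, "substantial");
* **B** -- external consistency: keep raters whose disagreement score for
  the feature is exactly 0 (never excluded by the optimizer);
* **C** -- both: the intersection of A and B.

Each policy's panels are re-scored with interrater AC1 per feature and
summarized as median and interquartile range across features.  Policy
distributions are compared with a normality-gated omnibus test: one-way
ANOVA with pairwise Welch tests (Sidak-adjusted, in the spirit of
Dunnett's T3) when every group looks normal, otherwise Kruskal-Wallis with
Dunn pairwise tests under Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .agreement import (
    AgreementEstimate,
    InsufficientRatingsError,
    gwet_ac1,
    intrarater_map,
)
from .optimizer import OptimizationTrace, optimize_all
from .ratings_io import RatingsMatrix, ReplicateTable
from .scoring import DisagreementScoreTable, disagreement_scores

logger = logging.getLogger(__name__)

METHODS = ("A", "B", "C")


@dataclass(frozen=True)
class SelectionOutcome:
    """Per-feature curated panels and their agreement, for one policy."""

    method: str
    per_feature: dict[str, tuple[tuple[str, ...], AgreementEstimate]]
    summary_median: float
    summary_iqr: tuple[float, float]
    dropped_features: tuple[str, ...] = ()

    def coefficients(self) -> list[float]:
        return [est.coefficient for _, est in self.per_feature.values()]


def _intra_value(entry) -> float:
    if isinstance(entry, AgreementEstimate):
        return entry.coefficient
    return float(entry)


def select_experts(
    intra: Mapping[tuple[str, str], AgreementEstimate | float],
    scores: Sequence[DisagreementScoreTable],
    method: str,
    intra_threshold: float = 0.6,
) -> dict[str, list[str]]:
    """Apply one inclusion policy per feature.

    ``intra`` maps (rater_id, feature_id) to an intrarater estimate; a rater
    with no intrarater estimate cannot pass policy A (or C).  ``scores``
    supplies the per-feature disagreement scores and defines both the rater
    universe and the feature list.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    selected: dict[str, list[str]] = {}
    for table in scores:
        fid = table.feature_id
        keep: list[str] = []
        for rater in table.scores:
            passes_a = True
            if method in ("A", "C"):
                entry = intra.get((rater, fid))
                passes_a = entry is not None and _intra_value(entry) > intra_threshold
            passes_b = True
            if method in ("B", "C"):
                passes_b = table.scores[rater] == 0
            if passes_a and passes_b:
                keep.append(rater)
        if not keep:
            logger.warning("feature %s: policy %s selects no raters", fid, method)
        selected[fid] = keep
    return selected


def evaluate_selection(
    features: Sequence[RatingsMatrix],
    subsets: Mapping[str, Sequence[str]],
    method: str = "custom",
) -> SelectionOutcome:
    """Interrater AC1 of each feature's selected sub-panel, with summary.

    Features whose subset has fewer than two raters are unestimable and
    dropped from the summary (logged).  All features unestimable is a hard
    error.
    """
    per_feature: dict[str, tuple[tuple[str, ...], AgreementEstimate]] = {}
    dropped: list[str] = []
    for matrix in features:
        subset = list(subsets.get(matrix.feature_id, ()))
        if len(subset) < 2:
            dropped.append(matrix.feature_id)
            logger.warning(
                "feature %s: %d selected raters, agreement unestimable",
                matrix.feature_id,
                len(subset),
            )
            continue
        est = gwet_ac1(matrix.select_raters(subset), compute_sd=False)
        per_feature[matrix.feature_id] = (tuple(subset), est)
    if not per_feature:
        raise InsufficientRatingsError(
            f"policy {method}: no feature retained >= 2 raters"
        )
    values = [est.coefficient for _, est in per_feature.values()]
    q25, median, q75 = np.percentile(values, [25, 50, 75])
    return SelectionOutcome(
        method=method,
        per_feature=per_feature,
        summary_median=float(median),
        summary_iqr=(float(q25), float(q75)),
        dropped_features=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based pairwise z tests with tie correction and Bonferroni."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in labels:
        size = groups[g].size
        mean_ranks[g] = float(ranks[start : start + size].mean())
        sizes[g] = size
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(labels, 2))
    results = []
    for a, b in pairs:
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
            1.0 / sizes[a] + 1.0 / sizes[b]
        )
        if var <= 0:
            results.append(
                {"groups": (a, b), "stat": float("nan"), "p_adj": float("nan"),
                 "significant": False}
            )
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        results.append({"groups": (a, b), "stat": float(z), "p_adj": min(1.0, p * len(pairs))})
    return results


def _welch_pairwise(groups: dict[str, np.ndarray]) -> list[dict]:
    """Unequal-variance pairwise t tests, Sidak-adjusted across all pairs."""
    labels = list(groups)
    pairs = list(itertools.combinations(labels, 2))
    results = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        p_adj = 1.0 - (1.0 - p) ** len(pairs)
        results.append({"groups": (a, b), "stat": float(t), "p_adj": float(min(1.0, p_adj))})
    return results


def compare_groups(
    groups: Mapping[str, Sequence[float]], normality_alpha: float = 0.05, alpha: float = 0.05
) -> dict:
    """Normality-gated omnibus + pairwise comparison of value groups.

    Returns a report dict with the path taken ("anova_welch_sidak" or
    "kruskal_dunn_bonferroni"), per-group normality p-values, the omnibus
    statistic and p-value, and per-pair adjusted p-values with significance
    flags at ``alpha``.  Zero variance everywhere is flagged undefined.
    """
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays.values()) and np.ptp(
        np.concatenate(list(arrays.values()))
    ) == 0:
        return {
            "path": "undefined",
            "normality_p": {},
            "omnibus": {"stat": float("nan"), "p": float("nan")},
            "pairwise": [],
            "alpha": alpha,
            "note": "all groups constant and identical; comparison undefined",
        }
    normality_p: dict[str, float] = {}
    all_normal = True
    for name, values in arrays.items():
        if np.ptp(values) == 0 or values.size < 3:
            normality_p[name] = 0.0
            all_normal = False
            continue
        p = float(stats.shapiro(values).pvalue)
        normality_p[name] = p
        if p <= normality_alpha:
            all_normal = False
    if all_normal:
        stat, p = stats.f_oneway(*arrays.values())
        pairwise = _welch_pairwise(arrays)
        path = "anova_welch_sidak"
    else:
        stat, p = stats.kruskal(*arrays.values())
        pairwise = _dunn_pairwise(arrays)
        path = "kruskal_dunn_bonferroni"
    for row in pairwise:
        row["significant"] = bool(row["p_adj"] < alpha) if np.isfinite(row["p_adj"]) else False
    return {
        "path": path,
        "normality_p": normality_p,
        "omnibus": {"stat": float(stat), "p": float(p)},
        "pairwise": pairwise,
        "alpha": alpha,
    }


def compare_methods(
    outcomes: Sequence[SelectionOutcome], normality_alpha: float = 0.05
) -> dict:
    """Compare the per-feature AC1 distributions of several policies."""
    if len(outcomes) < 2:
        raise ValueError("need >= 2 outcomes to compare")
    groups = {o.method: o.coefficients() for o in outcomes}
    return compare_groups(groups, normality_alpha=normality_alpha)


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStudy:
    """Everything produced by one full curation run."""

    traces: dict[str, OptimizationTrace]
    score_tables: tuple[DisagreementScoreTable, ...]
    intra: dict[tuple[str, str], AgreementEstimate]
    outcomes: dict[str, SelectionOutcome]
    comparison: dict


def run_selection_study(
    features: Sequence[RatingsMatrix],
    replicates: Sequence[ReplicateTable],
    threshold: float = 0.6,
    intra_threshold: float = 0.6,
    ci_multiplier: float = 2.0,
    min_raters: int = 3,
    max_rounds: int = 50,
    methods: Sequence[str] = METHODS,
) -> SelectionStudy:
    """Run optimization, scoring, selection and comparison over all features.

    ``features`` should already be restricted to nontesting items (see
    :func:`panelagree.ratings_io.nontesting_view`).
    """
    traces, errors = optimize_all(
        list(features),
        threshold=threshold,
        min_raters=min_raters,
        max_rounds=max_rounds,
        ci_multiplier=ci_multiplier,
    )
    usable = [m for m in features if m.feature_id in traces]
    score_tables = tuple(
        disagreement_scores(traces[m.feature_id], m.rater_ids) for m in usable
    )
    intra = intrarater_map(
        replicates, {m.feature_id: m.categories for m in usable}
    )
    outcomes: dict[str, SelectionOutcome] = {
        "original": evaluate_selection(
            usable, {m.feature_id: m.rater_ids for m in usable}, method="original"
        )
    }
    for method in methods:
        subsets = select_experts(intra, score_tables, method, intra_threshold)
        outcomes[method] = evaluate_selection(usable, subsets, method=method)
    comparison = compare_methods(list(outcomes.values()))
    if errors:
        comparison = dict(comparison, feature_errors=errors)
    return SelectionStudy(
        traces=traces,
        score_tables=score_tables,
        intra=intra,
        outcomes=outcomes,
        comparison=comparison,
    )
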