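"""Chance-corrected agreement coefficients for nominal multi-rater panels.

The workhorse is Gwet's first-order agreement coefficient AC1, which
corrects observed agreement for chance using the category marginal
probabilities pi_q and is robust to the prevalence-driven "kappa paradox"
(near-unanimous panels that kappa scores near zero).  With r_iq the number
of raters placing item i in category q and r_i = sum_q r_iq:

    P_a  = mean over items with r_i >= 2 of sum_q r_iq (r_iq - 1) / (r_i (r_i - 1))
    pi_q = mean over items with r_i >= 1 of r_iq / r_i
    P_e  = (1 / (Q - 1)) * sum_q pi_q (1 - pi_q)
    AC1  = (P_a - P_e) / (1 - P_e)

Missing ratings are tolerated: items with fewer than two ratings cannot
contribute observed agreement and are excluded from P_a (and from
``n_items_used``), while any rated item informs the chance term.

The standard error attached to AC1 is a delete-one-item jackknife over the
usable items, an assumption-free dispersion estimate for the panel
reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ratings_io import RatingsMatrix, ReplicateTable


class InsufficientRatingsError(ValueError):
    """Too few raters, items or non-missing cells for the requested estimate."""


class DegenerateChanceError(ValueError):
    """Chance agreement P_e reached 1, leaving the coefficient undefined."""


@dataclass(frozen=True)
class AgreementEstimate:
    """An agreement coefficient with its components and provenance.

    ``coefficient`` = (pa - pe) / (1 - pe) for chance-corrected methods and
    plain pa for percent agreement (pe = 0).
    """

    coefficient: float
    sd: float | None
    n_items_used: int
    n_raters: int
    pa: float
    pe: float
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# encoding and count-space internals (shared with the discordance module)
# ---------------------------------------------------------------------------


def encode(matrix: RatingsMatrix) -> np.ndarray:
    """Integer-code a ratings matrix: items x raters, -1 for missing."""
    values = matrix.ratings.to_numpy(dtype=object)
    codes = np.full(values.shape, -1, dtype=np.int64)
    for q, cat in enumerate(matrix.categories):
        codes[values == cat] = q
    return codes


def counts_from_codes(codes: np.ndarray, n_categories: int) -> np.ndarray:
    """Per-item category counts r_iq from an integer-coded grid."""
    return (codes[:, :, None] == np.arange(n_categories)[None, None, :]).sum(axis=1)


def _components(counts: np.ndarray) -> tuple[float, float, float, int]:
    """(coefficient, pa, pe, n_items_used) from an items x Q count table."""
    counts = np.asarray(counts, dtype=float)
    n_cat = counts.shape[1]
    r_i = counts.sum(axis=1)
    usable = r_i >= 2
    n_used = int(usable.sum())
    if n_used == 0:
        raise InsufficientRatingsError(
            "no item carries >= 2 non-missing ratings; observed agreement undefined"
        )
    c = counts[usable]
    r = r_i[usable]
    pa = float(((c * (c - 1)).sum(axis=1) / (r * (r - 1))).mean())
    present = r_i >= 1
    pi = (counts[present] / r_i[present, None]).mean(axis=0)
    pe = float((pi * (1.0 - pi)).sum() / (n_cat - 1)) if n_cat >= 2 else 0.0
    if 1.0 - pe <= 0.0:
        raise DegenerateChanceError(
            f"chance agreement pe={pe} leaves AC1 undefined (degenerate category marginals)"
        )
    coefficient = (pa - pe) / (1.0 - pe)
    return coefficient, pa, pe, n_used


def _jackknife_values(counts: np.ndarray) -> np.ndarray:
    """AC1 recomputed with each usable item deleted in turn (vectorized).

    Deleting an item removes it from both the observed-agreement mean and
    the category marginals.
    """
    counts = np.asarray(counts, dtype=float)
    n_cat = counts.shape[1]
    r_i = counts.sum(axis=1)
    usable = r_i >= 2
    present = r_i >= 1
    n_used = int(usable.sum())
    if n_used < 2:
        raise InsufficientRatingsError("jackknife needs >= 2 usable items")
    c = counts[usable]
    r = r_i[usable]
    a = (c * (c - 1)).sum(axis=1) / (r * (r - 1))
    sum_a = a.sum()
    p_all = counts[present] / r_i[present, None]
    sum_p = p_all.sum(axis=0)
    n_present = int(present.sum())
    # usable items are a subset of present items, so each deletion shrinks
    # both means by one term
    p_u = c / r[:, None]
    pa_del = (sum_a - a) / (n_used - 1)
    pi_del = (sum_p[None, :] - p_u) / (n_present - 1)
    if n_cat >= 2:
        pe_del = (pi_del * (1.0 - pi_del)).sum(axis=1) / (n_cat - 1)
    else:
        pe_del = np.zeros(n_used)
    if np.any(1.0 - pe_del <= 0.0):
        raise DegenerateChanceError("jackknife replicate with pe = 1")
    return (pa_del - pe_del) / (1.0 - pe_del)


def _jackknife_sd(counts: np.ndarray) -> float:
    values = _jackknife_values(counts)
    n = values.size
    return float(np.sqrt((n - 1) / n * ((values - values.mean()) ** 2).sum()))


def _require_panel(matrix: RatingsMatrix) -> None:
    if matrix.n_raters < 2:
        raise InsufficientRatingsError(
            f"{matrix.feature_id}: interrater agreement needs >= 2 raters"
        )
    if matrix.n_items < 1:
        raise InsufficientRatingsError(f"{matrix.feature_id}: no items")


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------


def gwet_ac1(matrix: RatingsMatrix, compute_sd: bool = True) -> AgreementEstimate:
    """Multi-rater Gwet AC1 for one feature's panel.

    Returns the coefficient with its jackknife SD (``compute_sd=False``
    skips the SD for tight loops).
    """
    _require_panel(matrix)
    counts = counts_from_codes(encode(matrix), len(matrix.categories))
    coefficient, pa, pe, n_used = _components(counts)
    sd = _jackknife_sd(counts) if (compute_sd and n_used >= 2) else None
    return AgreementEstimate(
        coefficient=coefficient,
        sd=sd,
        n_items_used=n_used,
        n_raters=matrix.n_raters,
        pa=pa,
        pe=pe,
        method="AC1",
    )


def percent_agreement(matrix: RatingsMatrix) -> AgreementEstimate:
    """Raw pairwise percent agreement (no chance correction, pe = 0)."""
    _require_panel(matrix)
    counts = counts_from_codes(encode(matrix), len(matrix.categories))
    _, pa, _, n_used = _components(counts)
    return AgreementEstimate(
        coefficient=pa,
        sd=None,
        n_items_used=n_used,
        n_raters=matrix.n_raters,
        pa=pa,
        pe=0.0,
        method="percent",
    )


def ac1_sd(matrix: RatingsMatrix) -> float:
    """Delete-one-item jackknife standard error of the panel's AC1."""
    _require_panel(matrix)
    counts = counts_from_codes(encode(matrix), len(matrix.categories))
    return _jackknife_sd(counts)


def ac1_jackknife(matrix: RatingsMatrix) -> np.ndarray:
    """The leave-one-item-out AC1 replicates behind :func:`ac1_sd`."""
    _require_panel(matrix)
    counts = counts_from_codes(encode(matrix), len(matrix.categories))
    return _jackknife_values(counts)


def intrarater_ac1(
    replicates: ReplicateTable, categories: Sequence[str] | None = None
) -> AgreementEstimate:
    """Test-retest AC1 of one rater across the two presentations.

    The two occasions are treated as a two-rater panel over the repeated
    items.  Pass the feature's full category set so that the chance term
    sees all categories even when this rater used only one.
    """
    if len(replicates) < 2:
        raise InsufficientRatingsError(
            f"{replicates.feature_id}/{replicates.rater_id}: intrarater agreement "
            "needs >= 2 repeated items"
        )
    if categories is None:
        categories = tuple(sorted(set(replicates.occasion1) | set(replicates.occasion2)))
    frame = pd.DataFrame(
        {"occasion1": replicates.occasion1, "occasion2": replicates.occasion2},
        index=pd.Index(replicates.item_ids, name="item"),
        dtype=object,
    )
    matrix = RatingsMatrix.from_frame(
        f"{replicates.feature_id}", frame, categories
    )
    est = gwet_ac1(matrix)
    return AgreementEstimate(
        coefficient=est.coefficient,
        sd=est.sd,
        n_items_used=est.n_items_used,
        n_raters=2,
        pa=est.pa,
        pe=est.pe,
        method="AC1",
    )


def intrarater_map(
    replicates: Sequence[ReplicateTable],
    categories_by_feature: Mapping[str, Sequence[str]] | None = None,
) -> dict[tuple[str, str], AgreementEstimate]:
    """Intrarater AC1 for every (rater, feature) replicate table."""
    out: dict[tuple[str, str], AgreementEstimate] = {}
    for table in replicates:
        cats = None
        if categories_by_feature is not None:
            cats = categories_by_feature.get(table.feature_id)
        out[(table.rater_id, table.feature_id)] = intrarater_ac1(table, cats)
    return out
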