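"""Leave-one-out detection of discordant raters.

A rater is discordant when the panel's actual reliability R_n falls below
the reliability one would predict for n raters from the remaining n-1
raters alone.  For each rater in turn:

1. compute R_loo, the AC1 of the other n-1 raters, and its jackknife SD;
2. extrapolate to n parallel raters with the Spearman-Brown prophecy
   formula, R_pred = k R_loo / (1 + (k - 1) R_loo) with k = n / (n - 1);
3. form Delta R = R_n - (R_pred - c * SD), with c = 2 by analogy with
   two-sigma outlier screens.

Delta R < 0 means the panel with the rater is less reliable than the lower
confidence bound predicted without them: excluding that rater is expected
to raise group reliability.  The symmetric case R_n > R_pred + c * SD
(the rater improves reliability) is only recorded as ``beneficial``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .agreement import (
    InsufficientRatingsError,
    _components,
    _jackknife_sd,
    counts_from_codes,
    encode,
)
from .ratings_io import RatingsMatrix


@dataclass(frozen=True)
class LeaveOneOutRecord:
    """Per-rater outcome of one leave-one-out pass."""

    rater_id: str
    r_loo: float
    sd_loo: float
    r_predicted: float
    delta_r: float
    discordant: bool
    beneficial: bool

    def to_dict(self) -> dict:
        return asdict(self)


def spearman_brown_predict(r: float, k_factor: float) -> float:
    """Predicted reliability of k-times-lengthened measurement.

    ``r`` is the reliability of the current panel; ``k_factor`` the length
    ratio (n/(n-1) for the leave-one-out extrapolation).  Fixed points:
    r = 0 -> 0 and r = 1 -> 1 for any k.
    """
    if k_factor <= 0:
        raise ValueError(f"k_factor must be positive, got {k_factor}")
    denom = 1.0 + (k_factor - 1.0) * r
    if denom == 0.0:
        raise ZeroDivisionError(
            f"Spearman-Brown denominator is zero for r={r}, k={k_factor}"
        )
    return k_factor * r / denom


def leave_one_out(
    matrix: RatingsMatrix, ci_multiplier: float = 2.0
) -> list[LeaveOneOutRecord]:
    """One leave-one-out pass over the panel, one record per rater.

    Needs at least three raters (the reduced panel must still support an
    interrater estimate).  Record order matches the matrix's rater order.
    """
    n = matrix.n_raters
    if n < 3:
        raise InsufficientRatingsError(
            f"{matrix.feature_id}: leave-one-out needs >= 3 raters, got {n}"
        )
    n_cat = len(matrix.categories)
    codes = encode(matrix)
    onehot = codes[:, :, None] == np.arange(n_cat)[None, None, :]
    totals = onehot.sum(axis=1)
    r_n, _, _, _ = _components(totals)
    k = n / (n - 1)
    records = []
    for j, rater_id in enumerate(matrix.rater_ids):
        counts_j = totals - onehot[:, j, :]
        r_loo, _, _, _ = _components(counts_j)
        sd_loo = _jackknife_sd(counts_j)
        r_pred = spearman_brown_predict(r_loo, k)
        delta_r = r_n - (r_pred - ci_multiplier * sd_loo)
        records.append(
            LeaveOneOutRecord(
                rater_id=rater_id,
                r_loo=float(r_loo),
                sd_loo=float(sd_loo),
                r_predicted=float(r_pred),
                delta_r=float(delta_r),
                discordant=bool(delta_r < 0.0),
                beneficial=bool(r_n > r_pred + ci_multiplier * sd_loo),
            )
        )
    return records
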