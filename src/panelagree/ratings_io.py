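"""Rating-panel data structures and CSV/JSON input-output.

A rating study is stored as one nominal ratings matrix per visual feature
(items in rows, raters in columns, missing cells allowed) plus, when a
subset of items was presented twice to every rater, a replicate table of
paired first/second-occasion ratings used for intrarater (test-retest)
agreement.  Two CSV dialects are supported:

* ``wide``  -- one file per feature; first column item id, remaining
  columns one per rater; empty cells are missing ratings.
* ``long``  -- a single file with columns ``feature,item,rater,occasion,
  rating`` where ``occasion`` is 1 or 2.  Occasion-2 rows (the repeated
  presentations) are routed to replicate tables, never into the
  interrater matrix.

Optimization traces and comparison reports are serialized as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("feature", "item", "rater", "occasion", "rating")


class RatingsFormatError(ValueError):
    """Malformed or inconsistent rating data on disk."""


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value == ""
    )


@dataclass(frozen=True)
class RatingsMatrix:
    """Nominal ratings of a set of items by a panel of raters for one feature.

    ``ratings`` is an items x raters :class:`pandas.DataFrame` of category
    codes (strings); missing ratings are NaN.  ``categories`` is the ordered
    set of legal category codes; in a binary presence/absence study it is
    ``("0", "1")`` or ``("not existed", "existed")`` -- codes are opaque.
    """

    feature_id: str
    ratings: pd.DataFrame
    categories: tuple[str, ...]

    def __post_init__(self):
        idx = self.ratings.index
        cols = self.ratings.columns
        if idx.has_duplicates:
            raise RatingsFormatError(f"{self.feature_id}: duplicate item ids")
        if cols.has_duplicates:
            raise RatingsFormatError(f"{self.feature_id}: duplicate rater ids")
        if len(set(self.categories)) != len(self.categories):
            raise RatingsFormatError(f"{self.feature_id}: duplicate categories")
        observed = {
            v for v in self.ratings.to_numpy(dtype=object).ravel() if not _is_missing(v)
        }
        unknown = observed - set(self.categories)
        if unknown:
            raise RatingsFormatError(
                f"{self.feature_id}: ratings outside category set: {sorted(unknown)}"
            )

    @classmethod
    def from_frame(
        cls,
        feature_id: str,
        frame: pd.DataFrame,
        categories: Sequence[str] | None = None,
    ) -> "RatingsMatrix":
        """Build from an items x raters frame, inferring categories if absent."""
        frame = frame.astype(object)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if categories is None:
            observed = sorted(
                {v for v in frame.to_numpy(dtype=object).ravel() if not _is_missing(v)}
            )
            categories = tuple(observed)
        return cls(str(feature_id), frame, tuple(str(c) for c in categories))

    # -- convenience views -------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return list(self.ratings.index)

    @property
    def rater_ids(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def n_missing(self) -> int:
        return int(self.ratings.isna().to_numpy().sum())

    def drop_raters(self, rater_ids: Iterable[str]) -> "RatingsMatrix":
        drop = list(rater_ids)
        return RatingsMatrix(
            self.feature_id, self.ratings.drop(columns=drop), self.categories
        )

    def select_raters(self, rater_ids: Iterable[str]) -> "RatingsMatrix":
        keep = list(rater_ids)
        return RatingsMatrix(self.feature_id, self.ratings.loc[:, keep], self.categories)

    def drop_items(self, item_ids: Iterable[str]) -> "RatingsMatrix":
        drop = [i for i in item_ids if i in self.ratings.index]
        return RatingsMatrix(
            self.feature_id, self.ratings.drop(index=drop), self.categories
        )


@dataclass(frozen=True)
class ReplicateTable:
    """Paired two-occasion ratings of the repeated items by one rater."""

    feature_id: str
    rater_id: str
    item_ids: tuple[str, ...]
    occasion1: tuple[str, ...]
    occasion2: tuple[str, ...]

    def __post_init__(self):
        if not (len(self.item_ids) == len(self.occasion1) == len(self.occasion2)):
            raise RatingsFormatError(
                f"{self.feature_id}/{self.rater_id}: occasion vectors and item ids "
                "must have equal length"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise RatingsFormatError(
                f"{self.feature_id}/{self.rater_id}: duplicate repeated item ids"
            )

    def __len__(self) -> int:
        return len(self.item_ids)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_long_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(LONG_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise RatingsFormatError(
            f"{path}: long layout needs columns {LONG_COLUMNS}, missing {sorted(missing_cols)}"
        )
    frame = frame.loc[:, list(LONG_COLUMNS)].copy()
    if not frame["occasion"].isin({"1", "2"}).all():
        raise RatingsFormatError(f"{path}: occasion must be 1 or 2")
    dup = frame.duplicated(subset=["feature", "item", "rater", "occasion"])
    if dup.any():
        rows = frame.loc[dup].head(3).to_dict("records")
        raise RatingsFormatError(
            f"{path}: duplicate (feature, item, rater, occasion) rows, e.g. {rows}"
        )
    frame["rating"] = frame["rating"].replace("", np.nan)
    return frame


def read_ratings_csv(
    path,
    layout: str = "wide",
    categories: Sequence[str] | None = None,
    feature_id: str | None = None,
) -> list[RatingsMatrix]:
    """Read one or more ratings matrices from a CSV file.

    Wide layout yields a single matrix whose feature id defaults to the file
    stem; long layout yields one matrix per feature from the occasion-1 rows
    (occasion-2 rows belong to :func:`read_replicates_csv`).  When an explicit
    ``categories`` set is given, any rating outside it is a hard error.
    """
    path = Path(path)
    if layout == "wide":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
        frame = frame.replace("", np.nan)
        fid = feature_id if feature_id is not None else path.stem
        return [RatingsMatrix.from_frame(fid, frame, categories)]
    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    frame = _read_long_frame(path)
    occ1 = frame[frame["occasion"] == "1"]
    matrices = []
    for fid, sub in occ1.groupby("feature", sort=True):
        grid = sub.pivot(index="item", columns="rater", values="rating")
        matrices.append(RatingsMatrix.from_frame(fid, grid, categories))
    return matrices


def read_replicates_csv(path, categories: Sequence[str] | None = None) -> list[ReplicateTable]:
    """Extract per-(feature, rater) replicate tables from a long-layout CSV.

    Repeated items must carry both occasions for a rater; items with a single
    occasion are dropped with a logged warning count.
    """
    frame = _read_long_frame(path)
    rep_items = frame.loc[frame["occasion"] == "2", ["feature", "item"]].drop_duplicates()
    if rep_items.empty:
        return []
    keyed = frame.merge(rep_items, on=["feature", "item"])
    tables: list[ReplicateTable] = []
    n_dropped = 0
    for (fid, rid), sub in keyed.groupby(["feature", "rater"], sort=True):
        wide = sub.pivot(index="item", columns="occasion", values="rating")
        for occ in ("1", "2"):
            if occ not in wide.columns:
                wide[occ] = np.nan
        complete = wide.dropna(subset=["1", "2"]).sort_index()
        n_dropped += len(wide) - len(complete)
        if complete.empty:
            continue
        if categories is not None:
            observed = set(complete["1"]) | set(complete["2"])
            unknown = observed - set(categories)
            if unknown:
                raise RatingsFormatError(
                    f"{fid}/{rid}: replicate ratings outside category set: {sorted(unknown)}"
                )
        tables.append(
            ReplicateTable(
                feature_id=str(fid),
                rater_id=str(rid),
                item_ids=tuple(complete.index),
                occasion1=tuple(complete["1"]),
                occasion2=tuple(complete["2"]),
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d repeated-item ratings lacking a second occasion", n_dropped
        )
    return tables


def nontesting_view(
    matrix: RatingsMatrix, replicates: Iterable[ReplicateTable]
) -> RatingsMatrix:
    """Restrict a matrix to its non-repeated ("nontesting") items.

    Interrater agreement is computed on items rated once; the twice-presented
    items serve the intrarater assessment only.
    """
    repeated: set[str] = set()
    for table in replicates:
        if table.feature_id == matrix.feature_id:
            repeated.update(table.item_ids)
    return matrix.drop_items(repeated)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_wide_csv(matrix: RatingsMatrix, path) -> None:
    out = matrix.ratings.copy()
    out.index.name = "item"
    out.to_csv(path, na_rep="")


def write_long_csv(
    matrices: Iterable[RatingsMatrix],
    path,
    replicates: Iterable[ReplicateTable] = (),
) -> None:
    """Write matrices (occasion 1) and replicate tables (occasions 1 and 2)
    into a single long-layout CSV."""
    rows = []
    for m in matrices:
        vals = m.ratings.to_numpy(dtype=object)
        for i, item in enumerate(m.item_ids):
            for j, rater in enumerate(m.rater_ids):
                v = vals[i, j]
                rows.append(
                    (m.feature_id, item, rater, 1, "" if _is_missing(v) else v)
                )
    for t in replicates:
        for item, r1, r2 in zip(t.item_ids, t.occasion1, t.occasion2):
            rows.append((t.feature_id, item, t.rater_id, 1, r1))
            rows.append((t.feature_id, item, t.rater_id, 2, r2))
    pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, index=False)


def write_trace(trace, path) -> None:
    """Serialize an optimization trace to JSON (lossless round trip)."""
    path = Path(path)
    path.write_text(json.dumps(trace.to_dict(), indent=2))


def read_trace(path):
    """Read an optimization trace written by :func:`write_trace`."""
    from .optimizer import OptimizationTrace

    payload = json.loads(Path(path).read_text())
    return OptimizationTrace.from_dict(payload)
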