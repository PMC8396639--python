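"""Record data model and CSV I/O for portal-style observation data.

The package consumes two flat tables:

* ``observations.csv`` — one row per portal submission:
  ``observer_id,date,grid_cell,taxon,life_stage,count,is_absence``
* ``wear.csv`` — one row per photo-scored adult:
  ``source_id,date,wear_class``

Dates are ISO-8601 (``YYYY-MM-DD``); missing values are empty cells; the grid
cell is an opaque hectare-cell identifier (the analysis only ever counts
distinct cells, so no geodesy is needed).

Rows that fail validation are collected with a reason, never silently
dropped: accepted + rejected always equals the number of rows read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

LIFE_STAGES = ("adult", "egg", "caterpillar", "pupa")
WEAR_CLASSES = (1, 2, 3, 4)  # immaculate, slightly, moderately, heavily worn

OBS_COLUMNS = ["observer_id", "date", "grid_cell", "taxon",
               "life_stage", "count", "is_absence"]
WEAR_COLUMNS = ["source_id", "date", "wear_class"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


@dataclass(frozen=True)
class ObservationRecord:
    """One portal submission: who, when, where, what, how many."""

    observer_id: str
    date: pd.Timestamp
    grid_cell: str
    taxon: str
    life_stage: str
    count: int
    is_absence: bool = False


@dataclass(frozen=True)
class WearRecord:
    """One photo-scored adult: date plus ordinal wear class 1-4."""

    source_id: str
    date: pd.Timestamp
    wear_class: int


@dataclass
class RecordSet:
    """Observation records plus wear labels and read provenance.

    ``observations`` and ``wear`` are plain DataFrames with the canonical
    column sets; ``rejected`` keeps every invalid input row together with a
    human-readable reason.
    """

    observations: pd.DataFrame
    wear: pd.DataFrame = None  # type: ignore[assignment]
    rejected: pd.DataFrame = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wear is None:
            self.wear = pd.DataFrame(columns=WEAR_COLUMNS)
        if self.rejected is None:
            self.rejected = pd.DataFrame(columns=OBS_COLUMNS + ["reason"])

    @property
    def n_read(self) -> int:
        return len(self.observations) + len(self.rejected)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __len__(self) -> int:
        return len(self.observations)

    @classmethod
    def from_records(cls, records: Iterable[ObservationRecord],
                     wear: Iterable[WearRecord] = (), **provenance) -> "RecordSet":
        obs = pd.DataFrame([r.__dict__ for r in records], columns=OBS_COLUMNS)
        obs = _coerce_obs_dtypes(obs)
        wear_df = pd.DataFrame([w.__dict__ for w in wear], columns=WEAR_COLUMNS)
        if len(wear_df):
            wear_df["date"] = pd.to_datetime(wear_df["date"])
            wear_df["wear_class"] = wear_df["wear_class"].astype(int)
        return cls(observations=obs, wear=wear_df, provenance=dict(provenance))

    def iter_records(self) -> Iterable[ObservationRecord]:
        for row in self.observations.itertuples(index=False):
            yield ObservationRecord(row.observer_id, row.date, row.grid_cell,
                                    row.taxon, row.life_stage, int(row.count),
                                    bool(row.is_absence))

    def deduplicate(self) -> "RecordSet":
        """Drop exact duplicate observation rows (fuzzy matching is out of scope)."""
        before = len(self.observations)
        obs = self.observations.drop_duplicates(subset=OBS_COLUMNS, ignore_index=True)
        prov = dict(self.provenance)
        prov["n_duplicates_dropped"] = before - len(obs)
        return RecordSet(observations=obs, wear=self.wear,
                         rejected=self.rejected, provenance=prov)


def _coerce_obs_dtypes(obs: pd.DataFrame) -> pd.DataFrame:
    obs = obs.copy()
    if len(obs):
        obs["date"] = pd.to_datetime(obs["date"])
        obs["count"] = obs["count"].astype(np.int64)
        obs["is_absence"] = obs["is_absence"].astype(bool)
    for col in ("observer_id", "grid_cell", "taxon", "life_stage"):
        obs[col] = obs[col].astype(str)
    return obs


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _parse_bool(series: pd.Series) -> pd.Series:
    """Map portal-style boolean strings to True/False/NaN (NaN = unparseable)."""
    s = series.astype(str).str.strip().str.lower()
    out = pd.Series(np.nan, index=series.index, dtype=object)
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    return out


def read_observations(path) -> RecordSet:
    """Read an observations CSV, validating every row.

    Invalid rows (bad date, negative count, unknown life stage, count/absence
    mismatch...) are returned in ``RecordSet.rejected`` with a reason.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, OBS_COLUMNS, path)
    raw = raw[OBS_COLUMNS]

    date = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    count = pd.to_numeric(raw["count"], errors="coerce")
    absence = _parse_bool(raw["is_absence"])

    reason = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        new = mask & (reason == "")
        reason[new] = why

    flag(date.isna(), "unparseable date")
    flag(raw["grid_cell"].str.strip() == "", "empty grid_cell")
    flag(raw["observer_id"].str.strip() == "", "empty observer_id")
    flag(~raw["life_stage"].isin(LIFE_STAGES), "unknown life_stage")
    flag(count.isna(), "unparseable count")
    flag((count % 1 != 0).fillna(False), "non-integer count")
    flag(count < 0, "negative count")
    flag(absence.isna(), "unparseable is_absence")
    # count = 0 iff is_absence
    ok = reason == ""
    flag(ok & (count == 0) & (absence == False), "zero count on non-absence record")  # noqa: E712
    flag(ok & (count > 0) & (absence == True), "positive count on absence record")  # noqa: E712

    good = reason == ""
    accepted = raw[good].copy()
    accepted["date"] = date[good]
    accepted["count"] = count[good].astype(np.int64)
    accepted["is_absence"] = absence[good].astype(bool)
    accepted = accepted.reset_index(drop=True)

    rejected = raw[~good].copy()
    rejected["reason"] = reason[~good]
    rejected = rejected.reset_index(drop=True)
    if len(rejected):
        logger.warning("%s: rejected %d of %d rows", path, len(rejected), len(raw))

    prov = {"source": str(path), "n_read": len(raw), "n_rejected": len(rejected)}
    if len(accepted):
        prov["date_range"] = (str(accepted["date"].min().date()),
                              str(accepted["date"].max().date()))
    return RecordSet(observations=accepted, rejected=rejected, provenance=prov)


@dataclass
class WearLabels:
    """Validated wear labels plus the rejected rows."""

    records: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_read(self) -> int:
        return len(self.records) + len(self.rejected)

    def __len__(self) -> int:
        return len(self.records)


def read_wear_labels(path) -> WearLabels:
    """Read photo wear labels; wear_class outside {1..4} is rejected with a reason."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, WEAR_COLUMNS, path)
    raw = raw[WEAR_COLUMNS]
    if not len(raw):
        logger.warning("%s: empty wear file", path)

    date = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    klass = pd.to_numeric(raw["wear_class"], errors="coerce")

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[date.isna() & (reason == "")] = "unparseable date"
    bad_class = klass.isna() | (klass % 1 != 0) | ~klass.isin(WEAR_CLASSES)
    reason[bad_class & (reason == "")] = "wear_class outside 1-4"

    good = reason == ""
    records = raw[good].copy()
    records["date"] = date[good]
    records["wear_class"] = klass[good].astype(int)
    records = records.reset_index(drop=True)
    rejected = raw[~good].copy()
    rejected["reason"] = reason[~good]
    return WearLabels(records=records, rejected=rejected.reset_index(drop=True))


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tabular result as CSV with a stable column order.

    Integers round-trip bit-identically; reals are written with 12 significant
    digits; missing values become empty cells (never the string ``"NaN"``).
    """
    if table is None:
        raise ValueError("table must not be None")
    table.to_csv(path, index=False, na_rep="", float_format="%.12g")
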