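"""Search-effort proxy and effort-corrected abundance indices.

Opportunistic portal records carry no explicit effort, so effort is proxied
by *proven day-grid-visits*: one observer having reported at least one record
(any taxon, absences included) from one 100 m hectare cell on one day. Only
*proficient* observers — at least ``min_records`` butterfly records of at
least ``min_species`` butterfly species in a given year — contribute, which
screens out casual submitters whose activity leaves too thin a trace to
reconstruct effort.

The daily abundance index is the quotient of target-taxon adults reported to
day-grid-visits. Because detectability swings strongly with daily weather,
the weekly index averages only the three best (highest-index) days of each
ISO week.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .records import RecordSet
from .weeks import iso_year_week

DEFAULT_MIN_RECORDS = 50
DEFAULT_MIN_SPECIES = 10


def select_proficient_observers(
    records: RecordSet,
    butterfly_taxa: Sequence[str],
    min_records: int = DEFAULT_MIN_RECORDS,
    min_species: int = DEFAULT_MIN_SPECIES,
) -> dict[int, set[str]]:
    """Per-year sets of observers with >= min_records butterfly records of
    >= min_species butterfly species in that year.

    Selection is per calendar year of the record date: an observer may
    qualify in some years only. Absence records of butterfly taxa count
    toward the record total (they document search activity for the species).
    """
    if not butterfly_taxa:
        raise ConfigError("butterfly_taxa must name at least one butterfly taxon")
    obs = records.observations
    bf = obs[obs["taxon"].isin(set(butterfly_taxa))]
    if not len(bf):
        return {}
    year = bf["date"].dt.year
    stats = bf.groupby([year.rename("year"), "observer_id"]).agg(
        n_records=("taxon", "size"), n_species=("taxon", "nunique"))
    keep = stats[(stats["n_records"] >= min_records)
                 & (stats["n_species"] >= min_species)]
    out: dict[int, set[str]] = {}
    for (yr, obs_id) in keep.index:
        out.setdefault(int(yr), set()).add(obs_id)
    return out


def _selected_mask(obs: pd.DataFrame, selected: Mapping[int, set[str]]) -> pd.Series:
    year = obs["date"].dt.year
    mask = pd.Series(False, index=obs.index)
    for yr, ids in selected.items():
        mask |= (year == yr) & obs["observer_id"].isin(ids)
    return mask


def compute_daily_effort(
    records: RecordSet,
    selected: Mapping[int, set[str]],
    union_cells: bool = False,
) -> pd.DataFrame:
    """Day-grid-visits per date from selected observers' records of any taxon.

    Default counts distinct cells *per observer* and sums over observers (two
    observers reporting from the same cell contribute 2). ``union_cells=True``
    instead counts the union of cells across observers per day.

    Returns a DataFrame with columns ``date`` and ``day_grid_visits``.
    """
    obs = records.observations
    sel = obs[_selected_mask(obs, selected)]
    if not len(sel):
        return pd.DataFrame(columns=["date", "day_grid_visits"])
    if union_cells:
        eff = sel.groupby("date")["grid_cell"].nunique()
    else:
        per_obs = sel.groupby(["date", "observer_id"])["grid_cell"].nunique()
        eff = per_obs.groupby("date").sum()
    return eff.rename("day_grid_visits").reset_index()


def compute_daily_index(
    records: RecordSet,
    effort: pd.DataFrame,
    target_taxon: str,
    selected: Mapping[int, set[str]] | None = None,
    restrict_numerator: bool = True,
) -> pd.DataFrame:
    """Daily abundance index: target adults / day-grid-visits.

    The numerator sums the ``count`` field of adult records of the target
    taxon (individuals, not records), by default restricted to the selected
    observers whose activity defines the denominator. Days with adults but
    zero effort get an *undefined* (NaN) index, flagged in ``defined``.
    """
    obs = records.observations
    tgt = obs[(obs["taxon"] == target_taxon)
              & (obs["life_stage"] == "adult")
              & (~obs["is_absence"])]
    if restrict_numerator:
        if selected is None:
            raise ConfigError("restrict_numerator=True requires the observer selection")
        tgt = tgt[_selected_mask(tgt, selected)]
    adults = tgt.groupby("date")["count"].sum().rename("n_target_adults")

    daily = effort.set_index("date").join(adults, how="outer")
    for col in ("n_target_adults", "day_grid_visits"):
        daily[col] = pd.to_numeric(daily[col], errors="coerce").fillna(0).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        daily["index"] = np.where(daily["day_grid_visits"] > 0,
                                  daily["n_target_adults"] / daily["day_grid_visits"],
                                  np.nan)
    daily["defined"] = daily["day_grid_visits"] > 0
    return daily.reset_index().sort_values("date", ignore_index=True)


def compute_weekly_index(daily: pd.DataFrame, n_best_days: int = 3) -> pd.DataFrame:
    """Weekly index: mean of the ``n_best_days`` highest defined daily indices.

    Weeks with fewer than ``n_best_days`` defined days use all available
    days and report how many were used (``n_days_used``); weeks with no
    defined day are omitted. Columns: ``year, week, index, n_days_used,
    adults_used, visits_used``.
    """
    defined = daily[daily["defined"]].copy()
    if not len(defined):
        return pd.DataFrame(columns=["year", "week", "index", "n_days_used",
                                     "adults_used", "visits_used"])
    yw = iso_year_week(defined["date"])
    defined["year"] = yw["year"]
    defined["week"] = yw["week"]

    def agg(group: pd.DataFrame) -> pd.Series:
        top = group.nlargest(n_best_days, "index", keep="first")
        return pd.Series({
            "index": top["index"].mean(),
            "n_days_used": len(top),
            "adults_used": int(top["n_target_adults"].sum()),
            "visits_used": int(top["day_grid_visits"].sum()),
        })

    weekly = (defined.groupby(["year", "week"])
              .apply(agg, include_groups=False)
              .reset_index())
    weekly["n_days_used"] = weekly["n_days_used"].astype(int)
    weekly["adults_used"] = weekly["adults_used"].astype(int)
    weekly["visits_used"] = weekly["visits_used"].astype(int)
    return weekly.sort_values(["year", "week"], ignore_index=True)


def weekly_index_pipeline(
    records: RecordSet,
    target_taxon: str,
    butterfly_taxa: Sequence[str],
    min_records: int = DEFAULT_MIN_RECORDS,
    min_species: int = DEFAULT_MIN_SPECIES,
    union_cells: bool = False,
    restrict_numerator: bool = True,
    n_best_days: int = 3,
) -> pd.DataFrame:
    """Convenience chain: select observers -> effort -> daily -> weekly index."""
    selected = select_proficient_observers(records, butterfly_taxa,
                                           min_records, min_species)
    effort = compute_daily_effort(records, selected, union_cells=union_cells)
    daily = compute_daily_index(records, effort, target_taxon,
                                selected=selected,
                                restrict_numerator=restrict_numerator)
    return compute_weekly_index(daily, n_best_days=n_best_days)
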