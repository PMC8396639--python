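"""Reproduction-stage phenology: weekly counts, caterpillar peaks and timing.

Egg, caterpillar and pupa records trace the reproductive cycles between the
adult flight peaks. Caterpillars are by far the best-reported immature stage
and show two clear within-year peaks (late May-early July; August-early
September). Each year's caterpillar records are split at the minimum-count
week inside a valley-search window, medians of record *dates* are taken per
peak (records, not individuals, are the unit — each record weighs 1
regardless of its count field), and the per-year gap between the two
medians summarises the spacing of the reproductive cycles.

Late-season records — eggs after week 36, caterpillars from October (week
>= 40) — are counted as indications of occasional third-cycle attempts.
Pupae are too rarely reported to peak-detect and are only tallied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .records import RecordSet
from .weeks import iso_year_week

IMMATURE_STAGES = ("egg", "caterpillar", "pupa")
DEFAULT_VALLEY_WINDOW = (28, 32)
LATE_EGG_WEEK = 36   # eggs strictly after this week flag a third cycle
LATE_CAT_WEEK = 40   # caterpillars from this week on (October)


def stage_weekly_counts(records: RecordSet, target_taxon: str | None = None) -> pd.DataFrame:
    """Record counts per (year, week, life_stage) for the immature stages."""
    obs = records.observations
    imm = obs[obs["life_stage"].isin(IMMATURE_STAGES) & (~obs["is_absence"])]
    if target_taxon is not None:
        imm = imm[imm["taxon"] == target_taxon]
    if not len(imm):
        return pd.DataFrame(columns=["year", "week", "life_stage", "n_records"])
    yw = iso_year_week(imm["date"])
    out = (imm.assign(year=yw["year"], week=yw["week"])
           .groupby(["year", "week", "life_stage"]).size()
           .rename("n_records").reset_index())
    return out.sort_values(["year", "week", "life_stage"], ignore_index=True)


def _lower_median(dates: pd.Series) -> pd.Timestamp:
    """Median record date; for even counts the earlier central date (tie -> earlier)."""
    s = dates.sort_values(ignore_index=True)
    return s.iloc[(len(s) - 1) // 2]


def detect_caterpillar_peaks(
    records: RecordSet,
    year: int,
    target_taxon: str | None = None,
    valley_window: tuple[int, int] = DEFAULT_VALLEY_WINDOW,
    min_records: int = 10,
) -> dict:
    """Split one year's caterpillar records into two peaks and take medians.

    The split week is the minimum-count week inside ``valley_window`` (ties
    to the earliest week; weeks with no records count 0); records in weeks
    <= split form the first peak. Returns a dict with the per-peak medians,
    counts and the gap in days; the second peak is ``None``-flagged when one
    side is empty.
    """
    obs = records.observations
    cats = obs[(obs["life_stage"] == "caterpillar") & (~obs["is_absence"])]
    if target_taxon is not None:
        cats = cats[cats["taxon"] == target_taxon]
    yw = iso_year_week(cats["date"])
    cats = cats.assign(week=yw["week"])[yw["year"] == year]
    if len(cats) < min_records:
        raise InsufficientDataError(
            f"year {year}: {len(cats)} caterpillar records (need >= {min_records})")

    lo, hi = valley_window
    weekly = cats.groupby("week").size().reindex(range(lo, hi + 1), fill_value=0)
    split_week = int(weekly.idxmin())  # idxmin ties -> earliest

    first = cats[cats["week"] <= split_week]
    second = cats[cats["week"] > split_week]
    out = {"year": year, "split_week": split_week,
           "n_first": int(len(first)), "n_second": int(len(second)),
           "median_first": None, "median_second": None, "gap_days": np.nan}
    if len(first):
        out["median_first"] = _lower_median(first["date"])
    if len(second):
        out["median_second"] = _lower_median(second["date"])
    if len(first) and len(second):
        out["gap_days"] = float((out["median_second"] - out["median_first"]).days)
    return out


def caterpillar_peak_table(
    records: RecordSet,
    target_taxon: str | None = None,
    valley_window: tuple[int, int] = DEFAULT_VALLEY_WINDOW,
    min_records: int = 10,
) -> pd.DataFrame:
    """Per-year caterpillar peak summary; years below the record threshold are skipped."""
    obs = records.observations
    cats = obs[(obs["life_stage"] == "caterpillar") & (~obs["is_absence"])]
    if target_taxon is not None:
        cats = cats[cats["taxon"] == target_taxon]
    rows = []
    for year in sorted(cats["date"].dt.isocalendar().year.unique()):
        try:
            rows.append(detect_caterpillar_peaks(records, int(year), target_taxon,
                                                 valley_window, min_records))
        except InsufficientDataError:
            continue
    return pd.DataFrame(rows, columns=["year", "split_week", "n_first", "n_second",
                                       "median_first", "median_second", "gap_days"])


def mean_peak_gap(peaks: pd.DataFrame) -> float:
    """Unweighted mean over years of the two caterpillar-peak medians' gap (days)."""
    gaps = peaks["gap_days"].dropna()
    if not len(gaps):
        raise InsufficientDataError("no year has both caterpillar peaks defined")
    return float(gaps.mean())


def annual_timing_shift(peaks: pd.DataFrame, min_years: int = 5) -> dict:
    """OLS slope of the second caterpillar peak's median week against year.

    Negative slope = the second reproduction period shifts earlier. Units:
    weeks per year.
    """
    sub = peaks.dropna(subset=["median_second"])
    if len(sub) < min_years:
        raise InsufficientDataError(
            f"timing shift needs >= {min_years} years with a second peak, got {len(sub)}")
    med = pd.to_datetime(sub["median_second"])
    week = iso_year_week(med)["week"].astype(float)
    fit = stats.linregress(sub["year"].to_numpy(float), week.to_numpy())
    return {"slope_weeks_per_year": float(fit.slope), "n_years": int(len(sub)),
            "p_value": float(fit.pvalue)}


def late_season_flags(stage_counts: pd.DataFrame) -> pd.DataFrame:
    """Counts of third-cycle indicators per year plus a pooled 'all' row.

    ``late_eggs``: egg records after week 36; ``late_caterpillars``:
    caterpillar records from week 40 (October) onwards.
    """
    eggs = stage_counts[(stage_counts["life_stage"] == "egg")
                        & (stage_counts["week"] > LATE_EGG_WEEK)]
    cats = stage_counts[(stage_counts["life_stage"] == "caterpillar")
                        & (stage_counts["week"] >= LATE_CAT_WEEK)]
    years = sorted(set(stage_counts.get("year", pd.Series(dtype=int))))
    rows = [{"year": y,
             "late_eggs": int(eggs[eggs["year"] == y]["n_records"].sum()),
             "late_caterpillars": int(cats[cats["year"] == y]["n_records"].sum())}
            for y in years]
    rows.append({"year": "all", "late_eggs": int(eggs["n_records"].sum()),
                 "late_caterpillars": int(cats["n_records"].sum())})
    return pd.DataFrame(rows, columns=["year", "late_eggs", "late_caterpillars"])
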