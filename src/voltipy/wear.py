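"""Wing-wear phenology: weekly class counts/proportions and wear progression.

Adults photographed by recorders are scored into four ordinal wear classes
(1 immaculate .. 4 heavily worn). Sudden weekly surges of class-1 animals
mark waves of freshly emerged adults — the signature that separates a true
new generation from worn individuals re-appearing after a summer rest.

Counts are pooled across years by ISO week. The sparse tails of the season
are lumped: weeks before 10 collapse into bin 8 and weeks after 44 into
bin 46 (lumping conserves totals). Wear *progression* summarises how fast
the population ages within a window as the OLS slope of the weekly mean
wear score against week — a package-defined diagnostic; the ordinal classes
are treated as 1-4 integer scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, VoltipyError
from .records import RecordSet, WEAR_CLASSES
from .weeks import iso_year_week

logger = logging.getLogger(__name__)

LUMP_LOW_WEEK, LUMP_LOW_BIN = 10, 8
LUMP_HIGH_WEEK, LUMP_HIGH_BIN = 44, 46


def weekly_wear_table(
    wear: pd.DataFrame,
    lump_edges: bool = True,
    per_year: bool = False,
) -> pd.DataFrame:
    """Weekly wear-class counts and proportions.

    Columns: ``week, n, c1..c4, p1..p4`` (plus ``year`` when ``per_year``).
    With ``lump_edges`` the sparse season tails are pooled at bins 8 and 46.
    """
    if not len(wear):
        raise VoltipyError("no wear records supplied")
    df = wear.copy()
    yw = iso_year_week(df["date"])
    week = yw["week"]
    if lump_edges:
        week = week.where(week >= LUMP_LOW_WEEK, LUMP_LOW_BIN)
        week = week.where(week <= LUMP_HIGH_WEEK, LUMP_HIGH_BIN)
    df["week"] = week
    keys = ["week"] if not per_year else ["year", "week"]
    if per_year:
        df["year"] = yw["year"]

    counts = (df.groupby(keys + ["wear_class"]).size()
              .unstack("wear_class", fill_value=0)
              .reindex(columns=list(WEAR_CLASSES), fill_value=0))
    counts.columns = [f"c{k}" for k in WEAR_CLASSES]
    out = counts.reset_index()
    out["n"] = out[[f"c{k}" for k in WEAR_CLASSES]].sum(axis=1)
    for k in WEAR_CLASSES:
        out[f"p{k}"] = out[f"c{k}"] / out["n"]
    cols = keys + ["n"] + [f"c{k}" for k in WEAR_CLASSES] + [f"p{k}" for k in WEAR_CLASSES]
    return out[cols].sort_values(keys, ignore_index=True)


def mean_wear_by_week(phenology: pd.DataFrame) -> pd.Series:
    """Weekly mean wear score (classes as 1-4 integers), indexed by week."""
    scores = sum(k * phenology[f"c{k}"] for k in WEAR_CLASSES)
    return (scores / phenology["n"]).set_axis(phenology["week"]).rename("mean_wear")


def wear_progression(
    phenology: pd.DataFrame,
    window: tuple[int, int],
) -> dict:
    """OLS slope of mean wear score per week within an inclusive week window.

    Returns ``{"slope", "intercept", "n_weeks", "n_records"}``; raises
    InsufficientDataError with fewer than 3 usable (n>0) weeks.
    """
    sub = phenology[(phenology["week"] >= window[0])
                    & (phenology["week"] <= window[1])
                    & (phenology["n"] > 0)]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"wear progression needs >= 3 non-empty weeks in {window}, got {len(sub)}")
    mean_wear = mean_wear_by_week(sub)
    fit = stats.linregress(mean_wear.index.to_numpy(float), mean_wear.to_numpy())
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "n_weeks": int(len(sub)), "n_records": int(sub["n"].sum())}


def photo_representativeness(
    records: RecordSet,
    wear: pd.DataFrame,
    target_taxon: str | None = None,
) -> pd.DataFrame:
    """Weekly photos-per-reported-individual rate and wear-class mix.

    A simplified representativeness diagnostic: if photographers favour
    fresh-looking butterflies, the photo rate should covary with the class
    mix. Requires the two sources to overlap in time.
    """
    obs = records.observations
    adults = obs[(obs["life_stage"] == "adult") & (~obs["is_absence"])]
    if target_taxon is not None:
        adults = adults[adults["taxon"] == target_taxon]
    if not len(wear):
        logger.warning("photo_representativeness: no photos supplied")
        return pd.DataFrame(columns=["week", "n_individuals", "n_photos", "photo_rate"])
    if not len(adults):
        raise VoltipyError("no adult observation records to compare photos against")
    lo = max(adults["date"].min(), wear["date"].min())
    hi = min(adults["date"].max(), wear["date"].max())
    if lo > hi:
        raise VoltipyError("observation and wear records do not overlap in time")

    a = adults.assign(week=iso_year_week(adults["date"])["week"])
    individuals = a.groupby("week")["count"].sum().rename("n_individuals")
    w = wear.assign(week=iso_year_week(wear["date"])["week"])
    photos = w.groupby("week").size().rename("n_photos")
    mix = (w.groupby(["week", "wear_class"]).size()
           .unstack("wear_class", fill_value=0)
           .reindex(columns=list(WEAR_CLASSES), fill_value=0))
    mix.columns = [f"photos_c{k}" for k in WEAR_CLASSES]

    out = pd.concat([individuals, photos, mix], axis=1).fillna(0).reset_index()
    out["photo_rate"] = np.where(out["n_individuals"] > 0,
                                 out["n_photos"] / out["n_individuals"], np.nan)
    int_cols = ["n_individuals", "n_photos"] + list(mix.columns)
    out[int_cols] = out[int_cols].astype(int)
    return out.sort_values("week", ignore_index=True)


def photo_class_homogeneity(
    available_by_class: np.ndarray,
    photographed_by_class: np.ndarray,
) -> dict:
    """Chi-square test that photo propensity is homogeneous across wear classes.

    ``available_by_class`` are the true class counts in the population (known
    in simulation), ``photographed_by_class`` the photographed subset. Under
    homogeneous propensity the photos are a multinomial draw proportional to
    availability.
    """
    avail = np.asarray(available_by_class, dtype=float)
    photo = np.asarray(photographed_by_class, dtype=float)
    keep = avail > 0
    if photo[~keep].sum() > 0:
        raise VoltipyError("photos recorded for a class with zero availability")
    avail, photo = avail[keep], photo[keep]
    expected = avail / avail.sum() * photo.sum()
    chi2, p = stats.chisquare(photo, f_exp=expected)
    return {"chi2": float(chi2), "p_value": float(p), "dof": int(len(photo) - 1)}
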