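import numpy as np
import pandas as pd
import pytest

import voltipy as v
from voltipy.records import OBS_COLUMNS


def make_obs(rows):
    """Build a canonical observations DataFrame from short tuples.

    Each row: (observer, date, cell, taxon, stage, count, is_absence).
    """
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    df["count"] = df["count"].astype(np.int64)
    df["is_absence"] = df["is_absence"].astype(bool)
    return df


def make_recordset(rows, wear=None):
    rs = v.RecordSet(observations=make_obs(rows))
    if wear is not None:
        wdf = pd.DataFrame(wear, columns=["source_id", "date", "wear_class"])
        wdf["date"] = pd.to_datetime(wdf["date"])
        rs.wear = wdf
    return rs


@pytest.fixture(scope="session")
def sim3():
    """A 3-year default-condition simulation shared across test modules."""
    cfg = v.SyntheticConfig(years=(2018, 2019, 2020), seed=7)
    return cfg, v.simulate(cfg)


# ---------------------------------------------------------------------------
# brute-force oracle: literal enumeration of observer-day-cell triples

def brute_force_selection(obs, butterfly_taxa, min_records=50, min_species=10):
    out = {}
    for row in obs.itertuples(index=False):
        if row.taxon in butterfly_taxa:
            out.setdefault(row.date.year, {}).setdefault(row.observer_id, []) \
                .append(row.taxon)
    sel = {yr: {o for o, taxa in d.items()
                if len(taxa) >= min_records and len(set(taxa)) >= min_species}
           for yr, d in out.items()}
    return {yr: obs for yr, obs in sel.items() if obs}


def brute_force_effort(obs, selected):
    cells = {}
    for row in obs.itertuples(index=False):
        if row.observer_id in selected.get(row.date.year, set()):
            cells.setdefault((row.date, row.observer_id), set()).add(row.grid_cell)
    effort = {}
    for (date, _obs), cc in cells.items():
        effort[date] = effort.get(date, 0) + len(cc)
    return effort


def brute_force_daily(obs, effort, target, selected):
    adults = {}
    for row in obs.itertuples(index=False):
        if (row.taxon == target and row.life_stage == "adult"
                and not row.is_absence
                and row.observer_id in selected.get(row.date.year, set())):
            adults[row.date] = adults.get(row.date, 0) + row.count
    out = {}
    for date in set(effort) | set(adults):
        visits = effort.get(date, 0)
        if visits > 0:
            out[date] = adults.get(date, 0) / visits
    return out  # only defined days


def brute_force_weekly(daily):
    byweek = {}
    for date, idx in daily.items():
        iso = date.isocalendar()
        byweek.setdefault((iso.year, min(iso.week, 52)), []).append(idx)
    return {yw: sum(sorted(vals, reverse=True)[:3]) / min(len(vals), 3)
            for yw, vals in byweek.items()}


def assert_indices_match_brute_force(rs, butterfly_taxa, target,
                                     min_records=3, min_species=2):
    """Full-chain equality of the vectorised indices vs literal enumeration."""
    from voltipy.effort import (compute_daily_effort, compute_daily_index,
                                compute_weekly_index,
                                select_proficient_observers)

    sel = select_proficient_observers(rs, butterfly_taxa,
                                      min_records=min_records,
                                      min_species=min_species)
    effort = compute_daily_effort(rs, sel)
    daily = compute_daily_index(rs, effort, target, selected=sel)
    weekly = compute_weekly_index(daily)

    obs = rs.observations
    bf_sel = brute_force_selection(obs, set(butterfly_taxa),
                                   min_records=min_records,
                                   min_species=min_species)
    assert {y: set(s) for y, s in sel.items()} == bf_sel
    bf_eff = brute_force_effort(obs, bf_sel)
    assert dict(zip(effort["date"], effort["day_grid_visits"])) == bf_eff
    bf_daily = brute_force_daily(obs, bf_eff, target, bf_sel)
    got_daily = {d: i for d, i, ok in zip(daily["date"], daily["index"],
                                          daily["defined"]) if ok}
    assert set(got_daily) == set(bf_daily)
    for d in bf_daily:
        assert got_daily[d] == pytest.approx(bf_daily[d])
    bf_weekly = brute_force_weekly(bf_daily)
    got_weekly = {(y, w): i for y, w, i in zip(weekly["year"], weekly["week"],
                                               weekly["index"])}
    assert set(got_weekly) == set(bf_weekly)
    for k in bf_weekly:
        assert got_weekly[k] == pytest.approx(bf_weekly[k])
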