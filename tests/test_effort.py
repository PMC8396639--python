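import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import voltipy as v
from voltipy.effort import (compute_daily_effort, compute_daily_index,
                            compute_weekly_index, select_proficient_observers,
                            weekly_index_pipeline)
from voltipy.exceptions import ConfigError

from conftest import assert_indices_match_brute_force, make_recordset

BF = ["Aglais io"] + [f"bf_{i}" for i in range(20)]


def _bulk_rows(observer, n, n_species, year=2020):
    """n butterfly records spread over n_species butterfly taxa."""
    return [(observer, f"{year}-06-{(i % 28) + 1:02d}", f"c{i % 5}",
             BF[i % n_species], "adult", 1, False) for i in range(n)]


class TestProficiencyFilter:
    def test_thresholds(self):
        rows = (_bulk_rows("rich", 60, 12)       # 60 records, 12 species -> in
                + _bulk_rows("narrow", 60, 5)    # 5 species -> out
                + _bulk_rows("light", 49, 20))   # 49 records -> out
        sel = select_proficient_observers(make_recordset(rows), BF)
        assert sel == {2020: {"rich"}}

    def test_selection_is_per_year(self):
        rows = _bulk_rows("a", 60, 12, year=2019) + _bulk_rows("a", 20, 12, year=2020)
        sel = select_proficient_observers(make_recordset(rows), BF)
        assert 2019 in sel and 2020 not in sel

    def test_non_butterfly_records_do_not_count(self):
        rows = [("a", "2020-06-01", "c1", f"moth_{i}", "adult", 1, False)
                for i in range(60)]
        sel = select_proficient_observers(make_recordset(rows), BF)
        assert sel == {}

    def test_empty_taxa_config_is_error(self):
        with pytest.raises(ConfigError):
            select_proficient_observers(make_recordset(_bulk_rows("a", 5, 3)), [])


SEL = {2020: {"a", "b"}}


class TestDailyEffort:
    def test_distinct_cells_single_observer(self):
        rows = [("a", "2020-06-01", c, "t", "adult", 1, False)
                for c in ("c1", "c2", "c3", "c1")]
        eff = compute_daily_effort(make_recordset(rows), SEL)
        assert eff["day_grid_visits"].tolist() == [3]

    def test_per_observer_sum_vs_union(self):
        rows = [("a", "2020-06-01", "cA", "t", "adult", 1, False),
                ("a", "2020-06-01", "cB", "t", "adult", 1, False),
                ("b", "2020-06-01", "cB", "t", "adult", 1, False),
                ("b", "2020-06-01", "cC", "t", "adult", 1, False)]
        rs = make_recordset(rows)
        assert compute_daily_effort(rs, SEL)["day_grid_visits"].tolist() == [4]
        assert compute_daily_effort(rs, SEL, union_cells=True)[
            "day_grid_visits"].tolist() == [3]

    def test_absences_and_any_taxon_count(self):
        rows = [("a", "2020-06-01", "c1", "not-a-butterfly", "adult", 1, False),
                ("a", "2020-06-01", "c2", "Aglais io", "adult", 0, True)]
        eff = compute_daily_effort(make_recordset(rows), SEL)
        assert eff["day_grid_visits"].tolist() == [2]

    def test_non_selected_observer_contributes_nothing(self):
        rows = [("zz", "2020-06-01", "c1", "t", "adult", 1, False)]
        eff = compute_daily_effort(make_recordset(rows), SEL)
        assert len(eff) == 0


class TestDailyIndex:
    def _daily(self, rows, effort_rows):
        rs = make_recordset(rows)
        eff = pd.DataFrame(effort_rows, columns=["date", "day_grid_visits"])
        eff["date"] = pd.to_datetime(eff["date"])
        return compute_daily_index(rs, eff, "Aglais io", selected=SEL)

    def test_quotient(self):
        daily = self._daily([("a", "2020-06-01", "c1", "Aglais io", "adult", 12, False)],
                            [("2020-06-01", 40)])
        assert daily["index"].iloc[0] == pytest.approx(0.30)

    def test_zero_adults_is_zero_not_undefined(self):
        daily = self._daily([], [("2020-06-01", 40)])
        assert daily["index"].iloc[0] == 0.0 and daily["defined"].iloc[0]

    def test_zero_effort_is_undefined_not_zero(self):
        daily = self._daily([("a", "2020-06-01", "c1", "Aglais io", "adult", 5, False)],
                            [])
        assert not daily["defined"].iloc[0] and np.isnan(daily["index"].iloc[0])

    def test_counts_individuals_not_records(self):
        daily = self._daily([("a", "2020-06-01", "c1", "Aglais io", "adult", 7, False),
                             ("b", "2020-06-01", "c1", "Aglais io", "adult", 3, False)],
                            [("2020-06-01", 10)])
        assert daily["n_target_adults"].iloc[0] == 10


def _daily_frame(indices):
    """Daily-index frame for consecutive June 2020 days with given index values."""
    dates = pd.date_range("2020-06-01", periods=len(indices))  # Mon..Sun, one ISO week
    return pd.DataFrame({"date": dates, "n_target_adults": 0,
                         "day_grid_visits": 1, "index": indices,
                         "defined": [not np.isnan(x) for x in indices]})


class TestWeeklyIndex:
    def test_average_of_three_best(self):
        weekly = compute_weekly_index(_daily_frame([0.5, 0.3, 0.1, 0.0, 0.0]))
        assert weekly["index"].iloc[0] == pytest.approx(0.3)
        assert weekly["n_days_used"].iloc[0] == 3

    def test_exactly_three_days(self):
        weekly = compute_weekly_index(_daily_frame([0.2, 0.2, 0.2]))
        assert weekly["index"].iloc[0] == pytest.approx(0.2)

    def test_single_defined_day(self):
        weekly = compute_weekly_index(_daily_frame([0.4, np.nan, np.nan]))
        assert weekly["index"].iloc[0] == pytest.approx(0.4)
        assert weekly["n_days_used"].iloc[0] == 1

    def test_permutation_invariance(self):
        a = compute_weekly_index(_daily_frame([0.5, 0.1, 0.3, 0.2, 0.0]))
        b = compute_weekly_index(_daily_frame([0.0, 0.2, 0.5, 0.3, 0.1]))
        assert a["index"].iloc[0] == b["index"].iloc[0]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=7),
           st.integers(0, 6), st.floats(0.01, 5))
    def test_monotone_in_daily_indices(self, vals, pos, bump):
        base = compute_weekly_index(_daily_frame(vals))["index"].iloc[0]
        vals2 = list(vals)
        vals2[pos % len(vals)] += bump
        bumped = compute_weekly_index(_daily_frame(vals2))["index"].iloc[0]
        assert bumped >= base - 1e-12


# ---------------------------------------------------------------------------
# oracle equivalence and index-vs-truth fidelity

random_recordsets = st.lists(
    st.tuples(st.sampled_from(["a", "b", "c", "d"]),
              st.integers(0, 27),
              st.sampled_from(["c1", "c2", "c3", "c4", "c5"]),
              st.sampled_from(BF[:6] + ["moth"]),
              st.sampled_from(["adult", "caterpillar"]),
              st.integers(0, 9)),
    min_size=1, max_size=60)


def _to_recordset(rows):
    return make_recordset([
        (o, (pd.Timestamp("2020-06-01") + pd.Timedelta(days=d)).date().isoformat(),
         c, t, s, n if n else 0, n == 0)
        for (o, d, c, t, s, n) in rows])


@settings(max_examples=200, derandomize=True, deadline=None)
@given(random_recordsets)
def test_indices_match_brute_force_enumeration(rows):
    """Vectorised effort/daily/weekly indices equal a literal enumeration."""
    assert_indices_match_brute_force(_to_recordset(rows), BF, "Aglais io")


def test_weekly_index_tracks_latent_abundance(sim3):
    """Rank correlation between weekly index and latent truth > 0.9 over 3 years."""
    cfg, sim = sim3
    weekly = weekly_index_pipeline(sim.records, cfg.target_taxon, cfg.butterfly_taxa)
    latent = v.simulate_latent_abundance(cfg)
    merged = weekly.merge(latent[["year", "week", "total"]], on=["year", "week"])
    rho = spearmanr(merged["index"], merged["total"]).statistic
    assert rho > 0.9
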