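"""ISO-week helpers used across the package.

All phenology in this package is kept on the ISO-8601 week grid. The handful
of dates that fall in ISO week 53 are folded into week 52 so that every year
has the same 52-week axis.
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

N_WEEKS = 52


def iso_year_week(dates: pd.Series) -> pd.DataFrame:
    """Return a DataFrame with ``year`` and ``week`` columns for datetime-like input.

    Week 53 is folded into week 52.
    """
    iso = pd.to_datetime(dates).dt.isocalendar()
    week = iso["week"].astype(int).clip(upper=N_WEEKS)
    return pd.DataFrame({"year": iso["year"].astype(int), "week": week},
                        index=dates.index)


def week_start(year: int, week: int) -> _dt.date:
    """Monday of the given ISO week (week clipped to 1..52)."""
    week = int(min(max(week, 1), N_WEEKS))
    return _dt.date.fromisocalendar(int(year), week, 1)
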