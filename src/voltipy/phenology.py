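"""Flight-curve segmentation, generation performance indices and voltinism.

The annual abundance phenogram of the peacock butterfly in the study region
shows three flight peaks: overwintered adults in spring (March-May), their
offspring in early summer (~July), and a third peak in autumn
(September-October). Each year's weekly index series is segmented into the
three generation windows, each generation is sized by the sum of weekly
indices across its window (an area-under-the-curve performance index), and
the year is classified by the third peak's share of the annual total:

* < 15%          -> univoltine (stray autumn flyers only)
* 15% .. 25%     -> partial bivoltinism
* > 25%          -> bivoltine (the majority reproduces twice)

Peak segmentation itself is this package's own procedure (smoothed local
maxima with valley-split boundaries, and fixed fallback windows when fewer
than three peaks stand out); the source data only ever show the peaks
empirically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import InsufficientDataError, VoltipyError
from .weeks import N_WEEKS

GENERATIONS = ("spring", "gen1", "gen2")

#: Fixed fallback windows (inclusive week ranges) used when the smoothed
#: series does not show three separable maxima.
FALLBACK_WINDOWS = ((9, 24), (25, 33), (34, 48))

UNIVOLTINE_MAX = 0.15   # exclusive upper bound for 'univoltine'
BIVOLTINE_MIN = 0.25    # exclusive lower bound for 'bivoltine'


@dataclass(frozen=True)
class SegmentationOptions:
    """Settings for flight-peak segmentation."""

    smoothing_window: int = 3          # centred moving-average width (weeks)
    min_prominence_frac: float = 0.10  # peak prominence, fraction of annual max
    min_defined_weeks: int = 20


def _weekly_series(weekly: pd.DataFrame, year: int) -> tuple[np.ndarray, int]:
    """Weeks 1..52 index vector for one year; undefined weeks contribute 0."""
    sub = weekly[weekly["year"] == year]
    series = np.zeros(N_WEEKS)
    series[sub["week"].to_numpy() - 1] = sub["index"].to_numpy()
    return series, len(sub)


def segment_flight_peaks(
    weekly: pd.DataFrame,
    year: int,
    options: SegmentationOptions = SegmentationOptions(),
) -> tuple[list[tuple[int, int]], str]:
    """Split one year's weekly index series into three generation windows.

    Returns ``(windows, method)`` where windows are three inclusive
    ``(start_week, end_week)`` ranges covering weeks 1..52 and method is
    ``"valley_split"`` or ``"fallback_fixed"``. Boundary (valley) weeks are
    assigned to the earlier generation; ties take the earlier week.
    """
    series, n_defined = _weekly_series(weekly, year)
    if n_defined < options.min_defined_weeks:
        raise InsufficientDataError(
            f"year {year}: only {n_defined} defined weeks "
            f"(need >= {options.min_defined_weeks})")
    if not np.any(series > 0):
        raise InsufficientDataError(f"year {year}: all-zero index series")

    w = options.smoothing_window
    kernel = np.ones(w) / w
    smooth = np.convolve(series, kernel, mode="same")

    prominence = options.min_prominence_frac * series.max()
    peaks, props = find_peaks(smooth, prominence=prominence)
    if len(peaks) < 3:
        return [tuple(win) for win in FALLBACK_WINDOWS], "fallback_fixed"
    if len(peaks) > 3:
        order = np.argsort(smooth[peaks])[::-1][:3]
        peaks = np.sort(peaks[order])

    # valley = minimum raw weekly index between consecutive peaks, tie -> earlier
    valleys = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        segment = series[left:right + 1]
        valleys.append(left + int(np.argmin(segment)))
    v1, v2 = (v + 1 for v in valleys)  # to 1-based weeks
    windows = [(1, v1), (v1 + 1, v2), (v2 + 1, N_WEEKS)]
    return windows, "valley_split"


def compute_generation_summaries(
    weekly: pd.DataFrame,
    year: int,
    windows: list[tuple[int, int]],
    method: str = "valley_split",
) -> pd.DataFrame:
    """Per-generation AUC index and peak week for one year.

    ``auc_index`` sums weekly indices over the window (undefined weeks count
    0 and are tallied in ``n_undefined_weeks``); ``peak_week`` is the window's
    argmax with ties going to the earliest week, and falls back to the window
    start when the window is all zero.
    """
    sub = weekly[weekly["year"] == year]
    by_week = sub.set_index("week")["index"]
    rows = []
    for gen, (start, end) in zip(GENERATIONS, windows):
        wk = np.arange(start, end + 1)
        vals = by_week.reindex(wk)
        n_undefined = int(vals.isna().sum())
        filled = vals.fillna(0.0).to_numpy()
        auc = float(filled.sum())
        peak_week = int(wk[int(np.argmax(filled))]) if filled.max() > 0 else start
        rows.append({"year": year, "generation": gen,
                     "start_week": start, "end_week": end,
                     "auc_index": auc, "peak_week": peak_week,
                     "n_undefined_weeks": n_undefined, "method": method})
    return pd.DataFrame(rows)


def percent_larger(auc_a: float, auc_b: float) -> float:
    """How much larger (percent) is b than a: 100 * (b - a) / a."""
    if auc_a <= 0:
        raise VoltipyError("percent_larger undefined for non-positive reference AUC")
    return 100.0 * (auc_b - auc_a) / auc_a


def proportion_third_peak(summaries: pd.DataFrame) -> float:
    """Share of the annual total held by the third flight peak (gen2)."""
    by_gen = summaries.set_index("generation")["auc_index"]
    total = float(by_gen[list(GENERATIONS)].sum())
    if total <= 0:
        raise VoltipyError("proportion undefined: total AUC is zero")
    return float(by_gen["gen2"]) / total


def classify_voltinism(p: float) -> str:
    """Classify a year from its third-peak proportion.

    < 0.15 univoltine; 0.15-0.25 partial_bivoltine; > 0.25 bivoltine.
    """
    if not (0.0 <= p <= 1.0):
        raise VoltipyError(f"proportion {p!r} outside [0, 1]")
    if p < UNIVOLTINE_MAX:
        return "univoltine"
    if p <= BIVOLTINE_MIN:
        return "partial_bivoltine"
    return "bivoltine"


def historical_series(
    proportions: pd.DataFrame,
    min_records: int = 30,
) -> pd.DataFrame:
    """Year-ordered voltinism series with regime labels.

    ``proportions`` needs ``year`` and ``proportion`` columns and may carry
    ``n_records``; years with fewer than ``min_records`` records are flagged
    ``insufficient`` (their regime is still reported). Historical pre-index
    data use the same thresholds on raw record shares per window.
    """
    if not len(proportions):
        return pd.DataFrame(columns=["year", "proportion", "regime", "insufficient"])
    out = proportions.sort_values("year", ignore_index=True).copy()
    out["regime"] = out["proportion"].map(classify_voltinism)
    if "n_records" in out.columns:
        out["insufficient"] = out["n_records"] < min_records
    else:
        out["insufficient"] = False
    return out[["year", "proportion", "regime", "insufficient"]]


def analyse_year(
    weekly: pd.DataFrame,
    year: int,
    options: SegmentationOptions = SegmentationOptions(),
) -> tuple[pd.DataFrame, dict]:
    """Segment, summarise and classify one year; returns (summaries, voltinism row)."""
    windows, method = segment_flight_peaks(weekly, year, options)
    summaries = compute_generation_summaries(weekly, year, windows, method)
    p = proportion_third_peak(summaries)
    record = {"year": year, "proportion_third_peak": p,
              "regime": classify_voltinism(p), "basis": "index_auc",
              "method": method}
    return summaries, record
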