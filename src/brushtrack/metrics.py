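"""Behavioural outcome measures per brushing session.

From the aggregated interval sequence of one session (either source) this
module computes:

* per-area brushing durations d_i (closed-jaw combined codes split evenly
  onto their two sextants, uncoded time excluded);
* the number of *events* — changes of the brushed area between consecutive
  time units;
* the systematics measures over the 12 smooth-surface areas (occlusal and
  incisal brushing is ignored):

      consistency      C = max(0, (1 - b/x) * i/n)
      isochronicity    I = 1 - n/(2(n-1)) * sum_i |d_i/x - 1/n|
      TSI              = C + I

  with b the number of changes between (smooth) areas, x the total smooth
  brushing duration in seconds, i the number of reached areas and n = 12
  the number of reachable areas.  C and I lie in [0, 1] — C rewards
  complete coverage with few changes, I rewards evenly distributed
  time — so the TSI lies in [0, 2], larger values meaning more systematic
  brushing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import split_combined_durations
from .areas import (
    ALL_AREAS,
    SMOOTH_AREAS,
    SMOOTH_AREAS_WITH_COMBINED,
    UNCODED,
)
from .errors import UndefinedResultError


@dataclass
class AreaDurations:
    """Seconds brushed per single-sextant area, after the even split of
    combined codes; the d_i of the isochronicity formula."""

    durations: dict  # area label -> seconds, all 18 keys present
    total_coded_s: float

    def vector(self, areas=ALL_AREAS) -> np.ndarray:
        return np.array([self.durations.get(a, 0.0) for a in areas])


@dataclass(frozen=True)
class TSIResult:
    """The systematics measures of one session plus the inputs behind them."""

    C: float
    I: float
    TSI: float
    b: int  # changes between smooth areas
    x: float  # smooth-surface brushing duration, s
    i_reached: int  # smooth areas with positive duration
    n: int = 12
    source: str = ""


def area_durations(intervals: pd.DataFrame) -> AreaDurations:
    """Per-area brushing durations from an aggregated interval table.

    Durations are summed interval lengths by label; uncoded intervals are
    excluded; combined closed-jaw codes are then split evenly onto their
    member sextants' vestibular areas, conserving the total exactly.
    """
    coded = intervals[intervals["label"] != UNCODED]
    lengths = (coded["end_s"] - coded["start_s"]).to_numpy()
    raw: dict[str, float] = {}
    for label, dur in zip(coded["label"], lengths):
        raw[label] = raw.get(label, 0.0) + float(dur)
    split = split_combined_durations(raw)
    durations = {a: split.get(a, 0.0) for a in ALL_AREAS}
    return AreaDurations(durations=durations, total_coded_s=float(sum(split.values())))


def count_events(labels, area_set=None) -> int:
    """Number of changes between areas in a time-ordered label sequence.

    Labels outside ``area_set`` (uncoded always) are removed first, then
    equal-label runs are collapsed and the transitions between consecutive
    distinct labels counted.  An interruption by a removed label that
    returns to the same area is therefore not a change.
    """
    arr = np.asarray(list(labels), dtype=object)
    keep = arr != UNCODED
    if area_set is not None:
        keep &= np.isin(arr, list(area_set))
    arr = arr[keep]
    if arr.size <= 1:
        return 0
    return int(np.sum(arr[1:] != arr[:-1]))


def consistency(b: float, x: float, i_reached: int, n: int = 12) -> float:
    """C = max(0, (1 - b/x) * i/n): coverage completeness with few changes.

    b is the number of changes between areas, x the brushing duration in
    seconds, i the number of reached areas out of n reachable.
    """
    if x <= 0:
        raise UndefinedResultError("consistency requires positive brushing time x")
    if not 0 <= i_reached <= n:
        raise ValueError("i_reached must lie in [0, n]")
    if b < 0:
        raise ValueError("b must be non-negative")
    return max(0.0, (1.0 - b / x) * (i_reached / n))


def isochronicity(durations, x: float | None = None) -> float:
    """I = 1 - n/(2(n-1)) * sum_i |d_i/x - 1/n|: evenness of brushing time.

    ``durations`` is the d_i vector over the n areas; x defaults to its
    sum.  I is 1 for perfectly even time, 0 when all time sits in one area.
    """
    d = np.asarray(list(durations), dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("isochronicity needs at least two areas")
    if (d < 0).any():
        raise ValueError("durations must be non-negative")
    if x is None:
        x = float(d.sum())
    if x <= 0:
        raise UndefinedResultError("isochronicity requires positive brushing time x")
    return 1.0 - n / (2.0 * (n - 1)) * float(np.abs(d / x - 1.0 / n).sum())


def tsi(intervals: pd.DataFrame, source: str = "") -> TSIResult:
    """Toothbrushing Systematics Index of one aggregated session.

    Computed on the 12 smooth-surface areas only: occlusal/incisal
    intervals are removed (an occlusal interruption returning to the same
    smooth area is not a change), combined codes are split evenly for the
    duration vector, and

        b = changes between smooth areas,  x = smooth duration (s),
        i = smooth areas with d_i > 0,     n = 12.
    """
    smooth = intervals[intervals["label"].isin(SMOOTH_AREAS_WITH_COMBINED)]
    if len(smooth) == 0:
        raise UndefinedResultError(
            "TSI is undefined: the session contains no smooth-surface "
            "(vestibular/oral) brushing time"
        )
    dur = area_durations(smooth)
    x = dur.total_coded_s
    d = dur.vector(SMOOTH_AREAS)
    b = count_events(smooth["label"], SMOOTH_AREAS_WITH_COMBINED)
    i_reached = int(np.sum(d > 0))
    n = len(SMOOTH_AREAS)
    c_val = consistency(b, x, i_reached, n)
    i_val = isochronicity(d, x)
    return TSIResult(
        C=c_val, I=i_val, TSI=c_val + i_val, b=b, x=x,
        i_reached=i_reached, n=n, source=source,
    )


def session_metrics(intervals: pd.DataFrame, meta: dict | None = None) -> dict:
    """Flat per-session metrics row: 18 per-area durations, the 18-area
    event count, and the TSI inputs and outputs.

    ``meta`` (subject_id, session, brush, source, ...) is prepended to the
    row.  The reported ``events`` count is taken over all areas on the
    aggregated grid; the TSI-internal b is the 12-smooth-area count and is
    reported separately.
    """
    row: dict = dict(meta or {})
    dur = area_durations(intervals)
    for area, sec in dur.durations.items():
        row[f"d_{area}"] = sec
    row["total_coded_s"] = dur.total_coded_s
    row["events"] = count_events(intervals["label"])
    t = tsi(intervals, source=row.get("source", ""))
    row.update(
        {"b": t.b, "x": t.x, "i_reached": t.i_reached,
         "C": t.C, "I": t.I, "TSI": t.TSI}
    )
    return row
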