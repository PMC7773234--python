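"""Downsampling raw streams onto the common 0.5 s interval grid.

Both sources are reduced to one area label per half-second interval: the VO
event log is first rasterized to a frame grid, MT samples are used as-is;
each interval takes the *majority vote* of its samples, ties going to the
label that occurs first in time within the interval.  A trailing partial
interval is kept and voted from its available samples, so binning conserves
coded duration.

Where an MT stream carries the brush-head angle, the occlusal-vs-smooth
surface decision can be (re)made per sample from the angle thresholds
before voting.  The convention is: angle is the inclination of the
brush-head axis relative to the occlusal plane, small angles meaning
occlusal/incisal contact, so ``angle <= threshold`` maps to surface 01 and
larger angles to the smooth surface indicated by the side flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .areas import (
    COMBINED_SEXTANT_MEMBERS,
    OCCLUSAL,
    ORAL,
    UNCODED,
    VESTIBULAR,
    parse_area_code,
)
from .errors import PairingError
from .streams import AngleThresholds, SessionStream, rasterize_events

INTERVAL_COLUMNS = ["index", "start_s", "end_s", "label", "support"]


@dataclass(frozen=True)
class CodedInterval:
    """One aggregated interval: [start_s, end_s) with its winning label and
    the number of samples (support) behind it."""

    index: int
    start_s: float
    end_s: float
    label: str
    support: int


def majority_label(labels) -> tuple[str, int]:
    """Majority vote over the samples of one interval.

    Uncoded samples do not vote.  Returns ``(label, support)``; an interval
    with no coded sample yields the uncoded sentinel with support 0.  Ties
    are broken in favour of the label occurring first in time within the
    interval.
    """
    arr = np.asarray(labels, dtype=object)
    arr = arr[arr != UNCODED]
    if arr.size == 0:
        return UNCODED, 0
    uniq, first_idx, counts = np.unique(arr, return_index=True, return_counts=True)
    top = counts == counts.max()
    winner_pos = first_idx[top].min()
    winner = arr[winner_pos]
    return str(winner), int(counts[top][first_idx[top] == winner_pos][0])


def bin_samples(
    samples: pd.DataFrame,
    bin_s: float = 0.5,
    session_start_s: float = 0.0,
    session_end_s: float | None = None,
) -> pd.DataFrame:
    """Aggregate a (t_s, area) sample table into half-open bins of ``bin_s``.

    Bins are [k*bin_s, (k+1)*bin_s) from session start; a trailing partial
    bin is retained and labelled from whatever samples it holds.  Returns a
    frame with columns index, start_s, end_s, label, support.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    t = samples["t_s"].to_numpy(dtype=float)
    labels = samples["area"].to_numpy(dtype=object)
    if session_end_s is None:
        session_end_s = float(t[-1]) + 1e-9 if t.size else session_start_s
    span = session_end_s - session_start_s
    n_bins = max(int(np.ceil(span / bin_s - 1e-9)), 0)
    rows = []
    bin_of = np.floor((t - session_start_s) / bin_s + 1e-9).astype(int)
    # sample times are sorted, so each bin is one contiguous slice
    boundaries = np.searchsorted(bin_of, np.arange(n_bins + 1))
    for k in range(n_bins):
        lo, hi = boundaries[k], boundaries[k + 1]
        label, support = majority_label(labels[lo:hi])
        start = session_start_s + k * bin_s
        end = min(start + bin_s, session_end_s)
        rows.append((k, start, end, label, support))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def bin_stream(
    stream: SessionStream,
    bin_s: float = 0.5,
    thresholds: AngleThresholds | None = None,
) -> pd.DataFrame:
    """Aggregate a session stream onto the interval grid.

    Event streams are rasterized at their sampling rate first.  If
    ``thresholds`` is given and the stream carries an angle channel, the
    surface digit pair of every sample is re-derived from the angle before
    voting (per-sample classification, then majority vote).
    """
    if stream.kind == "events":
        samples = rasterize_events(stream)
    else:
        samples = stream.records
        if thresholds is not None and "angle_deg" in samples.columns:
            samples = apply_angle_classifier(samples, thresholds)
    return bin_samples(
        samples,
        bin_s=bin_s,
        session_start_s=stream.session_start_s,
        session_end_s=stream.session_end_s,
    )


def classify_surface_from_angle(
    angle_deg: float,
    region: str,
    thresholds: AngleThresholds = AngleThresholds(),
    side: str = "vestibular_side",
) -> str:
    """Surface digit pair from the brush-head angle.

    ``angle <= threshold`` (20 deg molar, 13 deg anterior by default) means
    occlusal/incisal contact (01); larger angles mean smooth-surface
    brushing on the side given by ``side`` (02 vestibular, 03 oral).
    """
    if not 0 <= angle_deg <= 90:
        raise ValueError(f"angle must lie in [0, 90] deg, got {angle_deg}")
    if side not in ("vestibular_side", "oral_side"):
        raise ValueError(f"unknown side {side!r}")
    if angle_deg <= thresholds.for_region(region):
        return OCCLUSAL
    return VESTIBULAR if side == "vestibular_side" else ORAL


def apply_angle_classifier(
    samples: pd.DataFrame, thresholds: AngleThresholds
) -> pd.DataFrame:
    """Re-derive each sample's surface from its angle channel.

    The recorded code supplies the sextant and — when it is a smooth
    surface — the side flag; occlusal-coded samples default to the
    vestibular side when the angle says "smooth".  Combined closed-jaw
    codes are vestibular by definition and are left untouched, as are
    uncoded samples and samples without an angle value.
    """
    out = samples.copy()
    codes = out["area"].astype(str)
    angles = out["angle_deg"].to_numpy(dtype=float)
    regions = out["region"].astype(str).to_numpy()
    sextant = codes.str[:2].to_numpy()
    surface = codes.str[2:].to_numpy()
    active = (
        (codes.to_numpy() != UNCODED)
        & ~np.isnan(angles)
        & ~np.isin(sextant, list(COMBINED_SEXTANT_MEMBERS))
    )
    if active.any():
        a = angles[active]
        if (a < 0).any() or (a > 90).any():
            bad = a[(a < 0) | (a > 90)][0]
            raise ValueError(f"angle must lie in [0, 90] deg, got {bad}")
        thr = np.where(
            regions[active] == "anterior",
            thresholds.anterior_deg,
            thresholds.molar_deg,
        )
        smooth_side = np.where(surface[active] == ORAL, ORAL, VESTIBULAR)
        new_surface = np.where(a <= thr, OCCLUSAL, smooth_side)
        new_codes = codes.to_numpy(dtype=object)
        new_codes[active] = np.char.add(
            sextant[active].astype(str), new_surface.astype(str)
        ).astype(object)
        out["area"] = new_codes
    return out


def threshold_sensitivity(
    samples: pd.DataFrame,
    thresholds: AngleThresholds = AngleThresholds(),
    delta_deg: float = 3.0,
) -> dict:
    """Fraction of sample labels changed by perturbing both angle thresholds.

    Re-runs the per-sample surface classification with both thresholds
    shifted by +delta and by -delta and reports the changed-label fraction
    for each, a robustness probe for the occlusal/smooth decision.
    """
    base = apply_angle_classifier(samples, thresholds)["area"].to_numpy()
    out = {}
    for sign, key in ((+1, "raised"), (-1, "lowered")):
        pert = AngleThresholds(
            molar_deg=thresholds.molar_deg + sign * delta_deg,
            anterior_deg=thresholds.anterior_deg + sign * delta_deg,
        )
        lab = apply_angle_classifier(samples, pert)["area"].to_numpy()
        out[key] = float(np.mean(lab != base))
    return out


@dataclass
class PairedIntervalTable:
    """Per-interval VO and MT labels for one session, index-aligned.

    Intervals where either side is uncoded are flagged and excluded from
    all agreement denominators.
    """

    subject_id: str
    session: str
    brush: str
    table: pd.DataFrame  # columns: index, vo_label, mt_label
    dropped_vo: int = 0
    dropped_mt: int = 0

    @property
    def coded_mask(self) -> np.ndarray:
        return (
            (self.table["vo_label"] != UNCODED)
            & (self.table["mt_label"] != UNCODED)
        ).to_numpy()

    @property
    def n_coded(self) -> int:
        return int(self.coded_mask.sum())

    def coded_pairs(self) -> pd.DataFrame:
        return self.table.loc[self.coded_mask, ["vo_label", "mt_label"]]


def pair_streams(
    vo_intervals: pd.DataFrame,
    mt_intervals: pd.DataFrame,
    subject_id: str = "",
    session: str = "baseline",
    brush: str = "manual",
    vo_meta: dict | None = None,
    mt_meta: dict | None = None,
) -> PairedIntervalTable:
    """Pair two interval tables by index over the overlap of their spans.

    Both tables must come from the same bin grid.  If one stream is longer,
    its surplus intervals are dropped with a warning.  Metadata dicts, when
    given, must agree on subject and session.
    """
    if vo_meta is not None and mt_meta is not None:
        for key in ("subject_id", "session"):
            if vo_meta.get(key) != mt_meta.get(key):
                raise PairingError(
                    f"cannot pair streams: {key} differs "
                    f"({vo_meta.get(key)!r} vs {mt_meta.get(key)!r})"
                )
        subject_id = vo_meta.get("subject_id", subject_id)
        session = vo_meta.get("session", session)
        brush = vo_meta.get("brush", brush)
    n = min(len(vo_intervals), len(mt_intervals))
    d_vo, d_mt = len(vo_intervals) - n, len(mt_intervals) - n
    if d_vo or d_mt:
        longer = "VO" if d_vo else "MT"
        warnings.warn(
            f"stream lengths differ; dropping {max(d_vo, d_mt)} trailing "
            f"{longer} interval(s) outside the overlap"
        )
    table = pd.DataFrame(
        {
            "index": np.arange(n),
            "vo_label": vo_intervals["label"].to_numpy()[:n],
            "mt_label": mt_intervals["label"].to_numpy()[:n],
        }
    )
    return PairedIntervalTable(
        subject_id=subject_id,
        session=session,
        brush=brush,
        table=table,
        dropped_vo=d_vo,
        dropped_mt=d_mt,
    )


def pair_session(
    vo_stream: SessionStream,
    mt_stream: SessionStream,
    bin_s: float = 0.5,
    thresholds: AngleThresholds | None = None,
) -> PairedIntervalTable:
    """Bin both streams of one session and pair them (convenience)."""
    vo_int = bin_stream(vo_stream, bin_s=bin_s)
    mt_int = bin_stream(mt_stream, bin_s=bin_s, thresholds=thresholds)
    return pair_streams(
        vo_int,
        mt_int,
        vo_meta={
            "subject_id": vo_stream.subject_id,
            "session": vo_stream.session,
            "brush": vo_stream.brush,
        },
        mt_meta={
            "subject_id": mt_stream.subject_id,
            "session": mt_stream.session,
            "brush": mt_stream.brush,
        },
    )


def split_combined_durations(durations: dict) -> dict:
    """Distribute closed-jaw combined-code durations onto single sextants.

    Each combined code's duration is split 50/50 onto the vestibular areas
    of its two member sextants (e.g. 4 s of 1602 becomes 2 s each of 0102
    and 0602).  Total duration is conserved exactly.
    """
    out: dict[str, float] = {}
    for code, dur in durations.items():
        area = parse_area_code(code)
        if area.is_combined:
            for member in area.member_sextants:
                key = member + VESTIBULAR
                out[key] = out.get(key, 0.0) + dur / 2.0
        else:
            out[code] = out.get(code, 0.0) + dur
    return out
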