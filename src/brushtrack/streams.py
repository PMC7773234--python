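"""Session streams: in-memory containers and delimited-text readers/writers.

A *session stream* is one source's record of one brushing session.  Video
observation (VO) produces timed events — (start_s, end_s, area) rows coded
exhaustively by a human observer — while motion tracking (MT) produces a
100 Hz sample stream of (t_s, area) rows, optionally with the brush-head
angle in degrees and the threshold region (molar/anterior).

Time is seconds from session start; intervals are half-open [start, end).
Files are plain delimited text with a header row; a VO file may carry one
comment line ``# sync_offset_s=<float>`` whose offset is added to all times
at read time to move them onto the session clock.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .areas import UNCODED, parse_area_code
from .errors import StreamParseError

VO_COLUMNS = ["subject_id", "session", "brush", "source", "start_s", "end_s", "area"]
MT_COLUMNS = ["subject_id", "session", "brush", "source", "t_s", "area"]
MT_OPTIONAL = ["angle_deg", "region"]

SESSIONS = ("baseline", "post_instruction")
SOURCES = ("VO", "MT")
BRUSHES = ("manual", "powered")


@dataclass(frozen=True)
class SamplingSpec:
    """Sampling geometry: source rate in Hz and the aggregation bin in s."""

    rate_hz: float = 100.0
    bin_s: float = 0.5

    def __post_init__(self):
        if self.rate_hz <= 0 or self.bin_s <= 0:
            raise ValueError("rate_hz and bin_s must be positive")


#: Default sampling for the two sources: 100 Hz tracking, 50 fps video.
MT_SAMPLING = SamplingSpec(rate_hz=100.0, bin_s=0.5)
VO_SAMPLING = SamplingSpec(rate_hz=50.0, bin_s=0.5)


@dataclass(frozen=True)
class AngleThresholds:
    """Brush-angle cutoffs separating occlusal/incisal from smooth-surface
    brushing: 20 deg on the molars, 13 deg on the front teeth."""

    molar_deg: float = 20.0
    anterior_deg: float = 13.0

    def __post_init__(self):
        for v in (self.molar_deg, self.anterior_deg):
            if not 0 < v < 90:
                raise ValueError("angle thresholds must lie strictly in (0, 90)")

    def for_region(self, region: str) -> float:
        if region == "molar":
            return self.molar_deg
        if region == "anterior":
            return self.anterior_deg
        raise ValueError(f"unknown region {region!r}")


@dataclass
class SessionStream:
    """One source's time-ordered coded record of one brushing session.

    ``records`` is an event table (VO: start_s, end_s, area) or a sample
    table (MT: t_s, area[, angle_deg, region]).  All times are seconds from
    session start.
    """

    subject_id: str
    session: str
    source: str
    brush: str
    records: pd.DataFrame
    session_start_s: float = 0.0
    session_end_s: float | None = None
    sampling: SamplingSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.brush not in BRUSHES:
            raise ValueError(f"unknown brush {self.brush!r}")
        if self.sampling is None:
            self.sampling = MT_SAMPLING if self.source == "MT" else VO_SAMPLING
        if self.session_end_s is None:
            if self.kind == "events":
                end = self.records["end_s"].max() if len(self.records) else 0.0
            else:
                # last sample owns one full sample period
                end = (
                    self.records["t_s"].max() + 1.0 / self.sampling.rate_hz
                    if len(self.records)
                    else 0.0
                )
            self.session_end_s = float(end)
        self.validate()

    @property
    def kind(self) -> str:
        return "events" if "start_s" in self.records.columns else "samples"

    def validate(self) -> None:
        rec = self.records
        if self.kind == "events":
            if len(rec):
                if (rec["start_s"] >= rec["end_s"]).any():
                    raise ValueError("VO events must have start_s < end_s")
                starts = rec["start_s"].to_numpy()
                ends = rec["end_s"].to_numpy()
                if not (np.diff(starts) >= 0).all():
                    raise ValueError("VO events must be sorted by start time")
                if (starts[1:] < ends[:-1] - 1e-9).any():
                    raise ValueError("VO events must not overlap")
                if starts[0] < self.session_start_s - 1e-9 or (
                    ends[-1] > self.session_end_s + 1e-9
                ):
                    raise ValueError("VO events must lie within the session span")
        else:
            if len(rec):
                t = rec["t_s"].to_numpy()
                if not (np.diff(t) > 0).all():
                    raise ValueError("MT sample times must be strictly increasing")
                if t[0] < self.session_start_s - 1e-9 or t[-1] > self.session_end_s + 1e-9:
                    raise ValueError("MT samples must lie within the session span")
        for code in rec["area"].unique():
            if code != UNCODED:
                parse_area_code(code)

    @property
    def duration_s(self) -> float:
        return self.session_end_s - self.session_start_s


def _validated_frame(df, mandatory, path):
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise StreamParseError(f"missing mandatory columns {missing}", path=path)
    return df


def read_session_stream(path, dialect: str) -> SessionStream:
    """Read one session stream from a delimited text file.

    ``dialect`` is ``"vo_events"`` (timed events) or ``"mt_samples"``
    (sample rows).  A leading ``# sync_offset_s=<float>`` comment shifts all
    times onto the session clock.  Malformed files raise
    :class:`~brushtrack.errors.StreamParseError` with the offending line.
    """
    if dialect not in ("vo_events", "mt_samples"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        text = fh.read()
    sync_offset = 0.0
    lines = text.splitlines()
    data_start_line = 1
    if lines and lines[0].startswith("#"):
        head = lines[0].lstrip("# ").strip()
        if head.startswith("sync_offset_s="):
            sync_offset = float(head.split("=", 1)[1])
        data_start_line = 2
        text = "\n".join(lines[1:])
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"area": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise StreamParseError(f"unparseable file: {exc}", path=path) from exc

    mandatory = VO_COLUMNS if dialect == "vo_events" else MT_COLUMNS
    _validated_frame(df, mandatory, path)
    if df.empty:
        warnings.warn(f"{path}: stream file contains a header but no records")

    def _line(row_idx):
        # +1 for the header row, +1 to convert to 1-based
        return row_idx + data_start_line + 1

    for idx, code in df["area"].items():
        if code != UNCODED:
            try:
                parse_area_code(code)
            except ValueError as exc:
                raise StreamParseError(str(exc), line=_line(idx), path=path) from exc

    time_cols = ["start_s", "end_s"] if dialect == "vo_events" else ["t_s"]
    for col in time_cols:
        df[col] = df[col].astype(float) + sync_offset

    if dialect == "vo_events" and len(df) > 1:
        starts = df["start_s"].to_numpy()
        ends = df["end_s"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1] - 1e-9)[0]
        if bad.size:
            raise StreamParseError(
                "overlapping VO events", line=_line(int(bad[0]) + 1), path=path
            )
    if dialect == "mt_samples" and len(df) > 1:
        t = df["t_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise StreamParseError(
                "non-monotonic sample times", line=_line(int(bad[0]) + 1), path=path
            )

    meta = {}
    for col in ("subject_id", "session", "brush", "source"):
        vals = df[col].unique()
        if len(vals) > 1:
            raise StreamParseError(f"mixed values in column {col}: {vals}", path=path)
        meta[col] = str(vals[0]) if len(vals) else ""
    if df.empty:
        raise StreamParseError(
            "cannot infer session metadata from an empty file", path=path
        )

    keep = [c for c in df.columns if c not in ("subject_id", "session", "brush", "source")]
    records = df[keep].reset_index(drop=True)
    if dialect == "mt_samples":
        for opt in MT_OPTIONAL:
            if opt in records.columns and records[opt].isna().all():
                records = records.drop(columns=[opt])
    return SessionStream(
        subject_id=meta["subject_id"],
        session=meta["session"],
        source=meta["source"],
        brush=meta["brush"],
        records=records,
    )


def write_session_stream(stream: SessionStream, path) -> None:
    """Write a stream to delimited text; inverse of :func:`read_session_stream`.

    Times are written to millisecond and angles to 0.01 deg precision, so a
    read-back reproduces the stream exactly at that resolution.  Optional
    columns the stream lacks are omitted from the file.
    """
    rec = stream.records.copy()
    rec.insert(0, "subject_id", stream.subject_id)
    rec.insert(1, "session", stream.session)
    rec.insert(2, "brush", stream.brush)
    rec.insert(3, "source", stream.source)
    float_fmt = {}
    for col in ("start_s", "end_s", "t_s"):
        if col in rec.columns:
            float_fmt[col] = "%.3f"
    if "angle_deg" in rec.columns:
        float_fmt["angle_deg"] = "%.2f"
    for col, fmt in float_fmt.items():
        rec[col] = rec[col].map(lambda v: fmt % v)
    rec.to_csv(path, sep="\t", index=False)


def round_trip(stream: SessionStream, path) -> SessionStream:
    """Write then re-read a stream (convenience for tests and pipelines)."""
    write_session_stream(stream, path)
    dialect = "vo_events" if stream.kind == "events" else "mt_samples"
    return read_session_stream(path, dialect)


def rasterize_events(stream: SessionStream, rate_hz: float | None = None) -> pd.DataFrame:
    """Expand a VO event stream onto a frame grid of one sample per tick.

    Each frame [k/rate, (k+1)/rate) is labelled by the event covering its
    midpoint, which prevents double-labelling at event boundaries.  Frames
    covered by no event get the explicit ``uncoded`` sentinel — gaps are
    never silently dropped.  Returns a frame with columns ``t_s``, ``area``.
    """
    if stream.kind != "events":
        raise ValueError("rasterize_events expects an event-based stream")
    if rate_hz is None:
        rate_hz = stream.sampling.rate_hz
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    start, end = stream.session_start_s, stream.session_end_s
    n = int(round((end - start) * rate_hz))
    t = start + np.arange(n) / rate_hz
    mid = t + 0.5 / rate_hz
    labels = np.full(n, UNCODED, dtype=object)
    ev = stream.records
    if len(ev):
        starts = ev["start_s"].to_numpy()
        ends = ev["end_s"].to_numpy()
        idx = np.searchsorted(starts, mid, side="right") - 1
        valid = idx >= 0
        covered = np.zeros(n, dtype=bool)
        covered[valid] = mid[valid] < ends[idx[valid]]
        labels[covered] = ev["area"].to_numpy()[idx[covered]]
    return pd.DataFrame({"t_s": t, "area": labels})


def replace_records(stream: SessionStream, records: pd.DataFrame) -> SessionStream:
    """A copy of ``stream`` with new records (re-validated)."""
    return replace(stream, records=records)
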