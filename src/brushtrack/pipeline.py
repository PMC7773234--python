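"""End-to-end orchestration: simulate -> aggregate -> agree -> metrics -> stats.

The pipeline is deterministic given the master seed.  Every stage is also
usable on its own through delimited-text intermediates (see the CLI), and
:func:`run_full_study` chains them, writing all intermediates, the report
tables and a manifest that records every parameter and seed so any subset
of the run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregation import PairedIntervalTable, bin_stream, pair_streams
from .agreement import (
    AgreementSummary,
    confusion_matrix,
    heatmap_table,
    matching_distribution,
    matching_proportion,
)
from .areas import UNCODED
from .errors import UndefinedResultError
from .metrics import session_metrics
from .stats import run_study_analysis
from .streams import AngleThresholds, write_session_stream
from .synthetic import NoiseModel, StudyData, simulate_study

log = logging.getLogger("brushtrack")

FLOAT_FORMAT = "%.4f"


@dataclass
class PipelineConfig:
    """All tunables of a full study run, with the study defaults."""

    out_dir: str = "study_output"
    seed: int = 0
    n_manual: int = 51
    n_powered: int = 52
    n_instructed: int = 46
    bin_s: float = 0.5
    molar_deg: float = 20.0
    anterior_deg: float = 13.0
    alpha: float = 0.05
    margin_s: float = 8.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    profile_overrides: dict = field(default_factory=dict)
    instructed_overrides: dict = field(default_factory=dict)

    @property
    def thresholds(self) -> AngleThresholds:
        return AngleThresholds(molar_deg=self.molar_deg, anterior_deg=self.anterior_deg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_file(cls, path, **cli_overrides) -> "PipelineConfig":
        """Load a YAML config; explicit keyword (CLI) values take precedence
        over the file, which takes precedence over the defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        noise = data.pop("noise", None)
        data.update({k: v for k, v in cli_overrides.items() if v is not None})
        cfg = cls(**data)
        if noise is not None:
            cfg.noise = NoiseModel(**noise)
        return cfg


# ---------------------------------------------------------------------------
# In-memory stage functions (the CLI adds file plumbing around these)


def aggregate_study(
    study: StudyData, bin_s: float = 0.5, thresholds: AngleThresholds | None = None
) -> pd.DataFrame:
    """Interval tables for every stream of a study, in one long frame with
    columns subject_id, session, brush, source, index, start_s, end_s,
    label, support."""
    frames = []
    for rec in study:
        for source, stream in (("VO", rec.vo), ("MT", rec.mt)):
            ints = bin_stream(
                stream, bin_s=bin_s, thresholds=thresholds if source == "MT" else None
            )
            ints.insert(0, "subject_id", rec.subject_id)
            ints.insert(1, "session", rec.session)
            ints.insert(2, "brush", rec.brush)
            ints.insert(3, "source", source)
            frames.append(ints)
    out = pd.concat(frames, ignore_index=True)
    n_uncoded = int((out["label"] == UNCODED).sum())
    if n_uncoded:
        log.info("aggregation: %d uncoded interval(s) flagged", n_uncoded)
    return out


def paired_tables_from_intervals(intervals: pd.DataFrame) -> list[PairedIntervalTable]:
    """Pair the VO and MT interval sequences of each subject x session."""
    paired = []
    for (subject, session, brush), grp in intervals.groupby(
        ["subject_id", "session", "brush"], sort=True
    ):
        vo = grp[grp["source"] == "VO"].sort_values("index")
        mt = grp[grp["source"] == "MT"].sort_values("index")
        if len(vo) == 0 or len(mt) == 0:
            log.warning("session %s/%s lacks one source; skipped", subject, session)
            continue
        paired.append(
            pair_streams(vo, mt, subject_id=subject, session=session, brush=brush)
        )
    return paired


def agreement_table(paired: list[PairedIntervalTable]) -> pd.DataFrame:
    """Per-session matching proportions (one row per paired session)."""
    rows = []
    for p in paired:
        try:
            pct = matching_proportion(p)
        except UndefinedResultError:
            log.warning(
                "session %s/%s has no commonly coded interval; excluded",
                p.subject_id, p.session,
            )
            continue
        rows.append(
            {
                "subject_id": p.subject_id,
                "session": p.session,
                "brush": p.brush,
                "matching_pct": pct,
                "n_coded": p.n_coded,
            }
        )
    return pd.DataFrame(rows)


def metrics_table(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-session, per-source behavioural metrics rows."""
    rows = []
    for (subject, session, brush, source), grp in intervals.groupby(
        ["subject_id", "session", "brush", "source"], sort=True
    ):
        meta = {
            "subject_id": subject,
            "session": session,
            "brush": brush,
            "source": source,
        }
        try:
            rows.append(session_metrics(grp.sort_values("index"), meta))
        except UndefinedResultError as exc:
            log.warning("metrics skipped for %s/%s/%s: %s", subject, session, source, exc)
    return pd.DataFrame(rows)


@dataclass
class StudyAnalysis:
    """Everything the pipeline computes for one study, in memory."""

    intervals: pd.DataFrame
    paired: list
    agreement: pd.DataFrame
    confusion: pd.DataFrame
    heatmap: pd.DataFrame
    summary: AgreementSummary
    metrics: pd.DataFrame
    report: dict


def analyze_study(study: StudyData, config: PipelineConfig) -> StudyAnalysis:
    """Run every non-simulation stage on an in-memory study."""
    intervals = aggregate_study(study, bin_s=config.bin_s, thresholds=config.thresholds)
    paired = paired_tables_from_intervals(intervals)
    agree = agreement_table(paired)
    baseline_paired = [p for p in paired if p.session == "baseline"]
    confusion = confusion_matrix(baseline_paired)
    heat = heatmap_table(confusion)
    summary = matching_distribution(
        agree.loc[agree["session"] == "baseline", "matching_pct"]
    )
    metr = metrics_table(intervals)
    report = run_study_analysis(metr, agree, alpha=config.alpha)
    return StudyAnalysis(
        intervals=intervals,
        paired=paired,
        agreement=agree,
        confusion=confusion,
        heatmap=heat,
        summary=summary,
        metrics=metr,
        report=report,
    )


def write_study_streams(study: StudyData, out_dir: Path) -> list[str]:
    """One vo_events and one mt_samples file per subject x session."""
    streams_dir = Path(out_dir) / "streams"
    streams_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in study:
        for source, stream in (("vo", rec.vo), ("mt", rec.mt)):
            name = f"{rec.subject_id}_{rec.session}_{source}.tsv"
            write_session_stream(stream, streams_dir / name)
            written.append(name)
    return written


def write_ground_truth(study: StudyData, out_dir: Path) -> None:
    rows = []
    for rec in study:
        row = {
            "subject_id": rec.subject_id,
            "session": rec.session,
            "brush": rec.brush,
            "event_count": rec.ground_truth.event_count,
            "total_duration_s": rec.ground_truth.total_duration_s,
        }
        for area, sec in rec.ground_truth.area_durations.items():
            row[f"d_{area}"] = sec
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        Path(out_dir) / "ground_truth.tsv", sep="\t", index=False,
        float_format=FLOAT_FORMAT,
    )


def run_full_study(config: PipelineConfig) -> Path:
    """Simulate and analyse a whole study, writing every intermediate and
    report table under ``config.out_dir``.  Deterministic given the seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating study (seed=%d)", config.seed)
    study = simulate_study(
        n_manual=config.n_manual,
        n_powered=config.n_powered,
        n_instructed=config.n_instructed,
        seed=config.seed,
        noise=config.noise,
        profile_overrides=config.profile_overrides,
        instructed_overrides=config.instructed_overrides,
    )
    stream_files = write_study_streams(study, out)
    write_ground_truth(study, out)

    analysis = analyze_study(study, config)
    kw = dict(sep="\t", index=False, float_format=FLOAT_FORMAT)
    analysis.intervals.to_csv(out / "intervals.tsv", **kw)
    paired_frames = []
    for p in analysis.paired:
        t = p.table.copy()
        t.insert(0, "subject_id", p.subject_id)
        t.insert(1, "session", p.session)
        t.insert(2, "brush", p.brush)
        paired_frames.append(t)
    pd.concat(paired_frames, ignore_index=True).to_csv(out / "paired.tsv", **kw)
    analysis.agreement.to_csv(out / "agreement.tsv", **kw)
    analysis.confusion.to_csv(out / "confusion_matrix.tsv", sep="\t")
    analysis.heatmap.to_csv(out / "heatmap_table.tsv", **kw)
    analysis.metrics.to_csv(out / "metrics.tsv", **kw)
    for name, frame in analysis.report.items():
        frame.to_csv(out / f"report_{name}.tsv", **kw)
    hist = pd.DataFrame(
        {
            "bin_low_pct": analysis.summary.histogram_edges[:-1],
            "bin_high_pct": analysis.summary.histogram_edges[1:],
            "n_sessions": analysis.summary.histogram_counts,
        }
    )
    hist.to_csv(out / "matching_histogram.tsv", **kw)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed_derivation": "SeedSequence(master, spawn_key=(subject_index, session_index))",
        "counts": {
            "stream_files": len(stream_files),
            "sessions": len(study),
            "paired_sessions": len(analysis.paired),
            "intervals": int(len(analysis.intervals)),
            "uncoded_intervals": int((analysis.intervals["label"] == UNCODED).sum()),
            "coded_pairs": int(sum(p.n_coded for p in analysis.paired)),
        },
        "summary": {
            "matching_median_pct": analysis.summary.median_pct,
            "matching_min_pct": analysis.summary.min_pct,
            "matching_max_pct": analysis.summary.max_pct,
            "fraction_ge_80": analysis.summary.fraction_ge_80,
            "fraction_ge_90": analysis.summary.fraction_ge_90,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("study written to %s", out)
    return out
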