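"""Synthetic paired VO/MT brushing sessions and whole simulated studies.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without any recorded data:

* the ground-truth brushing path is a semi-Markov walk over the 18 areas
  (truncated-normal dwell times, next area drawn from visit weights with
  the current area excluded), or a deterministic systematic sequence for
  post-instruction behaviour;
* habitual behaviour brushes predominantly vestibular surfaces, neglects
  oral ones and switches frequently; instructed behaviour follows the
  systematic order with near-equal dwell per area and few changes;
* the MT stream is the ground truth sampled at 100 Hz with tracking noise:
  neighbour-sextant confusion near area boundaries, spurious
  micro-transitions that inflate the event count, and brush-angle jitter
  around the occlusal/smooth thresholds (the angle channel is generated as
  a threshold-crossing signal so the angle classifier is exercised);
* the VO stream is the ground truth smoothed the way a human coder codes:
  stretches shorter than the minimum codeable event duration are merged
  into their neighbours, then emitted as timed events.

Ground-truth segment boundaries are laid on the 20 ms grid (the common
period of the 100 Hz tracker and the 50 fps video), so with all noise off
the two sources aggregate to identical interval labels.

All randomness flows from one seed; per-subject/per-session substreams are
derived with ``numpy.random.SeedSequence(master, spawn_key=(subject_index,
session_index))`` so any subset of a study is reproducible independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areas import (
    ALL_AREAS,
    COMBINED_SEXTANT_MEMBERS,
    OCCLUSAL,
    ORAL,
    VESTIBULAR,
    AreaCode,
    parse_area_code,
    sextants_adjacent,
)
from .streams import MT_SAMPLING, VO_SAMPLING, AngleThresholds, SessionStream

#: Opposing-pair lookup: single sextant -> combined closed-jaw sextant code.
_PAIR_OF = {m: c for c, members in COMBINED_SEXTANT_MEMBERS.items() for m in members}

#: Time grid: ground-truth boundaries sit on 20 ms units, MT ticks on 10 ms.
UNIT_S = 0.02
MT_TICKS_PER_UNIT = 2
MT_TICK_S = 0.01

#: Distance of generated angles from the classification threshold (deg);
#: jitter is added on top, so the flip probability near the occlusal/smooth
#: boundary is governed by the noise model's jitter sd.
ANGLE_MARGIN_DEG = 6.0

_MIN_DWELL_S = 0.3


@dataclass(frozen=True)
class BehaviourProfile:
    """Behavioural parameters of the ground-truth brushing walk.

    ``switch_rate`` (expected area changes per minute) is the nominal rate
    realised through ``area_dwell_mean_s``; ``oral_neglect`` downweights
    the oral-surface visit weights by (1 - oral_neglect); a ``sequence``
    makes the walk deterministic (systematic brushing) instead of
    weight-driven.
    """

    area_dwell_mean_s: float = 4.0
    area_dwell_sd_s: float = 2.0
    area_visit_weights: tuple = tuple(
        {OCCLUSAL: 0.5, VESTIBULAR: 1.0, ORAL: 1.0}[a[2:]] for a in ALL_AREAS
    )
    switch_rate: float = 15.0
    oral_neglect: float = 0.7
    combined_code_prob: float = 0.15
    total_duration_s: float = 120.0
    sequence: tuple | None = None

    def __post_init__(self):
        w = np.asarray(self.area_visit_weights, dtype=float)
        if w.size != len(ALL_AREAS) or (w < 0).any() or w.sum() == 0:
            raise ValueError(
                "area_visit_weights must be 18 non-negative weights, not all zero"
            )
        for p in (self.oral_neglect, self.combined_code_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.total_duration_s <= 0 or self.area_dwell_mean_s <= 0:
            raise ValueError("durations must be positive")
        if self.area_dwell_sd_s < 0 or self.switch_rate < 0:
            raise ValueError("spreads and rates must be non-negative")

    def effective_weights(self) -> np.ndarray:
        w = np.asarray(self.area_visit_weights, dtype=float).copy()
        for i, area in enumerate(ALL_AREAS):
            if area[2:] == ORAL:
                w[i] *= 1.0 - self.oral_neglect
        if w.sum() == 0:
            raise ValueError("effective visit weights are all zero")
        return w


@dataclass(frozen=True)
class NoiseModel:
    """Imperfections of the two observation channels.

    The magnitudes are free parameters (no measured values exist for
    them); the defaults are chosen to reproduce the qualitative error
    structure of tracker-vs-observer data: mismatches clustered at
    neighbouring sextants and at the occlusal/smooth decision, and tracker
    event counts roughly double the observer's.
    """

    neighbour_confusion_prob: float = 0.08
    occlusal_smooth_jitter_sd_deg: float = 4.0
    micro_transition_rate: float = 10.0  # spurious MT transitions per minute
    vo_min_event_s: float = 0.5
    boundary_window_s: float = 0.3  # half-width of the confusion zone

    #: Switching rate (changes/min) at which ``micro_transition_rate`` is
    #: calibrated.  Spurious excursions happen where the brush crosses area
    #: borders, so their number scales with the session's true transition
    #: count; at this nominal rate the realised spurious rate equals
    #: ``micro_transition_rate`` per minute.
    nominal_switch_rate: float = 15.0

    def __post_init__(self):
        if not 0 <= self.neighbour_confusion_prob <= 1:
            raise ValueError("neighbour_confusion_prob must lie in [0, 1]")
        for v in (
            self.occlusal_smooth_jitter_sd_deg,
            self.micro_transition_rate,
            self.vo_min_event_s,
            self.boundary_window_s,
        ):
            if v < 0:
                raise ValueError("rates and spreads must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """A noiseless model (and no VO smoothing): VO == MT after binning."""
        return cls(
            neighbour_confusion_prob=0.0,
            occlusal_smooth_jitter_sd_deg=0.0,
            micro_transition_rate=0.0,
            vo_min_event_s=0.0,
        )


@dataclass
class GroundTruth:
    """The simulated truth behind one session, for parameter recovery."""

    labels: np.ndarray  # true area label per 100 Hz tick
    area_durations: dict  # seconds per single-sextant area (even-split)
    event_count: int  # true changes between areas
    segments: list  # (label, duration_s) run-length encoding
    total_duration_s: float


def systematic_sequence() -> list[AreaCode]:
    """The instructed systematic brushing order over all 18 areas.

    Oral surfaces first — lower jaw from the right posterior over the
    anterior to the left posterior, then the upper jaw from the left
    posterior back to the right — followed by the vestibular surfaces from
    the upper right posterior around both arches to the lower right
    posterior, and finally the occlusal surfaces.  Each of the 12 smooth
    areas appears exactly once before any occlusal area.
    """
    oral = ["06", "05", "04", "03", "02", "01"]
    vestibular = ["01", "02", "03", "04", "05", "06"]
    codes = [s + ORAL for s in oral]
    codes += [s + VESTIBULAR for s in vestibular]
    codes += [s + OCCLUSAL for s in vestibular]
    return [parse_area_code(c) for c in codes]


def make_profile(kind: str, brush: str = "manual", **overrides) -> BehaviourProfile:
    """Preset behaviour profiles.

    ``habitual``: frequent switching, vestibular-dominated, oral surfaces
    neglected, occasional closed-jaw combined codes; powered brushing
    switches somewhat more often than manual (as observer studies report).
    ``instructed``: the deterministic systematic sequence with near-equal
    dwell per area and no closed-jaw codes.  Keyword overrides replace any
    profile field.
    """
    if kind == "habitual":
        switch = 14.0 if brush == "manual" else 17.5
        base = BehaviourProfile(
            area_dwell_mean_s=60.0 / switch,
            area_dwell_sd_s=30.0 / switch,
            switch_rate=switch,
            oral_neglect=0.7,
            combined_code_prob=0.15,
            total_duration_s=120.0,
        )
    elif kind == "instructed":
        total = float(overrides.get("total_duration_s", 120.0))
        seq = tuple(a.code for a in systematic_sequence())
        base = BehaviourProfile(
            area_dwell_mean_s=total / len(seq),
            area_dwell_sd_s=0.8,
            area_visit_weights=tuple(1.0 for _ in ALL_AREAS),
            switch_rate=60.0 * (len(seq) - 1) / total,
            oral_neglect=0.0,
            combined_code_prob=0.0,
            total_duration_s=total,
            sequence=seq,
        )
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if overrides:
        base = dataclasses.replace(base, **overrides)
    return base


def _adjacent_sextants(sextant: str) -> list[str]:
    return [
        s
        for s in ("01", "02", "03", "04", "05", "06")
        if s != sextant and sextants_adjacent(s, sextant)
    ]


def _walk_segments(profile: BehaviourProfile, rng) -> list[tuple[str, float]]:
    """Ground-truth (label, duration) runs on the 20 ms unit grid."""
    total_units = int(round(profile.total_duration_s / UNIT_S))
    if profile.sequence is not None:
        labels = list(profile.sequence)
        dwells = rng.normal(
            profile.total_duration_s / len(labels),
            profile.area_dwell_sd_s,
            size=len(labels),
        )
        dwells = np.clip(dwells, _MIN_DWELL_S, None)
        dwells *= profile.total_duration_s / dwells.sum()
    else:
        weights = profile.effective_weights()
        labels, dwell_list = [], []
        t = 0.0
        current = None
        while t < profile.total_duration_s - 1e-9:
            w = weights.copy()
            if current is not None:
                w[ALL_AREAS.index(current)] = 0.0
            if w.sum() == 0:
                w = weights.copy()
            current = ALL_AREAS[rng.choice(len(ALL_AREAS), p=w / w.sum())]
            dwell = max(
                float(rng.normal(profile.area_dwell_mean_s, profile.area_dwell_sd_s)),
                _MIN_DWELL_S,
            )
            dwell = min(dwell, profile.total_duration_s - t)
            labels.append(current)
            dwell_list.append(dwell)
            t += dwell
        dwells = np.asarray(dwell_list)

    # closed-jaw combined-code substitution on vestibular runs
    out_labels = []
    for lab in labels:
        lab = lab if isinstance(lab, str) else str(lab)
        if lab[2:] == VESTIBULAR and lab[:2] in _PAIR_OF:
            if rng.random() < profile.combined_code_prob:
                lab = _PAIR_OF[lab[:2]] + VESTIBULAR
        out_labels.append(lab)

    # quantize run boundaries to whole 20 ms units, conserving the total
    bounds = np.round(np.cumsum(dwells) / UNIT_S).astype(int)
    bounds[-1] = total_units
    unit_counts = np.diff(np.concatenate([[0], bounds]))
    segs = [
        (lab, int(c) * UNIT_S)
        for lab, c in zip(out_labels, unit_counts)
        if c > 0
    ]
    # collapse equal-adjacent runs (possible after substitution/rounding)
    collapsed: list[tuple[str, float]] = []
    for lab, dur in segs:
        if collapsed and collapsed[-1][0] == lab:
            collapsed[-1] = (lab, collapsed[-1][1] + dur)
        else:
            collapsed.append((lab, dur))
    return collapsed


def _segments_to_ticks(segments) -> np.ndarray:
    counts = [int(round(d / MT_TICK_S)) for _, d in segments]
    return np.repeat(
        np.array([lab for lab, _ in segments], dtype=object), counts
    )


def _flip_to_neighbour(label: str, rng) -> str:
    """A neighbouring-sextant label with the same surface (the confusion the
    tracking geometry makes likely near area boundaries)."""
    sextant, surface = label[:2], label[2:]
    if sextant in COMBINED_SEXTANT_MEMBERS:
        member = COMBINED_SEXTANT_MEMBERS[sextant][int(rng.integers(2))]
        return member + VESTIBULAR
    nbrs = _adjacent_sextants(sextant)
    return nbrs[int(rng.integers(len(nbrs)))] + surface


def _apply_mt_noise(labels: np.ndarray, noise: NoiseModel, rng) -> np.ndarray:
    """Sextant-level tracking noise.

    Near every ground-truth boundary a contiguous cluster of samples (a
    binomial draw over the boundary window at the per-sample confusion
    probability) is assigned to a neighbouring sextant — the tracker
    wobbling into the adjacent area while the brush crosses a border.
    Spurious micro-transitions additionally insert short (0.1-0.3 s)
    excursions into an adjacent sextant at random times.
    """
    out = labels.copy()
    n = out.size
    if noise.neighbour_confusion_prob > 0 and n > 1:
        change = np.nonzero(out[1:] != out[:-1])[0] + 1
        window = int(round(noise.boundary_window_s / MT_TICK_S))
        for c in change:
            span = int(rng.binomial(window, noise.neighbour_confusion_prob))
            if span == 0:
                continue
            if rng.random() < 0.5:  # cluster on the leaving side
                lo, hi = max(0, c - span), c
            else:  # or on the entering side
                lo, hi = c, min(n, c + span)
            if hi > lo:
                out[lo:hi] = _flip_to_neighbour(str(out[lo]), rng)
    if noise.micro_transition_rate > 0:
        # spurious excursions cluster at boundary crossings: their expected
        # number scales with the true transition count, calibrated so that
        # behaviour switching at the nominal rate yields micro_transition_rate
        # spurious transitions per minute
        true_change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        per_transition = noise.micro_transition_rate / noise.nominal_switch_rate
        for c in true_change:
            for _ in range(int(rng.poisson(per_transition))):
                pos = int(
                    np.clip(c + rng.integers(-300, 301), 0, n - 1)
                )  # within ~3 s of the crossing
                length = int(rng.integers(10, 31))  # 0.1 - 0.3 s blips
                stop = min(n, pos + length)
                out[pos:stop] = _flip_to_neighbour(str(out[pos]), rng)
    return out


def _split_codes(labels: np.ndarray):
    s = pd.Series(labels.astype(str))
    return s.str[:2].to_numpy(), s.str[2:].to_numpy()


def _angles_for(labels: np.ndarray, thresholds: AngleThresholds, jitter_sd, rng):
    """Threshold-crossing angle signal.

    Occlusal ticks sit below the region threshold by a fixed margin and
    smooth ticks above it.  Jitter is a block-wise (1-2 s) Gaussian
    offset — brush-orientation error persists over seconds, so a
    sufficiently large excursion misclassifies whole intervals rather than
    isolated samples that the majority vote would erase.
    """
    n = labels.size
    sextant, surface = _split_codes(labels)
    anterior = np.isin(sextant, ("02", "05", "25"))
    thr = np.where(anterior, thresholds.anterior_deg, thresholds.molar_deg)
    angles = thr + np.where(
        surface == OCCLUSAL, -ANGLE_MARGIN_DEG, ANGLE_MARGIN_DEG
    )
    if jitter_sd > 0:
        offsets = []
        filled = 0
        while filled < n:
            block = int(rng.integers(100, 201))  # 1 - 2 s
            offsets.append(np.full(min(block, n - filled), rng.normal(0.0, jitter_sd)))
            filled += block
        angles = angles + np.concatenate(offsets)
    regions = np.where(anterior, "anterior", "molar").astype(object)
    return np.clip(angles, 0.0, 90.0), regions


def _classify_ticks(labels, angles, regions, thresholds: AngleThresholds):
    """Per-tick surface (re)classification from the angle channel, the way
    the tracker itself decides occlusal vs smooth.  Combined closed-jaw
    codes stay vestibular; an occlusal-true tick pushed over the threshold
    lands on the vestibular side."""
    sextant, surface = _split_codes(labels)
    combined = np.isin(sextant, list(COMBINED_SEXTANT_MEMBERS))
    thr = np.where(regions == "anterior", thresholds.anterior_deg, thresholds.molar_deg)
    smooth_side = np.where(surface == ORAL, ORAL, VESTIBULAR)
    new_surface = np.where(angles <= thr, OCCLUSAL, smooth_side)
    recoded = np.char.add(sextant.astype("U2"), new_surface.astype("U2"))
    return np.where(combined, labels, recoded.astype(object))


def _smooth_vo_segments(segments, min_event_s: float) -> list[tuple[str, float]]:
    """Human-coder smoothing: runs shorter than the minimum codeable event
    are merged (shortest first) into their longer neighbour."""
    segs = [list(s) for s in segments]
    while len(segs) > 1:
        durs = [d for _, d in segs]
        i = int(np.argmin(durs))
        if durs[i] >= min_event_s:
            break
        if i == 0:
            j = 1
        elif i == len(segs) - 1:
            j = i - 1
        else:
            j = i - 1 if segs[i - 1][1] >= segs[i + 1][1] else i + 1
        segs[j][1] += segs[i][1]
        del segs[i]
        # merging can bring equal labels together
        k = 1
        while k < len(segs):
            if segs[k][0] == segs[k - 1][0]:
                segs[k - 1][1] += segs[k][1]
                del segs[k]
            else:
                k += 1
    return [(lab, dur) for lab, dur in segs]


def simulate_session(
    profile: BehaviourProfile,
    noise: NoiseModel | None = None,
    seed=0,
    subject_id: str = "S001",
    session: str = "baseline",
    brush: str = "manual",
    thresholds: AngleThresholds = AngleThresholds(),
) -> tuple[SessionStream, SessionStream, GroundTruth]:
    """Simulate one brushing session observed by both sources.

    Returns the VO event stream, the MT sample stream (with angle and
    region channels) and the ground truth behind them.  Identical seeds
    give bit-identical output.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    segments = _walk_segments(profile, rng)
    gt_ticks = _segments_to_ticks(segments)
    n = gt_ticks.size

    unit_counts: dict[str, float] = {}
    for lab, dur in segments:
        unit_counts[lab] = unit_counts.get(lab, 0.0) + dur
    from .aggregation import split_combined_durations

    gt = GroundTruth(
        labels=gt_ticks,
        area_durations={
            a: split_combined_durations(unit_counts).get(a, 0.0) for a in ALL_AREAS
        },
        event_count=len(segments) - 1,
        segments=list(segments),
        total_duration_s=n * MT_TICK_S,
    )

    # --- MT: noisy 100 Hz sample stream with angle channel
    mt_labels = _apply_mt_noise(gt_ticks, noise, rng)
    angles, regions = _angles_for(
        mt_labels, thresholds, noise.occlusal_smooth_jitter_sd_deg, rng
    )
    mt_labels = _classify_ticks(mt_labels, angles, regions, thresholds)
    mt_records = pd.DataFrame(
        {
            "t_s": np.round(np.arange(n) * MT_TICK_S, 3),
            "area": mt_labels,
            "angle_deg": np.round(angles, 2),
            "region": regions,
        }
    )
    mt = SessionStream(
        subject_id=subject_id,
        session=session,
        source="MT",
        brush=brush,
        records=mt_records,
        session_start_s=0.0,
        session_end_s=gt.total_duration_s,
        sampling=MT_SAMPLING,
    )

    # --- VO: coder-smoothed timed events
    vo_segs = _smooth_vo_segments(segments, noise.vo_min_event_s)
    starts = np.concatenate([[0.0], np.cumsum([d for _, d in vo_segs])])
    vo_records = pd.DataFrame(
        {
            "start_s": np.round(starts[:-1], 3),
            "end_s": np.round(starts[1:], 3),
            "area": [lab for lab, _ in vo_segs],
        }
    )
    vo = SessionStream(
        subject_id=subject_id,
        session=session,
        source="VO",
        brush=brush,
        records=vo_records,
        session_start_s=0.0,
        session_end_s=gt.total_duration_s,
        sampling=VO_SAMPLING,
    )
    return vo, mt, gt


@dataclass
class SessionRecord:
    subject_id: str
    brush: str
    session: str
    vo: SessionStream
    mt: SessionStream
    ground_truth: GroundTruth
    seed_key: tuple


@dataclass
class StudyData:
    """All simulated streams of one study, plus the seeds that made them."""

    sessions: list
    master_seed: int
    arm_sizes: tuple  # (n_manual, n_powered, n_instructed)

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self):
        return len(self.sessions)


def instructed_split(n_manual: int, n_powered: int, n_instructed: int) -> tuple[int, int]:
    """How many instructed subjects come from each arm (floor-proportional
    to arm size, remainder to the powered arm)."""
    total = n_manual + n_powered
    if total == 0 or n_instructed == 0:
        return 0, 0
    from_manual = min(n_manual, int(np.floor(n_instructed * n_manual / total)))
    from_powered = min(n_powered, n_instructed - from_manual)
    return from_manual, from_powered


def simulate_study(
    n_manual: int = 51,
    n_powered: int = 52,
    n_instructed: int = 46,
    seed: int = 0,
    noise: NoiseModel | None = None,
    profile_overrides: dict | None = None,
    instructed_overrides: dict | None = None,
) -> StudyData:
    """Simulate a whole two-part study.

    Every subject contributes one habitual (baseline) session; the first
    ``n_instructed`` subjects (allocated to arms proportionally) also
    contribute a post-instruction session following the systematic
    sequence.  Per-subject seeds derive deterministically from the master
    seed, so the same master seed reproduces the identical dataset and any
    subject can be regenerated in isolation.
    """
    if min(n_manual, n_powered, n_instructed) < 0:
        raise ValueError("arm sizes must be non-negative")
    noise = NoiseModel() if noise is None else noise
    inst_manual, inst_powered = instructed_split(n_manual, n_powered, n_instructed)
    subjects = []
    for k in range(n_manual):
        subjects.append(("manual", k < inst_manual))
    for k in range(n_powered):
        subjects.append(("powered", k < inst_powered))

    sessions = []
    for idx, (brush, instructed) in enumerate(subjects):
        subject_id = f"S{idx + 1:03d}"
        plan = [("baseline", "habitual")]
        if instructed:
            plan.append(("post_instruction", "instructed"))
        for j, (session, kind) in enumerate(plan):
            overrides = dict(
                (profile_overrides if kind == "habitual" else instructed_overrides)
                or {}
            )
            profile = make_profile(kind, brush=brush, **overrides)
            key = (idx, j)
            ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
            vo, mt, gt = simulate_session(
                profile,
                noise,
                seed=ss,
                subject_id=subject_id,
                session=session,
                brush=brush,
            )
            sessions.append(
                SessionRecord(
                    subject_id=subject_id,
                    brush=brush,
                    session=session,
                    vo=vo,
                    mt=mt,
                    ground_truth=gt,
                    seed_key=key,
                )
            )
    return StudyData(
        sessions=sessions,
        master_seed=int(seed) if np.isscalar(seed) else 0,
        arm_sizes=(n_manual, n_powered, n_instructed),
    )
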