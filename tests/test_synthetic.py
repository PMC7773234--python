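import numpy as np
import pandas as pd
import pytest

import brushtrack as bt
from brushtrack.areas import LOWER_ARCH, ORAL, OCCLUSAL
from brushtrack.synthetic import instructed_split, systematic_sequence


class TestSystematicSequence:
    def test_starts_on_lower_jaw_oral_surface(self):
        first = systematic_sequence()[0]
        assert first.surface == ORAL
        assert first.sextant in LOWER_ARCH

    def test_occlusal_areas_come_last(self):
        seq = systematic_sequence()
        surfaces = [a.surface for a in seq]
        first_occ = surfaces.index(OCCLUSAL)
        assert all(s == OCCLUSAL for s in surfaces[first_occ:])
        assert all(s != OCCLUSAL for s in surfaces[:first_occ])

    def test_first_twelve_are_the_distinct_smooth_areas(self):
        seq = systematic_sequence()
        assert len(seq) >= 12
        first12 = [a.code for a in seq[:12]]
        assert len(set(first12)) == 12
        assert sorted(first12) == sorted(bt.SMOOTH_AREAS)

    def test_covers_all_18_areas_once(self):
        seq = [a.code for a in systematic_sequence()]
        assert len(seq) == 18
        assert sorted(seq) == sorted(bt.ALL_AREAS)


class TestProfiles:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            bt.make_profile("erratic")

    def test_overrides_propagate(self):
        p = bt.make_profile("habitual", total_duration_s=45.0, oral_neglect=0.2)
        assert p.total_duration_s == 45.0
        assert p.oral_neglect == 0.2

    def test_instructed_profile_follows_sequence(self):
        p = bt.make_profile("instructed")
        assert p.sequence is not None
        assert list(p.sequence) == [a.code for a in systematic_sequence()]
        assert p.combined_code_prob == 0.0

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            bt.BehaviourProfile(area_visit_weights=tuple([0.0] * 18))

    def test_oral_neglect_downweights_oral_areas(self):
        p = bt.make_profile("habitual")
        w = p.effective_weights()
        oral = [w[i] for i, a in enumerate(bt.ALL_AREAS) if a[2:] == "03"]
        vest = [w[i] for i, a in enumerate(bt.ALL_AREAS) if a[2:] == "02"]
        assert max(oral) < min(vest)


class TestSimulateSession:
    def test_determinism(self):
        p = bt.make_profile("habitual", total_duration_s=30.0)
        vo1, mt1, gt1 = bt.simulate_session(p, bt.NoiseModel(), seed=5)
        vo2, mt2, gt2 = bt.simulate_session(p, bt.NoiseModel(), seed=5)
        pd.testing.assert_frame_equal(vo1.records, vo2.records)
        pd.testing.assert_frame_equal(mt1.records, mt2.records)
        assert (gt1.labels == gt2.labels).all()

    def test_different_seeds_differ(self):
        p = bt.make_profile("habitual", total_duration_s=30.0)
        _, mt1, _ = bt.simulate_session(p, bt.NoiseModel(), seed=5)
        _, mt2, _ = bt.simulate_session(p, bt.NoiseModel(), seed=6)
        assert not mt1.records["area"].equals(mt2.records["area"])

    def test_zero_noise_sources_aggregate_identically(self, zero_noise_session):
        vo, mt, _ = zero_noise_session
        paired = bt.pair_session(vo, mt, thresholds=bt.AngleThresholds())
        assert bt.matching_proportion(paired) == 100.0

    def test_ground_truth_durations_conserve_total(self):
        rng = np.random.default_rng(10)
        for kind in ("habitual", "instructed"):
            for _ in range(5):
                total = float(rng.integers(20, 90))
                p = bt.make_profile(kind, total_duration_s=total)
                _, _, gt = bt.simulate_session(
                    p, bt.NoiseModel(), seed=int(rng.integers(1 << 30))
                )
                assert sum(gt.area_durations.values()) == pytest.approx(
                    total, abs=0.011
                )
                assert gt.total_duration_s == pytest.approx(total, abs=0.011)

    def test_concentrated_weights_concentrate_time(self):
        w = [0.0] * 18
        w[bt.ALL_AREAS.index("0302")] = 1.0
        # excluding the current area would leave nothing to draw, so give a
        # tiny weight elsewhere
        w[bt.ALL_AREAS.index("0202")] = 1e-6
        p = bt.make_profile(
            "habitual",
            area_visit_weights=tuple(w),
            oral_neglect=0.0,
            combined_code_prob=0.0,
            total_duration_s=60.0,
        )
        _, _, gt = bt.simulate_session(p, bt.NoiseModel.zero(), seed=3)
        share = (
            gt.area_durations["0302"] + gt.area_durations["0202"]
        ) / sum(gt.area_durations.values())
        assert share >= 0.99

    def test_streams_lie_within_session_span(self, noisy_session):
        vo, mt, _ = noisy_session
        assert vo.records["end_s"].max() <= vo.session_end_s + 1e-9
        assert mt.records["t_s"].max() < mt.session_end_s

    def test_vo_has_no_events_shorter_than_minimum(self):
        p = bt.make_profile("habitual", total_duration_s=60.0)
        noise = bt.NoiseModel(vo_min_event_s=0.5)
        vo, _, _ = bt.simulate_session(p, noise, seed=8)
        durations = vo.records["end_s"] - vo.records["start_s"]
        assert durations.min() >= 0.5 - 1e-9

    def test_mt_angle_channel_encodes_surface(self, zero_noise_session):
        _, mt, _ = zero_noise_session
        rec = mt.records
        thr = np.where(rec["region"] == "anterior", 13.0, 20.0)
        occ = rec["area"].str[2:] == "01"
        assert (rec.loc[occ, "angle_deg"] <= thr[occ]).all()
        assert (rec.loc[~occ, "angle_deg"] > thr[~occ]).all()


class TestNoiseEffects:
    def test_micro_transitions_monotonically_inflate_events(self):
        p = bt.make_profile("habitual", total_duration_s=40.0)
        rates = [0.0, 10.0, 30.0]
        mean_events = []
        for rate in rates:
            noise = bt.NoiseModel(
                neighbour_confusion_prob=0.0,
                occlusal_smooth_jitter_sd_deg=0.0,
                micro_transition_rate=rate,
            )
            counts = []
            for seed in range(40):
                _, mt, _ = bt.simulate_session(p, noise, seed=seed)
                labels = mt.records["area"].to_numpy()
                counts.append(int(np.sum(labels[1:] != labels[:-1])))
            mean_events.append(np.mean(counts))
        assert mean_events[0] <= mean_events[1] <= mean_events[2]

    def test_mt_events_exceed_vo_events_with_micro_transitions(self):
        p = bt.make_profile("habitual", total_duration_s=60.0)
        noise = bt.NoiseModel()
        mt_ev, vo_ev = [], []
        for seed in range(25):
            vo, mt, _ = bt.simulate_session(p, noise, seed=seed)
            paired_cfg = bt.AngleThresholds()
            vo_int = bt.bin_stream(vo)
            mt_int = bt.bin_stream(mt, thresholds=paired_cfg)
            vo_ev.append(bt.count_events(vo_int["label"]))
            mt_ev.append(bt.count_events(mt_int["label"]))
        assert np.median(mt_ev) > np.median(vo_ev)

    def test_zero_noise_recovers_ground_truth_durations(self):
        p = bt.make_profile("habitual", total_duration_s=50.0)
        _, mt, gt = bt.simulate_session(p, bt.NoiseModel.zero(), seed=44)
        intervals = bt.bin_stream(mt, thresholds=bt.AngleThresholds())
        durations = bt.area_durations(intervals)
        for area in bt.ALL_AREAS:
            assert durations.durations[area] == pytest.approx(
                gt.area_durations[area], abs=0.5
            )

    def test_instructed_beats_habitual_tsi_in_the_majority_of_seed_pairs(self):
        wins = 0
        n_pairs = 60
        for seed in range(n_pairs):
            tsis = {}
            for kind in ("habitual", "instructed"):
                p = bt.make_profile(kind, total_duration_s=120.0)
                _, mt, _ = bt.simulate_session(p, bt.NoiseModel.zero(), seed=seed)
                intervals = bt.bin_stream(mt, thresholds=bt.AngleThresholds())
                tsis[kind] = bt.tsi(intervals).TSI
            if tsis["instructed"] > tsis["habitual"]:
                wins += 1
        assert wins > n_pairs / 2

    def test_habitual_brushing_neglects_oral_surfaces(self):
        oral_frac, vest_frac = [], []
        for seed in range(50):
            p = bt.make_profile("habitual", total_duration_s=40.0)
            _, _, gt = bt.simulate_session(p, bt.NoiseModel.zero(), seed=seed)
            total = sum(gt.area_durations.values())
            oral_frac.append(
                sum(v for a, v in gt.area_durations.items() if a[2:] == "03") / total
            )
            vest_frac.append(
                sum(v for a, v in gt.area_durations.items() if a[2:] == "02") / total
            )
        assert np.mean(oral_frac) < np.mean(vest_frac)


class TestSimulateStudy:
    def test_session_counts_at_study_arm_sizes(self):
        study = bt.simulate_study(
            51, 52, 46, seed=1,
            profile_overrides={"total_duration_s": 4.0},
            instructed_overrides={"total_duration_s": 4.0},
        )
        sessions = list(study)
        baseline = [s for s in sessions if s.session == "baseline"]
        post = [s for s in sessions if s.session == "post_instruction"]
        assert len(baseline) == 103
        assert len(post) == 46
        assert sum(1 for s in post if s.brush == "manual") == 22
        assert sum(1 for s in post if s.brush == "powered") == 24

    def test_single_subject_study(self):
        study = bt.simulate_study(
            1, 0, 0, seed=2, profile_overrides={"total_duration_s": 10.0}
        )
        assert len(study) == 1
        rec = study.sessions[0]
        assert rec.vo.source == "VO" and rec.mt.source == "MT"

    def test_same_master_seed_reproduces_study(self):
        kw = dict(profile_overrides={"total_duration_s": 8.0})
        s1 = bt.simulate_study(2, 2, 1, seed=7, **kw)
        s2 = bt.simulate_study(2, 2, 1, seed=7, **kw)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.mt.records, b.mt.records)
            pd.testing.assert_frame_equal(a.vo.records, b.vo.records)

    def test_subject_substream_is_independent_of_study_size(self):
        kw = dict(profile_overrides={"total_duration_s": 8.0})
        small = bt.simulate_study(1, 0, 0, seed=7, **kw)
        large = bt.simulate_study(3, 2, 0, seed=7, **kw)
        pd.testing.assert_frame_equal(
            small.sessions[0].mt.records, large.sessions[0].mt.records
        )

    def test_instructed_split_matches_arm_proportions(self):
        assert instructed_split(51, 52, 46) == (22, 24)
        assert instructed_split(10, 10, 0) == (0, 0)
        assert instructed_split(0, 10, 5) == (0, 5)

    def test_negative_arms_rejected(self):
        with pytest.raises(ValueError):
            bt.simulate_study(-1, 0, 0, seed=0)
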