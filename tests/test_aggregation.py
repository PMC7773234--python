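from collections import Counter

import numpy as np
import pandas as pd
import pytest

import brushtrack as bt
from brushtrack.aggregation import (
    apply_angle_classifier,
    bin_samples,
    majority_label,
    threshold_sensitivity,
)
from brushtrack.streams import AngleThresholds


def brute_force_majority(labels):
    """Independent oracle: count with Counter, break ties by first scan hit."""
    coded = [l for l in labels if l != bt.UNCODED]
    if not coded:
        return bt.UNCODED
    counts = Counter(coded)
    top = max(counts.values())
    for l in coded:  # first occurrence among the top-count labels wins
        if counts[l] == top:
            return l


class TestMajorityVote:
    def test_plain_majority(self):
        labels = ["0102"] * 30 + ["0202"] * 20
        assert majority_label(labels)[0] == "0102"

    def test_tie_broken_by_first_occurrence_in_time(self):
        labels = ["0202"] * 25 + ["0102"] * 25
        assert majority_label(labels)[0] == "0202"
        labels = ["0202", "0102"] * 25  # interleaved, 0202 first
        assert majority_label(labels)[0] == "0202"

    def test_identity_and_support(self):
        label, support = majority_label(["0303"] * 50)
        assert label == "0303" and support == 50

    def test_empty_or_all_uncoded_yields_sentinel(self):
        assert majority_label([])[0] == bt.UNCODED
        assert majority_label([bt.UNCODED] * 10)[0] == bt.UNCODED

    def test_uncoded_samples_do_not_vote(self):
        labels = [bt.UNCODED] * 30 + ["0102"] * 5
        assert majority_label(labels)[0] == "0102"

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(0)
        pool = ["0102", "0202", "0103", bt.UNCODED]
        for _ in range(300):
            labels = list(rng.choice(pool, size=int(rng.integers(1, 60))))
            assert majority_label(labels)[0] == brute_force_majority(labels)

    def test_tie_break_ignores_later_permutations(self):
        # permuting occurrences after the first of each tied label never
        # changes the winner
        base = ["0102", "0202", "0202", "0102", "0102", "0202"]
        rng = np.random.default_rng(1)
        winner = majority_label(base)[0]
        for _ in range(20):
            tail = base[2:]
            rng.shuffle(tail)
            assert majority_label(base[:2] + tail)[0] == winner


class TestBinStream:
    def test_whole_session_tiling(self, zero_noise_session):
        _, mt, _ = zero_noise_session
        intervals = bt.bin_stream(mt, bin_s=0.5)
        assert len(intervals) == 120  # 60 s at 0.5 s
        lengths = intervals["end_s"] - intervals["start_s"]
        assert np.allclose(lengths.sum(), mt.duration_s)

    def test_trailing_partial_interval_kept(self):
        t = np.arange(0, 60.2, 0.01)
        samples = pd.DataFrame({"t_s": t, "area": ["0102"] * t.size})
        intervals = bin_samples(samples, 0.5, session_end_s=60.2)
        assert len(intervals) == 121
        last = intervals.iloc[-1]
        assert last["end_s"] - last["start_s"] == pytest.approx(0.2)
        assert last["label"] == "0102"

    def test_alternating_labels_resolved_by_tie_break(self):
        t = np.arange(0, 2.0, 0.01)
        labels = np.where(np.arange(t.size) % 2 == 0, "0102", "0202").astype(object)
        samples = pd.DataFrame({"t_s": t, "area": labels})
        intervals = bin_samples(samples, 0.5, session_end_s=2.0)
        assert (intervals["label"] == "0102").all()  # first in every bin

    def test_bin_contents_match_brute_force(self):
        rng = np.random.default_rng(7)
        pool = np.array(["0102", "0202", "0601", bt.UNCODED], dtype=object)
        for _ in range(50):
            n = int(rng.integers(10, 400))
            t = np.arange(n) * 0.01
            labels = rng.choice(pool, size=n)
            samples = pd.DataFrame({"t_s": t, "area": labels})
            intervals = bin_samples(samples, 0.5, session_end_s=n * 0.01)
            for _, row in intervals.iterrows():
                mask = (t >= row["start_s"]) & (t < row["end_s"])
                assert row["label"] == brute_force_majority(labels[mask])

    def test_aggregation_never_increases_transitions(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 500))
            # runs of random length make realistic label paths
            labels = []
            while len(labels) < n:
                labels += [str(rng.choice(["0102", "0202", "0103"]))] * int(
                    rng.integers(1, 80)
                )
            labels = np.array(labels[:n], dtype=object)
            samples = pd.DataFrame({"t_s": np.arange(n) * 0.01, "area": labels})
            intervals = bin_samples(samples, 0.5, session_end_s=n * 0.01)
            raw_trans = int(np.sum(labels[1:] != labels[:-1]))
            agg = intervals["label"].to_numpy()
            agg_trans = int(np.sum(agg[1:] != agg[:-1]))
            assert agg_trans <= raw_trans

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_samples(pd.DataFrame({"t_s": [0.0], "area": ["0102"]}), 0.0)


class TestAngleClassifier:
    @pytest.mark.parametrize(
        "angle,region,side,expected",
        [
            (25.0, "molar", "vestibular_side", "02"),
            (15.0, "molar", "vestibular_side", "01"),
            (15.0, "molar", "oral_side", "01"),
            (15.0, "anterior", "oral_side", "03"),
            (20.0, "molar", "vestibular_side", "01"),  # boundary inclusive
            (13.0, "anterior", "oral_side", "01"),
            (5.0, "anterior", "vestibular_side", "01"),
        ],
    )
    def test_threshold_rule(self, angle, region, side, expected):
        assert bt.classify_surface_from_angle(angle, region, side=side) == expected

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bt.classify_surface_from_angle(95.0, "molar")
        with pytest.raises(ValueError):
            bt.classify_surface_from_angle(-1.0, "molar")

    def test_vectorized_classifier_matches_scalar(self):
        rng = np.random.default_rng(3)
        n = 200
        sextants = rng.choice(["01", "02", "05", "06"], n)
        surfaces = rng.choice(["01", "02", "03"], n)
        angles = rng.uniform(0, 40, n)
        regions = np.where(np.isin(sextants, ["02", "05"]), "anterior", "molar")
        samples = pd.DataFrame(
            {
                "t_s": np.arange(n) * 0.01,
                "area": [s + f for s, f in zip(sextants, surfaces)],
                "angle_deg": angles,
                "region": regions,
            }
        )
        thresholds = AngleThresholds()
        out = apply_angle_classifier(samples, thresholds)["area"].to_numpy()
        for i in range(n):
            side = "oral_side" if surfaces[i] == "03" else "vestibular_side"
            expected = sextants[i] + bt.classify_surface_from_angle(
                angles[i], regions[i], thresholds, side
            )
            assert out[i] == expected

    def test_sensitivity_probe_reports_changed_fraction(self, noisy_session):
        _, mt, _ = noisy_session
        report = threshold_sensitivity(mt.records, delta_deg=3.0)
        assert set(report) == {"raised", "lowered"}
        for frac in report.values():
            assert 0.0 <= frac <= 1.0


class TestPairStreams:
    def test_identical_sequences_pair_perfectly(self, zero_noise_session):
        vo, mt, _ = zero_noise_session
        paired = bt.pair_session(vo, mt, thresholds=AngleThresholds())
        assert (paired.table["vo_label"] == paired.table["mt_label"]).all()

    def test_surplus_intervals_dropped_with_warning(self, make_intervals):
        vo = make_intervals(["0102"] * 12)
        mt = make_intervals(["0102"] * 10)
        with pytest.warns(UserWarning, match="dropping 2"):
            paired = bt.pair_streams(vo, mt)
        assert len(paired.table) == 10
        assert paired.dropped_vo == 2

    def test_uncoded_interval_excluded_from_denominator(self, make_intervals):
        vo = make_intervals(["0102", bt.UNCODED, "0202"])
        mt = make_intervals(["0102", "0102", "0202"])
        paired = bt.pair_streams(vo, mt)
        assert paired.n_coded == 2
        assert bt.matching_proportion(paired) == 100.0

    def test_metadata_mismatch_raises(self, make_intervals):
        from brushtrack.errors import PairingError

        with pytest.raises(PairingError, match="subject_id"):
            bt.pair_streams(
                make_intervals(["0102"]),
                make_intervals(["0102"]),
                vo_meta={"subject_id": "S001", "session": "baseline"},
                mt_meta={"subject_id": "S002", "session": "baseline"},
            )


class TestSplitCombined:
    def test_even_split(self):
        assert bt.split_combined_durations({"1602": 4.0}) == {
            "0102": 2.0,
            "0602": 2.0,
        }

    def test_empty(self):
        assert bt.split_combined_durations({}) == {}

    def test_split_adds_to_existing(self):
        out = bt.split_combined_durations({"2502": 1.0, "0202": 1.0})
        assert out == {"0202": 1.5, "0502": 0.5}

    def test_total_conserved_on_random_inputs(self):
        rng = np.random.default_rng(9)
        pool = list(bt.ALL_AREAS) + list(bt.COMBINED_CODES)
        for _ in range(50):
            durations = {
                str(a): float(rng.uniform(0, 10))
                for a in rng.choice(pool, size=int(rng.integers(1, 10)), replace=False)
            }
            out = bt.split_combined_durations(durations)
            assert sum(out.values()) == pytest.approx(sum(durations.values()))
            assert all(a[:2] in ("01", "02", "03", "04", "05", "06") for a in out)

    def test_unknown_combined_code_rejected(self):
        with pytest.raises(ValueError):
            bt.split_combined_durations({"9902": 1.0})
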