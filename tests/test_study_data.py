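"""Domain types, CSV round-trips, scoring, binarization and grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import readerstudy as rs
from readerstudy.simulate import OBSERVER_EXPERIENCE_TABLE


def make_record(observer="o1", patient="p1", slice_id="p1_s1", conf=3, session=1,
                box=(10.0, 20.0, 50.0, 60.0)):
    return rs.AnnotationRecord(
        observer_id=observer, patient_id=patient, slice_id=slice_id,
        box=box, confidence=conf, session=session,
    )


annotation_records = st.builds(
    make_record,
    observer=st.sampled_from(["o1", "o2", "o3"]),
    patient=st.sampled_from(["p1", "p2"]),
    slice_id=st.sampled_from(["p1_s1", "p1_s2", "p2_s1"]),
    conf=st.integers(1, 5),
    session=st.sampled_from([1, 2]),
    box=st.tuples(
        st.integers(0, 100), st.integers(0, 100),
        st.integers(101, 200), st.integers(101, 200),
    ).map(lambda t: tuple(float(v) for v in t)),
)


class TestAnnotationIO:
    def test_three_row_roundtrip(self, tmp_path):
        records = [make_record(conf=c) for c in (1, 3, 5)]
        path = tmp_path / "ann.csv"
        rs.write_annotations(records, path)
        assert rs.read_annotations(path) == records

    def test_confidence_out_of_range_rejected(self, tmp_path):
        with pytest.raises(rs.StudyDataError, match="confidence"):
            make_record(conf=6)
        # ... also when it arrives via a file
        path = tmp_path / "ann.csv"
        rs.write_annotations([make_record()], path)
        text = path.read_text().replace(",3,", ",6,")
        path.write_text(text)
        with pytest.raises(rs.StudyDataError, match=":2"):
            rs.read_annotations(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "ann.csv"
        rs.write_annotations([make_record(), make_record(conf=2)], path)
        lines = path.read_text().splitlines()
        lines[2] = "only,three,fields"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(rs.StudyDataError, match=":3"):
            rs.read_annotations(path)

    def test_degenerate_box_rejected(self):
        with pytest.raises(rs.StudyDataError, match="box"):
            make_record(box=(50.0, 20.0, 50.0, 60.0))

    @settings(max_examples=50, deadline=None)
    @given(records=st.lists(annotation_records, max_size=25))
    def test_roundtrip_property(self, tmp_path_factory, records):
        """write∘read is the identity and the bytes are stable."""
        path = tmp_path_factory.mktemp("rt") / "ann.csv"
        rs.write_annotations(records, path)
        back = rs.read_annotations(path)
        assert back == records
        first = path.read_bytes()
        rs.write_annotations(back, path)
        assert path.read_bytes() == first

    def test_observer_and_reference_roundtrip(self, tmp_path, fixture_study):
        opath, rpath = tmp_path / "obs.csv", tmp_path / "ref.csv"
        rs.write_observers(fixture_study.profiles, opath)
        assert tuple(rs.read_observers(opath)) == fixture_study.profiles
        rs.write_reference(fixture_study.reference, rpath)
        back = rs.read_reference(rpath)
        pd.testing.assert_series_equal(
            back.slice_labels, fixture_study.reference.slice_labels
        )
        pd.testing.assert_series_equal(
            back.slice_to_patient, fixture_study.reference.slice_to_patient
        )


class TestSliceScores:
    def test_max_rule_and_default_zero(self):
        records = [
            make_record(conf=2, slice_id="p1_s1"),
            make_record(conf=4, slice_id="p1_s1"),
        ]
        m = rs.slice_scores(records, ["p1_s1", "p1_s2"], ["o1"])
        assert m.scores.at["p1_s1", "o1"] == 4  # max over the two boxes
        assert m.scores.at["p1_s2", "o1"] == 0  # unannotated slice

    def test_unknown_ids_rejected(self):
        with pytest.raises(rs.StudyDataError, match="unknown slice"):
            rs.slice_scores([make_record()], ["other"], ["o1"])
        with pytest.raises(rs.StudyDataError, match="unknown observer"):
            rs.slice_scores([make_record()], ["p1_s1"], ["someone"])

    def test_sessions_are_separated(self):
        records = [make_record(conf=5, session=2)]
        m1 = rs.slice_scores(records, ["p1_s1"], ["o1"], session=1)
        m2 = rs.slice_scores(records, ["p1_s1"], ["o1"], session=2)
        assert m1.scores.at["p1_s1", "o1"] == 0
        assert m2.scores.at["p1_s1", "o1"] == 5

    def test_matches_brute_force_per_cell(self, rng):
        slices = [f"p1_s{i}" for i in range(10)]
        observers = [f"o{j}" for j in range(5)]
        records = [
            make_record(
                observer=rng.choice(observers),
                slice_id=rng.choice(slices),
                conf=int(rng.integers(1, 6)),
            )
            for _ in range(60)
        ]
        m = rs.slice_scores(records, slices, observers)
        for s in slices:
            for o in observers:
                expected = max(
                    (r.confidence for r in records
                     if r.slice_id == s and r.observer_id == o),
                    default=0,
                )
                assert m.scores.at[s, o] == expected


class TestBinarize:
    @pytest.mark.parametrize(
        "threshold,score,expected",
        [
            (40, 2, True),   # 2/5 = 40% certain meets an "at least 40%" rule
            (0, 0, False),   # no annotation is never positive
            (80, 3, False),  # 60% < 80%
            (0, 1, True),    # 0% threshold: any annotation is positive
            (100, 5, True),
        ],
    )
    def test_threshold_rule(self, threshold, score, expected):
        m = rs.ScoreMatrix(pd.DataFrame({"o1": [score]}, index=["p1_s1"]))
        profile = rs.ObserverProfile(
            observer_id="o1", years_experience=1, cine_cases=0,
            adhesion_cases=0, clinical_threshold_pct=threshold,
        )
        labels = rs.binarize_scores(m, [profile])
        assert labels.labels.at["p1_s1", "o1"] == expected

    def test_missing_profile_rejected(self):
        m = rs.ScoreMatrix(pd.DataFrame({"o1": [1]}, index=["p1_s1"]))
        with pytest.raises(rs.StudyDataError, match="missing observer profile"):
            rs.binarize_scores(m, [])

    def test_positives_monotone_in_threshold(self, rng):
        scores = pd.DataFrame(
            rng.integers(0, 6, size=(40, 1)), index=[f"s{i}" for i in range(40)],
            columns=["o1"],
        )
        m = rs.ScoreMatrix(scores)
        counts = []
        for thr in (0, 20, 40, 60, 80, 100):
            p = rs.ObserverProfile(
                observer_id="o1", years_experience=1, cine_cases=0,
                adhesion_cases=0, clinical_threshold_pct=thr,
            )
            counts.append(int(rs.binarize_scores(m, [p]).labels["o1"].sum()))
        assert counts == sorted(counts, reverse=True)


# expected low/high sides per observer from the reference experience table
EXPECTED_GROUPS = {
    "obs04": ("high", "high", "high"),
    "obs05": ("high", "high", "low"),
    "obs06": ("high", "high", "low"),
    "obs07": ("high", "high", "high"),
    "obs08": ("high", "high", "high"),
    "obs09": ("high", "low", "low"),
    "obs10": ("low", "low", "high"),
    "obs11": ("low", "low", "low"),
    "obs12": ("low", "low", "low"),
    "obs13": ("low", "low", "low"),
    "obs14": ("low", "high", "low"),
    "obs15": ("low", "low", "high"),
}


class TestGrouping:
    def test_default_cutoffs_reproduce_study_table(self):
        """Every observer row of the reference experience table lands in its documented low/high groups."""
        for obs_id, years, cine, adhesion, thr, consensus in OBSERVER_EXPERIENCE_TABLE:
            profile = rs.ObserverProfile(
                observer_id=obs_id, years_experience=years, cine_cases=cine,
                adhesion_cases=adhesion, clinical_threshold_pct=thr,
                is_consensus=consensus,
            )
            g = rs.assign_groups(profile)
            if consensus:
                assert g.groups == ("consensus",)
            else:
                assert (g.year, g.cine, g.adhesion) == EXPECTED_GROUPS[obs_id]

    def test_worked_example_observer15(self):
        profile = rs.ObserverProfile(
            observer_id="obs15", years_experience=4, cine_cases=20,
            adhesion_cases=20, clinical_threshold_pct=60,
        )
        assert rs.assign_groups(profile).groups == (
            "low-year", "low-cine", "high-adhesion",
        )

    def test_zero_experience_is_all_low(self):
        profile = rs.ObserverProfile(
            observer_id="x", years_experience=0, cine_cases=0,
            adhesion_cases=0, clinical_threshold_pct=0,
        )
        g = rs.assign_groups(profile)
        assert (g.year, g.cine, g.adhesion) == ("low", "low", "low")

    def test_group_members_partitions(self, fixture_study):
        members = rs.group_members(fixture_study.profiles)
        assert len(members["consensus"]) == 3
        for dim in ("year", "cine", "adhesion"):
            assert (
                sorted(members[f"low-{dim}"] + members[f"high-{dim}"])
                == sorted(o for o in fixture_study.observers
                          if o not in members["consensus"])
            )


class TestCohort:
    @pytest.mark.parametrize(
        "n,n_neg,pct",
        [(64, 15, 23), (10, 3, 30), (4, 0, 0)],
    )
    def test_negative_percentage(self, n, n_neg, pct):
        labels = {f"p{i}": i >= n_neg for i in range(n)}
        summary = rs.cohort_summary(labels)
        assert summary == {"n_patients": n, "n_negative": n_neg, "pct_negative": pct}

    def test_empty_cohort_rejected(self):
        with pytest.raises(rs.StudyDataError, match="empty"):
            rs.cohort_summary({})

    def test_percentages_partition(self):
        labels = {f"p{i}": i >= 15 for i in range(64)}
        summary = rs.cohort_summary(labels)
        pct_pos = round(100 * (64 - 15) / 64)  # 77; 23 + 77 = 100
        assert summary["pct_negative"] + pct_pos == 100


class TestStratifiedSample:
    LABELS = {f"p{i}": i >= 15 for i in range(64)}  # 15 negative, 49 positive

    def test_fraction_one_returns_all(self):
        assert rs.stratified_sample(self.LABELS, 1.0, seed=0) == list(self.LABELS)

    def test_ceiling_rounding_counts(self):
        sample = rs.stratified_sample(self.LABELS, 0.2, seed=1)
        n_neg = sum(not self.LABELS[p] for p in sample)
        n_pos = sum(self.LABELS[p] for p in sample)
        assert (n_neg, n_pos) == (3, 10)  # ceil(3.0), ceil(9.8)

    def test_floor_rounding_counts(self):
        sample = rs.stratified_sample(self.LABELS, 0.2, seed=1, rounding="floor")
        assert len(sample) == 3 + 9

    def test_deterministic_given_seed(self):
        a = rs.stratified_sample(self.LABELS, 0.3, seed=7)
        b = rs.stratified_sample(self.LABELS, 0.3, seed=7)
        assert a == b

    def test_fraction_out_of_range(self):
        with pytest.raises(rs.StudyDataError, match="fraction"):
            rs.stratified_sample(self.LABELS, 1.5, seed=0)
        with pytest.raises(rs.StudyDataError, match="fraction"):
            rs.stratified_sample(self.LABELS, 0.0, seed=0)
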