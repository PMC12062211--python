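"""Reference standard, cohort and case-control construction."""

import numpy as np
import pandas as pd
import pytest

import calibdrift as cd


def test_window_rule_forced(exam_builder):
    """30 months pre-diagnosis is a case at a 36-month window; 40 months is
    a control; both endpoints inclusive."""
    exams = exam_builder(
        [
            dict(exam_id="E1", participant_id="P1", exam_year=2014, exam_month=1,
                 diagnosis_year=2016, diagnosis_month=7, cancer_type="invasive"),  # 30 months
            dict(exam_id="E2", participant_id="P2", exam_year=2013, exam_month=3,
                 diagnosis_year=2016, diagnosis_month=7, cancer_type="invasive"),  # 40 months
            dict(exam_id="E3", participant_id="P3", exam_year=2014, exam_month=1),
            dict(exam_id="E4", participant_id="P4", exam_year=2019, exam_month=12),
        ]
    )
    ds = cd.label_exams(exams, 36, collection_end=(2019, 12))
    labels = ds.labels
    assert labels["E1"] == "case"
    assert labels["E2"] == "control"
    assert labels["E3"] == "control"
    # E4 is within 36 months of the collection end: healthy status
    # unconfirmable, excluded entirely
    assert "E4" not in labels.index


def test_exclusion_depends_on_window(exam_builder):
    exams = exam_builder(
        [
            dict(exam_id="E1", participant_id="P1", exam_year=2018, exam_month=6),
            dict(exam_id="E2", participant_id="P2", exam_year=2010, exam_month=6),
        ]
    )
    short = cd.label_exams(exams, 12, collection_end=(2019, 12))
    assert set(short.labels.index) == {"E1", "E2"}
    long = cd.label_exams(exams, 36, collection_end=(2019, 12))
    assert set(long.labels.index) == {"E2"}


def test_diagnosis_before_first_exam_errors(exam_builder):
    exams = exam_builder(
        [
            dict(exam_id="E1", participant_id="P1", exam_year=2015, exam_month=6,
                 diagnosis_year=2014, diagnosis_month=1, cancer_type="invasive"),
        ]
    )
    with pytest.raises(cd.DataIntegrityError, match="P1"):
        cd.label_exams(exams, 36, collection_end=(2019, 12))


def test_label_monotonicity(default_exams):
    """Enlarging the window never flips a case to control: among exams
    retained under every window, case sets nest 12 ⊆ 24 ⊆ 36 ⊆ 48."""
    end = (int(default_exams["exam_year"].max()), 12)
    case_sets = {}
    common = None
    for w in (12, 24, 36, 48):
        ds = cd.label_exams(default_exams, w, collection_end=end)
        ids = set(ds.labels.index)
        common = ids if common is None else common & ids
        case_sets[w] = set(ds.labels.index[ds.case_mask])
    assert case_sets[12] & common <= case_sets[24] & common
    assert case_sets[24] & common <= case_sets[36] & common
    assert case_sets[36] & common <= case_sets[48] & common


def test_cohort_filter_and_partition(exam_builder, default_exams):
    rows = [
        dict(exam_id=f"E{i}", participant_id=f"P{i}", exam_year=2017, exam_month=i + 1)
        for i in range(5)
    ] + [
        dict(exam_id=f"F{i}", participant_id=f"Q{i}", exam_year=2015, exam_month=i + 1)
        for i in range(3)
    ]
    exams = exam_builder(rows)
    cohort = cd.build_cohort(exams, 2017, 36, collection_end=(2021, 12))
    assert cohort.n_exams == 5

    # per-year cohorts partition the labelled exams
    labeled = cd.label_exams(default_exams, 36)
    end = (int(default_exams["exam_year"].max()), 12)
    total = 0
    for year in sorted(labeled.exams["exam_year"].unique()):
        total += cd.build_cohort(default_exams, int(year), 36, collection_end=end).n_exams
    assert total == labeled.n_exams


def test_cohort_empty_year_warns(exam_builder):
    exams = exam_builder([dict(exam_id="E1", participant_id="P1", exam_year=2010)])
    with pytest.warns(UserWarning, match="no labelled exams"):
        cd.build_cohort(exams, 2009, 36, collection_end=(2015, 12))


def _cc_population(n_healthy=80, seed=0):
    """Synthetic pool: cases in two screening years plus ample healthy."""
    rows = [
        # PA: diagnosed 2018-03; case exams 2017-05 (10m) and 2015-05 (34m)
        dict(exam_id="A1", participant_id="PA", exam_year=2015, exam_month=5,
             diagnosis_year=2018, diagnosis_month=3, cancer_type="invasive"),
        dict(exam_id="A2", participant_id="PA", exam_year=2017, exam_month=5,
             diagnosis_year=2018, diagnosis_month=3, cancer_type="invasive"),
        # PB: diagnosed 2016-08; case exam 2016-02 (6m)
        dict(exam_id="B1", participant_id="PB", exam_year=2016, exam_month=2,
             diagnosis_year=2016, diagnosis_month=8, cancer_type="invasive"),
        # PC: diagnosed 2017-12; case exam 2016-01 (23m)
        dict(exam_id="C1", participant_id="PC", exam_year=2016, exam_month=1,
             diagnosis_year=2017, diagnosis_month=12, cancer_type="in_situ"),
    ]
    for i in range(n_healthy):
        pid = f"H{i:02d}"
        rows.append(dict(exam_id=f"{pid}x1", participant_id=pid, exam_year=2016, exam_month=3))
        if i % 2 == 0:  # half also screened in 2017
            rows.append(dict(exam_id=f"{pid}x2", participant_id=pid, exam_year=2017, exam_month=3))
    return make_frame(rows)


def make_frame(rows):
    from conftest import make_exam_frame

    return make_exam_frame(rows)


def test_case_control_manual_walkthrough():
    """Step-by-step execution of the selection algorithm on a hand fixture:
    descending years, per-year case counting, 1:ratio control draw from the
    remaining pool, most-recent control exam, pool removal."""
    exams = _cc_population()
    ds = cd.build_case_control(exams, 36, ratio=5, seed=1, collection_end=(2021, 12))
    df = ds.to_frame()

    # case exams: all exams within the window before diagnosis
    case_ids = set(df.loc[df["label"] == "case", "exam_id"])
    assert case_ids == {"A1", "A2", "B1", "C1"}

    # year 2017: one case participant (PA) -> 5 controls drawn from healthy
    # with a 2017 exam; year 2016: PB and PC -> 10 more controls; 2015: none.
    ctrl = df[df["label"] == "control"]
    assert len(ctrl) == 15
    assert ctrl["participant_id"].is_unique
    # control exams are the most recent per participant up to the selection year
    for _, row in ctrl.iterrows():
        mine = exams[exams["participant_id"] == row["participant_id"]]
        assert row["exam_id"] == mine.sort_values(["exam_year", "exam_month", "exam_id"])["exam_id"].iloc[-1] or row["exam_year"] == 2016


def test_case_control_forced_count():
    """A year with 10 cases at ratio 5 and an ample pool selects exactly 50
    control participants."""
    rows = [
        dict(exam_id=f"K{i}", participant_id=f"PK{i}", exam_year=2016, exam_month=2,
             diagnosis_year=2016, diagnosis_month=9, cancer_type="invasive")
        for i in range(10)
    ] + [
        dict(exam_id=f"H{i:03d}", participant_id=f"PH{i:03d}", exam_year=2016, exam_month=3)
        for i in range(60)
    ]
    ds = cd.build_case_control(make_frame(rows), 36, ratio=5, seed=0, collection_end=(2021, 12))
    assert ds.n_controls == 50
    assert ds.n_cases == 10


def test_case_control_seed_behaviour():
    exams = _cc_population()
    a = cd.build_case_control(exams, 36, ratio=5, seed=1, collection_end=(2021, 12))
    b = cd.build_case_control(exams, 36, ratio=5, seed=1, collection_end=(2021, 12))
    c = cd.build_case_control(exams, 36, ratio=5, seed=2, collection_end=(2021, 12))
    pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
    case_a = set(a.labels.index[a.case_mask])
    case_c = set(c.labels.index[c.case_mask])
    assert case_a == case_c  # case set invariant to seed
    assert set(a.labels.index) != set(c.labels.index)  # controls differ


def test_case_control_most_recent_tie_broken_by_exam_id():
    rows = [
        dict(exam_id="Z1", participant_id="PZ", exam_year=2016, exam_month=4,
             diagnosis_year=2016, diagnosis_month=8, cancer_type="invasive"),
        dict(exam_id="T_a", participant_id="PT", exam_year=2016, exam_month=6),
        dict(exam_id="T_b", participant_id="PT", exam_year=2016, exam_month=6),
    ]
    ds = cd.build_case_control(make_frame(rows), 36, ratio=1, seed=0, collection_end=(2021, 12))
    ctrl_ids = set(ds.labels.index[~ds.case_mask])
    assert ctrl_ids == {"T_b"}


def test_control_shortfall_names_year():
    rows = [
        dict(exam_id="K1", participant_id="PK1", exam_year=2016, exam_month=2,
             diagnosis_year=2016, diagnosis_month=9, cancer_type="invasive"),
        dict(exam_id="H1", participant_id="PH1", exam_year=2016, exam_month=3),
    ]
    with pytest.raises(cd.ControlShortfallError, match="2016"):
        cd.build_case_control(make_frame(rows), 36, ratio=5, seed=0, collection_end=(2021, 12))


def test_no_participant_both_case_and_control(default_exams):
    ds = cd.build_case_control(default_exams, 36, ratio=5, seed=4)
    df = ds.to_frame()
    by_part = df.groupby("participant_id")["label"].nunique()
    assert (by_part == 1).all()


def test_case_control_ratio_on_generated(default_exams):
    """Per-participant control:case ratio equals the configured 1:5."""
    ds = cd.build_case_control(default_exams, 36, ratio=5, seed=4)
    df = ds.to_frame()
    n_case_p = df.loc[df["label"] == "case", "participant_id"].nunique()
    n_ctrl_p = df.loc[df["label"] == "control", "participant_id"].nunique()
    assert n_ctrl_p == 5 * n_case_p
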