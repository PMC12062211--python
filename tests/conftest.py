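import numpy as np
import pandas as pd
import pytest

import calibdrift as cd

EXAM_DEFAULTS = dict(
    exam_year=2014,
    exam_month=1,
    age_at_exam=55,
    density="B",
    vendor="GE",
    region="R1",
    radiologist_recall=False,
    score_ai_1=0.5,
    diagnosis_year=None,
    diagnosis_month=None,
    cancer_type="none",
)


def make_exam_frame(rows):
    """Build a hand-crafted exam table; each row dict overrides EXAM_DEFAULTS.

    ``exam_id``/``participant_id`` are required per row; diagnosis fields
    default to absent (healthy).
    """
    recs = []
    for row in rows:
        rec = dict(EXAM_DEFAULTS)
        rec.update(row)
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("diagnosis_year", "diagnosis_month"):
        df[col] = df[col].astype("Int64")
    score_cols = sorted(c for c in df.columns if c.startswith("score_"))
    cols = list(cd.EXAM_COLUMNS)
    cols = cols[: cols.index("diagnosis_year")] + score_cols + cols[cols.index("diagnosis_year"):]
    return df[cols]


@pytest.fixture
def exam_builder():
    return make_exam_frame


@pytest.fixture(scope="session")
def default_exams():
    """Mid-sized population under the full default study conditions."""
    pop = cd.default_population_config(n_participants=6000, seed=11)
    return cd.generate_population(pop, cd.default_score_config())


@pytest.fixture(scope="session")
def big_exams():
    """Large population for marginal-recovery checks."""
    pop = cd.default_population_config(n_participants=40_000, seed=5)
    return cd.generate_population(pop, cd.default_score_config())


@pytest.fixture(scope="session")
def labeled36(default_exams):
    return cd.label_exams(default_exams, 36)


def random_labeled_dataset(rng, n_exams, *, n_cases=None, tie_grid=None, n_systems=1):
    """Random labelled dataset for oracle checks (scores possibly tied)."""
    n_cases = n_cases if n_cases is not None else max(1, int(rng.integers(1, n_exams)))
    n_cases = min(n_cases, n_exams - 1)
    rows = []
    for i in range(n_exams):
        is_case = i < n_cases
        scores = {}
        for k in range(n_systems):
            if tie_grid:
                s = float(rng.choice(np.round(np.linspace(0, 1, tie_grid), 3)))
            else:
                s = float(rng.random())
            scores[f"score_ai_{k + 1}"] = s
        rows.append(
            dict(
                exam_id=f"E{i:04d}",
                participant_id=f"P{i:04d}",
                exam_year=2015,
                radiologist_recall=bool(rng.random() < 0.1),
                diagnosis_year=2016 if is_case else None,
                diagnosis_month=1 if is_case else None,
                cancer_type="invasive" if is_case else "none",
                **scores,
            )
        )
    exams = make_exam_frame(rows)
    labels = pd.Series(
        np.where(np.arange(n_exams) < n_cases, "case", "control"),
        index=exams["exam_id"],
        name="label",
    )
    return cd.LabeledDataset(exams, labels, cd.FollowUpWindow(36), "random fixture")
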