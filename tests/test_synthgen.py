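"""Generator: determinism, configured-marginal recovery, score-model oracle."""

import json

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from scipy.stats import norm

import calibdrift as cd
from calibdrift.synthgen import age_band, month_index


def small_config(**kw):
    kw.setdefault("n_participants", 2000)
    kw.setdefault("seed", 3)
    return cd.default_population_config(**kw)


def test_seeded_determinism(tmp_path):
    pop, sc = small_config(), cd.default_score_config()
    a = cd.generate_population(pop, sc)
    b = cd.generate_population(pop, sc)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    cd.write_exams(a, pa)
    cd.write_exams(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_different_seed_differs():
    sc = cd.default_score_config()
    a = cd.generate_population(small_config(seed=1), sc)
    b = cd.generate_population(small_config(seed=2), sc)
    assert not a.equals(b)


def test_in_situ_fraction_recovered(big_exams):
    """Observed in-situ share among diagnosed participants within 3 binomial
    SEs of the configured 13.3%."""
    diag = big_exams[big_exams["cancer_type"] != "none"]
    per_part = diag.groupby("participant_id")["cancer_type"].first()
    m = len(per_part)
    assert m > 500
    frac = (per_part == "in_situ").mean()
    se = np.sqrt(0.133 * 0.867 / m)
    assert abs(frac - 0.133) < 3 * se


def test_binormal_auc_closed_form():
    """With all subgroup shifts zero, the empirical AUC of each system must
    match Phi(delta / (sigma*sqrt(2))), the equal-variance binormal closed
    form, within Monte-Carlo error."""
    pop = cd.default_population_config(n_participants=10_000, seed=21)
    sc = cd.default_score_config(subgroup_shifts=False)
    exams = cd.generate_population(pop, sc)
    ds = cd.label_exams(exams, sc.detectability_horizon_months)
    for name, sys_cfg in sc.systems.items():
        delta = sys_cfg.case_mean - sys_cfg.control_mean
        theory = norm.cdf(delta / (sys_cfg.case_sd * np.sqrt(2)))
        r = cd.roc_curve(ds.scores(name), ds.case_mask)
        assert abs(r.auc - theory) < 3 * np.sqrt(r.auc_variance)


def test_marginal_recovery(big_exams):
    """Configured vendor mix per year and density-given-age vectors are
    recovered within 4 binomial SEs."""
    pop = cd.default_population_config(n_participants=40_000, seed=5)
    mix = pop.vendor_mix()
    for year in (2009, 2014, 2019):
        sub = big_exams[big_exams["exam_year"] == year]
        n = len(sub)
        for vendor, p in mix[year].items():
            obs = (sub["vendor"] == vendor).mean()
            assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-12
    bands = age_band(big_exams["age_at_exam"])
    for band, probs in pop.density_given_age.items():
        sub = big_exams[bands == band]
        n = len(sub)
        for cat, p in probs.items():
            obs = (sub["density"] == cat).mean()
            assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-12


def test_density_age_inverse_correlation(big_exams):
    """Dense categories (C/D) are more common in the youngest band than in
    the oldest, the structural assumption of the density confounder."""
    bands = age_band(big_exams["age_at_exam"])
    dense = big_exams["density"].isin(["C", "D"])
    assert dense[bands == "40-49"].mean() > dense[bands == "70+"].mean()


def test_reader_horizon_ordering(default_exams):
    """Radiologist sensitivity at a 12-month reference standard exceeds that
    at 48 months: recall probability decreases with months-to-diagnosis."""
    sens = {}
    for w in (12, 48):
        ds = cd.label_exams(default_exams, w)
        m = cd.radiologist_operating_point(ds, with_ci=False)
        sens[w] = m.sensitivity
    assert sens[12] > sens[48]


def test_participants_screened_on_schedule(default_exams):
    t = month_index(default_exams["exam_year"], default_exams["exam_month"])
    gaps = pd.Series(t).groupby(default_exams["participant_id"]).diff().dropna()
    assert (gaps == 24).all()


def test_exam_frame_valid(default_exams):
    cd.validate_exam_frame(default_exams, age_range=(40, 74))


# --- summarize_population ---------------------------------------------------


def test_summarize_single_exam(exam_builder):
    exams = exam_builder([dict(exam_id="E1", participant_id="P1")])
    table = cd.summarize_population(exams)
    for family in ("vendor", "age_band", "menopause", "density"):
        fam = table[table["family"] == family]
        assert (fam["count"] > 0).sum() == 2  # one exam cell + one participant cell


def test_summarize_hand_tally(exam_builder):
    """Six hand-built exams: counts match a manual tally."""
    exams = exam_builder(
        [
            dict(exam_id="E1", participant_id="P1", vendor="GE", density="A", age_at_exam=45),
            dict(exam_id="E2", participant_id="P1", vendor="GE", density="A", age_at_exam=47),
            dict(exam_id="E3", participant_id="P2", vendor="Philips", density="C", age_at_exam=60),
            dict(exam_id="E4", participant_id="P3", vendor="GE", density="B", age_at_exam=71),
            dict(
                exam_id="E5", participant_id="P4", vendor="Philips", density="D", age_at_exam=66,
                exam_year=2015, diagnosis_year=2016, diagnosis_month=6, cancer_type="invasive",
            ),
            dict(
                exam_id="E6", participant_id="P5", vendor="GE", density="B", age_at_exam=52,
                exam_year=2015, diagnosis_year=2015, diagnosis_month=12, cancer_type="in_situ",
            ),
        ]
    )
    table = cd.summarize_population(exams, window_months=36)

    def cell(family, level, status, unit):
        m = table[
            (table["family"] == family) & (table["level"] == level)
            & (table["status"] == status) & (table["unit"] == unit)
        ]
        return int(m["count"].iloc[0]) if len(m) else 0

    assert cell("vendor", "GE", "control", "exams") == 3
    assert cell("vendor", "GE", "case", "exams") == 1
    assert cell("vendor", "Philips", "case", "exams") == 1
    assert cell("density", "A", "control", "participants") == 1
    assert cell("cancer_type", "invasive", "case", "exams") == 1
    assert cell("cancer_type", "in_situ", "case", "exams") == 1
    # percentages sum to 100 within each family/status/unit group
    sums = table.groupby(["family", "status", "unit"])["pct"].sum()
    assert np.allclose(sums, 100.0, atol=0.1)


def test_summarize_age_bands_partition(default_exams):
    table = cd.summarize_population(default_exams)
    fam = table[(table["family"] == "age_band") & (table["unit"] == "exams")]
    assert fam["count"].sum() == len(default_exams)


def test_summarize_empty_raises():
    with pytest.raises(ValueError, match="empty"):
        cd.summarize_population(pd.DataFrame(columns=list(cd.EXAM_COLUMNS)))


# --- config validation ------------------------------------------------------


def test_invalid_probability_vector_named():
    with pytest.raises(ValidationError, match="density_given_age"):
        cd.PopulationConfig(
            n_participants=10,
            density_given_age={
                "40-49": {"A": 0.5, "B": 0.5, "C": 0.2, "D": 0.0},
                "50-69": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
                "70+": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
            },
        )


def test_incidence_out_of_range():
    with pytest.raises(ValidationError, match="incidence"):
        cd.PopulationConfig(n_participants=10, incidence_per_round=1.5)


def test_unknown_config_key_rejected():
    with pytest.raises(ValidationError):
        cd.PopulationConfig(n_participants=10, not_a_field=1)


def test_zero_participants_rejected():
    with pytest.raises(ValidationError):
        cd.PopulationConfig(n_participants=0)


def test_config_json_roundtrip(tmp_path):
    cfg = cd.default_population_config(n_participants=50, seed=9)
    path = tmp_path / "pop.json"
    path.write_text(cfg.model_dump_json())
    assert cd.PopulationConfig.from_json(path) == cfg
    blob = json.loads(path.read_text())
    blob["mystery"] = 1
    path.write_text(json.dumps(blob))
    with pytest.raises(ValidationError):
        cd.PopulationConfig.from_json(path)


def test_shift_map_coverage_checked():
    pop = small_config()
    sc = cd.default_score_config(1)
    bad = sc.model_copy(
        update={
            "systems": {
                "ai_1": cd.AISystemConfig(vendor_shift={"Siemens": (0.1, 0.1)})
            }
        }
    )
    with pytest.raises(ValueError, match="unknown vendor"):
        cd.generate_population(pop, bad)


def test_exam_record_invariants():
    base = dict(
        exam_id="E1", participant_id="P1", exam_year=2015, exam_month=3,
        age_at_exam=50, density="B", vendor="GE", region="R1",
        radiologist_recall=False, ai_scores={"ai_1": 0.4},
    )
    cd.ExamRecord(**base)
    with pytest.raises(ValidationError, match="ai_scores"):
        cd.ExamRecord(**{**base, "ai_scores": {"ai_1": 1.5}})
    with pytest.raises(ValidationError, match="cancer_type"):
        cd.ExamRecord(**{**base, "diagnosis_year": 2016, "diagnosis_month": 1})
    with pytest.raises(ValidationError, match="diagnosis"):
        cd.ExamRecord(**{**base, "cancer_type": "invasive"})


# --- IO ---------------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["csv", "parquet"])
def test_io_roundtrip(tmp_path, fmt):
    exams = cd.generate_population(small_config(n_participants=200), cd.default_score_config())
    path = tmp_path / f"exams.{fmt}"
    cd.write_exams(exams, path)
    back = cd.read_exams(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), exams.reset_index(drop=True), check_dtype=False
    )
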