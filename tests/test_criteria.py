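"""Rule evaluation: cutoff boundaries, mandatory gates, substitutions, the
dual-implementation classification oracle, and classifier invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsdx.cohort import ParticipantRecord
from metsdx.criteria import (
    CriterionDefinition,
    builtin_criteria,
    classify,
    classify_cohort,
    evaluate_components,
    get_criterion,
    prevalence,
)
from metsdx.simulate import CohortSpec, plant_labels, reference_classify


def rec(**overrides):
    base = dict(
        id="x",
        sex="female",
        age_years=30.0,
        waist_cm=70.0,
        bmi=22.0,
        sbp_mmHg=110.0,
        dbp_mmHg=70.0,
        glucose_mgdl=85.0,
        tg_mgdl=100.0,
        hdl_mgdl=60.0,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


# -- boundary comparators, one case per printed cutoff ----------------------

@pytest.mark.parametrize(
    "criterion,component,overrides,expect",
    [
        # waist: >= for harmonized/IDF/EGIR, strict > for NCEP and Barbosa
        ("IDF", "waist", dict(sex="female", waist_cm=80.0), True),
        ("IDF_AHA_NHLBI", "waist", dict(sex="male", waist_cm=90.0), True),
        ("IDF_AHA_NHLBI", "waist", dict(sex="male", waist_cm=89.9), False),
        ("NCEP_ATPIII", "waist", dict(sex="male", waist_cm=102.0), False),
        ("NCEP_ATPIII", "waist", dict(sex="female", waist_cm=88.0), False),
        ("NCEP_ATPIII", "waist", dict(sex="female", waist_cm=88.1), True),
        ("BARBOSA2006", "waist", dict(sex="female", waist_cm=84.0), False),
        ("BARBOSA2006", "waist", dict(sex="male", waist_cm=88.5), True),
        ("EGIR", "waist", dict(sex="male", waist_cm=94.0), True),
        # triglycerides >= 150 everywhere
        ("IDF_AHA_NHLBI", "triglycerides", dict(tg_mgdl=150.0), True),
        ("EGIR", "triglycerides", dict(tg_mgdl=149.9), False),
        # HDL strict <
        ("IDF_AHA_NHLBI", "hdl", dict(sex="female", hdl_mgdl=50.0), False),
        ("IDF_AHA_NHLBI", "hdl", dict(sex="male", hdl_mgdl=39.9), True),
        ("EGIR", "hdl", dict(sex="female", hdl_mgdl=39.0), False),
        ("EGIR", "hdl", dict(sex="male", hdl_mgdl=38.9), True),
        # blood pressure: either branch of the 130/85 (or 140/90) pair
        ("IDF_AHA_NHLBI", "blood_pressure", dict(sbp_mmHg=130.0), True),
        ("IDF_AHA_NHLBI", "blood_pressure", dict(dbp_mmHg=85.0), True),
        ("IDF_AHA_NHLBI", "blood_pressure", dict(sbp_mmHg=129.9, dbp_mmHg=84.9), False),
        ("EGIR", "blood_pressure", dict(sbp_mmHg=139.0, dbp_mmHg=90.0), True),
        ("EGIR", "blood_pressure", dict(sbp_mmHg=139.0, dbp_mmHg=89.0), False),
        # glucose >= 100 (harmonized family)
        ("IDF_AHA_NHLBI", "glucose", dict(glucose_mgdl=100.0), True),
        ("NCEP_ATPIII", "glucose", dict(glucose_mgdl=99.9), False),
    ],
)
def test_component_cutoff_boundaries(criterion, component, overrides, expect):
    status = evaluate_components(rec(**overrides), get_criterion(criterion))
    assert status.components[component] is expect


@pytest.mark.parametrize(
    "flag,component",
    [("dm_treatment", "glucose"), ("dm_diagnosis", "glucose"), ("sah_treatment", "blood_pressure")],
)
def test_treatment_substitutions(flag, component):
    """A normal measurement still counts as positive under prior
    diagnosis/treatment of the corresponding condition."""
    status = evaluate_components(rec(**{flag: True}), get_criterion("IDF_AHA_NHLBI"))
    assert status.components[component] is True


def test_nonclassifiable_record_names_missing_fields():
    r = rec()
    r.hdl_mgdl = None
    with pytest.raises(ValueError, match="hdl_mgdl"):
        evaluate_components(r, get_criterion("IDF"))


# -- mandatory gates ---------------------------------------------------------

def test_three_of_five_positive_under_harmonized():
    r = rec(tg_mgdl=200, hdl_mgdl=30, sbp_mmHg=140)
    assert classify(r, get_criterion("IDF_AHA_NHLBI"))


def test_idf_requires_central_obesity():
    """Four non-waist components positive: harmonized yes, IDF no."""
    r = rec(tg_mgdl=200, hdl_mgdl=30, sbp_mmHg=140, glucose_mgdl=110, waist_cm=70)
    assert classify(r, get_criterion("IDF_AHA_NHLBI"))
    assert not classify(r, get_criterion("IDF"))
    # with the mandatory waist satisfied, two others suffice
    assert classify(rec(waist_cm=85, tg_mgdl=200, hdl_mgdl=30), get_criterion("IDF"))


def test_egir_gate_fails_below_110():
    """All four EGIR components positive but glucose 105 and no DM history:
    the insulin-resistance gate fails."""
    r = rec(sex="male", waist_cm=100, tg_mgdl=200, hdl_mgdl=35, sbp_mmHg=145, glucose_mgdl=105)
    assert not classify(r, get_criterion("EGIR"))
    assert classify(dataclasses.replace(r, glucose_mgdl=110.0), get_criterion("EGIR"))
    assert classify(dataclasses.replace(r, dm_treatment=True), get_criterion("EGIR"))


def test_aace_gate_and_two_components():
    base = rec(tg_mgdl=200, hdl_mgdl=30)  # two components positive, no risk factor
    assert not classify(base, get_criterion("AACE"))
    for risk in (dict(bmi=25.0), dict(age_years=41.0), dict(sedentary=True), dict(pcos=True)):
        assert classify(rec(tg_mgdl=200, hdl_mgdl=30, **risk), get_criterion("AACE"))
    # risk factor alone, fewer than two components: negative
    assert not classify(rec(sedentary=True, tg_mgdl=200), get_criterion("AACE"))


def test_aace_unknown_history_flags_do_not_satisfy_gate():
    r = rec(tg_mgdl=200, hdl_mgdl=30, family_history_t2dm_htn_cvd=None)
    assert not classify(r, get_criterion("AACE"))
    assert classify(
        rec(tg_mgdl=200, hdl_mgdl=30, family_history_t2dm_htn_cvd=True), get_criterion("AACE")
    )


# -- cohort-level classification --------------------------------------------

def test_label_matrix_shape_and_order(registry, small_cohort):
    crits = list(registry.values())
    labels = classify_cohort(small_cohort, crits)
    assert labels.shape == (len(small_cohort), 6)
    assert list(labels.columns) == [c.name for c in crits]
    assert labels.dtypes.unique().tolist() == [np.dtype(bool)]


def test_all_negative_cohort_all_false(registry):
    from metsdx.cohort import Cohort

    cohort = Cohort([rec(id=f"r{i}", nonwhite=False) for i in range(5)])
    labels = classify_cohort(cohort, list(registry.values()))
    assert not labels.to_numpy().any()


@pytest.mark.parametrize("name", sorted(builtin_criteria()))
def test_classifier_matches_straight_line_oracle(name, registry):
    """Dual-implementation check on 500 simulated records: the declarative
    engine agrees exactly with an independent straight-line evaluation."""
    cohort, planted = plant_labels(CohortSpec(n=500, seed=97), registry[name])
    got = classify_cohort(cohort, [registry[name]])[name].to_numpy()
    assert (got == planted).all()


# -- invariants (property-based) ---------------------------------------------

measure_st = st.fixed_dictionaries(
    dict(
        sex=st.sampled_from(["female", "male"]),
        waist_cm=st.floats(55, 140),
        tg_mgdl=st.floats(40, 500),
        hdl_mgdl=st.floats(15, 120),
        sbp_mmHg=st.floats(85, 200),
        dbp_mmHg=st.floats(50, 130),
        glucose_mgdl=st.floats(60, 250),
        bmi=st.floats(15, 45),
        age_years=st.floats(20, 70),
    )
)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(fields=measure_st, name=st.sampled_from(sorted(builtin_criteria())))
def test_monotone_in_risk_direction(fields, name):
    """Worsening any measure (raising WC/TG/BP/glucose, lowering HDL) never
    flips a positive classification to negative."""
    crit = get_criterion(name)
    r = rec(**fields)
    if not classify(r, crit):
        return
    worse = dataclasses.replace(
        r,
        waist_cm=r.waist_cm + 5,
        tg_mgdl=r.tg_mgdl + 40,
        sbp_mmHg=r.sbp_mmHg + 10,
        dbp_mmHg=r.dbp_mmHg + 5,
        glucose_mgdl=r.glucose_mgdl + 20,
        hdl_mgdl=max(r.hdl_mgdl - 10, 1.0),
    )
    assert classify(worse, crit)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(fields=measure_st)
def test_sex_symmetry_of_shared_cutoffs(fields):
    """Components whose cutoffs are sex-independent (TG, BP, glucose, EGIR
    HDL) evaluate identically for both sexes at fixed measurements."""
    male = rec(**{**fields, "sex": "male"})
    female = rec(**{**fields, "sex": "female"})
    for name, comps in [
        ("IDF_AHA_NHLBI", ("triglycerides", "blood_pressure", "glucose")),
        ("EGIR", ("triglycerides", "blood_pressure", "hdl")),
    ]:
        crit = get_criterion(name)
        sm = evaluate_components(male, crit).components
        sf = evaluate_components(female, crit).components
        for comp in comps:
            assert sm[comp] == sf[comp]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(fields=measure_st)
def test_barbosa_ncep_agree_off_the_waist_band(fields):
    """Barbosa 2006 differs from NCEP-ATPIII only in the waist cutoff, so the
    two agree on any record on the same side of both cutoff pairs."""
    r = rec(**fields)
    lo, hi = (84.0, 88.0) if r.sex == "female" else (88.0, 102.0)
    if lo < r.waist_cm <= hi:
        return  # between the cutoff pairs: the definitions may disagree
    assert classify(r, get_criterion("BARBOSA2006")) == classify(r, get_criterion("NCEP_ATPIII"))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(fields=measure_st)
def test_idf_positive_implies_harmonized_positive(fields):
    """IDF positivity means waist plus >=2 others positive at cutoffs shared
    with the harmonized definition, i.e. >=3 harmonized components."""
    r = rec(**fields)
    if classify(r, get_criterion("IDF")):
        status = evaluate_components(r, get_criterion("IDF_AHA_NHLBI"))
        assert status.n_positive >= 3
        assert classify(r, get_criterion("IDF_AHA_NHLBI"))


def test_n_positive_counts_true_components():
    status = evaluate_components(rec(tg_mgdl=200, hdl_mgdl=30), get_criterion("IDF_AHA_NHLBI"))
    assert status.n_positive == sum(status.components.values()) == 2


# -- prevalence ---------------------------------------------------------------

def test_prevalence_matches_study_fractions():
    labels = np.zeros(1111, dtype=bool)
    labels[:347] = True
    est = prevalence(labels)
    assert est.percent == pytest.approx(31.23, abs=0.005)
    labels[:] = False
    labels[:52] = True
    assert prevalence(labels).percent == pytest.approx(4.68, abs=0.005)


def test_prevalence_zero_positives_lower_bound_zero():
    est = prevalence(np.zeros(50, dtype=bool))
    assert est.point == 0.0 and est.ci_low == 0.0 and est.ci_high > 0


def test_prevalence_empty_stratum_errors():
    with pytest.raises(ValueError, match="empty"):
        prevalence(np.ones(5, dtype=bool), stratum=np.zeros(5, dtype=bool))


# -- registry serialization ---------------------------------------------------

def test_criteria_round_trip_serialization(registry):
    for crit in registry.values():
        assert CriterionDefinition.from_dict(crit.to_dict()) == crit
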