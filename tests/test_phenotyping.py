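"""Phenotype-construction rules: cognitive impairment classifiers, ADL
counts, Fried frailty components and categories, comorbidity counts."""

import dataclasses
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costdecomp.errors import ConfigurationError, MissingDataError, ValidationError
from costdecomp.phenotyping import (
    FEMALE_CONDITIONS,
    MALE_CONDITIONS,
    ParticipantRecord,
    ReferenceNorms,
    classify_cognitive_impairment_cohort,
    classify_cognitive_impairment_nhats,
    classify_phenotypic_frailty,
    comorbidity_count,
    count_functional_impairments,
    frailty_components,
    phenotype_participant,
)

NORMS = ReferenceNorms(
    mean={"lt9": 90.0, "9to12": 90.0, "gt12": 90.0},
    sd={"lt9": 6.0, "9to12": 6.0, "gt12": 6.0},
)


def make_record(**overrides) -> ParticipantRecord:
    base = dict(
        id="p1",
        sex="female",
        age=75.0,
        race="nh_white",
        region="midwest",
        education="9to12",
        bmi=26.0,
        grip_kg=25.0,
        poor_energy=False,
        gait_ms=1.0,
        walking_aid=False,
        never_walks_and_no_mvpa=False,
        adl_walk=False,
        adl_climb=False,
        adl_transfer=False,
        adl_bathe=False,
        cog_score=95.0,
        dementia_dx=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestCognitiveImpairmentCohortRule:
    @pytest.mark.parametrize(
        "dementia_dx, cog_score, expected",
        [
            (True, 95.0, True),  # diagnosis alone suffices
            (False, 90.0 - 1.5 * 6.0, True),  # boundary is inclusive: 81.0
            (False, 81.1, False),  # just above the 1.5-SD cut
        ],
    )
    def test_rule(self, dementia_dx, cog_score, expected):
        p = make_record(dementia_dx=dementia_dx, cog_score=cog_score)
        assert classify_cognitive_impairment_cohort(p, NORMS) is expected

    def test_missing_both_inputs_is_a_missing_data_error(self):
        p = make_record(dementia_dx=None, cog_score=None)
        with pytest.raises(MissingDataError):
            classify_cognitive_impairment_cohort(p, NORMS)

    def test_norms_must_cover_all_strata(self):
        with pytest.raises(ConfigurationError):
            ReferenceNorms(mean={"lt9": 90.0}, sd={"lt9": 6.0})

    @given(score=st.floats(min_value=40, max_value=120))
    @settings(max_examples=60, deadline=None)
    def test_monotone_nonincreasing_in_score(self, score):
        """Lower scores can only move the classification toward impairment."""
        p_lo = make_record(cog_score=score)
        p_hi = make_record(cog_score=score + 5.0)
        impaired = lambda p: classify_cognitive_impairment_cohort(p, NORMS)
        assert impaired(p_hi) <= impaired(p_lo)


class TestCognitiveImpairmentNhatsRule:
    @pytest.mark.parametrize(
        "dx, ad8, domains, expected",
        [
            (True, 3, (False, False, False), True),  # dx + AD8 > 2
            (True, 2, (True, False, False), False),  # AD8 of 2 is not > 2
            (False, 0, (True, True, False), True),  # 2 of 3 domains impaired
        ],
    )
    def test_rule_arms(self, dx, ad8, domains, expected):
        p = make_record(
            dementia_dx=dx,
            ad8=ad8,
            dom_memory=domains[0],
            dom_orientation=domains[1],
            dom_executive=domains[2],
        )
        assert classify_cognitive_impairment_nhats(p) is expected

    def test_all_inputs_missing(self):
        p = make_record(dementia_dx=None, ad8=None)
        with pytest.raises(MissingDataError):
            classify_cognitive_impairment_nhats(p)


class TestFunctionalImpairments:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ((False, False, False, False), 0),
            ((True, True, True, True), 4),
            ((True, False, True, False), 2),
        ],
    )
    def test_counts(self, flags, expected):
        p = make_record(
            adl_walk=flags[0], adl_climb=flags[1], adl_transfer=flags[2], adl_bathe=flags[3]
        )
        assert count_functional_impairments(p) == expected

    def test_missing_flag(self):
        with pytest.raises(MissingDataError):
            count_functional_impairments(make_record(adl_bathe=None))

    @given(flags=st.tuples(*[st.booleans()] * 4), add_at=st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_adding_a_difficulty_never_decreases_the_count(self, flags, add_at):
        more = list(flags)
        more[add_at] = True
        count = lambda f: count_functional_impairments(
            make_record(adl_walk=f[0], adl_climb=f[1], adl_transfer=f[2], adl_bathe=f[3])
        )
        assert count(more) >= count(flags)


class TestFrailtyComponents:
    def test_male_grip_just_below_cutoff_is_weak(self):
        p = make_record(sex="male", grip_kg=31.9)
        assert frailty_components(p)[1] is True

    def test_female_gait_at_cutoff_is_not_slow(self):
        # strict inequality: 0.60 m/s is not below the 0.6 cut
        p = make_record(sex="female", gait_ms=0.60, walking_aid=False)
        assert frailty_components(p)[3] is False

    def test_low_bmi_triggers_shrinking(self):
        p = make_record(bmi=18.4, weight_loss_pct=0.0, weight_loss_lb=0.0)
        assert frailty_components(p)[0] is True

    @pytest.mark.parametrize("pct, lb, expected", [(5.0, 0.0, True), (4.9, 9.9, False)])
    def test_weight_loss_thresholds(self, pct, lb, expected):
        p = make_record(weight_loss_pct=pct, weight_loss_lb=lb, bmi=25.0)
        assert frailty_components(p)[0] is expected

    @given(grip=st.floats(15, 40), gait=st.floats(0.2, 1.4))
    @settings(max_examples=60, deadline=None)
    def test_female_thresholds_are_lower(self, grip, gait):
        """Flipping male → female with identical measures can only remove
        weakness/slowness, never add it."""
        m = frailty_components(make_record(sex="male", grip_kg=grip, gait_ms=gait))
        f = frailty_components(make_record(sex="female", grip_kg=grip, gait_ms=gait))
        assert f[1] <= m[1] and f[3] <= m[3]


class TestFrailtyCategory:
    def test_truth_table_over_all_component_combinations(self):
        """All 2^5 component combinations against a brute-force rule table."""
        for combo in itertools.product([False, True], repeat=5):
            count = sum(combo)
            expected = "robust" if count == 0 else ("prefrail" if count <= 2 else "frail")
            assert classify_phenotypic_frailty(count) == expected

    @pytest.mark.parametrize("count, cat", [(0, "robust"), (2, "prefrail"), (3, "frail")])
    def test_category_boundaries(self, count, cat):
        assert classify_phenotypic_frailty(count) == cat

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_phenotypic_frailty(6)

    @given(count=st.integers(0, 4))
    def test_adding_a_component_never_moves_toward_robust(self, count):
        order = {"robust": 0, "prefrail": 1, "frail": 2}
        assert (
            order[classify_phenotypic_frailty(count + 1)]
            >= order[classify_phenotypic_frailty(count)]
        )


class TestComorbidityCount:
    def test_empty(self):
        assert comorbidity_count(make_record(conditions=frozenset())) == 0

    def test_woman_three_conditions(self):
        p = make_record(conditions=frozenset({"anemia", "diabetes", "breast_cancer"}))
        assert comorbidity_count(p) == 3

    def test_sex_specific_list_excludes_other_sex_cancers(self):
        p = make_record(sex="male", conditions=frozenset({"breast_cancer"}))
        assert comorbidity_count(p) == 0

    def test_vocab_sizes(self):
        assert len(FEMALE_CONDITIONS) == 12
        assert len(MALE_CONDITIONS) == 11

    def test_unknown_label_warns(self):
        p = make_record(conditions=frozenset({"gout"}))
        with pytest.warns(UserWarning):
            assert comorbidity_count(p) == 0


class TestRecordValidation:
    def test_survivor_must_have_full_followup(self):
        with pytest.raises(ValidationError):
            make_record(followup_months=20.0, died=False)

    def test_cfi_domain(self):
        with pytest.raises(ValidationError):
            make_record(cfi=1.2)

    def test_full_profile(self):
        profile = phenotype_participant(
            make_record(adl_walk=True, grip_kg=19.0, poor_energy=True, gait_ms=0.5),
            norms=NORMS,
        )
        assert profile.n_adl_impairments == 1
        assert profile.frailty_component_count == 3  # weak, poor energy, slow
        assert profile.frailty_category == "frail"
        assert profile.cognitively_impaired is False
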