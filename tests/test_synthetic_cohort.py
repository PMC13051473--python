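"""Generator and generative-truth oracle: determinism, phenotype round-trip,
descriptive contrasts, and the oracle's null/pure-mediation limits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from costdecomp import generate, oracle, phenotype_cohort, preset
from costdecomp.errors import ValidationError
from costdecomp.synthetic_cohort import (
    DEFAULT_NORMS,
    GenerativeParams,
    MediatorParams,
    write_cohort,
)


class TestGeneration:
    def test_fixed_seed_regenerates_bit_identical_tables(self):
        p = preset("paper-like", n_female=300, n_male=300, seed=5)
        pd.testing.assert_frame_equal(generate(p), generate(p))

    def test_different_seeds_differ(self):
        p = preset("paper-like", n_female=300, n_male=300)
        assert not generate(p, seed=1).equals(generate(p, seed=2))

    def test_roundtrip_through_phenotyping_matches_truth_exactly(self, small_cohort):
        ph = phenotype_cohort(small_cohort, norms=DEFAULT_NORMS)
        assert (ph["cognitively_impaired"] == ph["sim_ci"]).all()
        assert (ph["n_adl_impairments"] == ph["sim_adl_count"]).all()
        assert (ph["frailty_component_count"] == ph["sim_frailty_count"]).all()
        assert (ph["frailty_category"] == ph["sim_frailty_category"]).all()
        assert (ph["comorbidity_count"] == ph["sim_comorbidity_count"]).all()

    def test_cost_distribution_is_right_skewed(self, small_cohort):
        thc = small_cohort["cumulative_cost"] / (small_cohort["followup_months"] / 12)
        assert stats.skew(thc) > 0

    def test_survivors_have_full_followup_and_decedents_are_truncated(self, small_cohort):
        died = small_cohort["died"] == 1
        assert (small_cohort.loc[~died, "followup_months"] == 36).all()
        assert (small_cohort.loc[died, "followup_months"] <= 36).all()
        assert (small_cohort.loc[died, "followup_months"] > 0).all()

    def test_paperlike_descriptive_contrasts(self, analytic_cohort):
        """The impaired group is older, frailer, more functionally impaired,
        costlier, and dies more, in both sexes; prevalence lands near the
        emulated cohort's 12.1% (women) and 10.9% (men)."""
        for sex, target_prev in (("female", 12.1), ("male", 10.9)):
            d = analytic_cohort[analytic_cohort["sex"] == sex]
            ci = d["cognitively_impaired"] == 1
            assert abs(100 * ci.mean() - target_prev) < 1.5
            assert d.loc[ci, "age"].mean() > d.loc[~ci, "age"].mean()
            assert (
                (d.loc[ci, "frailty_category"] == "frail").mean()
                > (d.loc[~ci, "frailty_category"] == "frail").mean()
            )
            assert d.loc[ci, "n_adl_impairments"].mean() > d.loc[~ci, "n_adl_impairments"].mean()
            assert d.loc[ci, "cfi"].mean() > d.loc[~ci, "cfi"].mean()
            assert d.loc[ci, "annualized_thc"].mean() > d.loc[~ci, "annualized_thc"].mean()
            assert d.loc[ci, "died"].mean() > d.loc[~ci, "died"].mean()

    def test_null_generator_shows_no_group_cost_difference(self):
        """With the CI cost coefficient and every mediator effect switched
        off, group mean costs agree within Monte-Carlo noise."""
        p = preset("null", n_female=20000, n_male=2, seed=3)
        sp = dataclasses.replace(
            p.female, cost=dataclasses.replace(p.female.cost, ci=0.0)
        )
        p = dataclasses.replace(p, female=sp)
        df = generate(p)
        d = df[df["sex"] == "female"]
        thc = d["cumulative_cost"] / (d["followup_months"] / 12)
        ci = d["sim_ci"] == 1
        diff = thc[ci].mean() - thc[~ci].mean()
        se = np.sqrt(thc[ci].var() / ci.sum() + thc[~ci].var() / (~ci).sum())
        assert abs(diff) < 3 * se

    def test_invalid_params_rejected_before_any_draw(self):
        p = preset("paper-like")
        with pytest.raises(ValidationError):
            dataclasses.replace(p.female, gamma_shape=-1.0)
        with pytest.raises(ValidationError):
            MediatorParams(
                adl_cutpoints=(2.0, 1.0, 3.0, 4.0),  # not non-decreasing
                adl_ci_effect=1.0,
                frailty_base_logits=(0,) * 5,
                frailty_ci_logodds=0.5,
                cfi_mean_unimpaired=0.2,
                cfi_mean_impaired=0.25,
                cfi_concentration=50,
            )

    def test_write_cohort_drops_truth_columns_and_records_provenance(
        self, tmp_path, small_cohort
    ):
        p = preset("paper-like", n_female=600, n_male=600, seed=11)
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path, params=p)
        back = pd.read_csv(path)
        assert not any(c.startswith("sim_") for c in back.columns)
        import json

        prov = json.loads((tmp_path / "cohort.csv.provenance.json").read_text())
        assert prov["n_rows"] == len(small_cohort)
        assert prov["seed"] == 11


class TestOracle:
    def test_null_mediation_preset_has_zero_indirect(self):
        p = preset("null", n_female=100, n_male=100)
        orc = oracle(p, n_mc=60_000, seed=1, sex="female")
        assert abs(orc.true_indirect) < 3 * orc.mc_se_indirect + 1e-9
        assert orc.true_total > 0

    def test_pure_mediation_preset_has_zero_direct(self):
        p = preset("pure-mediation", n_female=100, n_male=100)
        orc = oracle(p, n_mc=60_000, seed=1, sex="female")
        assert abs(orc.true_direct) <= 3 * orc.mc_se_direct + 1e-9
        assert orc.true_indirect > 0

    def test_doubling_the_cfi_cost_coefficient_increases_indirect(self):
        p = preset("paper-like")
        orc1 = oracle(p, n_mc=80_000, seed=2, sex="female", explanatory_set="cfi")
        stronger = dataclasses.replace(
            p,
            female=dataclasses.replace(
                p.female,
                cost=dataclasses.replace(p.female.cost, cfi=2 * p.female.cost.cfi),
            ),
        )
        orc2 = oracle(stronger, n_mc=80_000, seed=2, sex="female", explanatory_set="cfi")
        assert orc2.true_indirect > orc1.true_indirect

    def test_additivity_by_construction(self):
        orc = oracle(preset("paper-like"), n_mc=20_000, seed=4, sex="male")
        assert orc.true_direct + orc.true_indirect == pytest.approx(orc.true_total)

    def test_small_n_mc_rejected(self):
        with pytest.raises(ValidationError):
            oracle(preset("paper-like"), n_mc=100, seed=1)
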