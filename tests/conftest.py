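import numpy as np
import pandas as pd
import pytest

from costdecomp import annualize_cohort, generate, phenotype_cohort, preset
from costdecomp.synthetic_cohort import _generate_sex


@pytest.fixture(scope="session")
def paperlike_params():
    return preset("paper-like", seed=20260901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small paper-like cohort, raw (with generator truth columns)."""
    return generate(preset("paper-like", n_female=600, n_male=600, seed=11))


@pytest.fixture(scope="session")
def analytic_cohort(paperlike_params):
    """Full-size phenotyped + annualized paper-like cohort."""
    df = generate(paperlike_params)
    df = phenotype_cohort(df, norms=paperlike_params.norms)
    return annualize_cohort(df)


def model_frame_from_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Model columns straight from the generator's truth columns (the
    equivalence with the phenotyping path is asserted separately)."""
    return pd.DataFrame(
        {
            "sex": df["sex"].to_numpy(),
            "annualized_thc": (
                df["cumulative_cost"] / (df["followup_months"] / 12.0)
            ).to_numpy(),
            "cognitively_impaired": df["sim_ci"].to_numpy(),
            "age": df["age"].to_numpy(),
            "race": df["race"].to_numpy(),
            "region": df["region"].to_numpy(),
            "comorbidity_count": df["sim_comorbidity_count"].to_numpy(),
            "n_adl_impairments": df["sim_adl_count"].to_numpy(),
            "frailty_category": df["sim_frailty_category"].to_numpy(),
            "cfi": df["cfi"].to_numpy(),
        }
    )


def generate_women(params, seed) -> pd.DataFrame:
    """One-sex generation helper for simulation studies."""
    rng = np.random.default_rng(seed)
    return _generate_sex(rng, "female", params)
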