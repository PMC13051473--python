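"""Synthetic Medicare-like cohorts with a known exposure → mediator → cost
structure, and the generative-truth decomposition oracle.

The generator emulates a sex-stratified cohort of community-dwelling adults
aged 65+ with ~11-12% cognitive-impairment (CI) prevalence, right-skewed
gamma-distributed annualized costs with a log-linear mean, mediators (ADL
impairment count, phenotypic frailty, claims-based frailty index) positively
associated with both CI and costs, and death-truncated follow-up enriched in
the impaired group.

Causal structure (per sex):

    age, race, region, education, chronic conditions   (exogenous)
        → CI (logistic in age, race, comorbidity count)
        → mediators | CI  (ADL count: cumulative logit; frailty components:
                           per-component Bernoulli; CFI: beta with CI-shifted
                           mean)
        → annualized cost mean = exp(linear predictor in all of the above)

Cumulative cost is gamma-distributed with mean follow-up-years x the
annualized mean, so annualization recovers a gamma outcome whose mean does
not depend on follow-up. Raw component measures (grip, gait, BMI, weight
loss, cognitive scores) are emitted consistent with the drawn statuses, so a
generated table round-trips exactly through the phenotyping rules.

Because mediator laws depend only on CI, the conditional cost mean given CI
and the baseline covariates is exactly log-linear — the base gamma GLM of the
analysis is correctly specified on these cohorts.

The oracle evaluates the true total/direct/indirect decomposition by
Monte-Carlo g-computation on the generative law itself: the total contrast
sets CI to 1 vs 0 with mediators following their CI-conditional laws; the
direct contrast holds the explanatory mediators at their CI=0 law.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .phenotyping import (
    FEMALE_CONDITIONS,
    MALE_CONDITIONS,
    GAIT_CUTOFF_MS,
    GRIP_CUTOFF_KG,
    ReferenceNorms,
    classify_phenotypic_frailty,
)

__all__ = [
    "CostCoefficients",
    "MediatorParams",
    "SexParams",
    "GenerativeParams",
    "OracleDecomposition",
    "preset",
    "generate",
    "oracle",
    "write_cohort",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


AGE_CENTER = 80.0


@dataclass(frozen=True)
class CostCoefficients:
    """Log-scale coefficients of the annualized-cost mean."""

    intercept: float
    ci: float
    adl: tuple[float, float, float, float, float]
    frailty: tuple[float, float, float]  # robust, prefrail, frail
    cfi: float
    age: float  # per year, centered at AGE_CENTER
    race_black: float
    race_other: float
    region: Mapping[str, float]
    comorbidity: float


@dataclass(frozen=True)
class MediatorParams:
    """CI-conditional mediator laws.

    ADL count: cumulative logit P(count >= k | CI) = sigmoid(gamma*CI - c_k).
    Frailty components: independent Bernoulli on the logit scale with a
    common CI log-odds shift. CFI: Beta with CI-shifted mean at fixed
    concentration.
    """

    adl_cutpoints: tuple[float, float, float, float]
    adl_ci_effect: float
    frailty_base_logits: tuple[float, float, float, float, float]
    frailty_ci_logodds: float
    cfi_mean_unimpaired: float
    cfi_mean_impaired: float
    cfi_concentration: float

    def __post_init__(self) -> None:
        if any(
            b > a + 1e-12 for a, b in zip(self.adl_cutpoints[1:], self.adl_cutpoints)
        ):
            raise ValidationError("ADL cutpoints must be non-decreasing")
        for m in (self.cfi_mean_unimpaired, self.cfi_mean_impaired):
            if not 0 < m < 1:
                raise ValidationError("CFI means must lie in (0, 1)")
        if self.cfi_concentration <= 0:
            raise ValidationError("CFI concentration must be positive")


@dataclass(frozen=True)
class SexParams:
    n: int
    age_mean: float
    age_sd: float
    race_probs: Mapping[str, float]  # nh_white, nh_black, other
    ci_intercept: float
    ci_age_slope: float
    ci_race_black: float
    ci_race_other: float
    ci_comorb_slope: float
    condition_probs: Mapping[str, float]
    mediators: MediatorParams
    cost: CostCoefficients
    gamma_shape: float
    death_prob_unimpaired: float
    death_prob_impaired: float
    hcc_mean_unimpaired: float = 1.2
    hcc_mean_impaired: float = 1.6
    hcc_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValidationError("gamma shape must be positive")
        probs = list(self.race_probs.values()) + [
            self.death_prob_unimpaired,
            self.death_prob_impaired,
            *self.condition_probs.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("race probabilities must sum to 1")


@dataclass(frozen=True)
class GenerativeParams:
    female: SexParams
    male: SexParams
    region_probs: Mapping[str, float]
    education_probs: Mapping[str, float]
    norms: ReferenceNorms
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.region_probs, self.education_probs):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValidationError("probabilities must lie in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError("category probabilities must sum to 1")

    def for_sex(self, sex: str) -> SexParams:
        return self.female if sex == "female" else self.male


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_REGION_PROBS = {"midwest": 0.28, "northeast": 0.18, "south": 0.34, "west": 0.20}
_EDUCATION_PROBS = {"lt9": 0.15, "9to12": 0.45, "gt12": 0.40}

#: Fixed cognitive-test norms of adults aged 65-69 by education stratum.
DEFAULT_NORMS = ReferenceNorms(
    mean={"lt9": 84.0, "9to12": 88.0, "gt12": 92.0},
    sd={"lt9": 7.0, "9to12": 6.0, "gt12": 5.0},
)

_CONDITIONS_F = {
    "anemia": 0.20,
    "chronic_kidney_disease": 0.12,
    "copd": 0.12,
    "depression": 0.15,
    "diabetes": 0.22,
    "heart_failure": 0.10,
    "ischemic_heart_disease": 0.18,
    "osteoporosis": 0.20,
    "colorectal_cancer": 0.04,
    "lung_cancer": 0.02,
    "breast_cancer": 0.06,
    "endometrial_cancer": 0.02,
}
_CONDITIONS_M = {
    "anemia": 0.20,
    "chronic_kidney_disease": 0.14,
    "copd": 0.14,
    "depression": 0.10,
    "diabetes": 0.25,
    "heart_failure": 0.12,
    "ischemic_heart_disease": 0.22,
    "osteoporosis": 0.08,
    "colorectal_cancer": 0.05,
    "lung_cancer": 0.03,
    "prostate_cancer": 0.10,
}

# Calibrated once to the descriptive targets of the study population
# (prevalence, group age/race/comorbidity contrasts, mediator margins by CI
# status, group cost means/SDs, death proportions); see docs/methods.md.
_PAPERLIKE_F = dict(
    age_mean=79.9,
    age_sd=6.5,
    race_probs={"nh_white": 0.767, "nh_black": 0.197, "other": 0.036},
    ci_intercept=-2.6714,
    ci_age_slope=0.10,
    ci_race_black=0.90,
    ci_race_other=1.10,
    ci_comorb_slope=0.18,
    condition_probs=_CONDITIONS_F,
    mediators=MediatorParams(
        adl_cutpoints=(0.177, 1.078, 1.992, 2.987),
        adl_ci_effect=1.5,
        frailty_base_logits=(-1.6072, -0.2338, -0.4621, 0.1845, -0.2338),
        frailty_ci_logodds=0.6743,
        cfi_mean_unimpaired=0.16,
        cfi_mean_impaired=0.21,
        cfi_concentration=50.0,
    ),
    cost=CostCoefficients(
        intercept=8.8239,
        ci=0.1832,
        adl=(0.0, 0.1495, 0.2719, 0.3739, 0.4759),
        frailty=(0.0, 0.1224, 0.2719),
        cfi=1.3597,
        age=0.02,
        race_black=0.10,
        race_other=0.05,
        region={"midwest": 0.0, "northeast": 0.02, "south": 0.04, "west": 0.06},
        comorbidity=0.10,
    ),
    gamma_shape=0.3543,
    death_prob_unimpaired=0.11,
    death_prob_impaired=0.32,
    hcc_mean_unimpaired=1.2,
    hcc_mean_impaired=1.6,
    hcc_sd=1.0,
)
_PAPERLIKE_M = dict(
    age_mean=78.4,
    age_sd=6.0,
    race_probs={"nh_white": 0.809, "nh_black": 0.138, "other": 0.053},
    ci_intercept=-2.5466,
    ci_age_slope=0.10,
    ci_race_black=0.90,
    ci_race_other=0.60,
    ci_comorb_slope=0.18,
    condition_probs=_CONDITIONS_M,
    mediators=MediatorParams(
        adl_cutpoints=(0.915, 1.696, 2.617, 3.584),
        adl_ci_effect=1.5,
        frailty_base_logits=(-2.0688, -0.5709, -0.8921, -0.2455, -0.7251),
        frailty_ci_logodds=0.6596,
        cfi_mean_unimpaired=0.15,
        cfi_mean_impaired=0.18,
        cfi_concentration=50.0,
    ),
    cost=CostCoefficients(
        intercept=8.8027,
        ci=0.2925,
        adl=(0.0, 0.2102, 0.3821, 0.5254, 0.6687),
        frailty=(0.0, 0.1720, 0.3821),
        cfi=1.9105,
        age=0.02,
        race_black=0.10,
        race_other=0.05,
        region={"midwest": 0.0, "northeast": 0.02, "south": 0.04, "west": 0.06},
        comorbidity=0.10,
    ),
    gamma_shape=0.3038,
    death_prob_unimpaired=0.11,
    death_prob_impaired=0.32,
    hcc_mean_unimpaired=1.2,
    hcc_mean_impaired=1.7,
    hcc_sd=1.1,
)

#: Analytic-cohort sample sizes of the emulated study.
DEFAULT_N_FEMALE = 4318
DEFAULT_N_MALE = 3847

PRESETS = ("paper-like", "null", "pure-mediation")


def preset(
    name: str = "paper-like",
    n_female: int = DEFAULT_N_FEMALE,
    n_male: int = DEFAULT_N_MALE,
    seed: int = 0,
) -> GenerativeParams:
    """Shipped generator presets.

    "paper-like": calibrated to the study's descriptive margins.
    "null": mediator laws identical in both CI groups (all indirect paths
    off); the CI cost effect remains.
    "pure-mediation": the direct CI cost coefficient is zero; CI affects
    costs only through the mediators.
    """
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESETS}")
    sexes = {}
    for sex, base, n in (("female", _PAPERLIKE_F, n_female), ("male", _PAPERLIKE_M, n_male)):
        kw = dict(base, n=n)
        med: MediatorParams = kw["mediators"]
        cost: CostCoefficients = kw["cost"]
        if name == "null":
            kw["mediators"] = MediatorParams(
                adl_cutpoints=med.adl_cutpoints,
                adl_ci_effect=0.0,
                frailty_base_logits=med.frailty_base_logits,
                frailty_ci_logodds=0.0,
                cfi_mean_unimpaired=med.cfi_mean_unimpaired,
                cfi_mean_impaired=med.cfi_mean_unimpaired,
                cfi_concentration=med.cfi_concentration,
            )
        elif name == "pure-mediation":
            kw["cost"] = CostCoefficients(**{**asdict(cost), "ci": 0.0, "region": cost.region})
        sexes[sex] = SexParams(**kw)
    return GenerativeParams(
        female=sexes["female"],
        male=sexes["male"],
        region_probs=_REGION_PROBS,
        education_probs=_EDUCATION_PROBS,
        norms=DEFAULT_NORMS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_baseline(rng: np.random.Generator, sp: SexParams, params: GenerativeParams, n: int):
    """Exogenous covariates: age, race, region, education, conditions."""
    age = np.clip(rng.normal(sp.age_mean, sp.age_sd, size=n), 65.0, 102.0)
    races = list(sp.race_probs)
    race = rng.choice(races, size=n, p=list(sp.race_probs.values()))
    regions = list(params.region_probs)
    region = rng.choice(regions, size=n, p=list(params.region_probs.values()))
    edus = list(params.education_probs)
    education = rng.choice(edus, size=n, p=list(params.education_probs.values()))
    cond_names = list(sp.condition_probs)
    cond_flags = rng.random((n, len(cond_names))) < np.array(
        [sp.condition_probs[c] for c in cond_names]
    )
    return age, race, region, education, cond_names, cond_flags


def _ci_probability(sp: SexParams, age, race, comorb) -> np.ndarray:
    logit = (
        sp.ci_intercept
        + sp.ci_age_slope * (age - AGE_CENTER)
        + sp.ci_race_black * (race == "nh_black")
        + sp.ci_race_other * (race == "other")
        + sp.ci_comorb_slope * comorb
    )
    return _sigmoid(logit)


def _draw_mediators(rng: np.random.Generator, med: MediatorParams, ci: np.ndarray):
    """ADL count, frailty component flags, CFI — conditional on CI status."""
    n = len(ci)
    shift = med.adl_ci_effect * ci
    cum = _sigmoid(shift[:, None] - np.array(med.adl_cutpoints)[None, :])
    u = rng.random(n)
    adl_count = (u[:, None] < cum).sum(axis=1)
    comp_logit = np.array(med.frailty_base_logits)[None, :] + (
        med.frailty_ci_logodds * ci
    )[:, None]
    frailty_flags = rng.random((n, 5)) < _sigmoid(comp_logit)
    mean = np.where(ci == 1, med.cfi_mean_impaired, med.cfi_mean_unimpaired)
    k = med.cfi_concentration
    cfi = rng.beta(mean * k, (1.0 - mean) * k)
    return adl_count, frailty_flags, cfi


def _cost_eta(
    cost: CostCoefficients, ci, adl_count, frailty_count, cfi, age, race, region, comorb
) -> np.ndarray:
    frailty_cat = np.clip(frailty_count, 0, None)
    frail_idx = np.where(frailty_cat == 0, 0, np.where(frailty_cat <= 2, 1, 2))
    region_eff = np.array([cost.region[r] for r in region])
    return (
        cost.intercept
        + cost.ci * ci
        + np.array(cost.adl)[adl_count]
        + np.array(cost.frailty)[frail_idx]
        + cost.cfi * cfi
        + cost.age * (age - AGE_CENTER)
        + cost.race_black * (race == "nh_black")
        + cost.race_other * (race == "other")
        + region_eff
        + cost.comorbidity * comorb
    )


def _emit_raw_measures(
    rng: np.random.Generator,
    sex: str,
    norms: ReferenceNorms,
    education: np.ndarray,
    ci: np.ndarray,
    adl_count: np.ndarray,
    frailty_flags: np.ndarray,
) -> dict[str, np.ndarray]:
    """Raw measurements consistent with the drawn derived statuses, so the
    phenotyping rules reproduce them exactly."""
    n = len(ci)
    grip_cut = GRIP_CUTOFF_KG[sex]
    gait_cut = GAIT_CUTOFF_MS[sex]
    shrinking, weakness, poor_energy, slowness, low_activity = frailty_flags.T

    weight_loss_pct = np.where(shrinking, rng.uniform(5.0, 12.0, n), rng.uniform(0.0, 4.0, n))
    weight_loss_lb = np.where(shrinking, rng.uniform(10.0, 25.0, n), rng.uniform(0.0, 8.0, n))
    bmi = np.clip(rng.normal(27.0, 4.0, n), 18.6, 45.0)
    grip = np.where(
        weakness,
        rng.uniform(max(grip_cut - 12.0, 1.0), grip_cut - 0.1, n),
        rng.uniform(grip_cut + 0.1, grip_cut + 15.0, n),
    )
    walking_aid = slowness & (rng.random(n) < 0.4)
    gait = np.where(
        slowness & ~walking_aid,
        rng.uniform(max(gait_cut - 0.4, 0.05), gait_cut - 0.01, n),
        np.where(
            slowness,  # aid users: gait itself may be above or below the cut
            rng.uniform(max(gait_cut - 0.3, 0.05), gait_cut + 0.3, n),
            rng.uniform(gait_cut + 0.01, gait_cut + 0.6, n),
        ),
    )

    # ADL flags: `count` of the four tasks difficult, chosen at random
    adl = np.zeros((n, 4), dtype=bool)
    order = np.argsort(rng.random((n, 4)), axis=1)
    adl[np.arange(n)[:, None], order] = np.arange(4)[None, :] < adl_count[:, None]

    # cognitive measures consistent with CI status under the cohort rule
    thresholds = np.array([norms.threshold(e) for e in education])
    means = np.array([norms.mean[e] for e in education])
    sds = np.array([norms.sd[e] for e in education])
    dementia_dx = ci & (rng.random(n) < 0.5)
    cog = np.empty(n)
    low = ci & ~dementia_dx
    cog[low] = rng.uniform(thresholds[low] - 2.0 * sds[low], thresholds[low])
    rest = ~low
    a = (thresholds[rest] - means[rest]) / sds[rest]
    cog[rest] = stats.truncnorm.rvs(
        a + 1e-9, np.inf, loc=means[rest], scale=sds[rest], random_state=rng
    )
    # keep scores on the intended side of the cut point after rounding
    cog = np.round(cog, 2)
    cog[low] = np.minimum(cog[low], np.floor(thresholds[low] * 100) / 100)
    cog[rest] = np.maximum(cog[rest], np.ceil(thresholds[rest] * 100) / 100 + 0.01)
    return dict(
        weight_loss_pct=weight_loss_pct,
        weight_loss_lb=weight_loss_lb,
        bmi=bmi,
        grip_kg=grip,
        poor_energy=poor_energy,
        gait_ms=gait,
        walking_aid=walking_aid,
        never_walks_and_no_mvpa=low_activity,
        adl_walk=adl[:, 0],
        adl_climb=adl[:, 1],
        adl_transfer=adl[:, 2],
        adl_bathe=adl[:, 3],
        cog_score=cog,
        dementia_dx=dementia_dx,
    )


def _generate_sex(
    rng: np.random.Generator, sex: str, params: GenerativeParams
) -> pd.DataFrame:
    sp = params.for_sex(sex)
    n = sp.n
    age, race, region, education, cond_names, cond_flags = _draw_baseline(
        rng, sp, params, n
    )
    comorb = cond_flags.sum(axis=1)
    ci = (rng.random(n) < _ci_probability(sp, age, race, comorb)).astype(int)
    adl_count, frailty_flags, cfi = _draw_mediators(rng, sp.mediators, ci)
    frailty_count = frailty_flags.sum(axis=1)

    p_death = np.where(ci == 1, sp.death_prob_impaired, sp.death_prob_unimpaired)
    died = rng.random(n) < p_death
    # decedents: follow-up uniform on (0, 36] months (floored away from 0 so
    # the rounded CSV value stays annualizable)
    followup = np.where(died, np.maximum(rng.uniform(0.0, 36.0, n), 0.05), 36.0)

    eta = _cost_eta(sp.cost, ci, adl_count, frailty_count, cfi, age, race, region, comorb)
    fu_years = followup / 12.0
    mean_cost = fu_years * np.exp(eta)
    cumulative = rng.gamma(sp.gamma_shape, mean_cost / sp.gamma_shape)

    hcc_mean = np.where(ci == 1, sp.hcc_mean_impaired, sp.hcc_mean_unimpaired)
    hcc_shape = (hcc_mean / sp.hcc_sd) ** 2
    hcc = rng.gamma(hcc_shape, hcc_mean / hcc_shape)

    raw = _emit_raw_measures(
        rng, sex, params.norms, education, ci.astype(bool), adl_count, frailty_flags
    )
    conditions = [
        ";".join(name for name, flag in zip(cond_names, row) if flag)
        for row in cond_flags
    ]
    prefix = "F" if sex == "female" else "M"
    df = pd.DataFrame(
        {
            "id": [f"{prefix}{i:05d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 1),
            "race": race,
            "region": region,
            "education": education,
            "conditions": conditions,
            "hcc_score": np.round(hcc, 3),
            "cfi": np.round(cfi, 4),
            "followup_months": np.round(followup, 2),
            "died": died.astype(int),
            "cumulative_cost": np.round(cumulative, 2),
            "continuously_enrolled": 1,
            # generator-internal truth columns
            "sim_ci": ci,
            "sim_comorbidity_count": comorb,
            "sim_adl_count": adl_count,
            "sim_frailty_count": frailty_count,
            "sim_frailty_category": [
                classify_phenotypic_frailty(int(c)) for c in frailty_count
            ],
            "sim_eta": eta,
        }
    )
    for name, values in raw.items():
        df[name] = values.astype(int) if values.dtype == bool else values
    return df


def generate(params: GenerativeParams, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one cohort table (women then men), deterministically under
    ``seed`` (defaults to ``params.seed``).

    Truth columns are prefixed ``sim_``; :func:`write_cohort` drops them.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    frames = [_generate_sex(rng, "female", params), _generate_sex(rng, "male", params)]
    return pd.concat(frames, ignore_index=True)


def write_cohort(df: pd.DataFrame, path, params: Optional[GenerativeParams] = None) -> None:
    """Write the cohort CSV (truth columns dropped) plus a provenance JSON
    with the parameters, seed, and a content hash."""
    out = df[[c for c in df.columns if not c.startswith("sim_")]]
    out.to_csv(path, index=False)
    if params is not None:
        payload = {
            "params": json.loads(json.dumps(asdict(params), default=str)),
            "seed": params.seed,
            "n_rows": int(len(out)),
            "content_sha256": hashlib.sha256(
                out.to_csv(index=False).encode()
            ).hexdigest(),
        }
        with open(str(path) + ".provenance.json", "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# generative-truth oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleDecomposition:
    """True decomposition of the CI cost effect, dollars per person-year."""

    true_total: float
    true_direct: float
    mc_se_total: float
    mc_se_direct: float
    mc_se_indirect: float

    @property
    def true_indirect(self) -> float:
        return self.true_total - self.true_direct

    @property
    def mc_se(self) -> float:
        return max(self.mc_se_total, self.mc_se_direct, self.mc_se_indirect)


_ORACLE_SETS = {
    "functional_impairments": ("adl",),
    "phenotypic_frailty": ("frailty",),
    "cfi": ("cfi",),
    "all_three": ("adl", "frailty", "cfi"),
}


def oracle(
    params: GenerativeParams,
    n_mc: int = 200_000,
    seed: int = 0,
    sex: str = "female",
    explanatory_set: str = "all_three",
) -> OracleDecomposition:
    """Monte-Carlo g-computation of the true decomposition for one sex.

    true_total  = E[cost | do CI=1] - E[cost | do CI=0], mediators drawn from
    their CI-conditional laws.  true_direct holds the explanatory mediators at
    their CI=0 law in both arms (mediators outside the set still respond to
    CI).  true_indirect is the difference.  Cost noise integrates out, so the
    contrasts are evaluated on the mean scale exp(eta).
    """
    if n_mc < 10_000:
        raise ValidationError("oracle requires n_mc >= 10,000")
    which = _ORACLE_SETS[explanatory_set]
    sp = params.for_sex(sex)
    rng = np.random.default_rng(seed)
    age, race, region, education, _, cond_flags = _draw_baseline(rng, sp, params, n_mc)
    comorb = cond_flags.sum(axis=1)

    ones = np.ones(n_mc)
    zeros = np.zeros(n_mc)
    adl1, frail1, cfi1 = _draw_mediators(rng, sp.mediators, ones)
    adl0, frail0, cfi0 = _draw_mediators(rng, sp.mediators, zeros)
    fc1, fc0 = frail1.sum(axis=1), frail0.sum(axis=1)

    def mu(ci_val, adl, fc, cfi):
        return np.exp(
            _cost_eta(sp.cost, ci_val, adl, fc, cfi, age, race, region, comorb)
        )

    m1 = mu(ones, adl1, fc1, cfi1)
    m0 = mu(zeros, adl0, fc0, cfi0)
    # direct arm: explanatory mediators at their CI=0 draw, others at CI=1
    d_adl = adl0 if "adl" in which else adl1
    d_fc = fc0 if "frailty" in which else fc1
    d_cfi = cfi0 if "cfi" in which else cfi1
    d1 = mu(ones, d_adl, d_fc, d_cfi)

    total_i = m1 - m0
    direct_i = d1 - m0
    indirect_i = m1 - d1
    se = lambda v: float(np.std(v, ddof=1) / np.sqrt(n_mc))
    return OracleDecomposition(
        true_total=float(total_i.mean()),
        true_direct=float(direct_i.mean()),
        mc_se_total=se(total_i),
        mc_se_direct=se(direct_i),
        mc_se_indirect=se(indirect_i),
    )
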