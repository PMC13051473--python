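"""Harmonized phenotype construction for a multi-cohort Medicare-linked study.

Turns raw participant measures into the derived variables every downstream
model consumes: cognitive-impairment status, the count of activities-of-daily-
living (ADL) difficulties, the five-component physical frailty phenotype, a
chronic-condition comorbidity count, and pass-through continuous adjusters
(claims-based frailty index, CMS-HCC risk score).

Cognitive impairment has two classifiers:

* the cohort rule — a self/proxy-reported clinician diagnosis of dementia, or
  a cognitive test score at least 1.5 SD below the education-stratified mean
  of adults aged 65-69 (the reference norms);
* the NHATS rule — a reported dementia diagnosis combined with a proxy AD8
  score above 2, or impairment in at least two of three tested cognitive
  domains (memory, orientation, executive function).

Frailty follows the Fried physical-phenotype criteria with sex-specific grip
and gait cut points; 0 components is robust, 1-2 pre-frail, >=3 frail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, MissingDataError, ValidationError

EDUCATION_STRATA = ("lt9", "9to12", "gt12")

#: Grip-strength weakness cut points, kg (below → weak).
GRIP_CUTOFF_KG = {"male": 32.0, "female": 20.0}
#: Gait-speed slowness cut points, m/s (below → slow; a walking aid also counts).
GAIT_CUTOFF_MS = {"male": 0.8, "female": 0.6}

#: Chronic-condition vocabulary: cost-relevant, non-dementia conditions.
#: Women are scored on 12 conditions, men on 11 (sex-specific cancers).
SHARED_CONDITIONS = (
    "anemia",
    "chronic_kidney_disease",
    "copd",
    "depression",
    "diabetes",
    "heart_failure",
    "ischemic_heart_disease",
    "osteoporosis",
    "colorectal_cancer",
    "lung_cancer",
)
FEMALE_CONDITIONS = SHARED_CONDITIONS + ("breast_cancer", "endometrial_cancer")
MALE_CONDITIONS = SHARED_CONDITIONS + ("prostate_cancer",)

FRAILTY_CATEGORIES = ("robust", "prefrail", "frail")


def conditions_for_sex(sex: str) -> tuple[str, ...]:
    if sex == "female":
        return FEMALE_CONDITIONS
    if sex == "male":
        return MALE_CONDITIONS
    raise ValidationError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's raw measures, follow-up, and cumulative costs.

    ``None`` encodes a missing optional measure. Costs are cumulative dollars
    over the (possibly death-truncated) follow-up, ``followup_months`` in
    (0, 36].
    """

    id: str
    sex: str
    age: float
    race: str
    region: str
    education: str
    bmi: float
    grip_kg: float
    poor_energy: bool
    gait_ms: float
    walking_aid: bool
    never_walks_and_no_mvpa: bool
    adl_walk: Optional[bool]
    adl_climb: Optional[bool]
    adl_transfer: Optional[bool]
    adl_bathe: Optional[bool]
    conditions: frozenset = frozenset()
    cog_score: Optional[float] = None
    dementia_dx: Optional[bool] = None
    ad8: Optional[int] = None
    dom_memory: Optional[bool] = None
    dom_orientation: Optional[bool] = None
    dom_executive: Optional[bool] = None
    weight_loss_pct: Optional[float] = None
    weight_loss_lb: Optional[float] = None
    hcc_score: Optional[float] = None
    cfi: Optional[float] = None
    followup_months: float = 36.0
    died: bool = False
    cumulative_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.education not in EDUCATION_STRATA:
            raise ValidationError(
                f"education must be one of {EDUCATION_STRATA}, got {self.education!r}"
            )
        if self.cfi is not None and not (0.0 <= self.cfi <= 1.0):
            raise ValidationError(f"cfi must lie in [0, 1], got {self.cfi}")
        if not self.died and not math.isclose(self.followup_months, 36.0):
            raise ValidationError(
                "followup_months must equal 36 for participants who survived follow-up"
            )


@dataclass(frozen=True)
class ReferenceNorms:
    """Education-stratified cognitive-test norms of adults aged 65-69.

    The youngest age band is used as the reference to limit contamination of
    the norms by prevalent dementia.
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for stratum in EDUCATION_STRATA:
            if stratum not in self.mean or stratum not in self.sd:
                raise ConfigurationError(f"norms missing education stratum {stratum!r}")
            if not self.sd[stratum] > 0:
                raise ConfigurationError(f"norm SD for {stratum!r} must be positive")

    def threshold(self, stratum: str) -> float:
        """Impairment cut point: stratum mean minus 1.5 stratum SD."""
        if stratum not in self.mean:
            raise ConfigurationError(f"no norms for education stratum {stratum!r}")
        return self.mean[stratum] - 1.5 * self.sd[stratum]

    @classmethod
    def from_cohort(cls, df: pd.DataFrame) -> "ReferenceNorms":
        """Estimate norms from the cohort's own participants aged 65-69."""
        young = df[(df["age"] >= 65) & (df["age"] < 70) & df["cog_score"].notna()]
        mean, sd = {}, {}
        for stratum in EDUCATION_STRATA:
            scores = young.loc[young["education"] == stratum, "cog_score"]
            if len(scores) < 2:
                raise ConfigurationError(
                    f"cannot estimate norms: <2 scored participants aged 65-69 in stratum {stratum!r}"
                )
            mean[stratum] = float(scores.mean())
            sd[stratum] = float(scores.std(ddof=1))
        return cls(mean=mean, sd=sd)


@dataclass(frozen=True)
class PhenotypeProfile:
    """Derived statuses for one participant."""

    cognitively_impaired: bool
    n_adl_impairments: int
    frailty_component_count: int
    frailty_category: str
    comorbidity_count: int
    cfi: Optional[float] = None
    hcc_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frailty_category != classify_phenotypic_frailty(
            self.frailty_component_count
        ):
            raise ValidationError("frailty_category inconsistent with component count")


def classify_cognitive_impairment_cohort(
    p: ParticipantRecord, norms: ReferenceNorms
) -> bool:
    """Cohort-study rule: dementia diagnosis, or test score at/below the
    education-stratified 1.5-SD cut point (boundary inclusive)."""
    if p.dementia_dx is None and p.cog_score is None:
        raise MissingDataError(
            f"participant {p.id}: no dementia diagnosis and no cognitive score"
        )
    if p.dementia_dx:
        return True
    if p.cog_score is None:
        raise MissingDataError(f"participant {p.id}: cognitive score missing")
    return p.cog_score <= norms.threshold(p.education)


def classify_cognitive_impairment_nhats(p: ParticipantRecord) -> bool:
    """NHATS algorithm: reported dementia diagnosis with proxy AD8 > 2, or
    impairment in at least 2 of 3 cognitive domains."""
    domains = (p.dom_memory, p.dom_orientation, p.dom_executive)
    have_dx_arm = p.dementia_dx is not None and p.ad8 is not None
    have_domain_arm = all(d is not None for d in domains)
    if not have_dx_arm and not have_domain_arm:
        raise MissingDataError(f"participant {p.id}: no NHATS cognitive inputs")
    if have_dx_arm and p.dementia_dx and p.ad8 > 2:
        return True
    if have_domain_arm and sum(bool(d) for d in domains) >= 2:
        return True
    return False


def count_functional_impairments(p: ParticipantRecord) -> int:
    """Number of the four ADL tasks (walking blocks, climbing steps,
    bed-to-chair transfer, bathing) reported as difficult."""
    flags = (p.adl_walk, p.adl_climb, p.adl_transfer, p.adl_bathe)
    if any(f is None for f in flags):
        raise MissingDataError(f"participant {p.id}: ADL difficulty flag missing")
    return sum(bool(f) for f in flags)


def frailty_components(p: ParticipantRecord) -> tuple[bool, bool, bool, bool, bool]:
    """The five Fried components as booleans:
    (shrinking, weakness, poor_energy, slowness, low_activity).

    Shrinking: weight loss >= 5% or >= 10 lb, or BMI < 18.5 kg/m².
    Weakness: grip < 32 kg (men) / < 20 kg (women).
    Slowness: gait < 0.8 m/s (men) / < 0.6 m/s (women), or use of a walking aid.
    Low activity: never walks for exercise and no moderate/vigorous activity.
    """
    required = (
        p.bmi,
        p.grip_kg,
        p.poor_energy,
        p.gait_ms,
        p.walking_aid,
        p.never_walks_and_no_mvpa,
    )
    if any(v is None for v in required):
        raise MissingDataError(f"participant {p.id}: frailty component input missing")
    wl_pct = p.weight_loss_pct if p.weight_loss_pct is not None else 0.0
    wl_lb = p.weight_loss_lb if p.weight_loss_lb is not None else 0.0
    shrinking = wl_pct >= 5.0 or wl_lb >= 10.0 or p.bmi < 18.5
    weakness = p.grip_kg < GRIP_CUTOFF_KG[p.sex]
    slowness = p.gait_ms < GAIT_CUTOFF_MS[p.sex] or bool(p.walking_aid)
    return (
        shrinking,
        weakness,
        bool(p.poor_energy),
        slowness,
        bool(p.never_walks_and_no_mvpa),
    )


def classify_phenotypic_frailty(count: int) -> str:
    """Map a 0-5 component count to robust / prefrail / frail."""
    if not 0 <= count <= 5:
        raise ValidationError(f"frailty component count must be 0-5, got {count}")
    if count == 0:
        return "robust"
    if count <= 2:
        return "prefrail"
    return "frail"


def comorbidity_count(
    p: ParticipantRecord, condition_list: Optional[Iterable[str]] = None
) -> int:
    """Count of the participant's conditions within the sex-appropriate
    chronic-condition list (12 conditions for women, 11 for men)."""
    if condition_list is None:
        condition_list = conditions_for_sex(p.sex)
    vocab = set(FEMALE_CONDITIONS) | set(MALE_CONDITIONS)
    unknown = set(p.conditions) - vocab
    if unknown:
        import warnings

        warnings.warn(
            f"participant {p.id}: conditions outside the configured vocabulary: {sorted(unknown)}",
            stacklevel=2,
        )
    return len(set(p.conditions) & set(condition_list))


def phenotype_participant(
    p: ParticipantRecord,
    norms: Optional[ReferenceNorms] = None,
    rule: str = "cohort",
) -> PhenotypeProfile:
    """Derive the full phenotype profile for one participant.

    ``rule`` selects the cognitive classifier: "cohort" (needs ``norms``) or
    "nhats".
    """
    if rule == "cohort":
        if norms is None:
            raise ConfigurationError("cohort cognitive rule requires reference norms")
        ci = classify_cognitive_impairment_cohort(p, norms)
    elif rule == "nhats":
        ci = classify_cognitive_impairment_nhats(p)
    else:
        raise ConfigurationError(f"unknown cognitive rule {rule!r}")
    n_frail = sum(frailty_components(p))
    return PhenotypeProfile(
        cognitively_impaired=ci,
        n_adl_impairments=count_functional_impairments(p),
        frailty_component_count=n_frail,
        frailty_category=classify_phenotypic_frailty(n_frail),
        comorbidity_count=comorbidity_count(p),
        cfi=p.cfi,
        hcc_score=p.hcc_score,
    )


# --- cohort-table interface -------------------------------------------------

RECORD_COLUMNS = [f.name for f in ParticipantRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]

_BOOL_COLUMNS = (
    "poor_energy",
    "walking_aid",
    "never_walks_and_no_mvpa",
    "adl_walk",
    "adl_climb",
    "adl_transfer",
    "adl_bathe",
    "dementia_dx",
    "dom_memory",
    "dom_orientation",
    "dom_executive",
    "died",
)


def _opt_bool(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return bool(int(v)) if not isinstance(v, bool) else v


def _opt_float(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def record_from_row(row: Mapping) -> ParticipantRecord:
    """Build a :class:`ParticipantRecord` from one cohort-table row.

    Booleans are 0/1 in the CSV, missing values empty cells; ``conditions``
    is a semicolon-separated label list.
    """
    conditions = row.get("conditions", "")
    if conditions is None or (isinstance(conditions, float) and math.isnan(conditions)):
        conditions = ""
    if isinstance(conditions, str):
        conditions = frozenset(c for c in conditions.split(";") if c)
    else:
        conditions = frozenset(conditions)
    kwargs = {
        "id": str(row["id"]),
        "sex": row["sex"],
        "age": float(row["age"]),
        "race": row["race"],
        "region": str(row["region"]),
        "education": row["education"],
        "bmi": float(row["bmi"]),
        "grip_kg": float(row["grip_kg"]),
        "gait_ms": float(row["gait_ms"]),
        "conditions": conditions,
        "cog_score": _opt_float(row.get("cog_score")),
        "ad8": _opt_float(row.get("ad8")),
        "weight_loss_pct": _opt_float(row.get("weight_loss_pct")),
        "weight_loss_lb": _opt_float(row.get("weight_loss_lb")),
        "hcc_score": _opt_float(row.get("hcc_score")),
        "cfi": _opt_float(row.get("cfi")),
        "followup_months": float(row["followup_months"]),
        "cumulative_cost": float(row["cumulative_cost"]),
    }
    if kwargs["ad8"] is not None:
        kwargs["ad8"] = int(kwargs["ad8"])
    for col in _BOOL_COLUMNS:
        kwargs[col] = _opt_bool(row.get(col))
    kwargs["died"] = bool(kwargs["died"])
    kwargs["poor_energy"] = bool(kwargs["poor_energy"])
    kwargs["walking_aid"] = bool(kwargs["walking_aid"])
    kwargs["never_walks_and_no_mvpa"] = bool(kwargs["never_walks_and_no_mvpa"])
    return ParticipantRecord(**kwargs)


def phenotype_cohort(
    df: pd.DataFrame,
    norms: Optional[ReferenceNorms] = None,
    rule: str = "cohort",
) -> pd.DataFrame:
    """Phenotype every row of a cohort table.

    Returns the input table augmented with the derived columns
    ``cognitively_impaired``, ``n_adl_impairments``, ``frailty_component_count``,
    ``frailty_category`` and ``comorbidity_count``. Rows whose required inputs
    are missing raise :class:`MissingDataError`; run the exclusion cascade
    first to drop them (see :mod:`costdecomp.pipeline`).
    """
    if rule == "cohort" and norms is None:
        norms = ReferenceNorms.from_cohort(df)
    profiles = []
    for row in df.to_dict("records"):
        p = record_from_row(row)
        profiles.append(phenotype_participant(p, norms=norms, rule=rule))
    out = df.copy()
    out["cognitively_impaired"] = [int(pr.cognitively_impaired) for pr in profiles]
    out["n_adl_impairments"] = [pr.n_adl_impairments for pr in profiles]
    out["frailty_component_count"] = [pr.frailty_component_count for pr in profiles]
    out["frailty_category"] = [pr.frailty_category for pr in profiles]
    out["comorbidity_count"] = [pr.comorbidity_count for pr in profiles]
    return out
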