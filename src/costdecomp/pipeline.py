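"""End-to-end analysis pipeline: exclusion cascade, phenotyping, costing,
sex-stratified modelling, the decomposition suite, sensitivity analyses, and
report generation.

Percentages are printed to one decimal and dollars to the nearest integer in
the CSV reports; full precision is preserved in the JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .costing import InflationTable, annualize_cohort
from .decomposition import (
    DEFAULT_BASE_COVARIATES,
    BootstrapSettings,
    DecompositionResult,
    DecompositionSpec,
    bootstrap_cis,
    pool_sexes,
)
from .errors import ConfigurationError, ValidationError
from .glm_gamma import Term
from .phenotyping import ReferenceNorms, phenotype_cohort
from .synthetic_cohort import PRESETS, generate, preset

log = logging.getLogger("costdecomp")

EXPLANATORY_ORDER = ("functional_impairments", "phenotypic_frailty", "cfi", "all_three")

MODEL_LABELS = {
    "functional_impairments": "Base + functional impairments",
    "phenotypic_frailty": "Base + phenotypic frailty",
    "cfi": "Base + CFI",
    "all_three": "Base + functional impairments + phenotypic frailty + CFI",
}


# --- display conventions ----------------------------------------------------


def fmt_pct(x: float) -> str:
    """Percentages to one decimal, as printed in the reports."""
    return f"{x:.1f}"


def fmt_share(part: float, whole: float) -> str:
    """A component as a percentage of its total, to one decimal."""
    if whole == 0:
        raise ValidationError("share of a zero total is undefined")
    return fmt_pct(100.0 * part / whole)


def fmt_dollars(x: float) -> str:
    """Dollar amounts to the nearest integer."""
    return f"{x:.0f}"


# --- exclusion cascade ------------------------------------------------------

#: Columns every analyzable record must carry non-missing.
REQUIRED_COLUMNS = (
    "age",
    "sex",
    "race",
    "region",
    "education",
    "bmi",
    "grip_kg",
    "poor_energy",
    "gait_ms",
    "walking_aid",
    "never_walks_and_no_mvpa",
    "adl_walk",
    "adl_climb",
    "adl_transfer",
    "adl_bathe",
    "followup_months",
    "died",
    "cumulative_cost",
)


@dataclass
class ExclusionReport:
    n_initial: int
    n_missing_excluded: int
    n_enrollment_excluded: int
    per_reason: dict[str, int] = field(default_factory=dict)

    @property
    def n_analytic(self) -> int:
        return self.n_initial - self.n_missing_excluded - self.n_enrollment_excluded

    @property
    def pct_missing(self) -> str:
        return fmt_share(self.n_missing_excluded, self.n_initial)

    @property
    def pct_enrollment(self) -> str:
        return fmt_share(self.n_enrollment_excluded, self.n_initial)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_missing_excluded": self.n_missing_excluded,
            "n_enrollment_excluded": self.n_enrollment_excluded,
            "n_analytic": self.n_analytic,
            "pct_missing": self.pct_missing,
            "pct_enrollment": self.pct_enrollment,
            "per_reason": dict(sorted(self.per_reason.items())),
        }


def apply_exclusions(
    raw: pd.DataFrame, enrollment_column: str = "continuously_enrolled"
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records with missing phenotype/cost inputs first, then records
    not continuously enrolled, and account for every row exactly once.

    The order matters for the reported counts and mirrors the narrative
    ordering of the emulated study (missing data before enrollment).
    """
    n_initial = len(raw)
    per_reason: dict[str, int] = {}

    missing_mask = pd.Series(False, index=raw.index)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ConfigurationError(f"cohort table lacks required column {col!r}")
        col_missing = raw[col].isna() & ~missing_mask
        if col_missing.any():
            per_reason[f"missing_{col}"] = int(col_missing.sum())
        missing_mask |= raw[col].isna()
    # cognitive inputs: need a dementia flag or a test score
    have_cog = pd.Series(False, index=raw.index)
    for col in ("dementia_dx", "cog_score"):
        if col in raw.columns:
            have_cog |= raw[col].notna()
    cog_missing = ~have_cog & ~missing_mask
    if cog_missing.any():
        per_reason["missing_cognitive_inputs"] = int(cog_missing.sum())
    missing_mask |= ~have_cog
    # zero-exposure records cannot be annualized
    zero_fu = (raw["followup_months"] <= 0) & ~missing_mask
    if zero_fu.any():
        per_reason["zero_followup"] = int(zero_fu.sum())
    missing_mask |= raw["followup_months"] <= 0

    after_missing = raw[~missing_mask]
    if enrollment_column in raw.columns:
        enrolled = after_missing[enrollment_column].astype(bool)
    else:
        enrolled = pd.Series(True, index=after_missing.index)
    n_enroll_excl = int((~enrolled).sum())
    if n_enroll_excl:
        per_reason["not_continuously_enrolled"] = n_enroll_excl
    analytic = after_missing[enrolled]
    report = ExclusionReport(
        n_initial=n_initial,
        n_missing_excluded=int(missing_mask.sum()),
        n_enrollment_excluded=n_enroll_excl,
        per_reason=per_reason,
    )
    log.info(
        "exclusions: %d initial, %d missing (%s%%), %d enrollment (%s%%), %d analytic",
        report.n_initial,
        report.n_missing_excluded,
        report.pct_missing,
        report.n_enrollment_excluded,
        report.pct_enrollment,
        report.n_analytic,
    )
    return analytic, report


# --- descriptive table ------------------------------------------------------


def describe(analytic: pd.DataFrame) -> pd.DataFrame:
    """Characteristics by sex and cognitive-impairment status (the shape of
    the study's descriptive table): n, mean (SD) age, race %, comorbidity
    burden, ADL categories, frailty, CFI, annualized THC, deaths.

    Requires a phenotyped + annualized table. Optional columns absent from
    the data are reported as "—".
    """
    rows = []
    for sex in ("female", "male"):
        for ci_status, label in ((1, "cognitive impairment"), (0, "no cognitive impairment")):
            d = analytic[
                (analytic["sex"] == sex) & (analytic["cognitively_impaired"] == ci_status)
            ]
            n = len(d)
            row: dict[str, object] = {"sex": sex, "group": label, "n": n}
            if n == 0:
                rows.append(row)
                continue

            def mean_sd(col):
                if col not in d.columns or d[col].isna().all():
                    return "—"
                sd = d[col].std(ddof=1)
                return f"{d[col].mean():.1f} ({0.0 if np.isnan(sd) else sd:.1f})"

            row["age_mean_sd"] = mean_sd("age")
            for race in ("nh_white", "nh_black", "other"):
                row[f"race_{race}_pct"] = fmt_pct(100 * (d["race"] == race).mean())
            row["comorbidity_mean_sd"] = mean_sd("comorbidity_count")
            row["hcc_mean_sd"] = mean_sd("hcc_score")
            adl = d["n_adl_impairments"]
            row["adl_none_pct"] = fmt_pct(100 * (adl == 0).mean())
            row["adl_1_2_pct"] = fmt_pct(100 * adl.between(1, 2).mean())
            row["adl_3_4_pct"] = fmt_pct(100 * (adl >= 3).mean())
            row["frail_pct"] = fmt_pct(100 * (d["frailty_category"] == "frail").mean())
            if "cfi" in d.columns and d["cfi"].notna().any():
                row["cfi_mean_sd"] = f"{d['cfi'].mean():.2f} ({d['cfi'].std(ddof=1):.2f})"
            else:
                row["cfi_mean_sd"] = "—"
            thc = d["annualized_thc"]
            row["annualized_thc_mean_sd"] = (
                f"{fmt_dollars(thc.mean())} ({fmt_dollars(thc.std(ddof=1))})"
            )
            for col, name in (("hospitalized", "hospitalized_pct"), ("pac_stay", "pac_pct")):
                row[name] = (
                    fmt_pct(100 * d[col].astype(float).mean()) if col in d.columns else "—"
                )
            row["died_pct"] = fmt_pct(100 * d["died"].astype(float).mean())
            rows.append(row)
    return pd.DataFrame(rows)


# --- full analysis ----------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Configuration of one full pipeline run."""

    cohort_csv: Optional[str] = None
    preset_name: Optional[str] = "paper-like"
    seed: int = 0
    n_reps: int = 1000
    zero_rule: str = "replace_one"
    explanatory_sets: tuple[str, ...] = EXPLANATORY_ORDER
    base_covariates: tuple[Term, ...] = DEFAULT_BASE_COVARIATES
    norms: Optional[ReferenceNorms] = None
    inflation: Optional[InflationTable] = None
    cognitive_rule: str = "cohort"
    run_sensitivity_hcc: bool = True
    run_sensitivity_pooled: bool = True

    def __post_init__(self) -> None:
        # education defines cognitive impairment, so it may never be adjusted for
        if any(t.column == "education" for t in self.base_covariates):
            raise ConfigurationError(
                "education cannot be a model covariate: it is part of the "
                "cognitive-impairment definition"
            )
        if self.cohort_csv is None and self.preset_name not in PRESETS:
            raise ConfigurationError("config needs a cohort CSV or a generator preset")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "cohort_csv",
            "preset_name",
            "seed",
            "n_reps",
            "zero_rule",
            "cognitive_rule",
            "run_sensitivity_hcc",
            "run_sensitivity_pooled",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "explanatory_sets" in raw:
            kwargs["explanatory_sets"] = tuple(raw["explanatory_sets"])
        if "base_covariates" in raw:
            kwargs["base_covariates"] = tuple(
                Term(t["column"], t.get("kind", "linear"), t.get("reference"))
                for t in raw["base_covariates"]
            )
        if "norms" in raw:
            kwargs["norms"] = ReferenceNorms(
                mean=raw["norms"]["mean"], sd=raw["norms"]["sd"]
            )
        if "inflation" in raw:
            kwargs["inflation"] = InflationTable(
                multipliers={int(k): float(v) for k, v in raw["inflation"].items()}
            )
        return cls(**kwargs)


def _result_dict(res: DecompositionResult) -> dict:
    ci = lambda c: None if c is None else [c[0], c[1]]
    return {
        "total": res.total,
        "direct": res.direct,
        "indirect": res.indirect,
        "indirect_share_pct": res.indirect_share if res.share_defined else None,
        "share_defined": res.share_defined,
        "ci_total": ci(res.ci_total),
        "ci_direct": ci(res.ci_direct),
        "ci_indirect": ci(res.ci_indirect),
        "n_obs": res.n_obs,
        "n_reps_failed": res.n_reps_failed,
        "ci_approximate": res.ci_approximate,
    }


def _table3_rows(sex: str, es: str, res: DecompositionResult, base_res: DecompositionResult):
    # every emitted decomposition row must satisfy additivity exactly
    assert abs((res.direct + res.indirect) - res.total) < 1e-9
    fmt_ci = lambda c: ("", "") if c is None else (fmt_dollars(c[0]), fmt_dollars(c[1]))
    lo_d, hi_d = fmt_ci(res.ci_direct)
    lo_i, hi_i = fmt_ci(res.ci_indirect)
    share = fmt_share(res.indirect, res.total) if res.share_defined else "undefined"
    return [
        {
            "sex": sex,
            "model": MODEL_LABELS[es],
            "component": "direct",
            "estimate": fmt_dollars(res.direct),
            "ci_low": lo_d,
            "ci_high": hi_d,
            "share_pct": "",
        },
        {
            "sex": sex,
            "model": MODEL_LABELS[es],
            "component": "indirect",
            "estimate": fmt_dollars(res.indirect),
            "ci_low": lo_i,
            "ci_high": hi_i,
            "share_pct": share,
        },
    ]


@dataclass
class AnalysisReport:
    exclusions: ExclusionReport
    table2: pd.DataFrame
    table3: pd.DataFrame
    results: dict  # full-precision nested results
    analytic: pd.DataFrame


def prepare_cohort(config: AnalysisConfig) -> tuple[pd.DataFrame, ExclusionReport]:
    """Load or generate the cohort, run exclusions, phenotype and annualize."""
    if config.cohort_csv is not None:
        raw = pd.read_csv(config.cohort_csv)
        log.info("loaded %d rows from %s", len(raw), config.cohort_csv)
    else:
        params = preset(config.preset_name, seed=config.seed)
        raw = generate(params)
        if config.norms is None:
            config.norms = params.norms
        log.info("generated %d rows from preset %r", len(raw), config.preset_name)
    analytic, report = apply_exclusions(raw)
    if len(analytic) == 0:
        raise ValidationError("no analyzable records remain after exclusions")
    analytic = phenotype_cohort(analytic, norms=config.norms, rule=config.cognitive_rule)
    analytic = annualize_cohort(analytic, table=config.inflation)
    return analytic, report


def run(config: AnalysisConfig, out_dir: Optional[str] = None) -> AnalysisReport:
    """Execute the full sex-stratified analysis and (optionally) write the
    report files into ``out_dir``."""
    analytic, excl = prepare_cohort(config)
    table2 = describe(analytic)
    results: dict = {"per_sex": {}, "sensitivity": {}}
    table3_rows: list[dict] = []
    per_sex_results: dict[str, dict[str, DecompositionResult]] = {}

    for sex in ("female", "male"):
        d = analytic[analytic["sex"] == sex]
        sex_block: dict[str, object] = {}
        sex_results: dict[str, DecompositionResult] = {}
        base_res = None
        for es in config.explanatory_sets:
            spec = DecompositionSpec(
                explanatory_set=es,
                base_covariates=config.base_covariates,
                bootstrap=BootstrapSettings(n_reps=config.n_reps, seed=config.seed),
                zero_rule=config.zero_rule,
            )
            log.info("decomposing %s / %s (n=%d)", sex, es, len(d))
            res = bootstrap_cis(d, spec)
            sex_results[es] = res
            sex_block[es] = _result_dict(res)
            if base_res is None:
                base_res = res
                table3_rows.append(
                    {
                        "sex": sex,
                        "model": "Base",
                        "component": "total",
                        "estimate": fmt_dollars(res.total),
                        "ci_low": fmt_dollars(res.ci_total[0]),
                        "ci_high": fmt_dollars(res.ci_total[1]),
                        "share_pct": "",
                    }
                )
            table3_rows.extend(_table3_rows(sex, es, res, base_res))
        per_sex_results[sex] = sex_results
        results["per_sex"][sex] = sex_block

    if config.run_sensitivity_hcc and analytic["hcc_score"].notna().all():
        hcc_covariates = tuple(
            Term("hcc_score", "linear") if t.column == "comorbidity_count" else t
            for t in config.base_covariates
        )
        results["sensitivity"]["hcc"] = {}
        for sex in ("female", "male"):
            d = analytic[analytic["sex"] == sex]
            block = {}
            for es in config.explanatory_sets:
                spec = DecompositionSpec(
                    explanatory_set=es,
                    base_covariates=hcc_covariates,
                    bootstrap=BootstrapSettings(n_reps=config.n_reps, seed=config.seed),
                    zero_rule=config.zero_rule,
                )
                block[es] = _result_dict(bootstrap_cis(d, spec))
            results["sensitivity"]["hcc"][sex] = block

    if config.run_sensitivity_pooled:
        n_f = int((analytic["sex"] == "female").sum())
        n_m = int((analytic["sex"] == "male").sum())
        results["sensitivity"]["pooled"] = {}
        for weights in ("equal", "by_n"):
            block = {}
            for es in config.explanatory_sets:
                pooled = pool_sexes(
                    per_sex_results["female"][es],
                    per_sex_results["male"][es],
                    weights=weights,
                    n_f=n_f,
                    n_m=n_m,
                )
                block[es] = _result_dict(pooled)
            results["sensitivity"]["pooled"][weights] = block

    table3 = pd.DataFrame(table3_rows)
    report = AnalysisReport(
        exclusions=excl, table2=table2, table3=table3, results=results, analytic=analytic
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AnalysisReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table2.to_csv(out / "table2.csv", index=False)
    report.table3.to_csv(out / "table3.csv", index=False)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(report.exclusions.to_dict(), fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.results, fh, indent=2, sort_keys=True)
    try:
        plot_decomposition(report, out / "fig1.svg")
    except Exception as exc:  # plotting must never sink the analysis
        log.warning("figure generation failed: %s", exc)


def plot_decomposition(report: AnalysisReport, path) -> None:
    """Stacked direct/indirect bars per explanatory set, one panel per sex."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=True)
    for ax, sex in zip(axes, ("female", "male")):
        block = report.results["per_sex"][sex]
        sets = [es for es in EXPLANATORY_ORDER if es in block]
        direct = [block[es]["direct"] for es in sets]
        indirect = [block[es]["indirect"] for es in sets]
        x = np.arange(len(sets))
        ax.bar(x, direct, 0.6, label="direct", color="#4878a8")
        ax.bar(x, indirect, 0.6, bottom=direct, label="indirect", color="#e49444")
        ax.set_xticks(x)
        ax.set_xticklabels([es.replace("_", "\n") for es in sets], fontsize=8)
        ax.set_title(sex.capitalize())
        ax.axhline(0, color="k", lw=0.5)
    axes[0].set_ylabel("Incremental annualized THC (2023 USD)")
    axes[0].legend()
    fig.suptitle("Incremental costs of cognitive impairment: direct vs indirect")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
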