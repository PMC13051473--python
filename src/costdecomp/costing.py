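"""Death-truncated annualization and inflation standardization of total
healthcare costs (THC).

Cumulative THC over up to 36 months of follow-up is converted to dollars per
person-year by dividing by the observed follow-up; for decedents the
follow-up is truncated at death, so a participant who accrued $10,000 before
dying at month 12 contributes $10,000/yr. Inflation standardization to a
reference dollar-year is a simple year → multiplier table supplied in the
analysis config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError

REFERENCE_YEAR = 2023

#: Cost components summed into THC when supplied as separate columns.
COST_COMPONENT_COLUMNS = (
    "cost_hospital",
    "cost_snf",
    "cost_outpatient",
    "cost_dme",
    "cost_hhc",
)


@dataclass(frozen=True)
class AnnualizedCost:
    participant_id: str
    annualized_thc: float
    followup_years: float

    def __post_init__(self) -> None:
        if self.annualized_thc < 0:
            raise ValidationError("annualized THC cannot be negative")
        if not 0 < self.followup_years <= 3:
            raise ValidationError("follow-up must lie in (0, 3] years")


@dataclass(frozen=True)
class InflationTable:
    """Year → multiplier converting nominal dollars to reference-year dollars."""

    multipliers: Mapping[int, float]
    reference_year: int = REFERENCE_YEAR

    def __post_init__(self) -> None:
        for year, m in self.multipliers.items():
            if not m > 0:
                raise ConfigurationError(f"inflation multiplier for {year} must be > 0")
        ref = self.multipliers.get(self.reference_year)
        if ref is not None and abs(ref - 1.0) > 1e-12:
            raise ConfigurationError(
                f"multiplier for the reference year {self.reference_year} must equal 1"
            )

    def multiplier(self, year: int) -> float:
        if year not in self.multipliers:
            raise ConfigurationError(f"no inflation multiplier configured for {year}")
        return self.multipliers[year]


def annualize(
    cumulative_cost: float,
    followup_months: float,
    died: bool,
    participant_id: str = "",
) -> AnnualizedCost:
    """Annualized THC = cumulative cost / (follow-up months / 12).

    Survivors must have the full 36 months of follow-up; decedents are
    truncated at death. Zero-exposure records (followup <= 0) cannot be
    annualized and are excluded upstream.
    """
    if cumulative_cost < 0:
        raise ValidationError("cumulative cost cannot be negative")
    if followup_months <= 0:
        raise ValidationError("cannot annualize zero or negative follow-up")
    if followup_months > 36:
        raise ValidationError("follow-up exceeds the 36-month ascertainment window")
    if not died and abs(followup_months - 36.0) > 1e-9:
        raise ValidationError(
            "participants who survived follow-up must have 36 months of exposure"
        )
    years = followup_months / 12.0
    return AnnualizedCost(
        participant_id=participant_id,
        annualized_thc=cumulative_cost / years,
        followup_years=years,
    )


def standardize(cost: float, year: int, table: InflationTable) -> float:
    """Convert nominal dollars in ``year`` to reference-year dollars."""
    if cost < 0:
        raise ValidationError("cost cannot be negative")
    return cost * table.multiplier(year)


def annualize_cohort(
    df: pd.DataFrame,
    table: InflationTable | None = None,
    cost_year_column: str = "cost_year",
) -> pd.DataFrame:
    """Annualize every participant's THC, optionally inflation-standardizing.

    ``cumulative_cost`` may be supplied directly or as the component columns
    in :data:`COST_COMPONENT_COLUMNS`, which are then summed. Returns the
    table with ``followup_years`` and ``annualized_thc`` columns added.
    """
    out = df.copy()
    if "cumulative_cost" not in out.columns:
        missing = [c for c in COST_COMPONENT_COLUMNS if c not in out.columns]
        if missing:
            raise ConfigurationError(
                f"no cumulative_cost column and missing components: {missing}"
            )
        out["cumulative_cost"] = out[list(COST_COMPONENT_COLUMNS)].sum(axis=1)
    cost = out["cumulative_cost"].astype(float)
    if table is not None:
        if cost_year_column not in out.columns:
            raise ConfigurationError(
                f"inflation table supplied but column {cost_year_column!r} is absent"
            )
        cost = cost * out[cost_year_column].map(table.multiplier)
    annualized = [
        annualize(c, m, bool(d), participant_id=str(i))
        for c, m, d, i in zip(
            cost, out["followup_months"], out["died"], out["id"], strict=True
        )
    ]
    out["followup_years"] = [a.followup_years for a in annualized]
    out["annualized_thc"] = [a.annualized_thc for a in annualized]
    return out
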