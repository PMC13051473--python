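"""Difference-method decomposition of incremental costs, with bootstrap CIs.

The total incremental cost of cognitive impairment is the marginally
standardized cost contrast from a base gamma/log GLM adjusted for age, race,
geographic region and comorbidity burden. Re-estimating the contrast after
additionally adjusting for candidate explanatory variables (ADL functional
impairments, the phenotypic frailty category, the claims-based frailty index
CFI, or all three) yields the *direct* component — the part of the contrast
not running through those variables. The *indirect* component is defined by
subtraction, so direct + indirect = total holds exactly on every run.

Interval estimation is by percentile bootstrap: participants are resampled
with replacement (within sex strata when stratified), both models are refit
on each resample, and 2.5th/97.5th percentiles of each component are
reported. The indirect interval is taken over replicate-wise total − direct
differences, preserving the within-replicate correlation of the two fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, FitError
from .glm_gamma import (
    Design,
    ModelSpec,
    Term,
    apply_zero_rule,
    build_design,
    irls_gamma_log,
    marginal_means_from_design,
)

#: Default base adjustment: age (linear), race (ref non-Hispanic White),
#: geographic region (ref first alphabetically), comorbidity count (linear).
DEFAULT_BASE_COVARIATES: tuple[Term, ...] = (
    Term("age", "linear"),
    Term("race", "categorical", reference="nh_white"),
    Term("region", "categorical"),
    Term("comorbidity_count", "linear"),
)

#: Candidate explanatory-variable sets, in the codings used throughout:
#: ADL count categorical 0-4 (ref 0), frailty category (ref robust), CFI linear.
EXPLANATORY_SETS: dict[str, tuple[Term, ...]] = {
    "functional_impairments": (Term("n_adl_impairments", "categorical", reference="0"),),
    "phenotypic_frailty": (Term("frailty_category", "categorical", reference="robust"),),
    "cfi": (Term("cfi", "linear"),),
}
EXPLANATORY_SETS["all_three"] = (
    EXPLANATORY_SETS["functional_impairments"]
    + EXPLANATORY_SETS["phenotypic_frailty"]
    + EXPLANATORY_SETS["cfi"]
)


@dataclass(frozen=True)
class BootstrapSettings:
    n_reps: int = 1000
    seed: int = 0
    stratified_by_sex: bool = True


@dataclass(frozen=True)
class DecompositionSpec:
    explanatory_set: str = "functional_impairments"
    outcome: str = "annualized_thc"
    exposure: str = "cognitively_impaired"
    base_covariates: tuple[Term, ...] = DEFAULT_BASE_COVARIATES
    bootstrap: BootstrapSettings = BootstrapSettings()
    zero_rule: str = "replace_one"

    def __post_init__(self) -> None:
        if self.explanatory_set not in EXPLANATORY_SETS:
            raise ConfigurationError(
                f"unknown explanatory set {self.explanatory_set!r}; "
                f"choose one of {sorted(EXPLANATORY_SETS)}"
            )
        base_cols = {t.column for t in self.base_covariates}
        overlap = base_cols & {t.column for t in EXPLANATORY_SETS[self.explanatory_set]}
        if overlap:
            raise ConfigurationError(
                f"explanatory terms overlap the base adjustment: {sorted(overlap)}"
            )

    @property
    def base_model(self) -> ModelSpec:
        return ModelSpec(self.outcome, self.exposure, self.base_covariates)

    @property
    def adjusted_model(self) -> ModelSpec:
        return self.base_model.with_covariates(EXPLANATORY_SETS[self.explanatory_set])


@dataclass
class DecompositionResult:
    """Total/direct/indirect incremental cost, dollars per person-year."""

    total: float
    direct: float
    explanatory_set: str = ""
    n_obs: int = 0
    ci_total: Optional[tuple[float, float]] = None
    ci_direct: Optional[tuple[float, float]] = None
    ci_indirect: Optional[tuple[float, float]] = None
    replicates: Optional[np.ndarray] = None  # shape (n_kept, 2): total, direct
    n_reps_requested: int = 0
    n_reps_failed: int = 0
    ci_approximate: bool = False

    @property
    def indirect(self) -> float:
        return self.total - self.direct

    @property
    def share_defined(self) -> bool:
        return self.total > 0

    @property
    def indirect_share(self) -> float:
        """Indirect component as a percentage of the total; NaN when the
        total is non-positive (flagged via ``share_defined``)."""
        if not self.share_defined:
            return float("nan")
        return 100.0 * self.indirect / self.total


class _Prepared:
    """Designs and outcome prebuilt on the full data; bootstrap replicates
    row-slice these arrays instead of rebuilding matrices."""

    def __init__(self, data: pd.DataFrame, spec: DecompositionSpec):
        y_raw = data[spec.outcome].to_numpy(dtype=float)
        y, keep, self.n_zero = apply_zero_rule(y_raw, spec.zero_rule)
        rows = data.loc[keep] if not keep.all() else data
        self.y = y[keep]
        self.base = build_design(spec.base_model, rows)
        self.adjusted = build_design(spec.adjusted_model, rows)
        self.sex = (
            rows["sex"].to_numpy()
            if spec.bootstrap.stratified_by_sex and "sex" in rows.columns
            else None
        )
        self.n = len(self.y)
        self.beta_base: Optional[np.ndarray] = None
        self.beta_adj: Optional[np.ndarray] = None

    def contrasts(self, idx: Optional[np.ndarray] = None) -> tuple[float, float]:
        """Fit both models on the (optionally resampled) rows and return
        (total, direct) incremental costs."""
        if idx is None:
            Xb, Xa, y = self.base.X, self.adjusted.X, self.y
        else:
            Xb, Xa, y = self.base.X[idx], self.adjusted.X[idx], self.y[idx]
        out = []
        for X, design, warm in (
            (Xb, self.base, self.beta_base),
            (Xa, self.adjusted, self.beta_adj),
        ):
            try:
                factor = linalg.cho_factor(X.T @ X, lower=True)
            except linalg.LinAlgError as exc:  # dropped level in a resample
                raise FitError(f"singular design in resample: {exc}") from exc
            beta, _, _, converged = irls_gamma_log(X, y, beta0=warm, xtx_factor=factor)
            if not converged:
                raise FitError("IRLS did not converge on resample")
            mm = marginal_means_from_design(beta, Design(X, design.columns))
            out.append((beta, mm.incremental))
        if idx is None:
            self.beta_base, self.beta_adj = out[0][0], out[1][0]
        return out[0][1], out[1][1]


def decompose(data: pd.DataFrame, spec: DecompositionSpec) -> DecompositionResult:
    """Point decomposition: total from the base model, direct from the
    explanatory-adjusted model, indirect by subtraction."""
    prep = _Prepared(data, spec)
    total, direct = prep.contrasts()
    return DecompositionResult(
        total=total, direct=direct, explanatory_set=spec.explanatory_set, n_obs=prep.n
    )


def _resample_indices(
    rng: np.random.Generator, n: int, sex: Optional[np.ndarray]
) -> np.ndarray:
    if sex is None:
        return rng.integers(0, n, size=n)
    idx = np.empty(n, dtype=np.int64)
    pos = 0
    for stratum in np.unique(sex):
        members = np.flatnonzero(sex == stratum)
        k = len(members)
        idx[pos : pos + k] = members[rng.integers(0, k, size=k)]
        pos += k
    return idx


def bootstrap_cis(data: pd.DataFrame, spec: DecompositionSpec) -> DecompositionResult:
    """Percentile-bootstrap 95% intervals for all three components.

    Replicate r draws from RNG substream r of the configured seed, so
    results are reproducible and independent of execution order. Replicates
    whose refit fails (e.g., a covariate level vanished from the resample)
    are dropped and counted; a warning is attached when more than 5% drop.
    """
    bs = spec.bootstrap
    if bs.n_reps < 2:
        raise ConfigurationError("bootstrap requires n_reps >= 2")
    prep = _Prepared(data, spec)
    total, direct = prep.contrasts()  # also sets warm-start coefficients
    streams = np.random.SeedSequence(bs.seed).spawn(bs.n_reps)
    reps = []
    n_failed = 0
    for r in range(bs.n_reps):
        rng = np.random.default_rng(streams[r])
        idx = _resample_indices(rng, prep.n, prep.sex)
        try:
            reps.append(prep.contrasts(idx))
        except FitError:
            n_failed += 1
    if n_failed > 0.05 * bs.n_reps:
        import warnings

        warnings.warn(
            f"{n_failed}/{bs.n_reps} bootstrap replicates failed to fit",
            stacklevel=2,
        )
    arr = np.asarray(reps, dtype=float)
    totals, directs = arr[:, 0], arr[:, 1]
    indirects = totals - directs
    pct = lambda v: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
    return DecompositionResult(
        total=total,
        direct=direct,
        explanatory_set=spec.explanatory_set,
        n_obs=prep.n,
        ci_total=pct(totals),
        ci_direct=pct(directs),
        ci_indirect=pct(indirects),
        replicates=arr,
        n_reps_requested=bs.n_reps,
        n_reps_failed=n_failed,
    )


def pool_sexes(
    res_f: DecompositionResult,
    res_m: DecompositionResult,
    weights: str | tuple[float, float] = "equal",
    n_f: Optional[int] = None,
    n_m: Optional[int] = None,
) -> DecompositionResult:
    """Pool the female and male decompositions: each component combined as
    w_f·x_f + w_m·x_m with equal weights or weights proportional to sample
    size. Intervals pool bootstrap replicates when both sides carry the same
    number; otherwise endpoints are weighted and flagged approximate."""
    if res_f.explanatory_set != res_m.explanatory_set:
        raise ConfigurationError("cannot pool results from different explanatory sets")
    if isinstance(weights, (tuple, list)):
        w_f, w_m = float(weights[0]), float(weights[1])
        if abs(w_f + w_m - 1.0) > 1e-9:
            raise ConfigurationError("explicit pooling weights must sum to 1")
    elif weights == "equal":
        w_f = w_m = 0.5
    elif weights == "by_n":
        n_f = n_f if n_f is not None else res_f.n_obs
        n_m = n_m if n_m is not None else res_m.n_obs
        if not (n_f and n_m):
            raise ConfigurationError("by_n pooling requires sample sizes")
        w_f = n_f / (n_f + n_m)
        w_m = 1.0 - w_f
    else:
        raise ConfigurationError(f"unknown pooling weights {weights!r}")
    pooled = DecompositionResult(
        total=w_f * res_f.total + w_m * res_m.total,
        direct=w_f * res_f.direct + w_m * res_m.direct,
        explanatory_set=res_f.explanatory_set,
        n_obs=res_f.n_obs + res_m.n_obs,
    )
    have_reps = (
        res_f.replicates is not None
        and res_m.replicates is not None
        and len(res_f.replicates) == len(res_m.replicates)
    )
    pct = lambda v: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
    if have_reps:
        arr = w_f * res_f.replicates + w_m * res_m.replicates
        pooled.replicates = arr
        pooled.ci_total = pct(arr[:, 0])
        pooled.ci_direct = pct(arr[:, 1])
        pooled.ci_indirect = pct(arr[:, 0] - arr[:, 1])
    elif res_f.ci_total is not None and res_m.ci_total is not None:
        comb = lambda a, b: (w_f * a[0] + w_m * b[0], w_f * a[1] + w_m * b[1])
        pooled.ci_total = comb(res_f.ci_total, res_m.ci_total)
        pooled.ci_direct = comb(res_f.ci_direct, res_m.ci_direct)
        pooled.ci_indirect = comb(res_f.ci_indirect, res_m.ci_indirect)
        pooled.ci_approximate = True
    return pooled
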