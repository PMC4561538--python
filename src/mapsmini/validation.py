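"""Mixed-model validation of audit scores against physical-activity outcomes.

For each audit item (and the total score), each outcome class, and each age
group, a linear mixed model regresses the outcome on the item score with
demographic covariates and macrolevel walkability as fixed effects and a
random intercept for census block group (the recruitment cluster).  Models
are fit by REML; the predictor's Wald t statistic and a two-sided
normal-approximation p-value are reported, which is appropriate at the
cluster counts these studies use.  No multiple-testing correction is
applied by default (per-test alpha of 0.05); a Benjamini-Hochberg option
is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .accelerometry import AgeGroup
from .audit import Category, ItemDefinition, default_catalog

__all__ = [
    "ModelSpec",
    "ModelResult",
    "AssociationSummary",
    "QuintileContrast",
    "fit_item_model",
    "run_association_matrix",
    "count_significant",
    "benjamini_hochberg",
    "quintile_contrast",
    "matrix_to_frame",
    "default_design_na",
    "TOTAL_SCORE_ID",
]

TOTAL_SCORE_ID = "total_score"

BASE_COVARIATES = ["age", "sex", "education_college", "nonwhite", "walkability_high"]


@dataclass
class ModelSpec:
    """One item-outcome-group regression."""

    outcome: str
    predictor: str
    age_group: Optional[str] = None
    covariates: list[str] = field(default_factory=lambda: list(BASE_COVARIATES))
    cluster: str = "block_group_id"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} cannot also be a covariate")

    @classmethod
    def for_group(cls, outcome: str, predictor: str, age_group: str,
                  alpha: float = 0.05) -> "ModelSpec":
        covs = list(BASE_COVARIATES)
        if AgeGroup(age_group) is AgeGroup.OLDER_ADULT:
            covs.append("mobility_impairment")
        return cls(outcome=outcome, predictor=predictor, age_group=age_group,
                   covariates=covs, alpha=alpha)


@dataclass
class ModelResult:
    item_id: str
    outcome: str
    age_group: Optional[str]
    beta: float = np.nan
    se: float = np.nan
    t_value: float = np.nan
    p_value: float = np.nan
    n_obs: int = 0
    converged: bool = False
    available: bool = True
    error: Optional[str] = None


@dataclass
class AssociationSummary:
    outcome_class: str
    n_significant: int
    n_tests: int

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_tests


@dataclass
class QuintileContrast:
    outcome: str
    age_group: str
    mean_by_quintile: dict[int, float]
    abs_difference: float
    ratio_percent: Optional[float]  # None when the bottom-quintile mean is 0


def fit_item_model(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one random-intercept linear mixed model and report the Wald test
    of the predictor's fixed effect.

    Rows missing the outcome, predictor, any covariate, or the cluster id
    are dropped (listwise).  Covariates that are constant after deletion
    are silently excluded from the design; a constant predictor raises.
    Numerical failure or non-convergence is returned flagged, never
    silently dropped.
    """
    sub = table
    if spec.age_group is not None and "age_group" in table.columns:
        sub = table[table["age_group"] == spec.age_group]
    cols = [spec.outcome, spec.predictor, spec.cluster] + spec.covariates
    missing_cols = [c for c in cols if c not in sub.columns]
    if missing_cols:
        raise ValueError(f"analysis table lacks column(s) {missing_cols}")
    sub = sub[cols].dropna()

    result = ModelResult(item_id=spec.predictor, outcome=spec.outcome,
                         age_group=spec.age_group, n_obs=len(sub))
    if len(sub) == 0:
        result.available = False
        result.error = "no complete observations"
        return result
    if sub[spec.cluster].nunique() < 2:
        raise ValueError(f"need at least 2 clusters, got {sub[spec.cluster].nunique()}")
    if sub[spec.predictor].nunique() < 2:
        raise ValueError(f"predictor {spec.predictor!r} is constant")

    covs = [c for c in spec.covariates if sub[c].nunique() > 1]
    exog = sm.add_constant(sub[[spec.predictor] + covs].astype(float))
    endog = sub[spec.outcome].astype(float)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.MixedLM(endog, exog, groups=sub[spec.cluster])
            fit = model.fit(reml=True)
        conv_warned = any("converge" in str(w.message).lower() for w in caught)
    except (np.linalg.LinAlgError, ValueError) as exc:
        result.error = f"{type(exc).__name__}: {exc}"
        return result

    result.beta = float(fit.params[spec.predictor])
    result.se = float(fit.bse[spec.predictor])
    result.t_value = result.beta / result.se
    result.p_value = float(2.0 * stats.norm.sf(abs(result.t_value)))
    result.converged = bool(getattr(fit, "converged", True)) and not conv_warned
    return result


def default_design_na(item_id: str, outcome_class: str, age_group: str) -> bool:
    """Cells the study design leaves empty: adults wore no accelerometer,
    and the commercial-segment item was not available for the older-adult
    cohort."""
    if outcome_class == "mvpa" and age_group == AgeGroup.ADULT.value:
        return True
    if item_id == "commercial" and age_group == AgeGroup.OLDER_ADULT.value:
        return True
    return False


def run_association_matrix(
    table: pd.DataFrame,
    catalog: Optional[Sequence[ItemDefinition]] = None,
    outcome_classes: Sequence[str] = ("transport", "leisure", "mvpa"),
    age_groups: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    design_na: Callable[[str, str, str], bool] = default_design_na,
) -> list[ModelResult]:
    """Fit the full item x outcome x age-group matrix.

    Rows are the 14 tabled items plus the total score (the bicycle item is
    not part of the validation tables).  Cells the design leaves empty are
    returned as explicit not-available records; per-cell model failures are
    recorded and the run continues.
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    predictors = [it.item_id for it in catalog
                  if it.category is not Category.BICYCLE_FACILITIES]
    predictors.append(TOTAL_SCORE_ID)
    if age_groups is None:
        present = set(table["age_group"].dropna().unique()) if len(table) else set()
        age_groups = [g.value for g in AgeGroup if g.value in present]

    results: list[ModelResult] = []
    for outcome in outcome_classes:
        for group in age_groups:
            for pred in predictors:
                if design_na(pred, outcome, group):
                    results.append(ModelResult(
                        item_id=pred, outcome=outcome, age_group=group,
                        available=False, error="not available by design"))
                    continue
                col = "percent_of_max" if pred == TOTAL_SCORE_ID else pred
                spec = ModelSpec.for_group(outcome, col, group, alpha=alpha)
                try:
                    res = fit_item_model(table, spec)
                except ValueError as exc:
                    res = ModelResult(item_id=pred, outcome=outcome,
                                      age_group=group, error=str(exc))
                res.item_id = pred
                results.append(res)
    return results


def count_significant(results: Iterable[ModelResult], alpha: float = 0.05,
                      outcome_class: str = "") -> AssociationSummary:
    """Count associations with p <= alpha among available tests."""
    results = list(results)
    avail = [r for r in results if r.available]
    if not avail:
        raise ValueError("no available results to summarize")
    if not outcome_class:
        names = {r.outcome for r in avail}
        outcome_class = names.pop() if len(names) == 1 else "all"
    n_sig = sum(1 for r in avail if np.isfinite(r.p_value) and r.p_value <= alpha)
    return AssociationSummary(outcome_class=outcome_class,
                              n_significant=n_sig, n_tests=len(avail))


def benjamini_hochberg(results: Sequence[ModelResult], alpha: float = 0.05) -> np.ndarray:
    """FDR-adjusted rejection flags for the available tests (optional; the
    default reporting uses per-test alpha)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.array([r.p_value for r in results if r.available and np.isfinite(r.p_value)])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def quintile_contrast(table: pd.DataFrame, outcome: str, age_group: str) -> QuintileContrast:
    """Unadjusted mean outcome per score quintile, with the top-minus-bottom
    difference and its percentage ratio (undefined when the bottom mean is
    zero)."""
    sub = table[table["age_group"] == age_group] if "age_group" in table.columns else table
    sub = sub[[outcome, "quintile"]].dropna()
    means: dict[int, float] = {}
    for q in range(1, 6):
        grp = sub.loc[sub["quintile"] == q, outcome]
        if len(grp) == 0:
            raise ValueError(f"quintile {q} is empty for outcome {outcome!r}, "
                             f"age group {age_group!r}")
        means[q] = float(grp.mean())
    diff = means[5] - means[1]
    ratio = 100.0 * diff / means[1] if means[1] != 0 else None
    return QuintileContrast(outcome=outcome, age_group=age_group,
                            mean_by_quintile=means, abs_difference=diff,
                            ratio_percent=ratio)


def matrix_to_frame(results: Iterable[ModelResult]) -> pd.DataFrame:
    """Tidy results table (one row per item x outcome x age group)."""
    rows = []
    for r in results:
        rows.append({
            "item_id": r.item_id, "outcome": r.outcome, "age_group": r.age_group,
            "beta": r.beta, "se": r.se, "t_value": r.t_value, "p_value": r.p_value,
            "n_obs": r.n_obs, "converged": r.converged, "available": r.available,
            "error": r.error if r.error else "",
        })
    return pd.DataFrame(rows)
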