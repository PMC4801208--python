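"""Per-cohort Cox proportional-hazards association of AF with the gene score.

Three nested covariate tiers are fitted: tier 1 adjusts for age, sex and
center/cohort indicators; tier 2 adds education, height, smoking, BMI,
systolic/diastolic blood pressure, antihypertensive use, diabetes, left
ventricular hypertrophy and prior stroke/CHD/heart failure; tier 3 adds the
continuous lipid level of the score's fraction and lipid-medication use.
Cohorts missing a covariate adjust only for what they have; constant columns
(e.g. sex in a single-sex cohort) are dropped and reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .score import GeneScore
from .simulate import CohortData

__all__ = ["TIER_COVARIATES", "covariates_for", "CoxResult", "fit_cox"]

log = logging.getLogger(__name__)

_TIER1 = ["age", "sex", "center", "cohort"]
_TIER2 = _TIER1 + [
    "education",
    "height",
    "smoking",
    "bmi",
    "sbp",
    "dbp",
    "antihypertensive",
    "diabetes",
    "lvh",
    "prior_stroke",
    "prior_chd",
    "prior_hf",
]


def TIER_COVARIATES(tier: int, fraction: str | None = None) -> list[str]:
    """Covariate list for an adjustment tier (tiers are nested)."""
    if tier == 1:
        return list(_TIER1)
    if tier == 2:
        return list(_TIER2)
    if tier == 3:
        extra = [f"lipid_{fraction.lower()}"] if fraction else []
        return _TIER2 + extra + ["lipid_meds"]
    raise ValueError(f"tier must be 1, 2 or 3, got {tier}")


def covariates_for(
    tier: int, cohort: CohortData, fraction: str | None = None
) -> tuple[list[str], list[str]]:
    """Intersect the tier's covariates with the cohort's available columns.

    Returns (used, dropped): columns absent from the cohort or inestimable
    within it are dropped and reported. Inestimable means constant (e.g. sex
    in an all-female cohort) or a binary covariate with zero events in one of
    its levels, whose log-HR has a monotone partial likelihood. Order follows
    the tier list.
    """
    wanted = TIER_COVARIATES(tier, fraction)
    used, dropped = [], []
    for name in wanted:
        if name not in cohort.covariates.columns:
            dropped.append(name)
            continue
        col = cohort.covariates[name]
        if col.nunique(dropna=False) < 2:
            dropped.append(name)
            continue
        values = col.to_numpy()
        levels = np.unique(values)
        if len(levels) == 2 and any(
            cohort.event[values == lev].sum() == 0 for lev in levels
        ):
            dropped.append(name)  # no events in one level: log-HR diverges
            continue
        used.append(name)
    if dropped:
        log.info("%s tier %d: dropped unavailable/constant covariates %s",
                 cohort.name, tier, dropped)
    return used, dropped


@dataclass(frozen=True)
class CoxResult:
    """Per-cohort association of AF with a 1-SD gene-score increase."""

    cohort: str
    fraction: str | None
    nonpleiotropic: bool
    tier: int
    log_hr: float
    se: float
    n: int
    n_events: int
    covariates_used: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("SE must be positive")
        if self.n_events > self.n:
            raise ValueError("n_events cannot exceed n")

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_hr - 1.959963984540054 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_hr + 1.959963984540054 * self.se))

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.log_hr / self.se)))

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "fraction": self.fraction,
            "nonpleiotropic": self.nonpleiotropic,
            "tier": self.tier,
            "n": self.n,
            "n_events": self.n_events,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_hr": self.log_hr,
            "se": self.se,
            "covariates_used": ";".join(self.covariates_used),
        }


def fit_cox(
    cohort: CohortData,
    score: GeneScore,
    tier: int = 1,
    ties: str = "efron",
) -> CoxResult:
    """Cox partial-likelihood fit of time-to-AF on the standardized score.

    The score must be standardized and aligned to the cohort's individuals.
    Ties are handled by the Efron (default) or Breslow approximation. The
    returned log-HR is per 1 cohort-SD of the score with a model-based SE and
    Wald 95% CI on the exponentiated scale.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if score.standardized is None:
        raise ValueError("score must be standardized (call standardize first)")
    if list(score.individual_ids) != list(cohort.individual_ids):
        raise ValueError("score is not aligned to the cohort's individuals")
    if cohort.n_events == 0:
        raise ValueError(f"{cohort.name}: no AF events; Cox model undefined")

    used, _ = covariates_for(tier, cohort, score.fraction)
    X = pd.DataFrame({"score": score.standardized})
    for name in used:
        X[name] = cohort.covariates[name].to_numpy()
    if X.isna().any().any():
        raise ValueError(f"{cohort.name}: missing values among used covariates")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        raise ValueError(f"{cohort.name}: collinear covariates among {list(X.columns)}")

    model = PHReg(np.asarray(cohort.time, dtype=float), X.to_numpy(),
                  status=np.asarray(cohort.event, dtype=float), ties=ties)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            fit = model.fit(disp=False)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            # BFGS occasionally stalls near the optimum in small cohorts;
            # polish with Newton from the current point before giving up
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fit = model.fit(disp=False, method="newton", start_params=fit.params)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"{cohort.name}: Cox fit did not converge (columns {list(X.columns)})"
        ) from exc
    log_hr = float(fit.params[0])
    se = float(fit.bse[0])
    if not (np.isfinite(log_hr) and np.isfinite(se) and se > 0):
        raise ValueError(
            f"{cohort.name}: Cox fit did not converge (columns {list(X.columns)})"
        )
    return CoxResult(
        cohort=cohort.name,
        fraction=score.fraction,
        nonpleiotropic=score.nonpleiotropic,
        tier=tier,
        log_hr=log_hr,
        se=se,
        n=cohort.n,
        n_events=cohort.n_events,
        covariates_used=tuple(used),
    )
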