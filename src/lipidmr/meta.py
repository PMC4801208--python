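"""Fixed-effects meta-analysis, MR instrument power and the Wald ratio.

Per-cohort log-HRs are pooled by inverse-variance weighting on the log scale
with Cochran's Q and I² heterogeneity statistics. `mr_power` evaluates the
analytic power of a gene-score instrument against a binary outcome from a
normal non-centrality argument. `wald_ratio` is the single-instrument causal
estimator (gene-outcome over gene-exposure coefficient) with a first-order
delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import CoxResult

__all__ = ["MetaResult", "fixed_effects_meta", "PowerSpec", "mr_power", "wald_ratio"]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class MetaResult:
    fraction: str | None
    nonpleiotropic: bool
    tier: int
    pooled_log_hr: float
    pooled_se: float
    q: float
    df: int
    p_het: float
    i2: float
    weights: tuple[float, ...]  # normalized, ordered as the inputs
    cohorts: tuple[str, ...]

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_log_hr - _Z975 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_log_hr + _Z975 * self.pooled_se))

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "nonpleiotropic": self.nonpleiotropic,
            "tier": self.tier,
            "pooled_hr": self.pooled_hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pooled_log_hr": self.pooled_log_hr,
            "pooled_se": self.pooled_se,
            "q": self.q,
            "df": self.df,
            "p_het": self.p_het,
            "i2": self.i2,
            "weights": ";".join(f"{c}={w:.4f}" for c, w in zip(self.cohorts, self.weights)),
        }


def fixed_effects_meta(results: list[CoxResult]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-cohort log-HRs.

    All inputs must share fraction, tier and non-pleiotropic flag. Weights are
    w_k = 1/se_k²; the pooled SE is (Σw)^(-1/2), Q = Σw(log_hr − pooled)² on
    K−1 df, and I² = max(0, (Q − df)/Q).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 cohort results to meta-analyze")
    key = {(r.fraction, r.tier, r.nonpleiotropic) for r in results}
    if len(key) != 1:
        raise ValueError(f"mixed fraction/tier/nonpleiotropic among inputs: {sorted(key)}")
    se = np.array([r.se for r in results], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    y = np.array([r.log_hr for r in results], dtype=float)
    w = 1.0 / se**2
    pooled = float((w * y).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    q = float((w * (y - pooled) ** 2).sum())
    df = len(results) - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= df else float((q - df) / q)
    fraction, tier, nonpleio = next(iter(key))[0], results[0].tier, results[0].nonpleiotropic
    return MetaResult(
        fraction=fraction,
        nonpleiotropic=nonpleio,
        tier=tier,
        pooled_log_hr=pooled,
        pooled_se=pooled_se,
        q=q,
        df=df,
        p_het=p_het,
        i2=i2,
        weights=tuple(w / w.sum()),
        cohorts=tuple(r.cohort for r in results),
    )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the binary-outcome MR power calculation."""

    n_total: int
    case_fraction: float
    instrument_r2: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        for name, v in (
            ("case_fraction", self.case_fraction),
            ("instrument_r2", self.instrument_r2),
            ("alpha", self.alpha),
        ):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be positive")


def mr_power(spec: PowerSpec) -> float:
    """Analytic power of a score instrument against a binary outcome.

    The test statistic for the score-outcome association has non-centrality
    z* = sqrt(N · R² · K(1−K)) · |ln OR| with K the case fraction and OR the
    odds ratio per SD of the exposure; power for a two-sided level-α normal
    test is Φ(z* − z_{1−α/2}) + Φ(−z* − z_{1−α/2}). Monotone increasing in N,
    R² and |ln OR|; equals α when OR = 1.
    """
    K = spec.case_fraction
    ncp = np.sqrt(spec.n_total * spec.instrument_r2 * K * (1.0 - K)) * abs(
        np.log(spec.or_per_sd)
    )
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))


def wald_ratio(
    beta_zy: float, se_zy: float, beta_zx: float, se_zx: float
) -> tuple[float, float]:
    """Single-instrument causal estimate beta_zy/beta_zx with delta-method SE.

    beta_zy is the gene-score-to-outcome coefficient (e.g. log-HR per SD of
    score) and beta_zx the gene-score-to-exposure coefficient (exposure SD per
    score SD). A zero beta_zx (no instrument-exposure association) is an
    error: the ratio is undefined for a null instrument.
    """
    if beta_zx == 0:
        raise ValueError("beta_zx is zero: Wald ratio undefined (weak/null instrument)")
    if se_zy <= 0 or se_zx <= 0:
        raise ValueError("standard errors must be positive")
    estimate = beta_zy / beta_zx
    se = np.sqrt(se_zy**2 / beta_zx**2 + beta_zy**2 * se_zx**2 / beta_zx**4)
    return float(estimate), float(se)
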