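"""Synthetic multi-cohort consortium generator.

Generates data with the statistical structure the analysis assumes: genotypes
at Hardy-Weinberg equilibrium and linkage equilibrium, an additive lipid
architecture whose gene-score instrument explains a configurable fraction of
lipid variance (default 5%), simple parametric baseline covariates with
optional confounder paths, and proportional-hazards AF times with independent
death/dropout censoring and administrative end of follow-up.

The default seven-cohort configuration (``afgen7.yaml``) reproduces the
consortium's cohort sizes (total 64,901), sex composition, per-cohort
follow-up horizons, the covariate-availability pattern, and per-cohort AF
baseline hazards solved so that expected case counts total 5,434 (8.4%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .genotypes import GenotypeMatrix
from .panel import FRACTIONS, SnpPanel, SnpRecord, select_fraction

__all__ = [
    "CohortSpec",
    "ScenarioSpec",
    "CohortData",
    "SimulatedCohort",
    "synthetic_teslovich_panel",
    "simulate_genotypes",
    "simulate_lipid",
    "simulate_survival",
    "simulate_cohort",
    "simulate_consortium",
    "load_default_config",
    "default_cohort_specs",
    "solve_baseline_hazard",
    "genetic_variance",
]

#: Baseline mean lipid levels (mg/dL) used to place simulated phenotypes on a
#: realistic scale; the analysis is invariant to these offsets.
LIPID_BASE_MEAN = {"HDL": 55.0, "LDL": 130.0, "TC": 210.0, "TG": 125.0}

#: Continuous covariates simulated as Normal(mean, sd); all others Bernoulli.
CONTINUOUS_COVARIATES = ("age", "height", "bmi", "sbp", "dbp")


# --------------------------------------------------------------------------
# Synthetic SNP effect panel


def synthetic_teslovich_panel() -> SnpPanel:
    """Synthetic stand-in for the published lipid SNP effect panel.

    The real panel (index SNPs from the 95 lipid loci of the Teslovich GWAS,
    with unfavorable alleles and absolute effect sizes) is not redistributable
    here, so this builds a synthetic panel with the same published structure:
    95 SNPs; 47 HDL, 37 LDL, 52 total-cholesterol and 32 triglyceride score
    members; 14 SNPs exclusively associated with HDL and 13 with LDL (the
    non-pleiotropic sub-scores). Effect sizes (mg/dL) and allele frequencies
    are drawn once from plausible GWAS ranges with a fixed generator, so the
    panel is a deterministic constant of the package.
    """
    groups = [
        (("HDL",), 14),
        (("LDL",), 13),
        (("TC",), 4),
        (("TG",), 3),
        (("HDL", "TG"), 13),
        (("LDL", "TC"), 24),
        (("HDL", "TC"), 8),
        (("TC", "TG"), 4),
        (("HDL", "TC", "TG"), 12),
    ]
    allele_pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    rng = np.random.default_rng(95_2010)  # fixed: the panel is a constant
    records = []
    k = 0
    for fractions, count in groups:
        for _ in range(count):
            k += 1
            scored, other = allele_pairs[k % 4]
            if rng.random() < 0.5:
                scored, other = other, scored
            # |beta| on the Teslovich scale: mostly sub-mg/dL to a few mg/dL
            abs_effect = float(np.round(np.exp(rng.normal(0.4, 0.8)), 3))
            eaf = float(np.round(rng.uniform(0.05, 0.95), 3))
            nonpleio = frozenset(fractions) & {"HDL", "LDL"} if len(fractions) == 1 else frozenset()
            records.append(
                SnpRecord(
                    snp_id=f"rs{100000 + 97 * k}",
                    chrom=str(1 + (k - 1) % 22),
                    pos=1_000_000 + 50_000 * k,
                    scored_allele=scored,
                    other_allele=other,
                    abs_effect=abs_effect,
                    fractions=frozenset(fractions),
                    nonpleiotropic_for=frozenset(nonpleio),
                    eaf=eaf,
                )
            )
    return SnpPanel(records=tuple(records))


def reduced_panel_missing_snps(panel: SnpPanel) -> list[str]:
    """SNPs unavailable on the reduced genotyping platform (MDCS pattern).

    Drops 1 HDL-only, 5 HDL+TG and 5 LDL-only SNPs so the reduced cohort's
    scores use 41 HDL, 32 LDL and 27 TG SNPs; the total-cholesterol score is
    unavailable there altogether (handled by ``unavailable_fractions``).
    """
    take = {frozenset({"HDL"}): 1, frozenset({"HDL", "TG"}): 5, frozenset({"LDL"}): 5}
    missing: list[str] = []
    counts: dict[frozenset, int] = {k: 0 for k in take}
    for rec in panel.records:
        want = take.get(rec.fractions, 0)
        if counts.get(rec.fractions, 0) < want:
            counts[rec.fractions] += 1
            missing.append(rec.snp_id)
    return missing


# --------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class CohortSpec:
    """One cohort's size, demography, censoring structure and availability."""

    name: str
    n: int
    mean_age: float
    sd_age: float
    fraction_male: float
    followup_years: float  # administrative censoring horizon
    dropout_rate: float = 0.005  # per-year hazard of loss to follow-up
    death_rate: float = 0.01  # per-year hazard of death (censoring)
    target_case_fraction: float | None = None  # solves the AF baseline hazard
    baseline_hazard: float | None = None  # per-year AF hazard; overrides target
    covariate_params: dict = field(default_factory=dict)
    missing_covariates: tuple[str, ...] = ()
    unavailable_fractions: frozenset[str] = frozenset()
    missing_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.name}: n must be positive")
        if self.followup_years <= 0:
            raise ValueError(f"{self.name}: followup_years must be positive")
        for nm, r in (("dropout_rate", self.dropout_rate), ("death_rate", self.death_rate)):
            if r < 0:
                raise ValueError(f"{self.name}: {nm} must be >= 0")
        if not 0.0 <= self.fraction_male <= 1.0:
            raise ValueError(f"{self.name}: fraction_male must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """Data-generating parameters shared across cohorts.

    theta_lipid is the causal log-HR of AF per 1 SD of the exposure lipid
    (0 = the null); theta_direct a direct gene-score path violating the
    exclusion restriction; instrument_r2 the lipid variance explained by the
    score's genetic value; confounder_effects maps a covariate name to
    (shift of lipid in lipid-SD units per covariate SD, log-HR per covariate SD).
    """

    theta_lipid: float = 0.0
    theta_direct: float = 0.0
    instrument_r2: float = 0.05
    exposure_fraction: str = "LDL"
    confounder_effects: dict = field(default_factory=dict)
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.instrument_r2 < 1.0:
            raise ValueError("instrument_r2 must lie strictly in (0, 1)")
        if not (np.isfinite(self.theta_lipid) and np.isfinite(self.theta_direct)):
            raise ValueError("thetas must be finite")
        if self.exposure_fraction not in FRACTIONS:
            raise ValueError(f"unknown exposure fraction {self.exposure_fraction!r}")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


@dataclass
class CohortData:
    """Phenotypes for one cohort: covariates, follow-up time and AF event."""

    name: str
    individual_ids: list[str]
    covariates: pd.DataFrame  # unavailable covariates are absent, not imputed
    time: np.ndarray  # years to first of AF / death / dropout / admin end
    event: np.ndarray  # 1 = AF, 0 = censored

    def __post_init__(self) -> None:
        if not (len(self.individual_ids) == len(self.covariates) == len(self.time) == len(self.event)):
            raise ValueError("cohort component lengths differ")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    data: CohortData
    genotypes: GenotypeMatrix  # already coded to the scored allele


# --------------------------------------------------------------------------
# Generators


def simulate_genotypes(n: int, panel: SnpPanel, seed) -> GenotypeMatrix:
    """HWE/linkage-equilibrium dosages: d_ij ~ Binomial(2, eaf_i), coded to
    the scored allele."""
    rng = np.random.default_rng(seed)
    eaf = np.array([r.eaf for r in panel.records])
    dosage = rng.binomial(2, eaf, size=(n, len(eaf))).astype(float)
    return GenotypeMatrix(
        individual_ids=[f"I{i:06d}" for i in range(n)],
        snp_ids=panel.snp_ids,
        dosage=dosage,
        coded_allele={r.snp_id: r.scored_allele for r in panel.records},
    )


def genetic_variance(panel: SnpPanel) -> float:
    """Var of the signed genetic value under HWE: sum beta_i^2 * 2 p_i (1-p_i)."""
    return float(sum(r.abs_effect**2 * 2.0 * r.eaf * (1.0 - r.eaf) for r in panel.records))


def _signed_genetic_value(genotypes: GenotypeMatrix, panel: SnpPanel, fraction: str) -> np.ndarray:
    """Sum of signed beta * dosage; unfavorable alleles lower HDL and raise
    LDL/TC/TG, so the sign is -1 for HDL and +1 otherwise."""
    sign = -1.0 if fraction == "HDL" else 1.0
    idx = [genotypes.snp_ids.index(r.snp_id) for r in panel.records]
    beta = np.array([r.abs_effect for r in panel.records])
    return sign * (genotypes.dosage[:, idx] @ beta)


def _standardized_covariate(values: np.ndarray, params) -> np.ndarray:
    if isinstance(params, (list, tuple)):
        mean, sd = params
        return (values - mean) / sd
    p = float(params)
    return (values - p) / np.sqrt(p * (1.0 - p))


def simulate_lipid(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    scenario: ScenarioSpec,
    seed,
    confounder_z: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Simulate one fraction's lipid level (mg/dL) and return (lipid, SD).

    lipid = base + (g - E[g]) + sd_lipid * (confounder shifts + noise), with
    the noise variance chosen analytically so var(g)/var(lipid) equals the
    scenario's instrument R^2: sd_lipid = sqrt(var(g)/R^2) and the residual
    SD-unit variance is 1 - R^2 - sum(confounder shifts^2).
    """
    if panel.fraction is None:
        raise ValueError("panel must be fraction-filtered before simulating a lipid")
    rng = np.random.default_rng(seed)
    var_g = genetic_variance(panel)
    if var_g <= 0:
        raise ValueError("panel has zero genetic variance")
    r2 = scenario.instrument_r2
    conf_var = sum(d**2 for d, _ in scenario.confounder_effects.values())
    resid_var = 1.0 - r2 - conf_var
    if resid_var <= 0:
        raise ValueError(
            f"instrument_r2 ({r2}) plus confounder variance ({conf_var}) must be < 1"
        )
    sd_lipid = np.sqrt(var_g / r2)
    g = _signed_genetic_value(genotypes, panel, panel.fraction)
    sign = -1.0 if panel.fraction == "HDL" else 1.0
    expected_g = sign * sum(r.abs_effect * 2.0 * r.eaf for r in panel.records)
    shift = np.zeros(genotypes.n_individuals)
    if confounder_z:
        for cov, (delta, _) in scenario.confounder_effects.items():
            if cov in confounder_z:
                shift = shift + delta * confounder_z[cov]
    noise = rng.normal(0.0, np.sqrt(resid_var), size=genotypes.n_individuals)
    lipid = LIPID_BASE_MEAN[panel.fraction] + (g - expected_g) + sd_lipid * (shift + noise)
    return lipid, float(sd_lipid)


def solve_baseline_hazard(
    target_case_fraction: float,
    death_rate: float,
    dropout_rate: float,
    followup_years: float,
) -> float:
    """Per-year AF hazard lambda such that, under the null homogeneous model,
    P(AF observed) = lambda/Lambda * (1 - exp(-Lambda*T)) equals the target,
    with Lambda = lambda + death + dropout."""
    if not 0.0 < target_case_fraction < 1.0:
        raise ValueError("target case fraction must be in (0, 1)")
    mu = death_rate + dropout_rate
    T = followup_years

    def p_event(lam: float) -> float:
        total = lam + mu
        return lam / total * (1.0 - np.exp(-total * T))

    if p_event(50.0) < target_case_fraction:
        raise ValueError("target case fraction unattainable under the censoring rates")
    return float(brentq(lambda lam: p_event(lam) - target_case_fraction, 1e-10, 50.0, xtol=1e-12))


def simulate_survival(
    linear_predictor: np.ndarray,
    spec: CohortSpec,
    seed,
    baseline_hazard: float | None = None,
    weibull_shape: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportional-hazards AF times with independent censoring.

    AF time has hazard baseline * shape * t^(shape-1) * exp(linear_predictor)
    (exponential when shape = 1); death and dropout are independent
    exponentials; observed time is the minimum of the three and the
    administrative horizon, and event = 1 iff AF came first.
    """
    rng = np.random.default_rng(seed)
    n = len(linear_predictor)
    lam = baseline_hazard
    if lam is None:
        lam = spec.baseline_hazard
    if lam is None:
        if spec.target_case_fraction is None:
            raise ValueError(f"{spec.name}: neither baseline_hazard nor target_case_fraction set")
        lam = solve_baseline_hazard(
            spec.target_case_fraction, spec.death_rate, spec.dropout_rate, spec.followup_years
        )
    if lam < 0:
        raise ValueError("baseline hazard must be non-negative")
    rate_af = lam * np.exp(linear_predictor)
    t_af = (rng.exponential(1.0, n) / rate_af) ** (1.0 / weibull_shape)
    t_death = (
        rng.exponential(1.0 / spec.death_rate, n) if spec.death_rate > 0 else np.full(n, np.inf)
    )
    t_drop = (
        rng.exponential(1.0 / spec.dropout_rate, n) if spec.dropout_rate > 0 else np.full(n, np.inf)
    )
    time = np.minimum.reduce([t_af, t_death, t_drop, np.full(n, spec.followup_years)])
    event = (t_af <= np.minimum(t_death, np.minimum(t_drop, spec.followup_years))).astype(int)
    # guard against zero-duration pathologies from extreme hazards
    time = np.maximum(time, 1e-9)
    return time, event


def _simulate_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    cols["age"] = rng.normal(spec.mean_age, spec.sd_age, spec.n)
    cols["sex"] = rng.binomial(1, spec.fraction_male, spec.n).astype(float)
    for name, params in spec.covariate_params.items():
        if name in spec.missing_covariates:
            continue
        if isinstance(params, (list, tuple)):
            mean, sd = params
            cols[name] = rng.normal(mean, sd, spec.n)
        else:
            cols[name] = rng.binomial(1, float(params), spec.n).astype(float)
    return pd.DataFrame(cols)


def simulate_cohort(spec: CohortSpec, panel: SnpPanel, scenario: ScenarioSpec, seed) -> SimulatedCohort:
    """Simulate one cohort end to end: genotypes, covariates, lipids, survival."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_geno, s_cov, s_surv, *s_lip = ss.spawn(3 + len(FRACTIONS))

    cohort_panel = panel
    if spec.missing_snps:
        keep = [sid for sid in panel.snp_ids if sid not in set(spec.missing_snps)]
        cohort_panel = panel.subset(keep)
    genotypes = simulate_genotypes(spec.n, cohort_panel, s_geno)
    genotypes.individual_ids = [f"{spec.name}_{i:06d}" for i in range(spec.n)]

    rng_cov = np.random.default_rng(s_cov)
    cov = _simulate_covariates(spec, rng_cov)

    # standardized confounders feeding lipid and hazard paths
    conf_z: dict[str, np.ndarray] = {}
    for name in scenario.confounder_effects:
        if name not in cov.columns:
            continue
        params = (
            (spec.mean_age, spec.sd_age)
            if name == "age"
            else spec.covariate_params.get(name, (cov[name].mean(), cov[name].std() or 1.0))
        )
        if name == "sex":
            p = spec.fraction_male
            params = min(max(p, 1e-6), 1 - 1e-6)
        conf_z[name] = _standardized_covariate(cov[name].to_numpy(), params)

    lipids: dict[str, np.ndarray] = {}
    lipid_sd: dict[str, float] = {}
    for frac, s in zip(FRACTIONS, s_lip):
        try:
            sub = select_fraction(cohort_panel, frac)
        except ValueError:
            continue
        lipids[frac], lipid_sd[frac] = simulate_lipid(genotypes, sub, scenario, s, conf_z)

    # linear predictor on the AF log-hazard
    lp = np.zeros(spec.n)
    exp_frac = scenario.exposure_fraction
    if scenario.theta_lipid != 0.0 and exp_frac in lipids:
        z_lip = (lipids[exp_frac] - LIPID_BASE_MEAN[exp_frac]) / lipid_sd[exp_frac]
        lp = lp + scenario.theta_lipid * z_lip
    if scenario.theta_direct != 0.0:
        sub = select_fraction(cohort_panel, exp_frac)
        beta = np.array([r.abs_effect for r in sub.records])
        idx = [genotypes.snp_ids.index(r.snp_id) for r in sub.records]
        raw = genotypes.dosage[:, idx] @ beta
        lp = lp + scenario.theta_direct * (raw - raw.mean()) / raw.std(ddof=1)
    for name, (_, log_hr) in scenario.confounder_effects.items():
        if log_hr != 0.0 and name in conf_z:
            lp = lp + log_hr * conf_z[name]

    time, event = simulate_survival(lp, spec, s_surv, weibull_shape=scenario.weibull_shape)

    for frac, values in lipids.items():
        col = f"lipid_{frac.lower()}"
        if col not in spec.missing_covariates and frac not in spec.unavailable_fractions:
            cov[col] = values

    data = CohortData(
        name=spec.name,
        individual_ids=list(genotypes.individual_ids),
        covariates=cov,
        time=time,
        event=event,
    )
    return SimulatedCohort(spec=spec, data=data, genotypes=genotypes)


def simulate_consortium(
    cohort_specs: list[CohortSpec], panel: SnpPanel, scenario: ScenarioSpec
) -> list[SimulatedCohort]:
    """Simulate all cohorts with independent seed streams derived from the
    scenario seed; identical inputs give bit-identical output."""
    names = [s.name for s in cohort_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cohort names")
    children = np.random.SeedSequence(scenario.seed).spawn(len(cohort_specs))
    return [simulate_cohort(spec, panel, scenario, child)
            for spec, child in zip(cohort_specs, children)]


# --------------------------------------------------------------------------
# Default configuration


def load_default_config() -> dict:
    with resources.files("lipidmr.data").joinpath("afgen7.yaml").open() as fh:
        return yaml.safe_load(fh)


def _spec_from_dict(entry: dict, panel: SnpPanel | None) -> CohortSpec:
    missing_snps: tuple[str, ...] = ()
    if entry.get("reduced_panel") and panel is not None:
        missing_snps = tuple(reduced_panel_missing_snps(panel))
    return CohortSpec(
        name=entry["name"],
        n=int(entry["n"]),
        mean_age=float(entry["mean_age"]),
        sd_age=float(entry["sd_age"]),
        fraction_male=float(entry["fraction_male"]),
        followup_years=float(entry["followup_years"]),
        dropout_rate=float(entry.get("dropout_rate", 0.005)),
        death_rate=float(entry.get("death_rate", 0.01)),
        target_case_fraction=float(entry["cases"]) / float(entry["n"]) if "cases" in entry else None,
        baseline_hazard=entry.get("baseline_hazard"),
        covariate_params=dict(entry.get("covariates", {})),
        missing_covariates=tuple(entry.get("missing_covariates", ())),
        unavailable_fractions=frozenset(entry.get("unavailable_fractions", ())),
        missing_snps=missing_snps,
    )


def default_cohort_specs(panel: SnpPanel | None = None, size_factor: float = 1.0) -> list[CohortSpec]:
    """The packaged seven-cohort specs; `size_factor` scales every n (used by
    scaled-down replicate studies), leaving target case fractions unchanged."""
    cfg = load_default_config()
    specs = []
    for entry in cfg["cohorts"]:
        spec = _spec_from_dict(entry, panel)
        if size_factor != 1.0:
            spec = CohortSpec(**{**spec.__dict__, "n": max(2, round(spec.n * size_factor))})
        specs.append(spec)
    return specs


def default_scenario(seed: int | None = None, **overrides) -> ScenarioSpec:
    cfg = load_default_config()["scenario"]
    cfg.update(overrides)
    if seed is not None:
        cfg["seed"] = seed
    return ScenarioSpec(
        theta_lipid=float(cfg.get("theta_lipid", 0.0)),
        theta_direct=float(cfg.get("theta_direct", 0.0)),
        instrument_r2=float(cfg.get("instrument_r2", 0.05)),
        exposure_fraction=cfg.get("exposure_fraction", "LDL"),
        confounder_effects={k: tuple(v) for k, v in (cfg.get("confounder_effects") or {}).items()},
        weibull_shape=float(cfg.get("weibull_shape", 1.0)),
        seed=int(cfg.get("seed", 0)),
    )
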