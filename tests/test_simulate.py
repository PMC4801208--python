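"""Synthetic consortium generator: distributions, calibration, determinism."""

import numpy as np
import pytest

from lipidmr import (
    CohortSpec,
    ScenarioSpec,
    default_cohort_specs,
    default_scenario,
    select_fraction,
    simulate_consortium,
    simulate_genotypes,
    simulate_lipid,
    simulate_survival,
)
from lipidmr.simulate import genetic_variance, solve_baseline_hazard, simulate_cohort


def small_spec(n=2000, **kw):
    defaults = dict(
        name="TEST", n=n, mean_age=60, sd_age=8, fraction_male=0.5,
        followup_years=10.0, dropout_rate=0.0, death_rate=0.0,
        baseline_hazard=0.01,
        covariate_params={"height": [168, 9], "smoking": 0.2},
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


def test_genotypes_are_hwe_binomial(panel95):
    m = simulate_genotypes(100_000, panel95.subset([panel95.snp_ids[0]]), seed=1)
    rec = panel95.records[0]
    d = m.dosage[:, 0]
    # compare genotype frequencies with the binomial closed form
    p = rec.eaf
    expected = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
    for g, e in expected.items():
        assert abs((d == g).mean() - e) < 0.01


def test_rare_allele_gives_near_zero_dosages(toy_panel):
    import dataclasses

    rare = toy_panel.subset(["rsA"])
    rare = rare.__class__(records=(dataclasses.replace(rare.records[0], eaf=1e-4),))
    m = simulate_genotypes(50, rare, seed=2)
    assert m.dosage.sum() <= 1


def test_genotype_seed_determinism(panel95):
    a = simulate_genotypes(100, panel95, seed=5)
    b = simulate_genotypes(100, panel95, seed=5)
    np.testing.assert_array_equal(a.dosage, b.dosage)


def test_lipid_instrument_r2_matches_target(panel95):
    """Regression R^2 of lipid on the genetic value hits the configured 5%."""
    sub = select_fraction(panel95, "LDL")
    m = simulate_genotypes(100_000, sub, seed=3)
    scenario = ScenarioSpec(instrument_r2=0.05, seed=0)
    lipid, _ = simulate_lipid(m, sub, scenario, seed=4)
    beta = np.array([r.abs_effect for r in sub.records])
    g = m.dosage @ beta
    r2 = np.corrcoef(g, lipid)[0, 1] ** 2
    assert r2 == pytest.approx(0.05, abs=0.005)


def test_lipid_variance_bookkeeping(panel95):
    """Analytic lipid SD satisfies var(g)/var(lipid) = R^2 by construction."""
    sub = select_fraction(panel95, "TG")
    scenario = ScenarioSpec(instrument_r2=0.2, seed=0)
    m = simulate_genotypes(10, sub, seed=6)
    _, sd = simulate_lipid(m, sub, scenario, seed=7)
    assert sd**2 == pytest.approx(genetic_variance(sub) / 0.2)


def test_confounder_variance_overflow_is_error(panel95):
    sub = select_fraction(panel95, "TG")
    m = simulate_genotypes(10, sub, seed=8)
    scenario = ScenarioSpec(
        instrument_r2=0.5, confounder_effects={"bmi": (0.8, 0.0)}, seed=0
    )
    with pytest.raises(ValueError, match="must be < 1"):
        simulate_lipid(m, sub, scenario, seed=9)


def test_event_fraction_matches_exponential_closed_form():
    """No competing censoring: event fraction = 1 - exp(-lambda*T)."""
    spec = small_spec(n=50_000, baseline_hazard=0.02, followup_years=10.0)
    time, event = simulate_survival(np.zeros(spec.n), spec, seed=10)
    expected = 1 - np.exp(-0.02 * 10.0)
    assert event.mean() == pytest.approx(expected, abs=0.006)
    assert time.max() <= 10.0


def test_censoring_consistency():
    spec = small_spec(n=5000, death_rate=0.02, dropout_rate=0.01)
    time, event = simulate_survival(np.zeros(spec.n), spec, seed=11)
    assert (time > 0).all()
    assert time.max() <= spec.followup_years
    assert set(np.unique(event)) <= {0, 1}
    # administratively censored individuals are never events at the horizon
    at_horizon = time == spec.followup_years
    assert (event[at_horizon] == 0).all()


def test_solve_baseline_hazard_inverts_event_probability():
    lam = solve_baseline_hazard(0.084, death_rate=0.01, dropout_rate=0.005, followup_years=12.0)
    total = lam + 0.015
    assert lam / total * (1 - np.exp(-total * 12.0)) == pytest.approx(0.084, abs=1e-9)


def test_proportional_hazards_effect_is_recovered(panel95):
    """A log(0.8) per-SD effect on the true lipid is recovered by Cox."""
    from lipidmr.cox import fit_cox
    from lipidmr.score import compute_gene_score
    from statsmodels.duration.hazard_regression import PHReg

    sub = select_fraction(panel95, "LDL")
    n = 50_000
    m = simulate_genotypes(n, sub, seed=12)
    scenario = ScenarioSpec(instrument_r2=0.05, theta_lipid=np.log(0.8), seed=0)
    lipid, sd = simulate_lipid(m, sub, scenario, seed=13)
    z = (lipid - lipid.mean()) / sd
    spec = small_spec(n=n, baseline_hazard=0.01, followup_years=10.0)
    estimates, ses = [], []
    for seed in (14, 15, 16):
        time, event = simulate_survival(np.log(0.8) * z, spec, seed=seed)
        fit = PHReg(time, z.reshape(-1, 1), status=event.astype(float),
                    ties="efron").fit(disp=False)
        estimates.append(fit.params[0])
        ses.append(fit.bse[0])
    mean_est = np.mean(estimates)
    se_mean = np.mean(ses) / np.sqrt(len(estimates))
    assert abs(mean_est - np.log(0.8)) < 3 * se_mean


def test_consortium_structure(panel95):
    specs = default_cohort_specs(panel95)
    assert [s.name for s in specs] == ["AGES", "ARIC", "FHS", "MDCS", "RS-I", "RS-II", "WGHS"]
    assert sum(s.n for s in specs) == 64_901
    wghs = next(s for s in specs if s.name == "WGHS")
    assert wghs.fraction_male == 0.0
    mdcs = next(s for s in specs if s.name == "MDCS")
    assert "TC" in mdcs.unavailable_fractions
    assert len(mdcs.missing_snps) == 11
    # expected AF cases across cohorts total the consortium's 8.4%
    expected_cases = sum(s.n * s.target_case_fraction for s in specs)
    assert expected_cases == pytest.approx(5434.0)
    assert expected_cases / sum(s.n for s in specs) == pytest.approx(0.0837, abs=1e-4)


def test_consortium_availability_pattern(panel95):
    specs = default_cohort_specs(panel95, size_factor=0.02)
    scenario = default_scenario(seed=99)
    sims = simulate_consortium(specs, panel95, scenario)
    by_name = {s.spec.name: s for s in sims}
    assert "lvh" not in by_name["AGES"].data.covariates.columns
    assert "lipid_tc" not in by_name["MDCS"].data.covariates.columns
    assert "lipid_hdl" not in by_name["MDCS"].data.covariates.columns
    assert "education" not in by_name["FHS"].data.covariates.columns
    assert (by_name["WGHS"].data.covariates["sex"] == 0).all()
    # MDCS genotypes exclude the reduced-platform SNPs
    assert set(by_name["MDCS"].genotypes.snp_ids).isdisjoint(set(specs[3].missing_snps))


def test_consortium_seed_determinism(panel95):
    specs = default_cohort_specs(panel95, size_factor=0.02)
    scenario = default_scenario(seed=7)
    a = simulate_consortium(specs, panel95, scenario)
    b = simulate_consortium(specs, panel95, scenario)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.genotypes.dosage, y.genotypes.dosage)
        np.testing.assert_array_equal(x.data.time, y.data.time)
        np.testing.assert_array_equal(x.data.event, y.data.event)
        assert x.data.covariates.equals(y.data.covariates)


def test_duplicate_cohort_names_rejected(panel95):
    spec = small_spec(target_case_fraction=0.1, baseline_hazard=None, n=50)
    with pytest.raises(ValueError, match="duplicate"):
        simulate_consortium([spec, spec], panel95, ScenarioSpec(seed=0))
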