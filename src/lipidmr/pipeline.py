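"""End-to-end orchestration: simulate -> score -> Cox -> meta-analysis.

`analyze_consortium` is the in-memory workhorse used by tests and scripts;
`run_pipeline` wraps it with file output (per-cohort and pooled CSVs plus a
JSON manifest recording the config hash, seed, per-cohort SNP counts and
dropped covariates) and is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .cox import CoxResult, covariates_for, fit_cox
from .meta import MetaResult, fixed_effects_meta
from .panel import FRACTIONS, SnpPanel, read_panel, write_panel
from .score import compute_gene_score
from .simulate import (
    ScenarioSpec,
    SimulatedCohort,
    default_cohort_specs,
    default_scenario,
    simulate_consortium,
    synthetic_teslovich_panel,
)

__all__ = ["RunConfig", "default_analyses", "analyze_consortium", "run_pipeline"]

log = logging.getLogger(__name__)


def default_analyses() -> list[tuple[str, bool]]:
    """The six score analyses: four full-fraction plus two non-pleiotropic."""
    return [("HDL", False), ("LDL", False), ("TC", False), ("TG", False),
            ("HDL", True), ("LDL", True)]


@dataclass
class RunConfig:
    """Configuration for a reproducible pipeline run."""

    out_dir: str = "lipidmr_out"
    seed: int = 0
    analyses: list = field(default_factory=default_analyses)
    tiers: tuple[int, ...] = (1, 2, 3)
    ties: str = "efron"
    missing_strategy: str = "mean_impute"
    size_factor: float = 1.0
    scenario_overrides: dict = field(default_factory=dict)
    panel_path: str | None = None  # None -> packaged synthetic panel

    def validate(self) -> None:
        for fraction, nonpleio in self.analyses:
            if fraction not in FRACTIONS:
                raise ValueError(f"unknown fraction {fraction!r} in config")
            if nonpleio and fraction not in ("HDL", "LDL"):
                raise ValueError(f"non-pleiotropic score undefined for {fraction}")
        for tier in self.tiers:
            if tier not in (1, 2, 3):
                raise ValueError(f"unknown tier {tier}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {self.ties!r}")

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def analyze_consortium(
    cohorts: list[SimulatedCohort],
    panel: SnpPanel,
    analyses: list[tuple[str, bool]] | None = None,
    tiers: tuple[int, ...] = (1, 2, 3),
    ties: str = "efron",
    missing_strategy: str = "mean_impute",
) -> tuple[list[CoxResult], list[MetaResult]]:
    """Score every cohort, fit Cox models per tier, pool per analysis.

    Fractions a cohort cannot score (no available SNPs, or flagged
    unavailable) are skipped for that cohort and pooled over the rest.
    """
    analyses = default_analyses() if analyses is None else analyses
    cox_results: list[CoxResult] = []
    for fraction, nonpleio in analyses:
        per_tier: dict[int, list[CoxResult]] = {t: [] for t in tiers}
        for sim in cohorts:
            if fraction in sim.spec.unavailable_fractions:
                log.info("%s: fraction %s unavailable; skipped", sim.spec.name, fraction)
                continue
            score = compute_gene_score(
                sim.genotypes, panel, fraction, nonpleio, missing_strategy=missing_strategy
            )
            for tier in tiers:
                res = fit_cox(sim.data, score, tier=tier, ties=ties)
                per_tier[tier].append(res)
                cox_results.append(res)
    meta_results = []
    for fraction, nonpleio in analyses:
        for tier in tiers:
            group = [
                r for r in cox_results
                if r.fraction == fraction and r.nonpleiotropic == nonpleio and r.tier == tier
            ]
            if len(group) >= 2:
                meta_results.append(fixed_effects_meta(group))
    return cox_results, meta_results


def run_pipeline(config: RunConfig) -> dict:
    """Run the simulated-consortium pipeline and write its result bundle.

    Writes cox_results.csv, meta_results.csv and manifest.json under
    ``config.out_dir``; reruns with the same config produce identical bytes.
    Returns the manifest dict (with in-memory results attached under
    ``_results``).
    """
    config.validate()
    t0 = _time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = read_panel(config.panel_path) if config.panel_path else synthetic_teslovich_panel()
    specs = default_cohort_specs(panel, size_factor=config.size_factor)
    scenario = default_scenario(seed=config.seed, **config.scenario_overrides)
    log.info("simulating %d cohorts (total n=%d)", len(specs), sum(s.n for s in specs))
    cohorts = simulate_consortium(specs, panel, scenario)
    log.info("simulation done in %.1fs", _time.perf_counter() - t0)

    cox_results, meta_results = analyze_consortium(
        cohorts, panel, config.analyses, config.tiers, config.ties, config.missing_strategy
    )
    log.info("fitted %d Cox models, %d pooled rows in %.1fs",
             len(cox_results), len(meta_results), _time.perf_counter() - t0)

    cox_df = pd.DataFrame([r.to_dict() for r in cox_results])
    meta_df = pd.DataFrame([m.to_dict() for m in meta_results])
    cox_df.to_csv(out / "cox_results.csv", index=False, float_format="%.10g")
    meta_df.to_csv(out / "meta_results.csv", index=False, float_format="%.10g")

    snp_counts = {
        sim.spec.name: {
            fraction: sum(
                1 for r in panel.records
                if fraction in r.fractions and r.snp_id not in set(sim.spec.missing_snps)
            )
            for fraction in FRACTIONS
            if fraction not in sim.spec.unavailable_fractions
        }
        for sim in cohorts
    }
    dropped = {
        sim.spec.name: {
            str(tier): covariates_for(tier, sim.data, "LDL")[1] for tier in config.tiers
        }
        for sim in cohorts
    }
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_total": int(sum(s.n for s in specs)),
        "n_events_total": int(sum(sim.data.n_events for sim in cohorts)),
        "panel_snps_per_cohort": snp_counts,
        "dropped_covariates": dropped,
        "files": ["cox_results.csv", "meta_results.csv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["_results"] = (cox_results, meta_results)
    manifest["_cohorts"] = cohorts
    return manifest
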