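"""Weighted lipid gene scores.

For each individual j the raw score is sum_i d_ij * |beta_i| over the panel
SNPs available in the cohort, where d_ij counts unfavorable alleles and
|beta_i| is the absolute per-allele effect size (mg/dL). The raw sum is
rescaled by the mean |beta| of the SNPs actually used (so the rescaled score
is on an allele-count scale) and finally divided by its cohort-specific
sample standard deviation, giving a score with SD 1 but a positive mean.
No mean-centering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, harmonize
from .panel import SnpPanel, select_fraction

__all__ = ["GeneScore", "raw_and_rescaled", "standardize", "compute_gene_score"]


@dataclass(frozen=True)
class GeneScore:
    individual_ids: tuple[str, ...]
    raw: np.ndarray
    rescaled: np.ndarray
    standardized: np.ndarray | None
    n_snps_used: int
    fraction: str | None = None
    nonpleiotropic: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": list(self.individual_ids),
                "fraction": self.fraction,
                "nonpleiotropic": self.nonpleiotropic,
                "raw": self.raw,
                "rescaled": self.rescaled,
                "standardized": self.standardized,
                "n_snps_used": self.n_snps_used,
            }
        )


def raw_and_rescaled(genotypes: GenotypeMatrix, panel: SnpPanel) -> GeneScore:
    """Dosage-weighted sum of |effects|, rescaled by their mean.

    `genotypes` must be harmonized (no missing values, columns counting the
    scored allele). Panel SNPs absent from the genotype matrix are excluded
    both from the sum and from the rescaling denominator; `n_snps_used`
    records how many entered.
    """
    if np.isnan(genotypes.dosage).any():
        raise ValueError("genotypes contain missing dosages; harmonize first")
    used = [r for r in panel.records if r.snp_id in set(genotypes.snp_ids)]
    if not used:
        raise ValueError("no panel SNPs present in the genotype matrix")
    effects = np.array([r.abs_effect for r in used])
    mean_effect = effects.mean()
    if mean_effect == 0:
        raise ValueError("all panel effect sizes are zero; rescaling undefined")
    idx = [genotypes.snp_ids.index(r.snp_id) for r in used]
    raw = genotypes.dosage[:, idx] @ effects
    return GeneScore(
        individual_ids=tuple(genotypes.individual_ids),
        raw=raw,
        rescaled=raw / mean_effect,
        standardized=None,
        n_snps_used=len(used),
        fraction=panel.fraction,
        nonpleiotropic=panel.nonpleiotropic,
    )


def standardize(score: GeneScore) -> GeneScore:
    """Divide the rescaled score by its sample SD (ddof=1); no centering."""
    sd = float(np.std(score.rescaled, ddof=1))
    if not sd > 0:
        raise ValueError("rescaled score has zero standard deviation (monomorphic)")
    return replace(score, standardized=score.rescaled / sd)


def compute_gene_score(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    fraction: str,
    nonpleiotropic: bool = False,
    missing_strategy: str = "mean_impute",
    harmonized: bool = False,
) -> GeneScore:
    """Fraction-filter the panel, harmonize if needed, score and standardize."""
    sub = select_fraction(panel, fraction, nonpleiotropic)
    if not harmonized:
        genotypes = harmonize(genotypes, sub, missing_strategy=missing_strategy)
    return standardize(raw_and_rescaled(genotypes, sub))
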