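"""Genotype dosages and harmonization to the panel's scored allele.

Dosages are additive allele counts in [0, 2] (possibly fractional when
imputed). `harmonize` re-codes them so every column counts the panel's
"unfavorable" allele, which is the quantity entering the gene score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = [
    "GenotypeMatrix",
    "read_dosages",
    "write_dosage_tsv",
    "write_vcf",
    "harmonize",
]

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP coded allele.

    Missing dosages are NaN. `coded_allele` maps snp_id -> the allele the
    dosage counts (ALT for VCF input, the column-name suffix for dosage TSV).
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # float, shape (n_individuals, n_snps), NaN = missing
    coded_allele: dict[str, str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        if set(self.snp_ids) - set(self.coded_allele):
            raise ValueError("coded_allele missing entries for some SNPs")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(snp_id)]


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise ValueError(f"{path}: dosage TSV must have an 'IID' first column")
    snp_ids, coded = [], {}
    for col in df.columns[1:]:
        snp_id, _, allele = col.rpartition("_")
        if not snp_id or allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"{path}: column {col!r} is not of the form 'snpid_allele'")
        snp_ids.append(snp_id)
        coded[snp_id] = allele
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(
        individual_ids=df["IID"].tolist(),
        snp_ids=snp_ids,
        dosage=dosage,
        coded_allele=coded,
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids: list[str] = []
    coded: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: {var.ID or var.POS} is multi-allelic; panel SNPs are biallelic"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(np.isfinite(col), col, np.nan)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        finite = col[np.isfinite(col)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"{path}: dosage outside [0, 2] at {snp_id}")
        snp_ids.append(snp_id)
        coded[snp_id] = var.ALT[0]
        columns.append(col)
    dosage = np.column_stack(columns) if columns else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(
        individual_ids=individual_ids, snp_ids=snp_ids, dosage=dosage, coded_allele=coded
    )


def read_dosages(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read genotype dosages from a VCF (DS preferred over GT) or dosage TSV.

    The dosage TSV dialect has an ``IID`` column followed by one column per
    SNP named ``<snp_id>_<coded allele>``. For VCF input the coded allele is
    ALT; multi-allelic records are rejected.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    cols = {"IID": genotypes.individual_ids}
    for j, sid in enumerate(genotypes.snp_ids):
        cols[f"{sid}_{genotypes.coded_allele[sid]}"] = genotypes.dosage[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_vcf(genotypes: GenotypeMatrix, panel: SnpPanel, path) -> None:
    """Write a minimal VCF 4.2 with DS genotype dosages.

    REF is the panel's other allele and ALT the coded allele, so a round trip
    through `read_dosages` preserves the coded-allele convention.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, sid in enumerate(genotypes.snp_ids):
            rec = panel.get(sid)
            alt = genotypes.coded_allele[sid]
            ref = rec.other_allele if alt == rec.scored_allele else rec.scored_allele
            vals = [
                "." if not np.isfinite(d) else f"{d:.6g}" for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{sid}\t{ref}\t{alt}\t.\t.\t.\tDS\t"
                + "\t".join(vals)
                + "\n"
            )


def harmonize(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    missing_strategy: str = "mean_impute",
) -> GenotypeMatrix:
    """Re-code dosages so each retained column counts the panel's scored allele.

    Columns coded to the panel's other allele are flipped (d -> 2 - d). Panel
    SNPs absent from the genotype matrix are dropped with a logged report and
    excluded downstream (including from the score's rescaling denominator).
    A/T and C/G panel pairs are strand-ambiguous; a warning is logged and no
    strand flipping is attempted. A coded allele matching neither panel allele
    is an error.

    missing_strategy:
      - ``mean_impute``: missing dosages become 2 x the sample scored-allele
        frequency computed from the non-missing dosages of that SNP.
      - ``drop_individual``: individuals with any missing dosage are removed.

    The output has no missing values and is idempotent under re-application.
    """
    if missing_strategy not in ("mean_impute", "drop_individual"):
        raise ValueError(f"unknown missing_strategy {missing_strategy!r}")

    present = [r for r in panel.records if r.snp_id in set(genotypes.snp_ids)]
    absent = [r.snp_id for r in panel.records if r.snp_id not in set(genotypes.snp_ids)]
    if absent:
        log.info("harmonize: %d panel SNPs absent from genotypes and dropped: %s",
                 len(absent), ", ".join(absent))
    if not present:
        raise ValueError("no panel SNPs present in the genotype matrix")

    cols = []
    for rec in present:
        if rec.is_palindromic:
            log.warning(
                "harmonize: %s has strand-ambiguous alleles %s/%s; no strand flip attempted",
                rec.snp_id, rec.scored_allele, rec.other_allele,
            )
        coded = genotypes.coded_allele[rec.snp_id]
        d = genotypes.column(rec.snp_id).astype(float).copy()
        if coded == rec.scored_allele:
            pass
        elif coded == rec.other_allele:
            d = 2.0 - d
        else:
            raise ValueError(
                f"allele mismatch at {rec.snp_id}: genotypes coded to {coded!r} "
                f"but panel alleles are {rec.scored_allele}/{rec.other_allele}"
            )
        cols.append(d)
    dosage = np.column_stack(cols)
    individual_ids = list(genotypes.individual_ids)

    missing = ~np.isfinite(dosage)
    if missing.any():
        if missing_strategy == "drop_individual":
            keep = ~missing.any(axis=1)
            if not keep.any():
                raise ValueError("every individual has at least one missing dosage")
            dosage = dosage[keep]
            individual_ids = [iid for iid, k in zip(individual_ids, keep) if k]
        else:
            for j in range(dosage.shape[1]):
                col = dosage[:, j]
                miss = ~np.isfinite(col)
                if not miss.any():
                    continue
                if miss.all():
                    raise ValueError(
                        f"{present[j].snp_id}: all dosages missing; cannot mean-impute"
                    )
                p = col[~miss].mean() / 2.0  # sample scored-allele frequency
                col[miss] = 2.0 * p

    return GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=[r.snp_id for r in present],
        dosage=dosage,
        coded_allele={r.snp_id: r.scored_allele for r in present},
    )
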