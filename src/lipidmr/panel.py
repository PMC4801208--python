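"""SNP effect panels for lipid gene scores.

A panel row describes one GWAS index SNP: the "unfavorable" allele counted by
the score (lipid-raising for LDL/TC/TG, lipid-lowering for HDL), the other
allele, the absolute per-allele effect size in mg/dL, the lipid fractions the
SNP is associated with, and — for the non-pleiotropic sub-scores — whether the
SNP is exclusively associated with HDL or LDL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "FRACTIONS",
    "SnpRecord",
    "SnpPanel",
    "read_panel",
    "write_panel",
    "select_fraction",
]

log = logging.getLogger(__name__)

#: Lipid fractions a panel SNP may belong to.
FRACTIONS = ("HDL", "LDL", "TC", "TG")

#: Fractions for which a non-pleiotropic (single-fraction) score is defined.
NONPLEIO_FRACTIONS = ("HDL", "LDL")

_VALID_ALLELES = frozenset("ACGT")

PANEL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "scored_allele",
    "other_allele",
    "abs_effect",
    "fractions",
    "nonpleiotropic_for",
    "eaf",
]


@dataclass(frozen=True)
class SnpRecord:
    """One scored SNP: unfavorable allele, |effect| in mg/dL, memberships."""

    snp_id: str
    chrom: str
    pos: int  # 1-based (VCF convention)
    scored_allele: str
    other_allele: str
    abs_effect: float
    fractions: frozenset[str]
    nonpleiotropic_for: frozenset[str] = frozenset()
    eaf: float = 0.5  # scored-allele frequency; used only by the simulator

    def __post_init__(self) -> None:
        if self.scored_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: scored allele {self.scored_allele!r} is not one of A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: other allele {self.other_allele!r} is not one of A/C/G/T")
        if self.scored_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: scored and other allele are both {self.scored_allele}")
        if not self.abs_effect >= 0:
            raise ValueError(f"{self.snp_id}: abs_effect must be >= 0, got {self.abs_effect}")
        if not self.fractions:
            raise ValueError(f"{self.snp_id}: fractions must be non-empty")
        bad = set(self.fractions) - set(FRACTIONS)
        if bad:
            raise ValueError(f"{self.snp_id}: unknown fractions {sorted(bad)}")
        if not set(self.nonpleiotropic_for) <= set(self.fractions):
            raise ValueError(f"{self.snp_id}: nonpleiotropic_for must be a subset of fractions")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie strictly in (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
        return {self.scored_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class SnpPanel:
    """Ordered collection of SnpRecords, optionally filtered to one fraction."""

    records: tuple[SnpRecord, ...]
    fraction: str | None = None
    nonpleiotropic: bool = False

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise ValueError(f"duplicate snp_id {sid!r} in panel")
            seen.add(sid)
        if self.fraction is not None:
            for r in self.records:
                if self.fraction not in r.fractions:
                    raise ValueError(
                        f"{r.snp_id}: not associated with panel fraction {self.fraction}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SnpRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def subset(self, snp_ids) -> "SnpPanel":
        """Sub-panel restricted to `snp_ids`, original order preserved."""
        keep = set(snp_ids)
        return replace(self, records=tuple(r for r in self.records if r.snp_id in keep))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "scored_allele": r.scored_allele,
                "other_allele": r.other_allele,
                "abs_effect": r.abs_effect,
                "fractions": ",".join(f for f in FRACTIONS if f in r.fractions),
                "nonpleiotropic_for": ",".join(
                    f for f in FRACTIONS if f in r.nonpleiotropic_for
                ),
                "eaf": r.eaf,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def _parse_set(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(part.strip() for part in str(cell).split(",") if part.strip())


def read_panel(path, dialect: str = "tsv") -> SnpPanel:
    """Read a SNP effect panel from a tab-separated file.

    Expected header: snp_id, chrom, pos, scored_allele, other_allele,
    abs_effect, fractions (comma-joined), nonpleiotropic_for (comma-joined,
    may be empty), eaf. Row order is preserved.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown panel dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} is missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SnpRecord(
                    snp_id=str(row["snp_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    scored_allele=str(row["scored_allele"]).strip().upper(),
                    other_allele=str(row["other_allele"]).strip().upper(),
                    abs_effect=float(row["abs_effect"]),
                    fractions=_parse_set(row["fractions"]),
                    nonpleiotropic_for=_parse_set(row["nonpleiotropic_for"]),
                    eaf=float(row["eaf"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"panel file {path}, row {idx + 2}: {exc}") from exc
    return SnpPanel(records=tuple(records))


def write_panel(panel: SnpPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def select_fraction(panel: SnpPanel, fraction: str, nonpleiotropic: bool = False) -> SnpPanel:
    """Sub-panel of SNPs associated with `fraction`.

    With ``nonpleiotropic=True`` (HDL or LDL only) the result keeps only SNPs
    exclusively associated with that fraction, i.e. the non-pleiotropic score
    components. Original record order is preserved.
    """
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown lipid fraction {fraction!r}; expected one of {FRACTIONS}")
    if nonpleiotropic and fraction not in NONPLEIO_FRACTIONS:
        raise ValueError(
            f"non-pleiotropic scores are defined only for {NONPLEIO_FRACTIONS}, not {fraction}"
        )
    if nonpleiotropic:
        records = tuple(r for r in panel.records if fraction in r.nonpleiotropic_for)
    else:
        records = tuple(r for r in panel.records if fraction in r.fractions)
    if not records:
        raise ValueError(f"no panel SNPs for fraction {fraction} (nonpleiotropic={nonpleiotropic})")
    return SnpPanel(records=records, fraction=fraction, nonpleiotropic=nonpleiotropic)
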