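import numpy as np
import pytest

from lipidmr import GenotypeMatrix, SnpPanel, SnpRecord, synthetic_teslovich_panel


@pytest.fixture(scope="session")
def panel95() -> SnpPanel:
    """The packaged synthetic 95-SNP lipid panel."""
    return synthetic_teslovich_panel()


@pytest.fixture
def toy_panel() -> SnpPanel:
    """Three-SNP panel spanning the fraction/pleiotropy combinations."""
    return SnpPanel(
        records=(
            SnpRecord("rsA", "1", 100, "A", "G", 0.5, frozenset({"HDL"}),
                      frozenset({"HDL"}), eaf=0.3),
            SnpRecord("rsB", "2", 200, "C", "T", 1.2, frozenset({"HDL", "TG"}), eaf=0.5),
            SnpRecord("rsC", "3", 300, "G", "T", 2.0, frozenset({"LDL"}),
                      frozenset({"LDL"}), eaf=0.7),
        )
    )


def make_genotypes(panel: SnpPanel, dosage, coded=None, ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        individual_ids=ids or [f"I{i}" for i in range(dosage.shape[0])],
        snp_ids=panel.snp_ids,
        dosage=dosage,
        coded_allele=coded or {r.snp_id: r.scored_allele for r in panel.records},
    )
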