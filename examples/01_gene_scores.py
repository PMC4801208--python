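"""Build a weighted lipid gene score from a SNP panel and dosages.

Constructs a 3-SNP HDL panel inline, scores four individuals, and prints the
raw (dosage x |effect| sum), rescaled (divided by the mean |effect|) and
standardized (unit cohort SD) scores. The rescaled score is interpretable as
an unfavorable-allele count; the standardized score is what enters the Cox
models, so hazard ratios are per 1 SD of score.
"""

import numpy as np

from lipidmr import (
    GenotypeMatrix,
    SnpPanel,
    SnpRecord,
    compute_gene_score,
)

panel = SnpPanel(records=(
    SnpRecord("rs1", "1", 100, "A", "G", 0.4, frozenset({"HDL"}), frozenset({"HDL"}), eaf=0.3),
    SnpRecord("rs2", "2", 200, "C", "T", 1.0, frozenset({"HDL", "TG"}), eaf=0.5),
    SnpRecord("rs3", "3", 300, "G", "T", 1.6, frozenset({"HDL"}), frozenset({"HDL"}), eaf=0.7),
))

# dosages count the scored ("unfavorable") allele per individual
genotypes = GenotypeMatrix(
    individual_ids=["P1", "P2", "P3", "P4"],
    snp_ids=["rs1", "rs2", "rs3"],
    dosage=np.array([[0, 1, 2], [1, 1, 1], [2, 0, 1], [0, 2, 0]], dtype=float),
    coded_allele={"rs1": "A", "rs2": "C", "rs3": "G"},
)

score = compute_gene_score(genotypes, panel, fraction="HDL")
print(f"HDL score over {score.n_snps_used} SNPs (mean |effect| = 1.0 mg/dL):")
for iid, raw, resc, std in zip(score.individual_ids, score.raw,
                               score.rescaled, score.standardized):
    print(f"  {iid}: raw={raw:.2f}  rescaled={resc:.2f}  standardized={std:.2f}")
print(f"standardized-score SD = {np.std(score.standardized, ddof=1):.3f} (1 by construction)")

narrow = compute_gene_score(genotypes, panel, fraction="HDL", nonpleiotropic=True)
print(f"non-pleiotropic HDL score uses {narrow.n_snps_used} of {len(panel)} SNPs "
      "(only SNPs exclusively associated with HDL)")
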