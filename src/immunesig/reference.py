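"""Published validation counts and the packaged reference signature model.

The published pooled validation of the 23-probe (19-gene) immune signature
reports, for patients without anti-HER2 therapy, pCR in 170/424 Gp-R vs
83/679 Gp-NR, and with anti-HER2 therapy 61/120 vs 64/184; the newest
single-institution validation cohort had 13 pCR among 112 patients.  These
counts are inputs for the contingency reproductions.

The original signature's discriminant coefficients are distributed through
an external repository/patent and are not shipped here; instead a reference
model of the same form is trained once on a fixed-seed synthetic cohort so
the package is self-contained and every downstream stage is exercisable.
"""

from __future__ import annotations

import functools

from .signature import DLDASignatureResults, train_dlda
from .stats import ContingencyTable2x2

__all__ = [
    "POOLED_NO_ANTIHER2",
    "POOLED_ANTIHER2",
    "OUH_PCR_COUNT",
    "OUH_TOTAL",
    "reference_model",
    "reference_training_cohort",
]

#: pooled validation without anti-HER2 therapy: Gp-R 170/424, Gp-NR 83/679
POOLED_NO_ANTIHER2 = ContingencyTable2x2(170, 254, 83, 596, dataset="pooled-no-antiHER2")
#: pooled validation with anti-HER2 therapy: Gp-R 61/120, Gp-NR 64/184
POOLED_ANTIHER2 = ContingencyTable2x2(61, 59, 64, 120, dataset="pooled-antiHER2")
#: newest single-institution validation: 13 pCR of 112 patients
OUH_PCR_COUNT = 13
OUH_TOTAL = 112

REFERENCE_TRAINING_SEED = 201406
REFERENCE_TRAINING_N = 400


@functools.lru_cache(maxsize=1)
def _training_bundle():
    from .simulate import SyntheticConfig, signature_genes, simulate_cohort

    config = SyntheticConfig(
        n_samples=REFERENCE_TRAINING_N,
        n_datasets=1,
        seed=REFERENCE_TRAINING_SEED,
    )
    matrix, clinical, truth = simulate_cohort(config)
    sig = matrix.subset(signature_genes(config.signature_gene_count))
    labels = clinical.data["pcr"].to_numpy(dtype=bool)
    return sig, labels, clinical, truth


def reference_training_cohort():
    """The fixed-seed synthetic training cohort behind the reference model."""
    sig, labels, clinical, truth = _training_bundle()
    return sig, labels, clinical, truth


@functools.lru_cache(maxsize=1)
def reference_model() -> DLDASignatureResults:
    """Reference DLDA signature trained on the packaged synthetic cohort."""
    sig, labels, _, _ = _training_bundle()
    model = train_dlda(sig, labels)
    model.metadata["training_id"] = "synthetic-reference"
    return model
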