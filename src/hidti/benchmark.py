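"""Published summary statistics of the curated DrugBank-derived benchmark.

The real dataset (707 drugs with SMILES, 1489 proteins with sequences,
plus side-effect and disease vocabularies and six association matrices)
is an external download and is not shipped; these constants record its
published axis sizes and interaction counts so that synthetic presets
can mirror its shape and derived quantities can be computed without the
data itself.
"""

from __future__ import annotations

N_DRUGS = 707
N_PROTEINS = 1489
N_SIDE_EFFECTS = 4192
N_DISEASES = 5603

#: number of positive association pairs per interaction type
POSITIVE_COUNTS = {
    "drug_protein": 1909,
    "drug_drug": 10024,
    "drug_side_effect": 80160,
    "drug_disease": 199022,
    "protein_protein": 7133,
    "protein_disease": 1572157,
}

DRUG_EMBEDDING_DIM = 300  # Mol2vec
PROTEIN_EMBEDDING_DIM = 100  # ProtVec


def mean_positives_per_drug() -> float:
    """Average number of interacting proteins per drug in the benchmark."""
    return POSITIVE_COUNTS["drug_protein"] / N_DRUGS
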