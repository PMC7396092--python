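import numpy as np
import pandas as pd
import pytest

from prsubtype.io import GenotypeDataset, SummaryStatsTable


def make_stats(trait_id, trait_type, rows):
    """rows: dict variant -> (ea, oa, effect, p); builds a validated table."""
    df = pd.DataFrame(
        [(ea, oa, eff, p) for ea, oa, eff, p in rows.values()],
        index=pd.Index(list(rows), name="variant_id"),
        columns=["effect_allele", "other_allele", "effect", "p"],
    )
    return SummaryStatsTable(trait_id, trait_type, df)


def make_geno(dosage, variant_ids=None, counted=None, other=None,
              cohort_id="test", phenotype=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    variant_ids = variant_ids or [f"rs{j + 1}" for j in range(m)]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    pheno = None
    if phenotype is not None:
        pheno = pd.Series(phenotype, index=pd.Index(sample_ids, name="sample_id"))
    return GenotypeDataset(
        cohort_id=cohort_id,
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        counted_allele=np.array(counted or ["A"] * m),
        other_allele=np.array(other or ["G"] * m),
        dosage=dosage,
        phenotype=pheno,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
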