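import numpy as np
import pandas as pd
import pytest

from radzone.io_formats import GenotypeMatrix, LocusInfo, make_meta


def genotype_matrix(dosage, samples=None, tag_ids=None, depth=None):
    """Build a GenotypeMatrix from a plain nested list / array."""
    dosage = np.asarray(dosage, dtype=float)
    n_loci, n_samples = dosage.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    loci = [
        LocusInfo(
            locus_id=f"L{i + 1}",
            tag_id=tag_ids[i] if tag_ids else f"tag{i + 1}",
            snp_index_in_tag=0,
        )
        for i in range(n_loci)
    ]
    return GenotypeMatrix(loci=loci, samples=samples, dosage=dosage, depth=depth)


def sexed_meta(n_males, n_females):
    ids = [f"s{i + 1}" for i in range(n_males + n_females)]
    return make_meta(
        pd.DataFrame(
            {
                "sample_id": ids,
                "sex": ["M"] * n_males + ["F"] * n_females,
                "population_id": "p",
                "distance_km": 0.0,
                "mitotype": "unknown",
            }
        )
    )


@pytest.fixture
def meta_4m4f():
    return sexed_meta(4, 4)


@pytest.fixture
def meta_10m10f():
    return sexed_meta(10, 10)
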