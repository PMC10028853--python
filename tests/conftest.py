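import numpy as np
import pandas as pd
import pytest

from regdiff.io_formats import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def _variant_frame(p, chrom="1", start=1000, step=100):
    return pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(p)],
            "chrom": chrom,
            "pos": start + step * np.arange(p, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )


@pytest.fixture
def small_genotypes(rng):
    """60 samples x 12 common variants, complete calls, HWE by construction."""
    maf = rng.uniform(0.2, 0.5, 12)
    dosages = rng.binomial(2, maf, size=(60, 12)).astype(float)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"s{i}" for i in range(60)], dtype=object),
        variants=_variant_frame(12),
    )
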