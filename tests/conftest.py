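import numpy as np
import pandas as pd
import pytest

from regionbvs.genotypes import GenotypeMatrix, PhenotypeVector


def make_G(dosages, chrom="1", pos_start=1000, pos_step=100, chroms=None):
    """Build a GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if chroms is None:
        chroms = [chrom] * p
    pos, counters = [], {}
    for c in chroms:
        counters[c] = counters.get(c, -1) + 1
        pos.append(pos_start + counters[c] * pos_step)
    meta = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(p)],
            "chrom": [str(c) for c in chroms],
            "pos": pos,
            "minor": ["A"] * p,
            "major": ["G"] * p,
        }
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_G(rng):
    return make_G(rng.integers(0, 3, size=(40, 12)).astype(float))


@pytest.fixture
def balanced_y():
    def _make(n, rng=None, seed=0):
        r = rng or np.random.default_rng(seed)
        return PhenotypeVector(r.permutation(np.repeat([0, 1], n // 2)))

    return _make
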