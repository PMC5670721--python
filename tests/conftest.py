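import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


def random_sparse_alpha(rng, p=None, n_entries=None, min_mag=1e-3):
    """Random sparse pair coefficients with magnitudes bounded away from 0."""
    from pairzero import PairCoefficients

    p = p if p is not None else int(rng.integers(2, 12))
    q = p * (p - 1) // 2
    n_entries = n_entries if n_entries is not None else int(rng.integers(0, min(q, 8) + 1))
    jj, kk = np.triu_indices(p, k=1)
    chosen = rng.choice(q, size=n_entries, replace=False)
    entries = {}
    for c in chosen:
        mag = rng.uniform(min_mag, 3.0)
        entries[(int(jj[c]), int(kk[c]))] = float(rng.choice([-1.0, 1.0]) * mag)
    return PairCoefficients(p=p, entries=entries)
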