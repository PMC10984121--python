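import numpy as np
import pytest

from electrome.config import default_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def brute_force_apen(x, m, r):
    """Independent O(N^2) transcription of the Pincus ApEn definition:
    Phi^m(r) - Phi^(m+1)(r), Chebyshev distance, self-matches included."""
    from scipy.spatial.distance import cdist

    x = np.asarray(x, dtype=float)

    def phi(mm):
        n = x.size - mm + 1
        emb = np.array([x[i:i + mm] for i in range(n)])
        d = cdist(emb, emb, metric="chebyshev")
        c = (d <= r).sum(axis=1) / n
        return np.mean(np.log(c))

    return phi(m) - phi(m + 1)
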