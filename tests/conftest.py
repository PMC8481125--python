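import numpy as np
import pandas as pd
import pytest

from egfr_groups.screen import SelectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture
def toy_matrix():
    """3 mutations x 2 drugs with hand-checkable values."""
    values = pd.DataFrame(
        [[-1.0, 0.0], [-0.5, 0.5], [0.0, 1.0]],
        index=pd.Index(["m1", "m2", "m3"], name="mutation"),
        columns=pd.Index(["dA", "dB"], name="drug"),
    )
    return SelectivityMatrix(values, None)


def brute_force_spearman(x, y):
    """Rank-correlation oracle: average ranks + Pearson on ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / total

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))
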