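"""Independent oracles used by the test suite.

These deliberately share no code with the package: the 1-D k-means optimum is
found by dynamic programming over sorted prefix sums, and the radiative
physics is evaluated in 50-digit decimal arithmetic.
"""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 50


def dp_kmeans_1d_wcss(values: np.ndarray, k: int) -> float:
    """Exact optimal within-cluster sum of squares for 1-D k-means.

    Clusters of an optimal 1-D solution are contiguous in sorted order, so
    DP over split points is exact.  O(k n^2).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:  # x[i:j]
        m = j - i
        seg = s[j] - s[i]
        return (ss[j] - ss[i]) - seg * seg / m

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            dp[c, j] = min(dp[c - 1, i] + cost(i, j) for i in range(c - 1, j))
    return float(dp[k, n])


def dec_radiative_power(skin_c, ambient_c, emissivity="0.98", sigma="5.673e-8") -> Decimal:
    ts = Decimal(repr(float(skin_c))) + Decimal("273.15")
    ta = Decimal(repr(float(ambient_c))) + Decimal("273.15")
    return Decimal(emissivity) * Decimal(sigma) * (ts**4 - ta**4)


def dec_bsa(weight_kg) -> Decimal:
    w = Decimal(repr(float(weight_kg)))
    return (4 * w + 7) / (w + 90)


def dec_tee_per_area(p, radiative_fraction="0.75") -> Decimal:
    return (Decimal(repr(float(p))) * 86400) / (4184 * Decimal(radiative_fraction))


def dec_one_sample_t(mean, sd, n, mu0) -> Decimal:
    num = Decimal(repr(float(mean))) - Decimal(repr(float(mu0)))
    den = Decimal(repr(float(sd))) / Decimal(n).sqrt()
    return num / den
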