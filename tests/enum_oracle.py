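"""Brute-force oracles, independent of the simulation engine.

Used to check one-generation offspring copy-number distributions by exact
enumeration on toy genomes small enough to sum over every outcome.
"""

import numpy as np
from scipy import stats


def offspring_load_distribution(copy_numbers, n_sites, u, v, a, b):
    """Exact one-generation offspring load distribution (asexual).

    One offspring is produced by: picking a parent with probability
    proportional to ``exp(-a n - b n^2/2)``; drawing ``Binomial(n, u)``
    transpositions, of which at most the number of empty sites insert; then
    surviving each of the resulting copies independently with probability
    ``1 - v``.  Returns an array ``p`` with ``p[m] = P(load = m)`` over
    ``m = 0..n_sites``.
    """
    copy_numbers = np.asarray(copy_numbers)
    w = np.exp(-a * copy_numbers - 0.5 * b * copy_numbers.astype(float) ** 2)
    pick = w / w.sum()
    p = np.zeros(n_sites + 1)
    for n_i, p_i in zip(copy_numbers, pick):
        empty = n_sites - n_i
        for g in range(n_i + 1):
            pg = stats.binom.pmf(g, n_i, u)
            n_after = n_i + min(g, empty)
            for m in range(n_after + 1):
                p[m] += p_i * pg * stats.binom.pmf(m, n_after, 1.0 - v)
    assert abs(p.sum() - 1.0) < 1e-12
    return p


def total_variation(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
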