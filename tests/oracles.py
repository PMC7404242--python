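"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the hypergeometric
tail is counted by enumerating every possible draw, and expected values
frozen in tests were computed with these functions.
"""

from itertools import combinations

import numpy as np


def hypergeom_upper_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = 0
    tot = 0
    for draw in combinations(range(N), n):
        tot += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / tot


def hypergeom_upper_tail_table(N: int, n: int) -> np.ndarray:
    """Upper-tail table P(X >= k) for every K and k at fixed (N, n).

    Enumerates the C(N, n) draws once; the overlap with the first K items
    of the population is, for every K simultaneously, the number of drawn
    indices below K.  Returns an array ``tail[K, k]``.
    """
    draws = np.array(list(combinations(range(N), n)), dtype=np.int64)
    if draws.size == 0:
        draws = draws.reshape(1, 0)
    tails = np.zeros((N + 1, n + 2))
    for K in range(N + 1):
        overlap = (draws < K).sum(axis=1)
        counts = np.bincount(overlap, minlength=n + 2)
        # P(X >= k) = 1 - cumulative below k
        cum = np.concatenate([[0], np.cumsum(counts)])[: n + 2]
        tails[K] = 1.0 - cum / draws.shape[0]
    return tails
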