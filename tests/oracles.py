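"""Independent brute-force reference implementations.

Deliberately naive (double loops, explicit enumeration) and written
against the textbook definitions, so they share no code path with the
package's vectorized implementations.
"""

from __future__ import annotations

from math import factorial, log

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy by explicit O(n^2) template comparison."""
    x = np.asarray(x, dtype=float)
    n = x.size
    tol = r * x.std()
    n_templates = n - m  # windows of length m+1 that exist

    def count(length: int) -> int:
        total = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = 0.0
                for k in range(length):
                    d = max(d, abs(x[i + k] - x[j + k]))
                if d <= tol:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.inf
    return -log(a / b)


def lz76_bruteforce(bits: np.ndarray) -> int:
    """LZ76 phrase count via the Kaspar-Schuster character scan."""
    s = list(int(v) for v in bits)
    n = len(s)
    if n == 0:
        return 0
    c, i, k, k_max, j = 1, 0, 1, 1, 1
    while j + k <= n:
        if s[i + k - 1] == s[j + k - 1]:
            k += 1
            if j + k > n:
                c += 1
                break
        else:
            k_max = max(k_max, k)
            i += 1
            if i == j:
                c += 1
                j += k_max
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def specen_bruteforce(power: np.ndarray) -> float:
    """Normalized Shannon entropy of a power vector, direct summation."""
    p = np.asarray(power, dtype=float)
    q = p / p.sum()
    h = 0.0
    for v in q:
        if v > 0:
            h -= v * log(v)
    return h / log(len(q))


def permen_bruteforce(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Permutation entropy by explicit ordinal-pattern tallying."""
    x = np.asarray(x, dtype=float)
    counts: dict[tuple, int] = {}
    n_patterns = x.size - (order - 1) * delay
    for i in range(n_patterns):
        window = [x[i + k * delay] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = 0.0
    for v in counts.values():
        p = v / total
        h -= p * log(p)
    return h / log(factorial(order))
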