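"""Independent reference implementations used only to check the package.

These are deliberately written in a different style from the library code
(string dictionaries and explicit formulas instead of trie walks and
library calls) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def lz78_count_naive(s: str) -> int:
    """Brute-force LZ78 phrase count on a string of '0'/'1' characters.

    Keeps the dictionary as a set of phrase strings and extends the
    current phrase by slicing; a trailing phrase that exhausts the input
    while still matching a dictionary entry counts as one phrase.
    """
    dictionary: set[str] = set()
    i, L, n = 0, 0, len(s)
    while i < n:
        j = i + 1
        w = s[i:j]
        while w in dictionary and j < n:
            j += 1
            w = s[i:j]
        L += 1
        if w in dictionary:  # ran out of symbols mid-match
            break
        dictionary.add(w)
        i = j
    return L


def detrend_explicit(x: np.ndarray) -> np.ndarray:
    """Least-squares linear detrend via the normal equations."""
    t = np.arange(x.size, dtype=float)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ coef


def polyfit_ols(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial least squares, coefficients in ascending order."""
    return np.polynomial.polynomial.polyfit(x, y, degree)


def cohens_d_formula(a, b) -> float:
    """Cohen's d written out longhand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sa2 = ((a - a.mean()) ** 2).sum() / (na - 1)
    sb2 = ((b - b.mean()) ** 2).sum() / (nb - 1)
    sp = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
    return (a.mean() - b.mean()) / sp
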