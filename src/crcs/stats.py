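"""Shared statistical primitives.

The one-sided Mann-Whitney U test uses exact enumeration of all group
assignments for small samples (n_a + n_b <= 12, ties handled through the
midrank U statistic) and the normal approximation with tie correction
otherwise (scipy).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["mannwhitney_greater", "EXACT_LIMIT"]

#: Largest pooled sample size for which the exact enumeration branch is used.
EXACT_LIMIT = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #{(i,j): a_i > b_j} + 0.5 * #ties."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mannwhitney_greater(a, b) -> float:
    """One-sided Mann-Whitney U p-value for alternative 'a > b'."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n = len(a) + len(b)
    if n <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        u_obs = _u_statistic(a, b)
        count = 0
        total = 0
        for pick in combinations(range(n), len(a)):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                count += 1
        return count / total
    res = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)
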