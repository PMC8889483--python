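"""Two-sided permutation tests on differences of group means.

The statistic is d = mean(group A) - mean(group B).  The null distribution
is built by reassigning group labels (sampling without replacement).  Two
regimes:

* exact enumeration over all C(n_a+n_b, n_a) label splits when that count
  does not exceed ``n_perm`` (strictly more accurate at no extra cost for
  small groups); the observed arrangement is one of the enumerated splits
  and p = #{|d*| >= |d_obs|} / total;
* Monte-Carlo otherwise, with the add-one estimator
  p = (1 + #{|d*| >= |d_obs|}) / (n_perm + 1), which guarantees p in (0, 1]
  and validity of the test.

``permutation_test_columns`` runs many tests that share the same group
labels (one test per column of a value matrix) and reuses a single set of
permutations across columns — each column's marginal p-value is unchanged,
but the work of drawing permutations is done once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["PermutationResult", "permutation_test", "permutation_test_columns"]

# Relative tolerance when comparing |d*| against |d_obs|: permuted statistics
# that tie with the observed one up to floating-point noise count as extreme.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one two-sided permutation test.

    ``cell`` identifies what was tested (an AOI label or an AOI pair);
    ``observed_diff`` is mean(A) - mean(B); ``significant`` is evaluated
    against a (possibly Bonferroni-corrected) threshold.
    """

    cell: str
    observed_diff: float
    p_value: float
    n_permutations: int
    significant: bool
    exact: bool = False


def _tie_threshold(d_obs: np.ndarray) -> np.ndarray:
    return np.abs(d_obs) - _TIE_RTOL * np.maximum(1.0, np.abs(d_obs))


def permutation_test_columns(values: np.ndarray, labels: np.ndarray,
                             n_perm: int = 100_000,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Column-wise two-sided permutation tests with shared permutations.

    Parameters
    ----------
    values : (n, k) array — one row per unit, one column per tested quantity.
    labels : (n,) array of {0, 1} — group membership (1 = group A).

    Returns
    -------
    (observed_diff, p_values, n_used, exact) where ``n_used`` is the number
    of splits examined (all of them in exact mode).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    n, _k = values.shape
    n_a = int(np.sum(labels == 1))
    n_b = n - n_a
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    col_sum = values.sum(axis=0)
    obs_sum_a = values[labels == 1].sum(axis=0)
    d_obs = obs_sum_a / n_a - (col_sum - obs_sum_a) / n_b
    thresh = _tie_threshold(d_obs)

    total = comb(n, n_a)
    if total <= n_perm:
        count = np.zeros(values.shape[1], dtype=np.int64)
        for idx in combinations(range(n), n_a):
            sum_a = values[list(idx)].sum(axis=0)
            d = sum_a / n_a - (col_sum - sum_a) / n_b
            count += np.abs(d) >= thresh
        return d_obs, count / total, total, True

    if rng is None:
        rng = np.random.default_rng()
    count = np.zeros(values.shape[1], dtype=np.int64)
    done = 0
    chunk = min(n_perm, max(1, 20_000_000 // max(n, 1)))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random subsets of size n_a, as a 0/1 assignment matrix
        order = np.argsort(rng.random((m, n)), axis=1)[:, :n_a]
        mask = np.zeros((m, n))
        np.put_along_axis(mask, order, 1.0, axis=1)
        sum_a = mask @ values
        d = sum_a / n_a - (col_sum - sum_a) / n_b
        count += (np.abs(d) >= thresh).sum(axis=0)
        done += m
    p = (1 + count) / (n_perm + 1)
    return d_obs, p, n_perm, False


def permutation_test(values_a, values_b, n_perm: int = 100_000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     cell: str = "", threshold: float = 0.05,
                     ) -> PermutationResult:
    """Two-sided permutation test for a difference in group means.

    ``values_a`` and ``values_b`` are the per-unit measurements of the two
    groups.  ``threshold`` only sets the ``significant`` flag on the result.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = np.concatenate([a, b])[:, None]
    labels = np.concatenate([np.ones(a.size, dtype=int),
                             np.zeros(b.size, dtype=int)])
    d, p, n_used, exact = permutation_test_columns(values, labels, n_perm, rng)
    p_val = float(p[0])
    return PermutationResult(cell, float(d[0]), p_val, n_used,
                             bool(p_val < threshold), exact)
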