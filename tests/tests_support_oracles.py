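"""Independent brute-force oracles shared by the acceptance tests.

Deliberately naive implementations (complete enumeration, scipy formulas)
kept separate from the package code they validate.
"""

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from pathmarkers.activity import ActivityMatrix


def make_activity(matrix: np.ndarray) -> ActivityMatrix:
    matrix = np.asarray(matrix, dtype=float)
    samples = [f"s{i}" for i in range(matrix.shape[0])]
    names = [f"p{k}" for k in range(matrix.shape[1])]
    return ActivityMatrix(
        pd.DataFrame(matrix, index=samples, columns=names),
        pd.DataFrame((~np.isnan(matrix)).astype(int), index=samples, columns=names),
    )


def exhaustive_p_oracle(column: np.ndarray, n_a: int) -> float:
    """Exact permutation p for one column: enumerate every assignment of
    n_a class-A positions, count unsigned t values >= the observed one
    (observed assignment = the first n_a samples)."""
    n = len(column)

    def unsigned_t(positions) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[list(positions)] = True
        a, b = column[mask], column[~mask]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        return abs(stats.ttest_ind(a, b).statistic)

    observed = unsigned_t(range(n_a))
    assignments = list(itertools.combinations(range(n), n_a))
    c = sum(unsigned_t(m) >= observed - 1e-12 for m in assignments)
    return c / len(assignments)
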