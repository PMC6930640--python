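"""Naive loop-based reference implementations used by the test suite.

Deliberately written from the textbook formulas, independent of the
vectorized package code they are used to check.
"""

import math

import numpy as np


def pearson_r2(y, yh):
    n = len(y)
    my = sum(y) / n
    mh = sum(yh) / n
    num = sum((a - my) * (b - mh) for a, b in zip(y, yh))
    den = math.sqrt(sum((a - my) ** 2 for a in y)) * math.sqrt(
        sum((b - mh) ** 2 for b in yh)
    )
    return (num / den) ** 2


def rmse(y, yh):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yh)) / len(y))


def mae(y, yh):
    return sum(abs(a - b) for a, b in zip(y, yh)) / len(y)


def rm2(y, yh):
    def one_way(y, yh):
        k = sum(a * b for a, b in zip(y, yh)) / sum(b * b for b in yh)
        ybar = sum(y) / len(y)
        r0sq = 1.0 - sum((a - k * b) ** 2 for a, b in zip(y, yh)) / sum(
            (a - ybar) ** 2 for a in y
        )
        rsq = pearson_r2(y, yh)
        return rsq * (1.0 - math.sqrt(max(rsq - r0sq, 0.0)))

    fwd = one_way(list(y), list(yh))
    rev = one_way(list(yh), list(y))
    return (fwd + rev) / 2.0, abs(fwd - rev)


def dense_hat_diagonal(X_train, X_query):
    """Explicit (X'X)^-1 hat diagonal on the intercept-augmented design."""
    A = np.hstack([np.ones((X_train.shape[0], 1)), X_train])
    B = np.hstack([np.ones((X_query.shape[0], 1)), X_query])
    inv = np.linalg.inv(A.T @ A)
    return np.array([b @ inv @ b for b in B])
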