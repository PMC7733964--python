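"""Independent reference implementations used to check the package's results.

These deliberately use different code paths from the implementation: explicit
normal-equation regressions, covariance-matrix inversion, and pure-Python
double loops over kernel evaluations.
"""

import math

import numpy as np


def residual_regression_oracle(x, y, Z):
    """Partial correlation via explicit regressions + np.corrcoef."""
    design = np.column_stack([np.ones(len(x)), Z]) if Z.size else np.ones((len(x), 1))
    bx = np.linalg.solve(design.T @ design, design.T @ x)
    by = np.linalg.solve(design.T @ design, design.T @ y)
    return np.corrcoef(x - design @ bx, y - design @ by)[0, 1]


def precision_matrix_oracle(X):
    """rho_ij.rest = -p_ij / sqrt(p_ii * p_jj) from the inverse covariance."""
    P = np.linalg.inv(np.cov(X.T))
    d = np.sqrt(np.diag(P))
    R = -P / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def mmd2_double_loop(A, B, sigma, estimator="biased"):
    """Squared MMD via explicit double loops over kernel evaluations."""

    def k(x, y):
        return math.exp(-float(np.sum((x - y) ** 2)) / (2.0 * sigma**2))

    n, m = len(A), len(B)
    kaa = sum(k(A[i], A[j]) for i in range(n) for j in range(n))
    kbb = sum(k(B[i], B[j]) for i in range(m) for j in range(m))
    kab = sum(k(A[i], B[j]) for i in range(n) for j in range(m))
    if estimator == "biased":
        return kaa / n**2 + kbb / m**2 - 2 * kab / (n * m)
    return (kaa - n) / (n * (n - 1)) + (kbb - m) / (m * (m - 1)) - 2 * kab / (n * m)
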