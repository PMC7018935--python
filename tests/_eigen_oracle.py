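"""Brute-force eigendecomposition oracle, independent of LAPACK's symmetric
eigensolvers: characteristic polynomial by Faddeev–LeVerrier + numpy's
companion-matrix root finder for eigenvalues, shifted inverse iteration for
eigenvectors."""

import numpy as np


def charpoly_eigenvalues(A):
    n = A.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    M = np.zeros_like(A)
    for k in range(1, n + 1):
        M = A @ M + coeffs[k - 1] * np.eye(n)
        coeffs[k] = -np.trace(A @ M) / k
    return np.sort(np.roots(coeffs).real)[::-1]


def inverse_iteration_eigenvector(A, lam, seed=0):
    n = A.shape[0]
    v = np.random.default_rng(seed).normal(size=n)
    B = A - (lam + 1e-9) * np.eye(n)
    for _ in range(50):
        v = np.linalg.solve(B, v)
        v /= np.linalg.norm(v)
    return v
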