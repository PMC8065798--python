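"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: correspondence
coordinates come from symmetric eigendecompositions rather than the
package's SVD, and clustering optima from exhaustive partition
enumeration rather than Lloyd iteration.
"""

import itertools

import numpy as np
import scipy.linalg


def brute_force_ca(A):
    """Eigendecomposition-based CA coordinates of a nonnegative table."""
    A = np.asarray(A, dtype=float)
    P = A / A.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals_c, V = scipy.linalg.eigh(S.T @ S)
    order = np.argsort(evals_c)[::-1]
    evals_c, V = evals_c[order], V[:, order]
    keep = evals_c > 1e-24
    evals_c, V = evals_c[keep], V[:, keep]
    sv = np.sqrt(evals_c)
    G = V * sv / np.sqrt(c)[:, None]
    U = S @ V / sv
    F = U * sv / np.sqrt(r)[:, None]
    return F, G, evals_c


def exhaustive_best_cost(points, k, metric="distance"):
    """Global optimum clustering cost over every surjective assignment."""
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        a = np.asarray(assign)
        centers = np.vstack([points[a == j].mean(axis=0) for j in range(k)])
        d = np.linalg.norm(points - centers[a], axis=1)
        best = min(best, float(np.mean(d if metric == "distance" else d**2)))
    return best


def assert_equal_up_to_sign(A, B, atol=1e-6):
    assert A.shape == B.shape
    for s in range(A.shape[1]):
        a, b = A[:, s], B[:, s]
        assert np.allclose(a, b, atol=atol) or np.allclose(a, -b, atol=atol), f"axis {s}"
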