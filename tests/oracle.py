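"""Independent DEA oracle: dual-vertex enumeration with plain linear algebra.

The CRS input-oriented score of unit *o* equals the optimum of the
multiplier LP

    max  mu . y_o
    s.t. v . x_o = 1
         mu . y_j - v . x_j <= 0   for every unit j
         mu, v >= 0.

On tiny instances that optimum sits at a vertex of the feasible
polyhedron, i.e. at the intersection of the normalisation equality
with (n_in + n_out - 1) further active constraints drawn from the ratio
constraints and the nonnegativity bounds.  Enumerating every such
basis with ``numpy.linalg.solve`` and keeping the best feasible point
is an exhaustive, solver-free check of the LP route.
"""

from itertools import combinations

import numpy as np


def crs_input_score_oracle(X, Y, o, tol=1e-9):
    """Exact CRS input-oriented score of row ``o`` by vertex enumeration."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    H, n_in = X.shape
    n_out = Y.shape[1]
    dim = n_in + n_out  # variables z = (v, mu)

    # constraint rows a.z <= 0 (ratio) and -z_k <= 0 (bounds)
    rows = [np.concatenate([-X[j], Y[j]]) for j in range(H)]
    rows += [-np.eye(dim)[k] for k in range(dim)]
    rows = np.array(rows)
    norm = np.concatenate([X[o], np.zeros(n_out)])  # v.x_o = 1
    obj = np.concatenate([np.zeros(n_in), Y[o]])

    best = -np.inf
    for active in combinations(range(len(rows)), dim - 1):
        A = np.vstack([norm, rows[list(active)]])
        b = np.zeros(dim)
        b[0] = 1.0
        try:
            z = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if (z < -tol).any():
            continue
        if (rows @ z > tol).any():
            continue
        best = max(best, float(obj @ z))
    return best
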