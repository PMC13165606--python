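"""Independent reference implementations used by the graph tests."""

import numpy as np


def brute_force_adjacency(x, k, symmetrize="max"):
    """Loop/sort reference for the cosine Top-K graph (float64)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    xn = np.zeros_like(x)
    for i in range(n):
        nrm = np.sqrt((x[i] ** 2).sum())
        if nrm > 1e-12:
            xn[i] = x[i] / nrm
    s = xn @ xn.T
    a = np.zeros((n, n))
    for i in range(n):
        cands = [(j, s[i, j]) for j in range(n) if j != i and s[i, j] > 0]
        cands.sort(key=lambda t: (-t[1], t[0]))  # ties -> lower column index
        for j, v in cands[:k]:
            a[i, j] = v
    out = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            out[i, j] = (
                max(a[i, j], a[j, i]) if symmetrize == "max" else 0.5 * (a[i, j] + a[j, i])
            )
    return out


def dense_cheb_oracle(x, lap, thetas):
    """Explicit polynomial-in-matrix evaluation of the Chebyshev filter."""
    lt = lap - np.eye(lap.shape[-1])
    terms = [np.eye(lap.shape[-1]), lt]
    while len(terms) < len(thetas):
        terms.append(2 * lt @ terms[-1] - terms[-2])
    return sum((t @ x) @ th for t, th in zip(terms, thetas))
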