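"""Compiled inner loops (numba) for the Gibbs sampler.

Kept free of any package imports so they compile once and cache on disk.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def csr_positions(indptr, indices, rows, cols):
    """Index into a CSR data array for each requested (row, col) entry.

    All requested entries must exist in the pattern (column indices sorted
    within each row).  Returns -1 where an entry is absent.
    """
    out = np.empty(rows.shape[0], dtype=np.int64)
    for k in range(rows.shape[0]):
        r = rows[k]
        c = cols[k]
        lo = indptr[r]
        hi = indptr[r + 1]
        pos = np.searchsorted(indices[lo:hi], c) + lo
        if pos < hi and indices[pos] == c:
            out[k] = pos
        else:
            out[k] = -1
    return out


@njit(cache=True)
def gauss_seidel_sample(indptr, indices, data, rhs, theta, z):
    """One sweep of single-site Gibbs draws over all equations.

    For equation j with coefficient row C_j and diagonal c_jj, the full
    conditional of theta_j is N((rhs_j - C_{j,-j} theta_{-j}) / c_jj,
    1 / c_jj); ``z`` supplies one standard normal per equation.
    """
    n = theta.shape[0]
    for j in range(n):
        s = 0.0
        cjj = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            col = indices[k]
            if col == j:
                cjj = data[k]
            else:
                s += data[k] * theta[col]
        mean = (rhs[j] - s) / cjj
        theta[j] = mean + z[j] / np.sqrt(cjj)


@njit(cache=True)
def quad_form_csr(indptr, indices, data, U):
    """U' K U for CSR K and dense (n x c) U; returns (c x c)."""
    n, c = U.shape
    out = np.zeros((c, c))
    for i in range(n):
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            v = data[k]
            for a in range(c):
                uia = U[i, a]
                for b in range(c):
                    out[a, b] += v * uia * U[j, b]
    return out
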