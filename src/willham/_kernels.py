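"""Compiled single-site Gauss–Seidel sweep for the location effects.

The sweep visits every scalar location equation (fixed effects, direct and
maternal breeding values, permanent-environment effects) in a fixed order and
draws each from its univariate normal full conditional given everything else.
Residuals are kept current incrementally, so one sweep costs O(nnz(design) +
nnz(A^-1) * dim(G)) regardless of chain length.

The caller supplies one standard-normal deviate per equation (``z``), drawn
from the package's single seeded generator, so the kernel itself holds no
random state.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def location_sweep(
    theta, e, z, Rinv, Ginv, Pinv,
    eq_trait, indptr, rec_idx, wt,
    geq_start, n_ped, ai_indptr, ai_indices, ai_data,
    peq_start, n_dam,
):
    """One Gauss–Seidel sampling sweep over all location equations.

    Returns -1 on success, or the index of an equation whose conditional
    precision was not positive (aliasing missed upstream).
    """
    n_eq = theta.shape[0]
    n_traits = Rinv.shape[0]
    dimG = Ginv.shape[0]
    dimP = Pinv.shape[0]

    for k in range(n_eq):
        t = eq_trait[k]
        lhs_data = 0.0
        rhs = 0.0
        for p in range(indptr[k], indptr[k + 1]):
            r = rec_idx[p]
            w = wt[p]
            s = 0.0
            for tt in range(n_traits):
                s += Rinv[t, tt] * e[r, tt]
            rhs += w * s
            lhs_data += w * w * Rinv[t, t]
        old = theta[k]
        rhs += lhs_data * old  # add back this effect's own data contribution
        lhs = lhs_data

        if geq_start <= k < peq_start and dimG > 0:
            off = k - geq_start
            u = off // n_ped
            i = off - u * n_ped
            for p in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[p]
                aij = ai_data[p]
                for v in range(dimG):
                    if v == u and j == i:
                        lhs += Ginv[u, u] * aij
                    else:
                        rhs -= Ginv[u, v] * aij * theta[geq_start + v * n_ped + j]
        elif k >= peq_start and dimP > 0:
            off = k - peq_start
            w_dim = off // n_dam
            l = off - w_dim * n_dam
            lhs += Pinv[w_dim, w_dim]
            for v in range(dimP):
                if v != w_dim:
                    rhs -= Pinv[w_dim, v] * theta[peq_start + v * n_dam + l]

        if lhs <= 0.0:
            return k
        new = rhs / lhs + z[k] / np.sqrt(lhs)
        d = new - old
        theta[k] = new
        for p in range(indptr[k], indptr[k + 1]):
            e[rec_idx[p], t] -= wt[p] * d
    return -1
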