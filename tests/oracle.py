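"""Independent dummy-variable least-squares contrast oracle.

Fits each SNP pair with an explicit one-hot design matrix and generic
linear-algebra routines (lstsq + pseudo-inverse), deliberately sharing no
code path with the package's cell-means sufficient-statistics engine.
"""

import numpy as np
from scipy import stats

W_A = np.array([-1.0, 0.0, 1.0])
W_D = np.array([-0.5, 1.0, -0.5])
_W = {"A": W_A, "D": W_D}


def contrast_vector(effect_type):
    return np.outer(_W[effect_type[0]], _W[effect_type[1]]).ravel()


def ls_fit(y, g1, g2):
    """One-hot least squares of y on the occupied two-locus cells."""
    y = np.asarray(y, float)
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    valid = (g1 >= 0) & (g2 >= 0)
    y, g1, g2 = y[valid], g1[valid], g2[valid]
    cells = 3 * g1.astype(int) + g2
    occupied = np.unique(cells)
    X = (cells[:, None] == occupied[None, :]).astype(float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    df = n - k
    v2 = float(resid @ resid) / df if df > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    return beta, xtx_inv, v2, df, occupied


def ls_contrast(y, g1, g2, effect_type):
    """(L, var_L, t, p, df) for one contrast, or None if non-estimable."""
    beta, xtx_inv, v2, df, occupied = ls_fit(y, g1, g2)
    if df < 1:
        return None
    s = contrast_vector(effect_type)
    if set(np.flatnonzero(s != 0)) - set(occupied):
        return None
    s_occ = s[occupied]
    L = float(s_occ @ beta)
    var_L = float(v2 * s_occ @ xtx_inv @ s_occ)
    if var_L <= 0:
        return None
    t = abs(L) / np.sqrt(var_L)
    p = min(2.0 * float(stats.t.sf(t, df)), 1.0)
    return L, var_L, float(t), p, df


def random_instance(rng, n=60, maf_range=(0.1, 0.5)):
    """Random genotype pair + phenotype with all contrasts likely estimable."""
    f1, f2 = rng.uniform(*maf_range, size=2)
    g1 = rng.binomial(2, f1, size=n).astype(np.int8)
    g2 = rng.binomial(2, f2, size=n).astype(np.int8)
    y = rng.standard_normal(n) + 0.3 * g1 * g2
    return y, g1, g2
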