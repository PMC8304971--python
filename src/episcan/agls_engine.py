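"""Approximate-GLS epistasis contrast tests for one SNP pair.

The procedure tests, for every SNP pair, the four orthogonal interaction
components of the two-locus genotypic-value surface:

* additive x additive (AA),
* additive x dominance (AD),
* dominance x additive (DA),
* dominance x dominance (DD).

The polygenic background is removed approximately before any pair is
fitted: the working phenotype is ``y_adj = y - 2*PTA``, where PTA (predicted
transmitting ability, half the estimated breeding value) comes from routine
genetic evaluation.  Subtracting twice the PTA approximates the mixed-model
polygenic correction without ever forming or inverting the phenotypic
covariance matrix, which is what makes an all-pairs scan feasible.

Each pair is then fitted by ordinary least squares in the *cell-means*
parameterization: the up-to-nine two-locus genotype classes (0/1/2 copies of
the counted allele at each SNP) each get their own mean.  For cell means,
``X'X`` is diagonal (the cell counts), the estimates are the per-cell sample
means, and the residual variance is ``v2 = RSS / (n - k)`` with ``k`` the
number of occupied cells.  An interaction component ``j`` is tested by a
linear contrast of the cell means,

    L_j = s_j' ghat,      var(L_j) = v2 * s_j' (X'X)^- s_j,
    t_j = |L_j| / sqrt(var(L_j)),

with ``s_j`` the outer product of an additive contrast ``w_a = (-1, 0, 1)``
and/or a dominance contrast ``w_d = (-1/2, 1, -1/2)`` at the two loci, and a
two-sided Student-t tail probability on ``n - k`` degrees of freedom.  A
contrast is *estimable* only when every cell it weights is occupied.

For extremely significant pairs the two-sided p-value underflows double
precision (p < 1e-308).  On that branch the significance score log10(1/p)
is continued by the empirical power law ``0.2416 * t**1.9713`` (floored at
308 so the score never decreases across the switch); see
:func:`extreme_log10p`.

The module is pure computation: scalar entry points (:func:`fit_pair`,
:func:`test_contrast`) mirror the definitions above one pair at a time, and
the ``*_block`` kernels evaluate many pairs at once from the same sufficient
statistics for the genome-wide scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import TraitRecords

EFFECT_TYPES = ("AA", "AD", "DA", "DD")

#: Additive contrast over 0/1/2 copies of the counted allele.
W_ADDITIVE = np.array([-1.0, 0.0, 1.0])
#: Dominance (heterozygote-deviation) contrast over 0/1/2 copies.
W_DOMINANCE = np.array([-0.5, 1.0, -0.5])

_W = {"A": W_ADDITIVE, "D": W_DOMINANCE}

#: Smallest two-sided p treated as representable; below it the empirical
#: power-law continuation of log10(1/p) takes over.
UNDERFLOW_P = 1e-308
UNDERFLOW_LOG10 = 308.0
EXTREME_P_COEF = 0.2416
EXTREME_P_EXPONENT = 1.9713


class DegenerateFitError(ValueError):
    """Raised when a pair has no residual degrees of freedom (n_used <= k)."""


@dataclass
class AdjustedTrait:
    """Phenotype after the approximate polygenic correction y - 2*PTA."""

    individual_ids: list[str]
    y_adj: np.ndarray


def adjust_phenotype(records: TraitRecords) -> AdjustedTrait:
    """Subtract twice the predicted transmitting ability from the phenotype.

    2*PTA estimates the individual's additive polygenic value, so the
    adjusted phenotype carries (approximately) only non-additive genetic
    signal plus residual -- the quantity the pairwise interaction tests
    operate on.
    """
    records.validate()
    y_adj = np.asarray(records.y, dtype=float) - 2.0 * np.asarray(records.pta, dtype=float)
    if not np.all(np.isfinite(y_adj)):
        raise ValueError("non-finite adjusted phenotype")
    return AdjustedTrait(individual_ids=list(records.individual_ids), y_adj=y_adj)


def contrast_coefficients(effect_type: str) -> np.ndarray:
    """Nine-cell contrast vector for one interaction component.

    Cells are ordered row-major over (copies at SNP1, copies at SNP2).
    The vector is the outer product of the per-locus contrasts: e.g. "AD"
    uses the additive contrast at SNP1 and the dominance contrast at SNP2.
    Every vector sums to zero.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {effect_type!r}; expected one of {EFFECT_TYPES}")
    w1, w2 = _W[effect_type[0]], _W[effect_type[1]]
    return np.outer(w1, w2).ravel()


@dataclass
class PairFit:
    """Cell-means least-squares fit of one SNP pair.

    ``ghat`` and ``xtx_inv_gg`` cover occupied cells only (row-major cell
    order); for a cell-means fit ghat equals the per-cell sample means and
    (X'X)^- is diagonal with entries 1/cell_count.
    """

    cell_counts: np.ndarray     # (3,3) int64
    cell_means: np.ndarray      # (3,3) float, NaN where count==0
    ghat: np.ndarray            # (k,) occupied-cell means
    xtx_inv_gg: np.ndarray      # (k,) 1/count per occupied cell
    v2: float                   # residual variance estimate
    df: int                     # n_used - k
    n_used: int
    occupied: np.ndarray        # (9,) bool, row-major


@dataclass
class ContrastResult:
    """One interaction component's contrast test for one pair."""

    effect_type: str
    s: np.ndarray
    L: float
    var_L: float
    t: float
    p: float
    log10_inv_p: float
    estimable: bool


def _cell_stats(y: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    """Counts, y-sums and y^2-sums per two-locus cell (pairwise complete case)."""
    valid = (g1 >= 0) & (g2 >= 0)
    cells = np.where(valid, 3 * g1.astype(np.int64) + g2, 9)
    counts = np.bincount(cells, minlength=10)[:9]
    ysum = np.bincount(cells, weights=y, minlength=10)[:9]
    ysq = np.bincount(cells, weights=y * y, minlength=10)[:9]
    return counts, ysum, ysq


def fit_pair(y_adj, g1, g2) -> PairFit:
    """Cell-means least squares of the adjusted phenotype on one SNP pair.

    Individuals missing either genotype are excluded (pairwise complete
    case).  Raises :class:`DegenerateFitError` if no residual degrees of
    freedom remain.
    """
    y = y_adj.y_adj if isinstance(y_adj, AdjustedTrait) else np.asarray(y_adj, float)
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    counts, ysum, ysq = _cell_stats(y, g1, g2)
    occupied = counts > 0
    k = int(occupied.sum())
    n_used = int(counts.sum())
    df = n_used - k
    if df < 1:
        raise DegenerateFitError(f"n_used={n_used} <= k={k} occupied cells")
    means9 = np.full(9, np.nan)
    means9[occupied] = ysum[occupied] / counts[occupied]
    rss = float(ysq.sum() - (ysum[occupied] ** 2 / counts[occupied]).sum())
    v2 = max(rss, 0.0) / df
    return PairFit(
        cell_counts=counts.reshape(3, 3),
        cell_means=means9.reshape(3, 3),
        ghat=means9[occupied],
        xtx_inv_gg=1.0 / counts[occupied],
        v2=v2,
        df=df,
        n_used=n_used,
        occupied=occupied,
    )


def test_contrast(fit: PairFit, effect_type: str) -> ContrastResult:
    """t-test of one epistasis contrast against a cell-means fit.

    Non-estimable results (an empty weighted cell, or zero contrast
    variance) carry ``estimable=False`` and NaN statistics rather than
    raising.
    """
    s = contrast_coefficients(effect_type)
    nz = s != 0.0
    if not fit.occupied[nz].all():
        return ContrastResult(effect_type, s, np.nan, np.nan, np.nan,
                              np.nan, np.nan, estimable=False)
    s_occ = s[fit.occupied]
    L = float(s_occ @ fit.ghat)
    var_L = float(fit.v2 * (s_occ * s_occ) @ fit.xtx_inv_gg)
    if var_L <= 0.0:
        return ContrastResult(effect_type, s, L, var_L, np.nan,
                              np.nan, np.nan, estimable=False)
    t = abs(L) / np.sqrt(var_L)
    p = min(float(2.0 * stats.t.sf(t, fit.df)), 1.0)
    return ContrastResult(effect_type, s, L, var_L, float(t), p,
                          float(extreme_log10p(t, fit.df)), estimable=True)


# not a pytest test despite the field-conventional name
test_contrast.__test__ = False


def extreme_log10p(t, df):
    """log10(1/p) of the two-sided t-test, continued past double underflow.

    While the two-sided p is representable (>= 1e-308) this is exactly
    -log10(p).  Beyond that the score follows the empirical power law
    ``0.2416 * t**1.9713``, floored at 308 (the representability bound) so
    the score is monotone nondecreasing in t across the switch.  At the
    switch point for large df the two branches agree to well under 2%.

    Accepts scalars or arrays; vectorized over both ``t`` and ``df``.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    p = 2.0 * stats.t.sf(t_arr, df)
    p = np.minimum(p, 1.0)
    out = np.empty_like(t_arr)
    rep = p >= UNDERFLOW_P
    with np.errstate(divide="ignore"):
        out[rep] = -np.log10(p[rep])
    out[~rep] = np.maximum(
        UNDERFLOW_LOG10, EXTREME_P_COEF * t_arr[~rep] ** EXTREME_P_EXPONENT)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Block kernels for the genome-wide scan
# ---------------------------------------------------------------------------

def pair_block_stats(g_left: np.ndarray, g_right: np.ndarray, y: np.ndarray):
    """Sufficient statistics for the pairs (g_left, g_right[:, j]) for all j.

    Parameters
    ----------
    g_left : (n,) int genotype column (0/1/2, -1 missing)
    g_right : (n, m) int genotype block
    y : (n,) adjusted phenotype

    Returns
    -------
    counts, ysum, ysq : (m, 9) arrays of per-cell counts, y-sums, y^2-sums,
    computed pairwise complete-case (either genotype missing drops the
    individual for that pair only).
    """
    n, m = g_right.shape
    valid = (g_left[:, None] >= 0) & (g_right >= 0)
    cells = np.where(valid, 3 * g_left[:, None].astype(np.int64) + g_right, 9)
    cells += np.arange(m, dtype=np.int64) * 10
    flat = cells.ravel()
    counts = np.bincount(flat, minlength=10 * m).reshape(m, 10)[:, :9]
    yb = np.broadcast_to(y[:, None], (n, m)).ravel()
    ysum = np.bincount(flat, weights=yb, minlength=10 * m).reshape(m, 10)[:, :9]
    ysq = np.bincount(flat, weights=yb * np.broadcast_to(y[:, None], (n, m)).ravel(),
                      minlength=10 * m).reshape(m, 10)[:, :9]
    return counts, ysum, ysq


def contrast_tests_block(counts: np.ndarray, ysum: np.ndarray, ysq: np.ndarray):
    """All four epistasis contrast tests for a block of pairs.

    Vectorized mirror of :func:`fit_pair` + :func:`test_contrast`.

    Returns a dict with (m,) ``df``, ``degenerate`` and (m, 4) arrays
    ``L``, ``t``, ``p``, ``log10_inv_p``, ``estimable`` in
    :data:`EFFECT_TYPES` order.
    """
    m = counts.shape[0]
    occ = counts > 0
    k = occ.sum(axis=1)
    n_used = counts.sum(axis=1)
    df = n_used - k
    degenerate = df < 1
    safe_counts = np.where(occ, counts, 1)
    means = np.where(occ, ysum / safe_counts, 0.0)
    rss = ysq.sum(axis=1) - np.where(occ, ysum * ysum / safe_counts, 0.0).sum(axis=1)
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v2 = np.where(degenerate, np.nan, rss / np.maximum(df, 1))

    L = np.empty((m, 4))
    tstat = np.full((m, 4), np.nan)
    pval = np.full((m, 4), np.nan)
    log10p = np.full((m, 4), np.nan)
    estim = np.zeros((m, 4), dtype=bool)
    for j, et in enumerate(EFFECT_TYPES):
        s = contrast_coefficients(et)
        nz = s != 0.0
        ok = occ[:, nz].all(axis=1) & ~degenerate
        Lj = means @ s
        varj = v2 * ((s * s)[None, :] / safe_counts * occ).sum(axis=1)
        ok &= varj > 0.0
        L[:, j] = Lj
        if ok.any():
            tj = np.abs(Lj[ok]) / np.sqrt(varj[ok])
            tstat[ok, j] = tj
            pj = np.minimum(2.0 * stats.t.sf(tj, df[ok]), 1.0)
            pval[ok, j] = pj
            log10p[ok, j] = extreme_log10p(tj, df[ok])
        estim[:, j] = ok
    return {"df": df, "degenerate": degenerate, "L": L, "t": tstat,
            "p": pval, "log10_inv_p": log10p, "estimable": estim}
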