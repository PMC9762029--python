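"""Differential-expression statistics.

The core test is a two-part ("hurdle") comparison in the spirit of MAST:
single-cell expression is modelled as a detection component (is the gene
observed at all in a cell?) and a continuous component (how high is it,
given detection). The two parts are tested separately — a G-test
(likelihood-ratio) on the 2x2 detection table and a Welch t-test on the
positive values — and combined additively on the deviance scale, with the
degrees of freedom adapting to how many parts the data can support.

Fold changes follow the Seurat convention: log2 of pseudocounted means of
``expm1`` of log-normalized values, so a reported log2FC of 1 means the
(back-transformed) mean expression roughly doubles.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import xlogy
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "fold_change",
    "hurdle_test",
    "paired_signed_rank",
    "bh_adjust",
    "group_summaries",
    "hurdle_test_arrays",
    "fold_change_arrays",
]

_TINY_P = 1e-300


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def fold_change(xa, xb) -> float:
    """Seurat-style log2 fold change between two groups of lognorm values.

    ``log2(mean(expm1(xa)) + 1) - log2(mean(expm1(xb)) + 1)``. Antisymmetric
    in its arguments.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("fold_change requires two nonempty groups")
    return float(
        np.log2(np.mean(np.expm1(xa)) + 1.0) - np.log2(np.mean(np.expm1(xb)) + 1.0)
    )


# ---------------------------------------------------------------------------
# hurdle test
# ---------------------------------------------------------------------------

def _g_statistic(ka, na, kb, nb):
    """G (likelihood-ratio) statistic for the 2x2 table of detection x group.

    Vectorized over leading dimensions of ``ka``/``kb``. Cells with zero
    observed count contribute zero via the x*log(x) limit.
    """
    ka = np.asarray(ka, dtype=float)
    kb = np.asarray(kb, dtype=float)
    n = na + nb
    k = ka + kb
    # expected counts under independence
    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (
            xlogy(ka, ka) + xlogy(kb, kb)
            + xlogy(na - ka, na - ka) + xlogy(nb - kb, nb - kb)
            + xlogy(n, n)
            - xlogy(k, k) - xlogy(n - k, n - k)
            - xlogy(na, na) - xlogy(nb, nb)
        )
    return np.maximum(g, 0.0)


def _welch_p(ma, va, ka, mb, vb, kb):
    """Two-sided Welch t-test p from summary statistics (vectorized).

    Entries where either count is < 2 are returned as NaN (part unavailable).
    Zero-variance cases: p=1 if the means agree, else effectively 0.
    """
    ma, va, ka = (np.asarray(v, dtype=float) for v in (ma, va, ka))
    mb, vb, kb = (np.asarray(v, dtype=float) for v in (mb, vb, kb))
    ok = (ka >= 2) & (kb >= 2)
    p = np.full(np.broadcast(ma, mb).shape, np.nan)
    if not np.any(ok):
        return p
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / ka + vb / kb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / ka) ** 2 / np.maximum(ka - 1, 1)
            + (vb / kb) ** 2 / np.maximum(kb - 1, 1)
        )
        pt = 2.0 * t_dist.sf(np.abs(t), np.maximum(df, 1.0))
    zero_var = ok & (se2 == 0)  # t is inf/nan there
    pt = np.where(zero_var & (ma == mb), 1.0, pt)
    pt = np.where(zero_var & (ma != mb), _TINY_P, pt)
    p[ok] = pt[ok]
    return p


def hurdle_test_arrays(ka, na, kb, nb, ma, va, mb, vb):
    """Combined hurdle p-values from per-group summary statistics.

    Parameters are vectorized: detection counts ``ka``/``kb`` out of group
    sizes ``na``/``nb`` and mean/variance of the *positive* values per group.
    Parts are combined as a sum of 1-df deviances against a chi-square with
    df equal to the number of parts the data support; with no usable part
    (e.g. both groups all zero) the p-value is 1.
    """
    ka = np.asarray(ka, dtype=float)
    kb = np.asarray(kb, dtype=float)
    shape = np.broadcast(ka, kb).shape
    stat = np.zeros(shape)
    parts = np.zeros(shape, dtype=int)

    k = ka + kb
    n = na + nb
    # Detection part is degenerate when the indicator is constant or the
    # 2x2 table is too sparse for the chi-square reference (Cochran-style
    # rule: smallest expected cell count >= 1).
    min_expected = np.minimum(k, n - k) * np.minimum(na, nb) / n
    det_ok = (k > 0) & (k < n) & (min_expected >= 1.0)
    g = _g_statistic(ka, na, kb, nb)
    stat += np.where(det_ok, g, 0.0)
    parts += det_ok.astype(int)

    p_cont = _welch_p(ma, va, ka, mb, vb, kb)
    cont_ok = np.isfinite(p_cont)
    z = norm.isf(np.clip(np.where(cont_ok, p_cont, 1.0), _TINY_P, 1.0) / 2.0)
    stat += np.where(cont_ok, z * z, 0.0)
    parts += cont_ok.astype(int)

    p = np.ones(shape)
    use = parts > 0
    p[use] = chi2.sf(stat[use], parts[use])
    return p


def hurdle_test(xa, xb) -> float:
    """Two-part hurdle test p-value for one gene, two groups of lognorm values."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("hurdle_test requires two nonempty groups")
    pa, pb = xa[xa > 0], xb[xb > 0]
    ma = pa.mean() if pa.size else 0.0
    mb = pb.mean() if pb.size else 0.0
    va = pa.var(ddof=1) if pa.size >= 2 else 0.0
    vb = pb.var(ddof=1) if pb.size >= 2 else 0.0
    return float(
        hurdle_test_arrays(
            pa.size, xa.size, pb.size, xb.size, ma, va, mb, vb
        )
    )


# ---------------------------------------------------------------------------
# matrix drivers (genes x cells sparse input)
# ---------------------------------------------------------------------------

def group_summaries(X, mask):
    """Per-gene summaries over the cells selected by ``mask``.

    ``X`` is a genes x cells sparse matrix of lognorm values. Returns
    ``(k, n, mean_pos, var_pos, mean_expm1)``: detection count, group size,
    mean and variance of positive values, and mean of expm1 (for fold
    changes), each a vector over genes.
    """
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    sub = X[:, np.asarray(mask)].tocsr()
    n = sub.shape[1]
    k = np.diff(sub.indptr).astype(float)
    # positive-value moments; data of a lognorm layer are all > 0
    s1 = np.asarray(sub.sum(axis=1)).ravel()
    sq = sub.copy()
    sq.data = sq.data**2
    s2 = np.asarray(sq.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pos = np.where(k > 0, s1 / np.maximum(k, 1), 0.0)
        var_pos = np.where(
            k >= 2, (s2 - np.maximum(k, 1) * mean_pos**2) / np.maximum(k - 1, 1), 0.0
        )
    var_pos = np.maximum(var_pos, 0.0)
    e = sub.copy()
    e.data = np.expm1(e.data)
    mean_expm1 = np.asarray(e.sum(axis=1)).ravel() / max(n, 1)
    return k, n, mean_pos, var_pos, mean_expm1


def fold_change_arrays(mean_expm1_a, mean_expm1_b):
    """Vectorized Seurat-convention log2FC from per-group expm1 means."""
    return np.log2(np.asarray(mean_expm1_a) + 1.0) - np.log2(
        np.asarray(mean_expm1_b) + 1.0
    )


# ---------------------------------------------------------------------------
# paired signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks, w):
    # Exact null distribution of W+ over all sign assignments, by dynamic
    # programming over doubled (mid)ranks so ties stay integral.
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2.0 * w))
    cdf_lo = dist[: w2 + 1].sum()
    cdf_hi = dist[w2:].sum()
    return min(1.0, 2.0 * min(cdf_lo, cdf_hi))


def paired_signed_rank(x, y, exact_limit: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped. With at most ``exact_limit`` nonzero
    differences the null distribution is enumerated exactly (ties handled
    through midranks); beyond that a normal approximation with tie
    correction is used. All differences zero returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_signed_rank requires equal-length vectors")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w = float(r[d > 0].sum())
    if d.size <= exact_limit:
        return _exact_signed_rank_p(r, w)
    mean = r.sum() / 2.0
    var = float((r**2).sum()) / 4.0  # midranks absorb the tie correction
    z = (w - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values):
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
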