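"""Weir & Cockerham (1984) F_ST for haplotype data, and LSBL.

Two-population variance-components estimator on haploid samples: per site
the among-population component ``a`` and within-population component ``b``
are accumulated and the window estimate is the ratio of sums
``sum(a) / sum(a + b)`` (ratio of averages).  Negative estimates are
reported as computed, never clamped.

The locus-specific branch length (LSBL) decomposes the three pairwise
distances of a population trio into per-population branch lengths,
identifying which population drives the differentiation at a locus.
"""

from __future__ import annotations

import numpy as np

NAN = float("nan")


def wc_components(d1, n1, d2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site WC84 components (a, b) for two haploid samples.

    ``d?`` are derived (or alternate) allele counts, ``n?`` the per-site
    effective sample sizes.  Sites with either n < 2 yield (0, 0).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = d1 / n1
        p2 = d2 / n2
        r = 2.0
        nbar = (n1 + n2) / r
        pbar = (d1 + d2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * inner
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(a) | ~np.isfinite(b)
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    return a, b


def fst_window(counts_a, counts_b) -> float:
    """Window F_ST from per-site (derived count, n) pairs of two populations.

    ``counts_?`` are (d, n) arrays over the same sites.  Only sites
    polymorphic in the pooled sample contribute; with none, or a
    non-positive denominator, NaN is returned.
    """
    d1, n1 = (np.asarray(x) for x in counts_a)
    d2, n2 = (np.asarray(x) for x in counts_b)
    pooled = d1 + d2
    poly = (pooled > 0) & (pooled < n1 + n2) & (n1 >= 2) & (n2 >= 2)
    if not np.any(poly):
        return NAN
    a, b = wc_components(d1[poly], n1[poly], d2[poly], n2[poly])
    denom = float(np.sum(a + b))
    if denom <= 0:
        return NAN
    return float(np.sum(a) / denom)


def lsbl(d_ab: float, d_ac: float, d_bc: float) -> tuple[float, float, float]:
    """Branch lengths (A, B, C) from the three pairwise distances of a trio.

    lsbl_A = (d_AB + d_AC - d_BC) / 2 and cyclic permutations; the identity
    lsbl_A + lsbl_B = d_AB holds exactly.  Any non-finite input yields all
    NaN.
    """
    vals = (d_ab, d_ac, d_bc)
    if not all(np.isfinite(v) for v in vals):
        return NAN, NAN, NAN
    la = (d_ab + d_ac - d_bc) / 2.0
    lb = (d_ab + d_bc - d_ac) / 2.0
    lc = (d_ac + d_bc - d_ab) / 2.0
    return la, lb, lc
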