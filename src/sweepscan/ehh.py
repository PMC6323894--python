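"""Extended haplotype homozygosity: EHH curves, iHH, iHS and XP-EHH.

EHH at a distance x from a core site is the probability that two randomly
chosen haplotypes carrying the core allele are identical over the whole
stretch from the core out to x:  EHH = sum_h C(c_h, 2) / C(c, 2) over the
distinct extended haplotypes h among the c carriers.  iHH is the trapezoidal
integral of the EHH curve over genetic distance, summed over both sides and
truncated once EHH decays to the cutoff (default 0.05).  A long, slowly
decaying curve around a core allele is the footprint of a recent sweep.

iHS is the log-ratio ln(iHH_ancestral / iHH_derived) at each core SNP,
standardized to mean 0 / sd 1 within derived-allele-frequency bins; XP-EHH
compares the same quantity between two populations (all chromosomes pooled
per population, truncation extent set by the pooled-sample EHH) and is
standardized genome-wide.

Integration stops across inter-SNP gaps larger than ``max_gap_bp``
(default 200 kb) to guard against assembly gaps; when no genetic map is
given, physical distance at 1 cM/Mb is used.

Two implementations coexist: :func:`ehh_curve` is a plain-Python reference
that materialises the whole curve, while the per-site scans (iHS, XP-EHH)
run a compiled kernel that refines the haplotype partition site by site,
dropping singleton groups as it goes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .panel import HaplotypePanel

TRUNCATION = 0.05
MAX_GAP_BP = 200_000


@dataclass
class EHHCurve:
    side: str                   # 'left' or 'right'
    distances: np.ndarray       # cM from core, non-negative increasing
    distances_bp: np.ndarray
    ehh: np.ndarray             # starts at 1, non-increasing


def _carriers(panel: HaplotypePanel, core_site: int, allele_class: str) -> np.ndarray:
    der = panel.derived_alleles()[:, core_site]
    if allele_class == "derived":
        return np.nonzero(der == 1)[0]
    if allele_class == "ancestral":
        return np.nonzero(der == 0)[0]
    if allele_class == "all":
        return np.nonzero(der >= 0)[0]
    raise ValueError(f"unknown allele class {allele_class!r}")


# ---------------------------------------------------------------------------
# reference implementation (full curves)
# ---------------------------------------------------------------------------

def ehh_curve(panel: HaplotypePanel, core_site: int,
              allele_class: str = "derived", side: str = "right",
              max_gap_bp: int | None = None) -> EHHCurve:
    """EHH decay curve of one allele class on one side of a core SNP.

    The curve starts at (0, 1) and is evaluated at each successive site,
    out to the chromosome end or until EHH reaches 0 (beyond which it
    stays 0).  Haplotypes with a missing allele at a site drop out of
    their group from that site onward; the denominator stays C(c, 2) of
    the original carriers.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    carriers = _carriers(panel, core_site, allele_class)
    c = len(carriers)
    if c < 2:
        raise ValueError("core site has fewer than 2 carriers of that class")
    der = panel.derived_alleles()
    pos, gpos = panel.positions, panel.gpos()
    denom = c * (c - 1)
    groups = [carriers]
    pts = [(0.0, 0, 1.0)]
    step = 1 if side == "right" else -1
    j = core_site + step
    p_prev = pos[core_site]
    while 0 <= j < panel.n_sites:
        if max_gap_bp is not None and abs(int(pos[j]) - int(p_prev)) > max_gap_bp:
            break
        new_groups, num = [], 0
        for g in groups:
            a = der[g, j]
            for val in (0, 1):
                sub = g[a == val]
                if len(sub) >= 2:
                    new_groups.append(sub)
                    num += len(sub) * (len(sub) - 1)
        groups = new_groups
        e = num / denom
        pts.append((abs(float(gpos[j]) - float(gpos[core_site])),
                    abs(int(pos[j]) - int(pos[core_site])), e))
        if e == 0.0:
            break
        p_prev = pos[j]
        j += step
    d, dbp, e = (np.asarray(x) for x in zip(*pts))
    return EHHCurve(side=side, distances=d.astype(float),
                    distances_bp=dbp.astype(np.int64), ehh=e.astype(float))


def ihh(curve: EHHCurve, truncation: float = TRUNCATION,
        max_gap_bp: int | None = MAX_GAP_BP) -> float:
    """Truncated trapezoidal integral of an EHH curve over genetic distance.

    Integration stops at the first point whose EHH is <= ``truncation``
    (that segment excluded) or across a physical gap > ``max_gap_bp``.
    """
    total = 0.0
    for k in range(1, len(curve.ehh)):
        if max_gap_bp is not None and \
                curve.distances_bp[k] - curve.distances_bp[k - 1] > max_gap_bp:
            break
        if curve.ehh[k] <= truncation:
            break
        total += 0.5 * (curve.ehh[k - 1] + curve.ehh[k]) * \
            (curve.distances[k] - curve.distances[k - 1])
    return float(total)


# ---------------------------------------------------------------------------
# compiled per-core walk (partition refinement, singleton dropping)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _walk_ihh(der, carriers, core, step, gpos, pos, stop_trunc, max_gap,
              limit):  # pragma: no cover - exercised via wrappers
    """Integrate EHH outward from ``core`` in direction ``step`` (+1/-1).

    ``stop_trunc`` < 0 disables truncation; ``max_gap`` <= 0 disables the
    gap rule; ``limit`` >= 0 bounds the walk at that site index
    (inclusive).  Returns (ihh, index of the last integrated site).
    """
    c0 = carriers.shape[0]
    denom = c0 * (c0 - 1)
    order = carriers.copy()
    gid = np.zeros(c0, dtype=np.int64)
    scratch_o = np.empty(c0, dtype=np.int64)
    scratch_g = np.empty(c0, dtype=np.int64)
    active = c0
    ehh_prev = 1.0
    d_prev = 0.0
    p_prev = pos[core]
    total = 0.0
    end = core
    n_sites = der.shape[1]
    j = core + step
    while 0 <= j < n_sites:
        if limit >= 0 and (j - limit) * step > 0:
            break
        gap = pos[j] - p_prev
        if gap < 0:
            gap = -gap
        if max_gap > 0 and gap > max_gap:
            break
        # stable partition refinement of column j over the active groups
        num = 0
        w = 0
        g_new = 0
        i = 0
        while i < active:
            k = i
            g = gid[i]
            while k < active and gid[k] == g:
                k += 1
            z = 0
            o = 0
            for t in range(i, k):
                a = der[order[t], j]
                if a == 0:
                    z += 1
                elif a == 1:
                    o += 1
            if z >= 2:
                for t in range(i, k):
                    if der[order[t], j] == 0:
                        scratch_o[w] = order[t]
                        scratch_g[w] = g_new
                        w += 1
                g_new += 1
                num += z * (z - 1)
            if o >= 2:
                for t in range(i, k):
                    if der[order[t], j] == 1:
                        scratch_o[w] = order[t]
                        scratch_g[w] = g_new
                        w += 1
                g_new += 1
                num += o * (o - 1)
            i = k
        for t in range(w):
            order[t] = scratch_o[t]
            gid[t] = scratch_g[t]
        active = w
        e = num / denom
        if stop_trunc >= 0.0 and e <= stop_trunc:
            break
        d = gpos[j] - gpos[core]
        if d < 0:
            d = -d
        total += 0.5 * (ehh_prev + e) * (d - d_prev)
        end = j
        ehh_prev = e
        d_prev = d
        p_prev = pos[j]
        if e == 0.0:
            break
        j += step
    return total, end


def _ihh_fast(der: np.ndarray, carriers: np.ndarray, core: int, side: str,
              gpos: np.ndarray, pos: np.ndarray,
              stop_trunc: float | None, max_gap_bp: int | None,
              limit: int | None = None) -> tuple[float, int]:
    return _walk_ihh(
        np.ascontiguousarray(der, dtype=np.int8),
        np.asarray(carriers, dtype=np.int64),
        int(core), 1 if side == "right" else -1,
        np.asarray(gpos, dtype=np.float64),
        np.asarray(pos, dtype=np.int64),
        -1.0 if stop_trunc is None else float(stop_trunc),
        -1 if max_gap_bp is None else int(max_gap_bp),
        -1 if limit is None else int(limit))


def _ihh_both_sides(der, carriers, core, pos, gpos, truncation, max_gap_bp):
    total = 0.0
    for side in ("left", "right"):
        s, _ = _ihh_fast(der, carriers, core, side, gpos, pos,
                         truncation, max_gap_bp)
        total += s
    return total


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def _standardize_binned(raw: np.ndarray, daf: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean-0 / sd-1 standardization within equal-width daf bins."""
    out = np.full_like(raw, np.nan)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(daf, edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        sel = (idx == b) & np.isfinite(raw)
        if sel.sum() >= 2:
            vals = raw[sel]
            sd = vals.std()
            if sd > 0:
                out[sel] = (vals - vals.mean()) / sd
    return out


def ihs_scores(panel: HaplotypePanel, maf_min: float = 0.05, n_bins: int = 20,
               truncation: float = TRUNCATION, max_gap_bp: int = MAX_GAP_BP,
               standardize: bool = True) -> np.ndarray:
    """Per-site iHS, aligned to the panel's sites (NaN where undefined).

    raw iHS = ln(iHH_A / iHH_D) at polarized cores with derived-allele
    frequency within [maf_min, 1 - maf_min]; standardized within ``n_bins``
    equal-width daf bins.  Cores in bins with fewer than two scores, or
    with a zero iHH for either allele, stay NaN.
    """
    der = np.ascontiguousarray(panel.derived_alleles(), dtype=np.int8)
    pos, gpos = panel.positions, panel.gpos()
    d, ne = panel.derived_counts()
    pol = panel.polarized()
    raw = np.full(panel.n_sites, np.nan)
    daf = np.full(panel.n_sites, np.nan)
    for i in range(panel.n_sites):
        if not pol[i] or ne[i] == 0:
            continue
        f = d[i] / ne[i]
        if f < maf_min or f > 1.0 - maf_min:
            continue
        if d[i] < 2 or ne[i] - d[i] < 2:
            continue
        anc = np.nonzero(der[:, i] == 0)[0]
        dvd = np.nonzero(der[:, i] == 1)[0]
        ihh_a = _ihh_both_sides(der, anc, i, pos, gpos, truncation, max_gap_bp)
        ihh_d = _ihh_both_sides(der, dvd, i, pos, gpos, truncation, max_gap_bp)
        if ihh_a > 0 and ihh_d > 0:
            raw[i] = np.log(ihh_a / ihh_d)
            daf[i] = f
    if not standardize:
        return raw
    return _standardize_binned(raw, daf, n_bins)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def xpehh_scores(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                 truncation: float = TRUNCATION, max_gap_bp: int = MAX_GAP_BP,
                 standardize: bool = True) -> np.ndarray:
    """Per-site XP-EHH of population A versus B (positive = longer
    haplotypes, i.e. candidate sweep, in A).

    Both panels must share site coordinates.  At each core the truncation
    extent is set by the EHH of the pooled sample; each population's iHH
    (all chromosomes, both sides) is then integrated over exactly that
    extent and raw = ln(iHH_A / iHH_B) is standardized genome-wide to
    mean 0 / sd 1.  Swapping the panels negates every score exactly.
    """
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share site coordinates")
    pos, gpos = panel_a.positions, panel_a.gpos()
    der_a = np.ascontiguousarray(panel_a.derived_alleles(), dtype=np.int8)
    der_b = np.ascontiguousarray(panel_b.derived_alleles(), dtype=np.int8)
    pooled = np.ascontiguousarray(np.vstack([der_a, der_b]), dtype=np.int8)
    all_a = np.arange(panel_a.n, dtype=np.int64)
    all_b = np.arange(panel_b.n, dtype=np.int64)
    all_p = np.arange(pooled.shape[0], dtype=np.int64)
    raw = np.full(panel_a.n_sites, np.nan)
    for i in range(panel_a.n_sites):
        ihh_a = ihh_b = 0.0
        for side in ("left", "right"):
            _, end = _ihh_fast(pooled, all_p, i, side, gpos, pos,
                               truncation, max_gap_bp)
            if end == i:
                continue
            sa, _ = _ihh_fast(der_a, all_a, i, side, gpos, pos,
                              None, None, limit=end)
            sb, _ = _ihh_fast(der_b, all_b, i, side, gpos, pos,
                              None, None, limit=end)
            ihh_a += sa
            ihh_b += sb
        if ihh_a > 0 and ihh_b > 0:
            raw[i] = np.log(ihh_a / ihh_b)
    if not standardize:
        return raw
    fin = np.isfinite(raw)
    if fin.sum() >= 2 and raw[fin].std() > 0:
        out = np.full_like(raw, np.nan)
        out[fin] = (raw[fin] - raw[fin].mean()) / raw[fin].std()
        return out
    return np.full_like(raw, np.nan)
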