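"""Site-frequency-spectrum neutrality tests on windowed haplotype data.

The statistics contrast three classical estimators of the scaled mutation
rate theta computed from the same window: Watterson's S/a1 (segregating
sites), pi (pairwise heterozygosity) and theta_H (homozygosity of derived
alleles).  Under the standard neutral model their expectations coincide;
directional selection skews the spectrum and drives the contrasts away from
zero:

* Tajima's D = (pi - S/a1) / sd — negative for an excess of rare alleles.
* Fu & Li's D/F — contrast total mutations (or pi) with the count of derived
  singletons eta_e ("external" mutations), outgroup versions.
* Fay & Wu's H = theta_pi - theta_H — negative for an excess of
  high-frequency derived alleles, the classic hitchhiking footprint.

Per-site effective sample sizes handle missing data; sites with more than 20%
missing haplotypes are dropped from every statistic.  Variance constants use
the panel haplotype count n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .panel import HaplotypePanel
from .windows import GenomicWindow

MAX_MISSING_FRACTION = 0.2


@dataclass
class WindowSiteSummary:
    """Sufficient statistics of one (panel, window) for the SFS tests."""

    n: int                      # panel haplotype count
    S: int = 0                  # segregating sites (polarized or not)
    pi: float = 0.0             # sum over sites of 2 d (ne-d) / (ne (ne-1))
    pi_polarized: float = 0.0   # same sum restricted to polarized sites
    theta_h: float = 0.0        # sum over polarized sites of 2 d^2 / (ne (ne-1))
    eta_s: int = 0              # singletons of either allele
    eta_e: int = 0              # derived singletons (external mutations)
    S_polarized: int = 0
    xi: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self):
        if len(self.xi) == 0:
            self.xi = np.zeros(max(self.n - 1, 0), dtype=np.int64)


def site_summaries(panel: HaplotypePanel, window: GenomicWindow) -> WindowSiteSummary:
    """Tally S, pi, the derived SFS and singleton counts inside a window.

    Missing alleles are excluded per site (per-site effective n); sites
    exceeding the missingness ceiling are dropped entirely.  Unpolarized
    sites contribute to S, pi and eta_s only.
    """
    sl = panel.site_slice(window.start, window.end)
    der = panel.derived_alleles()[:, sl]
    pol = panel.polarized()[sl]
    n = panel.n
    s = WindowSiteSummary(n=n)
    if der.shape[1] == 0:
        return s
    obs = der >= 0
    n_eff = obs.sum(axis=0)
    d = np.where(obs, der, 0).sum(axis=0)   # derived count (alt count if unpolarized)
    keep = (n_eff >= 2) & (n_eff >= (1 - MAX_MISSING_FRACTION) * n)
    seg = keep & (d > 0) & (d < n_eff)
    for j in np.nonzero(seg)[0]:
        ne, dj = int(n_eff[j]), int(d[j])
        h = 2.0 * dj * (ne - dj) / (ne * (ne - 1))
        s.S += 1
        s.pi += h
        if min(dj, ne - dj) == 1:
            s.eta_s += 1
        if pol[j]:
            s.S_polarized += 1
            s.pi_polarized += h
            s.theta_h += 2.0 * dj * dj / (ne * (ne - 1))
            if dj == 1:
                s.eta_e += 1
            if 1 <= dj <= n - 1:
                s.xi[dj - 1] += 1
    return s


# ---------------------------------------------------------------------------
# variance constants
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict:
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


@lru_cache(maxsize=None)
def fu_li_constants(n: int) -> dict:
    """Constants for the outgroup versions of Fu & Li's D and F.

    The corrected variance coefficients in universal use (DnaSP/libsequence
    convention) are computed from the harmonic sums a_n and b_n.
    """
    a, b = _harmonics(n)
    a_next = a + 1.0 / n                      # a_{n+1}
    if n > 2:
        c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        c = 1.0
    vd = 1.0 + (a * a / (b + a * a)) * (c - (n + 1) / (n - 1))
    ud = a - 1.0 - vd
    vf = (c + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a * a + b)
    uf = (1.0 + (n + 1) / (3.0 * (n - 1))
          - 4.0 * ((n + 1) / (n - 1) ** 2) * (a_next - 2.0 * n / (n + 1))) / a - vf
    return {"a": a, "ud": ud, "vd": vd, "uf": uf, "vf": vf}


# ---------------------------------------------------------------------------
# the tests
# ---------------------------------------------------------------------------

def tajimas_d(summary: WindowSiteSummary) -> float:
    """Tajima's D; NaN when the window has no segregating site."""
    S, n = summary.S, summary.n
    if S < 1 or n < 3:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (summary.pi - S / k["a1"]) / np.sqrt(var)


def fu_li_tests(summary: WindowSiteSummary) -> tuple[float, float]:
    """Fu & Li's (D, F), outgroup versions using derived singletons eta_e."""
    S, n = summary.S, summary.n
    if S < 1 or n < 3 or summary.S_polarized == 0:
        return float("nan"), float("nan")
    k = fu_li_constants(n)
    eta_e = summary.eta_e
    var_d = k["ud"] * S + k["vd"] * S * S
    var_f = k["uf"] * S + k["vf"] * S * S
    d = (S - k["a"] * eta_e) / np.sqrt(var_d) if var_d > 0 else float("nan")
    f = (summary.pi - eta_e) / np.sqrt(var_f) if var_f > 0 else float("nan")
    return float(d), float(f)


def fay_wu_h(summary: WindowSiteSummary) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H over polarized sites."""
    if summary.S < 1 or summary.S_polarized == 0:
        return float("nan")
    return float(summary.pi_polarized - summary.theta_h)
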