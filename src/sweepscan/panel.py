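"""Phased haplotype panels.

A :class:`HaplotypePanel` is the in-memory representation of one population's
phased, biallelic haplotypes on one chromosome: an ``(n_haplotypes, n_sites)``
matrix of 0/1 alleles (``-1`` = missing), physical positions in bp, optional
genetic positions in cM, and per-site ancestral-allele polarity.  Allele 0 is
the REF allele of the source VCF; whether REF is ancestral is recorded per
site so that derived-allele statistics can be computed on polarized sites and
folded statistics everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1

#: cM per bp used when no genetic map is supplied (1 cM/Mb).
DEFAULT_CM_PER_BP = 1e-6


@dataclass
class HaplotypePanel:
    alleles: np.ndarray                 # (n, n_sites) int8 in {0, 1, -1}
    positions: np.ndarray               # bp, int64, strictly increasing
    population: str
    chrom: str = "1"
    genetic_positions: np.ndarray | None = None   # cM, non-decreasing
    ancestral_is_ref: np.ndarray | None = None    # int8: 1 / 0 / -1 unknown
    ref_alleles: np.ndarray | None = None         # per-site REF base (str)
    alt_alleles: np.ndarray | None = None         # per-site ALT base (str)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x sites matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length does not match number of sites")
        if self.n < 2:
            raise ValueError("a panel needs at least 2 haplotypes")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.ancestral_is_ref is None:
            self.ancestral_is_ref = np.ones(self.n_sites, dtype=np.int8)
        else:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=np.int8)
            if self.ancestral_is_ref.shape[0] != self.n_sites:
                raise ValueError("ancestral_is_ref length mismatch")
        if self.genetic_positions is not None:
            self.genetic_positions = np.asarray(self.genetic_positions, dtype=float)
            if self.genetic_positions.shape[0] != self.n_sites:
                raise ValueError("genetic_positions length mismatch")
            if np.any(np.diff(self.genetic_positions) < 0):
                raise ValueError("genetic_positions must be non-decreasing")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def gpos(self) -> np.ndarray:
        """Genetic positions in cM; falls back to 1 cM/Mb from bp."""
        if self.genetic_positions is not None:
            return self.genetic_positions
        return self.positions.astype(float) * DEFAULT_CM_PER_BP

    # -- polarity ----------------------------------------------------------
    def polarized(self) -> np.ndarray:
        """Boolean mask of sites with known ancestral allele."""
        return self.ancestral_is_ref >= 0

    def derived_alleles(self) -> np.ndarray:
        """Allele matrix recoded so 1 = derived allele.

        Unpolarized columns are returned as-is (REF/ALT coding); use
        :meth:`polarized` to mask them.  Missing stays ``-1``.
        """
        out = self.alleles.copy()
        flip = self.ancestral_is_ref == 0
        if np.any(flip):
            cols = out[:, flip]
            obs = cols >= 0
            cols[obs] = 1 - cols[obs]
            out[:, flip] = cols
        return out

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived count, effective sample size) over non-missing."""
        der = self.derived_alleles()
        obs = der >= 0
        n_eff = obs.sum(axis=0)
        d = np.where(obs, der, 0).sum(axis=0)
        return d.astype(np.int64), n_eff.astype(np.int64)

    # -- slicing -----------------------------------------------------------
    def site_slice(self, start_bp: int, end_bp: int) -> slice:
        """Slice of site indices with start_bp <= pos < end_bp."""
        lo = int(np.searchsorted(self.positions, start_bp, side="left"))
        hi = int(np.searchsorted(self.positions, end_bp, side="left"))
        return slice(lo, hi)

    def restrict(self, start_bp: int, end_bp: int) -> "HaplotypePanel":
        sl = self.site_slice(start_bp, end_bp)
        return HaplotypePanel(
            alleles=self.alleles[:, sl],
            positions=self.positions[sl],
            population=self.population,
            chrom=self.chrom,
            genetic_positions=None if self.genetic_positions is None
            else self.genetic_positions[sl],
            ancestral_is_ref=self.ancestral_is_ref[sl],
            ref_alleles=None if self.ref_alleles is None else self.ref_alleles[sl],
            alt_alleles=None if self.alt_alleles is None else self.alt_alleles[sl],
        )
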