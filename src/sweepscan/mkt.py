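"""McDonald–Kreitman test per protein-coding gene.

The MKT contrasts non-synonymous and synonymous variation within a species
(polymorphism Pn, Ps) against fixed differences from an outgroup (divergence
Dn, Ds) in a 2x2 table.  Under strict neutrality Dn/Ds = Pn/Ps; an excess of
non-synonymous divergence indicates recurrent adaptive protein evolution,
summarized as alpha = 1 - (Ds*Pn)/(Dn*Ps), the proportion of adaptive
non-synonymous substitutions.  Slightly deleterious non-synonymous variants
segregating at low frequency inflate Pn and bias alpha downward; the
corrected estimator partitions polymorphism at a derived-allele-frequency
cutoff and replaces Pn by its neutral share estimated from the synonymous
frequency spectrum:

    Pn_neutral = Pn_high * (1 + Ps_low / Ps_high)
    alpha_corrected = 1 - (Ds * Pn_neutral) / (Dn * Ps)

Significance is a two-sided Fisher's exact test on the 2x2 table; a gene is
called selected when alpha (corrected when available) exceeds ``alpha_min``
(default 0) and the Fisher P-value is below ``p_max`` (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import HaplotypePanel

DAF_CUTOFF = 0.05

_CODON_TABLE = {}          # filled lazily from Biopython's standard table
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _codon_table() -> dict:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate_codon(codon: str) -> str:
    return _codon_table().get(codon.upper(), "X")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    cds: list                      # [(start, end), ...] 0-based half-open, ordered
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError("CDS intervals must be non-overlapping")
        if self.cds_length % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def coding_positions(self) -> np.ndarray:
        """Genomic positions in coding (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class MKTCounts:
    Pn: int = 0
    Ps: int = 0
    Dn: int = 0
    Ds: int = 0
    Pn_low: int = 0
    Pn_high: int = 0
    Ps_low: int = 0
    Ps_high: int = 0
    cutoff: float = DAF_CUTOFF
    multi_hit_codons: int = 0      # codons with >1 variable position (flagged)

    def __post_init__(self):
        if self.Pn_low + self.Pn_high not in (0, self.Pn):
            raise ValueError("Pn partition does not sum to Pn")
        if self.Ps_low + self.Ps_high not in (0, self.Ps):
            raise ValueError("Ps partition does not sum to Ps")


@dataclass
class MKTResult:
    counts: MKTCounts
    alpha: float
    alpha_corrected: float
    fisher_p: float
    selected: bool


def _strand_base(base: str, strand: str) -> str:
    return _COMPLEMENT[base] if strand == "-" else base


def mkt_counts_from_gene(panel: HaplotypePanel, outgroup_seq,
                         reference_seq, gene: GeneModel,
                         cutoff: float = DAF_CUTOFF) -> MKTCounts:
    """Classify every variable or divergent CDS site of one gene.

    ``reference_seq`` and ``outgroup_seq`` are per-base nucleotide strings
    (or arrays) on the gene's chromosome coordinates.  The codon context is
    the panel-major-allele codon; each site is classified by substituting
    the alternative (or outgroup) base into that codon and comparing amino
    acids, one change per codon (codons with more than one variable
    position are classified site-by-site and flagged).

    Polymorphic = segregating in the panel, partitioned at the
    derived-allele-frequency ``cutoff`` (daf < cutoff is "low").
    Divergent = fixed in the panel and different from the outgroup base;
    polymorphic sites are never counted as divergent.
    """
    ref = np.frombuffer(bytes(str(reference_seq), "ascii"), dtype="S1") \
        if isinstance(reference_seq, str) else np.asarray(reference_seq, dtype="S1")
    out_seq = np.frombuffer(bytes(str(outgroup_seq), "ascii"), dtype="S1") \
        if isinstance(outgroup_seq, str) else np.asarray(outgroup_seq, dtype="S1")

    coding = gene.coding_positions()
    n_codons = len(coding) // 3

    d, ne = panel.derived_counts()
    panel_pos = {int(p): j for j, p in enumerate(panel.positions)}

    def panel_base(gpos: int) -> str:
        """Panel major-allele base at a genomic position (+ strand)."""
        j = panel_pos.get(gpos)
        base = ref[gpos].decode()
        if j is not None and ne[j] > 0:
            # derived allele is ALT of the simulator's coding (anc = REF)
            ref_b = (panel.ref_alleles[j] if panel.ref_alleles is not None
                     else base)
            alt_b = (panel.alt_alleles[j] if panel.alt_alleles is not None
                     else "N")
            anc_is_ref = panel.ancestral_is_ref[j] != 0
            d_count = d[j]
            derived_b = alt_b if anc_is_ref else ref_b
            ancestral_b = ref_b if anc_is_ref else alt_b
            base = derived_b if d_count * 2 > ne[j] else ancestral_b
        return base

    counts = MKTCounts(cutoff=cutoff)
    for ci in range(n_codons):
        gpos3 = coding[3 * ci: 3 * ci + 3]
        codon = "".join(_strand_base(panel_base(int(g)), gene.strand)
                        for g in gpos3)
        aa_ref = translate_codon(codon)
        variable_positions = []
        for off, gpos in enumerate(gpos3):
            gpos = int(gpos)
            j = panel_pos.get(gpos)
            seg = j is not None and 0 < d[j] < ne[j]
            out_b = out_seq[gpos].decode()
            maj = panel_base(gpos)
            if seg:
                variable_positions.append(off)
                # the non-major allele substituted into the codon
                ref_b = (panel.ref_alleles[j] if panel.ref_alleles is not None
                         else ref[gpos].decode())
                alt_b = (panel.alt_alleles[j] if panel.alt_alleles is not None
                         else "N")
                minor = alt_b if maj == ref_b else ref_b
                mut = _substitute(codon, off, _strand_base(minor, gene.strand))
                syn = translate_codon(mut) == aa_ref
                daf = _site_daf(panel, j, d[j], ne[j])
                low = daf < cutoff
                if syn:
                    counts.Ps += 1
                    counts.Ps_low += low
                    counts.Ps_high += not low
                else:
                    counts.Pn += 1
                    counts.Pn_low += low
                    counts.Pn_high += not low
            elif out_b != maj:
                # fixed in panel (or invariant reference) and differs from
                # the outgroup: a fixed difference
                mut = _substitute(codon, off, _strand_base(out_b, gene.strand))
                syn = translate_codon(mut) == aa_ref
                if syn:
                    counts.Ds += 1
                else:
                    counts.Dn += 1
        if len(variable_positions) > 1:
            counts.multi_hit_codons += 1
    return counts


def _substitute(codon: str, off: int, base: str) -> str:
    return codon[:off] + base + codon[off + 1:]


def _site_daf(panel: HaplotypePanel, j: int, d: int, ne: int) -> float:
    if panel.ancestral_is_ref[j] >= 0:
        return d / ne
    # unpolarized: fold (use minor-allele frequency, conservative)
    return min(d, ne - d) / ne


def fisher_exact_2x2(counts: MKTCounts) -> float:
    """Two-sided Fisher's exact P of the 2x2 MKT table.

    The two-sided P sums the probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's.  Any zero margin gives P = 1.
    """
    table = [[counts.Pn, counts.Ps], [counts.Dn, counts.Ds]]
    margins = (counts.Pn + counts.Ps, counts.Dn + counts.Ds,
               counts.Pn + counts.Dn, counts.Ps + counts.Ds)
    if min(margins) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def alpha_standard(counts: MKTCounts) -> float:
    """alpha = 1 - (Ds * Pn) / (Dn * Ps); NaN when Dn or Ps is zero."""
    if counts.Dn == 0 or counts.Ps == 0:
        return float("nan")
    return 1.0 - (counts.Ds * counts.Pn) / (counts.Dn * counts.Ps)


def alpha_corrected(counts: MKTCounts) -> float:
    """alpha with low-frequency deleterious non-synonymous excess removed.

    The neutral share of low-frequency Pn is estimated from the synonymous
    spectrum: Pn_neutral = Pn_high * (1 + Ps_low / Ps_high).  NaN when
    Ps_high, Dn or Ps is zero.
    """
    if counts.Ps_high == 0 or counts.Dn == 0 or counts.Ps == 0:
        return float("nan")
    pn_neutral = counts.Pn_high * (1.0 + counts.Ps_low / counts.Ps_high)
    return 1.0 - (counts.Ds * pn_neutral) / (counts.Dn * counts.Ps)


def gene_selection_call(alpha: float, fisher_p: float,
                        alpha_min: float = 0.0, p_max: float = 0.05) -> bool:
    """Positive-selection call: alpha > alpha_min and Fisher P < p_max."""
    if not np.isfinite(alpha):
        return False
    return alpha > alpha_min and fisher_p < p_max


def mkt_eligible(counts: MKTCounts) -> bool:
    """Variability eligibility: some polymorphism and some divergence."""
    return (counts.Pn + counts.Ps) > 0 and (counts.Dn + counts.Ds) > 0


def mkt_test(panel: HaplotypePanel, outgroup_seq, reference_seq,
             gene: GeneModel, cutoff: float = DAF_CUTOFF,
             alpha_min: float = 0.0, p_max: float = 0.05) -> MKTResult:
    """Full MKT for one gene in one population panel."""
    counts = mkt_counts_from_gene(panel, outgroup_seq, reference_seq, gene,
                                  cutoff=cutoff)
    a = alpha_standard(counts)
    ac = alpha_corrected(counts)
    p = fisher_exact_2x2(counts)
    used = ac if np.isfinite(ac) else a
    sel = mkt_eligible(counts) and gene_selection_call(used, p, alpha_min, p_max)
    return MKTResult(counts=counts, alpha=a, alpha_corrected=ac,
                     fisher_p=p, selected=sel)
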