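# Methods

## The scan

The package detects candidate regions of recent positive selection from
phased haplotype panels by an empirical-outlier approach. Seven windowed
statistics are computed in non-overlapping 10-kb windows:

* **Linkage disequilibrium (LD)**: iHS (within-population integrated
  haplotype score) and XP-EHH (cross-population extended haplotype
  homozygosity), sensitive to sweeps at moderate and high derived-allele
  frequency respectively.
* **Site frequency spectrum (SFS)**: Tajima's *D*, Fu & Li's *D* and *F*
  (outgroup versions based on derived singletons), Fay & Wu's *H*
  (excess of high-frequency derived alleles), and Weir–Cockerham *F*<sub>ST</sub>
  for population pairs.

Each (population-or-pair, statistic, chromosome-class) combination forms its
own empirical distribution: windows are ranked within it and the window's
empirical *P*-value is its quantile. Tajima's *D*, Fu & Li's *D*/*F* and Fay &
Wu's *H* are two-tailed (*p* = 2·min(upper, lower), capped at 1); windowized
iHS, XP-EHH and *F*<sub>ST</sub> use the upper tail. Autosomes are pooled per
key; the X chromosome is ranked separately and carries no iHS/XP-EHH.
Windows with fewer than 5 segregating sites are discarded first; for pair
statistics the window must pass in both member populations (implemented by
storing the pair row's S as the minimum of the two).

A candidate region is a maximal run of analyzed windows with *p* below the
extension threshold containing at least one seed window below the seed
threshold; the run may jump unanalyzed stretches strictly shorter than
20 kb, and an analyzed window at or above the extension threshold always
terminates it. Genome-scale defaults are seed 0.0005 and extension 0.005
(the 0.05% and 0.5% tails). Per-key regions are collapsed by ≥1-bp
coordinate overlap into joint regions (book-ended regions stay separate);
joint regions entirely inside the alignment blacklist, or overlapping an
assembly gap by any amount, are removed. Pair-statistic regions are
attributed to one member population by the locus-specific branch length
(LSBL): the three pairwise *F*<sub>ST</sub> distances of a population trio are
decomposed as lsbl_A = (d_AB + d_AC − d_BC)/2 (and cyclically), and the
member with the larger mean branch over the region's windows wins; exact
ties go to the first member of the ordered pair and are flagged.

Protein-coding genes overlapping joint regions, with some polymorphism and
some divergence, are tested by the McDonald–Kreitman test. A gene is called
selected when α (corrected where defined, see below) exceeds 0 and the
two-sided Fisher exact *P* of the 2×2 table is below 0.05; a positive call
adds the ProteinChanges signature to the overlapping regions without
extending their meta-population membership.

## Statistic definitions and numerical choices

* **Per-window site summaries.** Missing alleles are excluded per site
  (per-site effective sample size *n*ₑ); sites with more than 20% missing
  haplotypes are dropped entirely. Variance constants use the panel
  haplotype count *n*. Unpolarized sites contribute to *S*, π and total
  singletons but not to the derived spectrum ξ, η_e, Fay & Wu's *H* or
  Fu & Li's tests.
* **Tajima's D** = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
  from the harmonic sums; S = 0 yields a missing value, never 0.
* **Fu & Li's D, F** use the outgroup ("external mutations") form with the
  derived-singleton count η_e and the corrected variance coefficients in
  universal use (the originally printed constants contain typos).
* **Fay & Wu's H** is the unnormalized θ_π − θ_H with
  θ_H = Σ 2ξᵢi²/(n(n−1)), computed over polarized sites.
* ***F*<sub>ST</sub>** is the Weir–Cockerham (1984) two-population
  variance-components estimator for haploid samples, combined across the
  window's pooled-polymorphic sites as a ratio of sums (Σa / Σ(a+b)).
  Negative estimates are reported as computed.
* **EHH** at distance *x* from a core is Σ_h C(c_h,2)/C(c,2) over distinct
  extended haplotypes among the c core-allele carriers, evaluated at each
  successive SNP. **iHH** is the trapezoidal integral over genetic distance
  (cM; physical distance at 1 cM/Mb when no map is supplied), summed over
  both sides. Integration stops at the first point whose EHH is **≤** the
  truncation cutoff (default 0.05) — the ≤ rule makes a truncation of 1.0
  integrate nothing — and across inter-SNP gaps larger than 200 kb (an
  assembly-gap guard).
* **iHS** = ln(iHH_ancestral / iHH_derived) at polarized cores with derived
  frequency in [0.05, 0.95], standardized to mean 0 / sd 1 within 20
  equal-width derived-frequency bins (bins with fewer than two scores yield
  missing values). **XP-EHH** = ln(iHH_pop1 / iHH_pop2) with both
  populations' all-chromosome iHH integrated over the truncation extent of
  the *pooled* sample, standardized genome-wide; swapping the populations
  negates every score exactly.
* **Windowization** of SNP-level LD scores: mean of |standardized score|
  over the window's SNPs (configurable to max); windows without scored SNPs
  are missing.
* **Window tiling**: consecutive windows from position 0; a final partial
  window is kept iff it is at least half the window size.
* **Empirical P-values** count ties conservatively (max-rank, self
  included): p_upper(i) = #{j : v_j ≥ v_i}/M.
* **MKT classification**: the codon context is the panel-major-allele
  codon; each variable CDS site is classified by substituting the
  alternative allele (divergent sites: the outgroup base) and comparing
  amino acids, one change per codon; codons with several variable positions
  are classified site-by-site and flagged. Divergent = fixed in the panel
  and different from the outgroup; polymorphic sites are never divergent.
  The slightly-deleterious correction partitions polymorphism at a derived
  allele frequency cutoff (default 0.05) and estimates the neutral share of
  non-synonymous polymorphism from the synonymous spectrum:
  Pn_neutral = Pn_high·(1 + Ps_low/Ps_high),
  α_corrected = 1 − (Ds·Pn_neutral)/(Dn·Ps). The uncorrected α is always
  reported alongside; several published variants of this correction exist,
  and this frequency-partition form is the one implemented here.
* Coordinates are 0-based half-open everywhere internally; VCF I/O is
  1-based per the standard.

## The synthetic-data generator

`simulate_populations` is a forward Wright–Fisher simulation chosen so that
sweeps with selection are trivial to plant: one ancestral population of
*N* diploids is burned in from a monomorphic state for 4·*N* generations,
then split into daughter populations that evolve independently. Mutations
hit a fixed grid of sites (infinite sites approximated by disallowing
mutation at positions currently carrying a derived allele; a site freed by
loss can mutate again), recombination is uniform crossover with a
per-generation Poisson count, and an optional additive sweep (fitnesses 1,
1+s, 1+2s) runs at a focal site in one population, re-seeded from one copy
whenever it is lost. The outgroup substitutes each grid site independently
with the configured probability. Because daughter populations evolve
independently, the same grid site can mutate in two populations (to the
same predetermined alternative base) — a small departure from strict
infinite sites across populations.

What the generator emulates: multi-population panels with shared ancestry
and drift, hard sweeps with a known truth interval, ancestral polarization,
outgroup divergence for the MKT, window tables with outliers planted at
exact empirical ranks, and annotation tracks/gene models/gaps/blacklists at
configurable densities. What it does not emulate: demographic realism
(growth, migration, admixture), variable recombination maps, sequencing
error, phasing error, and genome-scale window counts. Passing tests
therefore demonstrate the machinery's correctness and its operating
characteristics under an idealised rescaled model, not calibrated power on
real human data.

## The desk-scale sweep-recovery experiment

`pipeline.sweep_recovery_experiment` measures end-to-end operating
characteristics under a small rescaled model: 3 populations of 200
diploids, 50 kb on a 400-site grid (μ = 1e−4 per site per generation, so a
10-kb window carries a few dozen segregating sites; ρ = 2e−8 per bp, low
enough for the sweep to hitchhike the whole replicate), 150 generations of
post-split evolution, and an s = 0.05 additive sweep seeded at the split in
one population — sampled late in its trajectory (derived frequency
typically 0.7–1.0), the regime the haplotype and high-frequency-derived
statistics are designed for. Sweep replicates whose allele never
established (final frequency < 0.5) are re-drawn with a fresh seed, the
experiment-level analogue of the generator's re-seeding rule: the question
is whether a sweep that happened is recovered, not whether every new allele
survives drift.

One hundred neutral replicates supply the per-key empirical null
distribution (500 windows per key) and the standardization moments for iHS
(per derived-frequency bin) and XP-EHH. Standardizing against the pooled
null — rather than within each 50-kb replicate — is the desk-scale
equivalent of genome-wide standardization; within-replicate standardization
would remove a whole-chromosome sweep signal by construction. Each
evaluated replicate is ranked against (null + its own) windows and scanned
with thresholds seed 0.02 / extension 0.05: with ~505-window distributions
the genome-scale quantiles (0.0005/0.005) are unreachable (the minimum
attainable two-tailed *p* is 2/505), so the desk thresholds are calibrated
to the experiment's false-positive budget — an expected ~0.5 false joint
regions per neutral 50-kb replicate across all 21 keys, the same
genome-wide budget logic behind the original tail choice. A sweep replicate
counts as recovered when a joint region overlaps the planted truth interval
with the sweep population among its assigned populations (directly for
single-population keys, via LSBL for pair keys).

With a small N, an s = 0.05 sweep fixes on the drift timescale, so its
footprint competes with strong genealogical noise; sampling near the end of
the sweep, pooled-null standardization and the moderate split length are
what make recovery reliable at this scale. At genome scale none of these
desk calibrations apply and the package defaults are the 0.05%/0.5% tails.

## Known limitations

* Fu & Li's tests use total S with η_e from polarized sites; with heavily
  unpolarized data the contrast is conservative.
* The MKT codon machinery assumes one reading frame per gene, ignores
  multiple hits along the outgroup lineage (no Jukes–Cantor correction) and
  polarization error.
* The region caller requires an unbroken run of sub-threshold analyzed
  windows; an interior analyzed window at or above the extension threshold
  always splits a region.
* The desk-scale experiment's statistical power statement is specific to
  its rescaled parameters; it is not a power analysis for human data.
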