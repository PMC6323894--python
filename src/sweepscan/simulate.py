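"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`simulate_populations` — a forward Wright–Fisher simulation of one
  ancestral population split into daughter populations, with per-generation
  mutation on a fixed site grid (infinite sites approximated by disallowing
  mutation at occupied positions), uniform crossover recombination, optional
  additive selection at a focal site (a hard sweep) and an outgroup sequence
  for polarization and divergence.

* :func:`synth_window_table` — a pre-tabulated per-window statistic table
  with i.i.d. null values per distribution key and outlier windows planted
  at requested empirical extremeness, for exercising the outlier scan
  without simulating haplotypes.

* :func:`synth_annotations` — interval tracks, gene models, gaps, blacklist
  and publication intervals at configurable densities per Mb.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import METRIC_REGISTRY, AnnotationBundle, AnnotationTrack
from .mkt import GeneModel
from .panel import HaplotypePanel
from .scan import TAIL_MODES, DistributionKey
from .stats_table import LD_STATS, WindowStatTable
from .windows import X

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SweepSpec:
    population: int                # focal population index
    site_index: int                # focal site on the grid
    s: float                       # additive selection coefficient (>= 0)
    introduction_generation: int = 0   # generations after the split

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class SimulationConfig:
    n_populations: int = 3
    diploid_size: int = 100
    sequence_length: int = 50_000
    n_sites: int = 400
    mu: float = 1e-4               # per-site per-generation, on the grid
    rho: float = 1e-8              # per-bp per-generation crossover rate
    split_generations: int = 300
    sweep: SweepSpec | None = None
    outgroup_divergence: float = 0.05  # expected substitutions per grid site
    seed: int = 0
    burn_in_factor: int = 4        # burn-in = factor * diploid_size generations
    truth_radius: int = 25_000     # half-width of the recorded sweep interval
    max_reseed: int = 1000
    chrom: str = "1"

    def __post_init__(self):
        if self.diploid_size < 2:
            raise ValueError("diploid_size must be >= 2")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if not (0 <= self.mu <= 1 and 0 <= self.rho <= 1):
            raise ValueError("mu and rho must be probabilities")
        if self.n_sites < 1 or self.n_sites > self.sequence_length:
            raise ValueError("n_sites must be in [1, sequence_length]")
        if self.sweep is not None and not \
                (0 <= self.sweep.site_index < self.n_sites):
            raise ValueError("sweep site index out of range")


@dataclass
class TruthSet:
    """Ground truth of planted signals for downstream evaluation."""

    planted_intervals: list = field(default_factory=list)
    # entries: (chrom, start, end, population-or-unit label, mechanism)
    sweep_final_frequency: list = field(default_factory=list)
    sweep_established: bool = True
    reseed_attempts: int = 0


@dataclass
class SimulationResult:
    panels: dict                       # population label -> HaplotypePanel
    outgroup: np.ndarray               # 0/1 per panel site (1 = substituted)
    truth: TruthSet
    reference: str                     # ancestral nucleotide sequence
    outgroup_substituted_sites: np.ndarray  # grid-site indices substituted
    grid_positions: np.ndarray         # all grid positions (bp)
    alt_bases: np.ndarray              # predetermined alt base per grid site
    config: SimulationConfig = None

    def outgroup_sequence(self) -> str:
        """Full outgroup nucleotide sequence on reference coordinates."""
        arr = np.frombuffer(bytes(self.reference, "ascii"), dtype="S1").copy()
        idx = self.grid_positions[self.outgroup_substituted_sites]
        arr[idx] = self.alt_bases[self.outgroup_substituted_sites]
        return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _next_generation(pop: np.ndarray, rng, mu: float, co_rate: float,
                     seq_len: int, grid_pos: np.ndarray,
                     sel_site: int | None = None, s: float = 0.0) -> np.ndarray:
    """One non-overlapping Wright-Fisher generation.

    Each of the 2N gametes draws an independent diploid parent (weighted by
    fitness 1, 1+s, 1+2s at the focal site when selection is active) and
    recombines the parent's two haplotypes with Poisson(co_rate) uniform
    crossovers.  Mutations then hit unoccupied grid sites (no derived copy
    present) at rate mu per gamete per free site.
    """
    n2, m = pop.shape
    n = n2 // 2
    if sel_site is not None and s > 0:
        g = pop[0::2, sel_site].astype(np.int64) + pop[1::2, sel_site]
        w = 1.0 + s * g
        parents = rng.choice(n, size=n2, p=w / w.sum())
    else:
        parents = rng.integers(0, n, size=n2)
    which = rng.integers(0, 2, size=n2)
    children = pop[2 * parents + which].copy()
    nco = rng.poisson(co_rate, size=n2)
    for idx in np.nonzero(nco > 0)[0]:
        h1 = pop[2 * parents[idx] + which[idx]]
        h2 = pop[2 * parents[idx] + 1 - which[idx]]
        bp = np.sort(rng.integers(0, seq_len, size=nco[idx]))
        cuts = np.searchsorted(grid_pos, bp)
        gam = h1.copy()
        src = 0
        prev = 0
        for c in np.append(cuts, m):
            if src == 1:
                gam[prev:c] = h2[prev:c]
            src ^= 1
            prev = c
        children[idx] = gam
    free = np.nonzero(~children.any(axis=0))[0]
    if len(free) and mu > 0:
        n_mut = min(rng.binomial(n2 * len(free), mu), len(free))
        if n_mut:
            sites = rng.choice(free, size=n_mut, replace=False)
            haps = rng.integers(0, n2, size=n_mut)
            children[haps, sites] = 1
    return children


def _evolve(pop: np.ndarray, generations: int, rng, cfg: SimulationConfig,
            grid_pos: np.ndarray, sweep: SweepSpec | None = None,
            truth: TruthSet | None = None) -> np.ndarray:
    co_rate = cfg.rho * cfg.sequence_length
    site = sweep.site_index if sweep else None
    for gen in range(generations):
        active = sweep is not None and gen >= sweep.introduction_generation
        if sweep is not None and gen == sweep.introduction_generation:
            if not pop[:, site].any():
                pop[rng.integers(0, pop.shape[0]), site] = 1
        pop = _next_generation(
            pop, rng, cfg.mu, co_rate, cfg.sequence_length, grid_pos,
            sel_site=site if active else None, s=sweep.s if active else 0.0)
        if active and not pop[:, site].any():
            if truth is not None and truth.reseed_attempts >= cfg.max_reseed:
                if truth is not None:
                    truth.sweep_established = False
                continue
            pop[rng.integers(0, pop.shape[0]), site] = 1
            if truth is not None:
                truth.reseed_attempts += 1
    return pop


def simulate_populations(config: SimulationConfig
                         ) -> SimulationResult:
    """Simulate the multi-population haplotype panels and the outgroup.

    One ancestral population of ``diploid_size`` diploids is burned in for
    ``burn_in_factor * diploid_size`` generations from a monomorphic state,
    split into ``n_populations`` copies that evolve independently for
    ``split_generations``, with the optional sweep in its focal population.
    The outgroup carries independent substitutions at each grid site with
    probability ``outgroup_divergence``.  Panels share site coordinates:
    every grid site carrying a derived allele in any population or an
    outgroup substitution becomes a panel column.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.sequence_length / cfg.n_sites
    grid_pos = (np.arange(cfg.n_sites) * spacing + spacing / 2).astype(np.int64)
    if len(np.unique(grid_pos)) != cfg.n_sites:
        raise ValueError("site grid too dense for sequence length")

    ref = rng.choice(_BASES, size=cfg.sequence_length)
    alt_shift = rng.integers(1, 4, size=cfg.n_sites)
    base_idx = np.searchsorted(_BASES, ref[grid_pos])
    alt_bases = _BASES[(base_idx + alt_shift) % 4]

    n2 = 2 * cfg.diploid_size
    ancestral = np.zeros((n2, cfg.n_sites), dtype=np.int8)
    ancestral = _evolve(ancestral, cfg.burn_in_factor * cfg.diploid_size,
                        rng, cfg, grid_pos)

    truth = TruthSet()
    pops = []
    for i in range(cfg.n_populations):
        pop = ancestral.copy()
        sweep = cfg.sweep if (cfg.sweep is not None
                              and cfg.sweep.population == i) else None
        pop = _evolve(pop, cfg.split_generations, rng, cfg, grid_pos,
                      sweep=sweep, truth=truth if sweep else None)
        pops.append(pop)

    outgroup_flip = rng.random(cfg.n_sites) < cfg.outgroup_divergence

    if cfg.sweep is not None:
        site = cfg.sweep.site_index
        focal = pops[cfg.sweep.population]
        freq = float(focal[:, site].mean())
        truth.sweep_final_frequency.append(freq)
        if freq == 0.0:
            truth.sweep_established = False
        center = int(grid_pos[site])
        truth.planted_intervals.append((
            cfg.chrom,
            max(0, center - cfg.truth_radius),
            min(cfg.sequence_length, center + cfg.truth_radius),
            f"pop{cfg.sweep.population}", "sweep"))

    keep = np.zeros(cfg.n_sites, dtype=bool)
    for pop in pops:
        keep |= pop.any(axis=0)
    keep |= outgroup_flip
    keep_idx = np.nonzero(keep)[0]

    cm_per_bp = cfg.rho * 100.0
    panels = {}
    for i, pop in enumerate(pops):
        panels[f"pop{i}"] = HaplotypePanel(
            alleles=pop[:, keep_idx],
            positions=grid_pos[keep_idx],
            population=f"pop{i}",
            chrom=cfg.chrom,
            genetic_positions=grid_pos[keep_idx].astype(float) * cm_per_bp,
            ancestral_is_ref=np.ones(len(keep_idx), dtype=np.int8),
            ref_alleles=np.array([b.decode() for b in ref[grid_pos[keep_idx]]]),
            alt_alleles=np.array([b.decode() for b in alt_bases[keep_idx]]),
        )
    return SimulationResult(
        panels=panels,
        outgroup=outgroup_flip[keep_idx].astype(np.int8),
        truth=truth,
        reference=ref.tobytes().decode(),
        outgroup_substituted_sites=np.nonzero(outgroup_flip)[0],
        grid_positions=grid_pos,
        alt_bases=alt_bases,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# window-table generator with planted outliers
# ---------------------------------------------------------------------------

def _planted_values(null_values: np.ndarray, plants: list, tail: str,
                    rng) -> np.ndarray:
    """Overwrite planted windows so their empirical p matches the request.

    ``plants`` is a list of (window index, quantile).  The target is a rank
    k = max(1, floor(q_one_sided * M)) from the relevant tail, realised by
    constructing the final sorted arrangement and interpolating planted
    values between their order-statistic neighbours.
    """
    m = len(null_values)
    planted_idx = [w for w, _ in plants]
    ranks = {}
    for w, q in plants:
        q_one = q / 2.0 if tail == "two" else q
        k = max(1, int(np.floor(q_one * m)))
        # position in the final ascending order (0-based)
        ranks[w] = (k - 1) if tail != "upper" else (m - k)
    others = np.sort(np.delete(null_values, planted_idx))
    slots = np.full(m, np.nan)
    taken = sorted(ranks.values())
    if len(set(taken)) != len(taken):
        # collide rarely (several plants at the same rank): spread them
        used = set()
        for w in sorted(ranks, key=lambda w: ranks[w]):
            r = ranks[w]
            while r in used:
                r += 1
            ranks[w] = min(r, m - 1)
            used.add(ranks[w])
    open_slots = [i for i in range(m) if i not in set(ranks.values())]
    slots[open_slots] = others
    spread = (others[-1] - others[0]) if len(others) > 1 else 1.0
    spread = spread if spread > 0 else 1.0
    # fill planted slots by interpolating between filled neighbours
    filled = ~np.isnan(slots)
    for w in sorted(ranks, key=lambda w: ranks[w]):
        r = ranks[w]
        left = slots[:r][filled[:r]]
        right = slots[r + 1:][filled[r + 1:]]
        lo = left[-1] if len(left) else (right[0] - spread if len(right) else 0.0)
        hi = right[0] if len(right) else lo + spread
        slots[r] = 0.5 * (lo + hi)
        filled[r] = True
    out = null_values.copy()
    for w in ranks:
        out[w] = slots[ranks[w]]
    return out


def synth_window_table(n_windows: int, keys: list[DistributionKey],
                       null_model=None, planted: list = (), seed: int = 0,
                       low_s_fraction: float = 0.02,
                       missing_windows=(), window_size: int = 10_000
                       ) -> tuple[WindowStatTable, TruthSet]:
    """A per-window statistic table with outliers planted at known ranks.

    ``planted`` entries are (window indices, key, quantile) with the
    quantile interpreted as the window's final empirical P-value under the
    key's tail mode.  Null values are i.i.d. draws from ``null_model`` (a
    frozen scipy distribution; standard normal by default).  Per-window
    segregating-site counts are >= 5 except for a configurable low-S
    fraction (never a planted window); ``missing_windows`` lists window
    indices left unanalyzed.
    """
    rng = np.random.default_rng(seed)
    missing = set(int(w) for w in missing_windows)
    seen = set()
    plants_by_key: dict[DistributionKey, list] = {}
    for wins, key, q in planted:
        if not (0 < q < 1):
            raise ValueError("extremeness quantile must be in (0, 1)")
        wins = [wins] if np.isscalar(wins) else list(wins)
        for w in wins:
            if not (0 <= w < n_windows):
                raise ValueError("planted window out of range")
            if (w, key) in seen:
                raise ValueError(f"duplicate planting for window {w}, {key}")
            seen.add((w, key))
            plants_by_key.setdefault(key, []).append((int(w), float(q)))

    units = sorted({k.unit for k in keys})
    s_by_unit = {}
    protected = {w for w, _ in sum(plants_by_key.values(), [])}
    for u in units:
        s = rng.integers(5, 51, size=n_windows)
        if low_s_fraction > 0:
            eligible = np.array([w for w in range(n_windows)
                                 if w not in protected], dtype=np.int64)
            n_low = int(round(low_s_fraction * n_windows))
            n_low = min(n_low, len(eligible))
            if n_low:
                low = rng.choice(eligible, size=n_low, replace=False)
                s[low] = rng.integers(0, 5, size=n_low)
        s_by_unit[u] = s

    rows = []
    truth = TruthSet()
    for key in keys:
        if null_model is None:
            vals = rng.normal(size=n_windows)
        else:
            vals = np.asarray(null_model.rvs(size=n_windows, random_state=rng),
                              dtype=float)
        tail = TAIL_MODES[key.statistic]
        if key in plants_by_key:
            vals = _planted_values(vals, plants_by_key[key], tail, rng)
            mech = ("outlier_LD" if key.statistic in LD_STATS
                    else "outlier_SFS")
            for w, _ in plants_by_key[key]:
                truth.planted_intervals.append(
                    (_key_chrom(key), w * window_size, (w + 1) * window_size,
                     key.unit, mech))
        chrom = _key_chrom(key)
        for w in range(n_windows):
            if w in missing:
                continue
            rows.append({"chrom": chrom, "start": w * window_size,
                         "end": (w + 1) * window_size, "unit": key.unit,
                         "statistic": key.statistic, "value": float(vals[w]),
                         "S": int(s_by_unit[key.unit][w])})
    return WindowStatTable.from_rows(rows), truth


def _key_chrom(key: DistributionKey) -> str:
    return "X" if key.chrom_class == X else "1"


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

DEFAULT_DENSITIES = {name: 10.0 for name in METRIC_REGISTRY
                     if name not in ("mappability", "distance_to_gap")}
DEFAULT_DENSITIES.update({"blacklist": 1.0, "gaps": 1.0, "publications": 5.0,
                          "genes": 5.0})


def _draw_track(rng, chrom_length: int, density: float,
                min_len: int = 200, max_len: int = 2000) -> np.ndarray:
    n = rng.poisson(density * chrom_length / 1e6)
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64)
    starts = rng.integers(0, max(1, chrom_length - min_len), size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    ends = np.minimum(starts + lengths, chrom_length)
    ivs = np.stack([starts, ends], axis=1)
    return ivs[np.argsort(ivs[:, 0])]


def synth_annotations(chrom_length: int, densities: dict | None = None,
                      seed: int = 0, chrom: str = "1") -> AnnotationBundle:
    """Random annotation tracks, gene models, gaps, blacklist, publications.

    ``densities`` maps a track name (or "blacklist" / "gaps" /
    "publications" / "genes") to elements per Mb; omitted names use the
    defaults.  Gaps and blacklist never overlap each other; gene models
    have CDS lengths divisible by 3.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    dens = dict(DEFAULT_DENSITIES)
    if densities:
        dens.update(densities)
    rng = np.random.default_rng(seed)

    tracks = {}
    for name, (category, style) in METRIC_REGISTRY.items():
        if style in ("distance", "inverse_pct"):
            continue
        ivs = _draw_track(rng, chrom_length, dens.get(name, 0.0))
        scores = None
        if style == "constrained":
            scores = rng.normal(1.5, 1.0, size=len(ivs))
        tracks[name] = AnnotationTrack(name=name, category=category,
                                       intervals=ivs, scores=scores)

    blacklist = _draw_track(rng, chrom_length, dens.get("blacklist", 0.0),
                            min_len=1000, max_len=5000)
    gaps = []
    raw_gaps = _draw_track(rng, chrom_length, dens.get("gaps", 0.0),
                           min_len=1000, max_len=5000)
    for s, e in raw_gaps:
        if not any(min(e, be) - max(s, bs) > 0 for bs, be in blacklist):
            gaps.append((s, e))
    gaps = np.asarray(gaps, dtype=np.int64).reshape(-1, 2)

    pub_ivs = _draw_track(rng, chrom_length, dens.get("publications", 0.0),
                          min_len=5000, max_len=50_000)
    pub_ids = [f"PMID:{rng.integers(10_000_000, 40_000_000)}"
               for _ in range(len(pub_ivs))]
    publications = AnnotationTrack(name="publications",
                                   category="publications",
                                   intervals=pub_ivs, ids=pub_ids) \
        if len(pub_ivs) else AnnotationTrack(
            name="publications", category="publications",
            intervals=np.zeros((0, 2), np.int64), ids=[])

    genes = []
    n_genes = rng.poisson(dens.get("genes", 0.0) * chrom_length / 1e6)
    for gi in range(n_genes):
        n_exons = int(rng.integers(1, 4))
        exon_codons = rng.integers(10, 60, size=n_exons)
        start = int(rng.integers(0, max(1, chrom_length - 20_000)))
        cds = []
        cur = start
        for codons in exon_codons:
            length = int(codons) * 3
            end = min(cur + length, chrom_length)
            if end - cur >= 3:
                cds.append((cur, cur + ((end - cur) // 3) * 3))
            cur = end + int(rng.integers(100, 2000))
            if cur >= chrom_length:
                break
        if not cds:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"gene{gi}", chrom=chrom, cds=cds,
                               strand=strand))

    return AnnotationBundle(gene_models=genes, tracks=tracks, gaps=gaps,
                            blacklist=blacklist, publications=publications)
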