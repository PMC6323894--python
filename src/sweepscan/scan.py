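"""Empirical-outlier genome scan: stratified empirical P-values, seed /
extension / gap region calling, cross-statistic collapsing and exclusion
filters.

The scan treats every (population-or-pair, statistic, chromosome-class)
combination as its own empirical distribution: windows are ranked within it
and a window's empirical P-value is its quantile (max-rank under ties, the
conservative convention).  Tajima's D, Fu & Li's D and F and Fay & Wu's H
are two-tailed (p = 2 * min tail, capped at 1); windowized iHS, XP-EHH and
F_ST use the upper tail.  A candidate region contains at least one seed
window (p < 0.0005), extends over adjacent analyzed windows with p < 0.005,
and may jump unanalyzed stretches strictly shorter than 20 kb; an analyzed
window at or above the extension threshold always terminates the region.
Candidate regions from all distributions are then collapsed by coordinate
overlap into joint regions, and joint regions entirely inside the blacklist
or touching an assembly gap are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import lsbl
from .intervals import contained_in_union, overlaps_any
from .stats_table import (ALL_STATS, LD_STATS, PAIR_STATS, SFS_STATS,
                          SINGLE_POP_STATS, WindowStatTable, pair_unit)
from .windows import AUTOSOME, X, chrom_class

log = logging.getLogger(__name__)

TAIL_MODES = {
    "iHS": "upper", "XPEHH": "upper", "FST": "upper",
    "TajimaD": "two", "FuLiD": "two", "FuLiF": "two", "FayWuH": "two",
}

#: 1000GP Phase III minus the four admixed-American populations.
DEFAULT_METAPOPULATIONS = {
    "CEU": "EUR", "TSI": "EUR", "FIN": "EUR", "GBR": "EUR", "IBS": "EUR",
    "YRI": "AFR", "LWK": "AFR", "GWD": "AFR", "MSL": "AFR", "ESN": "AFR",
    "ASW": "AFR", "ACB": "AFR",
    "GIH": "SAS", "PJL": "SAS", "BEB": "SAS", "STU": "SAS", "ITU": "SAS",
    "CHB": "EAS", "JPT": "EAS", "CHS": "EAS", "CDX": "EAS", "KHV": "EAS",
}
DEFAULT_POPULATIONS = tuple(DEFAULT_METAPOPULATIONS)
DEFAULT_PAIRS = (("CEU", "YRI"), ("CEU", "CHB"), ("YRI", "CHB"))


@dataclass(frozen=True)
class DistributionKey:
    unit: str            # population label or "A-B" pair label
    statistic: str
    chrom_class: str     # autosome / X

    def __post_init__(self):
        if self.chrom_class == X and self.statistic in LD_STATS:
            raise ValueError(f"{self.statistic} is not available on the X")


@dataclass
class ScanConfig:
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    metapopulations: dict = field(
        default_factory=lambda: dict(DEFAULT_METAPOPULATIONS))
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    statistics: tuple[str, ...] = ALL_STATS
    seed_p: float = 0.0005
    extend_p: float = 0.005
    min_S: int = 5
    max_unanalyzed_gap: int = 20_000
    alpha_min: float = 0.0
    mkt_p_max: float = 0.05
    window_size: int = 10_000

    def __post_init__(self):
        if not (0 < self.seed_p <= self.extend_p < 1):
            raise ValueError("need 0 < seed_p <= extend_p < 1")


@dataclass
class WindowPValue:
    chrom: str
    start: int
    end: int
    key: DistributionKey
    value: float
    p: float


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    key: DistributionKey
    seed_windows: list
    members: list                      # WindowPValue, sorted by start
    assigned_population: str | None = None
    assignment_tied: bool = False


@dataclass
class Signal:
    unit: str
    statistic: str
    value: float
    p: float


@dataclass
class JointRegion:
    chrom: str
    start: int
    end: int
    signals: list                      # Signal
    signature_types: set
    metapopulations: set
    assigned_populations: set
    genes: list = field(default_factory=list)
    sources: list = field(default_factory=lambda: ["sweepscan"])

    @property
    def min_p(self) -> float:
        return min(s.p for s in self.signals)


# ---------------------------------------------------------------------------
# distribution stratification
# ---------------------------------------------------------------------------

def enumerate_distribution_keys(config: ScanConfig) -> list[DistributionKey]:
    """All (unit, statistic, chromosome-class) empirical distributions.

    Single-population statistics per population and pair statistics per
    ordered pair, separately for the autosomes and the X; iHS and XP-EHH do
    not exist on the X.  With the default 22 populations and 3 pairs this
    yields 116 autosomal and 91 X distributions.
    """
    keys = []
    singles = [s for s in SINGLE_POP_STATS if s in config.statistics]
    pairs_stats = [s for s in PAIR_STATS if s in config.statistics]
    for cls in (AUTOSOME, X):
        for pop in config.populations:
            for stat in singles:
                if cls == X and stat in LD_STATS:
                    continue
                keys.append(DistributionKey(pop, stat, cls))
        for a, b in config.pairs:
            for stat in pairs_stats:
                if cls == X and stat in LD_STATS:
                    continue
                keys.append(DistributionKey(pair_unit(a, b), stat, cls))
    return keys


def filter_min_segsites(table: WindowStatTable, min_S: int = 5) -> WindowStatTable:
    """Drop rows whose window has fewer than ``min_S`` segregating sites."""
    df = table.df
    keep = df["S"] >= min_S
    frac = 1.0 - keep.mean() if len(df) else 0.0
    log.info("min-S filter (S >= %d): removed %d/%d rows (%.3f%%)",
             min_S, int((~keep).sum()), len(df), 100 * frac)
    return WindowStatTable(df[keep].reset_index(drop=True))


def empirical_pvalues(values: np.ndarray, tail: str) -> np.ndarray:
    """Empirical P-values by rank within one distribution.

    p_upper(i) = #{j : v_j >= v_i} / M (self included; max-rank under
    ties); two-tailed p = min(1, 2 * min(p_upper, p_lower)).  NaN values
    get NaN; M counts finite values only and must be at least 2.
    """
    values = np.asarray(values, dtype=float)
    fin = np.isfinite(values)
    m = int(fin.sum())
    if m < 2:
        raise ValueError("an empirical distribution needs at least 2 values")
    srt = np.sort(values[fin])
    out = np.full(values.shape, np.nan)
    v = values[fin]
    p_upper = (m - np.searchsorted(srt, v, side="left")) / m
    p_lower = np.searchsorted(srt, v, side="right") / m
    if tail == "upper":
        p = p_upper
    elif tail == "lower":
        p = p_lower
    elif tail == "two":
        p = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    else:
        raise ValueError(f"unknown tail mode {tail!r}")
    out[fin] = p
    return out


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_regions(pvalues: list[WindowPValue],
                 config: ScanConfig) -> list[CandidateRegion]:
    """Seed/extension/gap region calling for one key on one chromosome.

    ``pvalues`` holds the analyzed windows only (windows without a value
    for this key are unanalyzed stretches).  A region is the maximal run of
    analyzed windows with p < extend_p around at least one seed
    (p < seed_p), where consecutive analyzed windows may be separated by
    strictly less than ``max_unanalyzed_gap`` unanalyzed bases.
    """
    wins = sorted(pvalues, key=lambda w: w.start)
    regions: list[CandidateRegion] = []
    run: list[WindowPValue] = []

    def close(run):
        seeds = [w for w in run if w.p < config.seed_p]
        if seeds:
            regions.append(CandidateRegion(
                chrom=run[0].chrom, start=run[0].start, end=run[-1].end,
                key=run[0].key, seed_windows=[(w.start, w.end) for w in seeds],
                members=list(run)))

    for w in wins:
        extendable = w.p < config.extend_p
        if run:
            gap = w.start - run[-1].end
            if extendable and gap < config.max_unanalyzed_gap:
                run.append(w)
                continue
            close(run)
            run = []
        if extendable:
            run = [w]
    if run:
        close(run)
    return regions


def assign_pair_population(region: CandidateRegion,
                           lsbl_by_window: dict) -> CandidateRegion:
    """Attribute a pair-key region to one member population via LSBL.

    ``lsbl_by_window`` maps a member window (chrom, start) to the
    (branch_A, branch_B) lengths of the pair's two populations.  The member
    with the larger mean branch over the region's windows wins; an exact
    tie goes to the first population of the ordered pair and is flagged.
    With no LSBL available the assignment is "undetermined" and the region
    is retained.
    """
    pops = region.key.unit.split("-")
    if len(pops) != 2:
        raise ValueError("assign_pair_population needs a pair-key region")
    vals = [lsbl_by_window[(w.chrom, w.start)] for w in region.members
            if (w.chrom, w.start) in lsbl_by_window]
    vals = [v for v in vals if all(np.isfinite(x) for x in v)]
    if not vals:
        region.assigned_population = "undetermined"
        return region
    mean_a = float(np.mean([v[0] for v in vals]))
    mean_b = float(np.mean([v[1] for v in vals]))
    if mean_a > mean_b:
        region.assigned_population = pops[0]
    elif mean_b > mean_a:
        region.assigned_population = pops[1]
    else:
        region.assigned_population = pops[0]
        region.assignment_tied = True
    return region


def _region_populations(region: CandidateRegion) -> set:
    pops = region.key.unit.split("-")
    if len(pops) == 1:
        return {pops[0]}
    if region.assigned_population and region.assigned_population != "undetermined":
        return {region.assigned_population}
    return set()


def _signature_of(statistic: str) -> str:
    if statistic in LD_STATS:
        return "LD"
    if statistic in SFS_STATS:
        return "SFS"
    return "ProteinChanges"


def collapse_regions(regions: list[CandidateRegion],
                     config: ScanConfig) -> list[JointRegion]:
    """Collapse per-key candidate regions into a joint set by coordinates.

    Regions overlapping by at least 1 bp are unioned; book-ended regions
    stay separate.  Each joint region aggregates one signal per
    contributing key (the member window with the smallest p), the signature
    types of the contributing statistics, and the meta-populations of the
    contributing populations (pair keys via their LSBL-assigned
    population).
    """
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    clusters: list[list[CandidateRegion]] = [[regions[0]]]
    for r in regions[1:]:
        last = clusters[-1]
        cur_end = max(x.end for x in last)
        if r.chrom == last[0].chrom and r.start < cur_end:
            last.append(r)
        else:
            clusters.append([r])
    joint = []
    for cluster in clusters:
        best_by_key: dict[DistributionKey, WindowPValue] = {}
        pops: set = set()
        sigs: set = set()
        for r in cluster:
            best = min(r.members, key=lambda w: (w.p, -abs(w.value)))
            prev = best_by_key.get(r.key)
            if prev is None or best.p < prev.p:
                best_by_key[r.key] = best
            pops |= _region_populations(r)
            sigs.add(_signature_of(r.key.statistic))
        signals = [Signal(k.unit, k.statistic, w.value, w.p)
                   for k, w in sorted(best_by_key.items(),
                                      key=lambda kv: (kv[0].unit, kv[0].statistic))]
        metas = {config.metapopulations[p] for p in pops
                 if p in config.metapopulations}
        joint.append(JointRegion(
            chrom=cluster[0].chrom,
            start=min(r.start for r in cluster),
            end=max(r.end for r in cluster),
            signals=signals, signature_types=sigs,
            metapopulations=metas, assigned_populations=pops))
    return joint


def exclusion_filter(joint: list[JointRegion], blacklist=None,
                     gaps=None) -> list[JointRegion]:
    """Remove regions entirely inside the blacklist or touching any gap.

    ``blacklist`` and ``gaps`` map chromosome label to a (k, 2) interval
    array (a bare array is taken to apply to every chromosome).
    """
    def lookup(track, chrom):
        if track is None:
            return np.zeros((0, 2), dtype=np.int64)
        if isinstance(track, dict):
            return track.get(chrom, np.zeros((0, 2), dtype=np.int64))
        return track

    kept = []
    removed = 0
    for r in joint:
        bl = lookup(blacklist, r.chrom)
        gp = lookup(gaps, r.chrom)
        if len(bl) and contained_in_union(r.start, r.end, bl):
            removed += 1
            continue
        if len(gp) and overlaps_any(r.start, r.end, gp):
            removed += 1
            continue
        kept.append(r)
    log.info("exclusion filter removed %d/%d joint regions", removed, len(joint))
    return kept


def attach_mkt(joint: list[JointRegion], gene_calls: list,
               config: ScanConfig | None = None) -> list[JointRegion]:
    """Attach MKT gene-level selection evidence to overlapping regions.

    ``gene_calls`` is a list of (GeneModel, population, MKTResult); genes
    whose test is a positive call add the ProteinChanges signature, the
    gene id and an alpha signal to every joint region they overlap.
    Meta-population membership is never extended by MKT evidence alone.
    """
    for gene, population, result in gene_calls:
        if not result.selected:
            continue
        g_start = min(s for s, _ in gene.cds)
        g_end = max(e for _, e in gene.cds)
        alpha = (result.alpha_corrected
                 if np.isfinite(result.alpha_corrected) else result.alpha)
        for r in joint:
            if r.chrom != gene.chrom:
                continue
            if min(r.end, g_end) - max(r.start, g_start) > 0:
                r.signature_types.add("ProteinChanges")
                if gene.gene_id not in r.genes:
                    r.genes.append(gene.gene_id)
                r.signals.append(Signal(population, "Alpha", alpha,
                                        result.fisher_p))
    return joint


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    candidates: dict                   # DistributionKey -> list[CandidateRegion]
    joint: list                        # JointRegion
    n_candidate: int = 0
    n_joint_before_exclusion: int = 0


def _lsbl_windows(df: pd.DataFrame, pair: tuple[str, str],
                  pairs: tuple) -> dict:
    """Per-window (branch_A, branch_B) for ``pair`` from the pair F_ST rows.

    Requires a third population forming a trio with the pair among the
    configured pairs; returns an empty dict when no trio exists.
    """
    a, b = pair
    members = {p for ab in pairs for p in ab}
    fst = df[df["statistic"] == "FST"]
    by_unit = {u: g.set_index(["chrom", "start"])["value"]
               for u, g in fst.groupby("unit")}

    def series(x, y):
        return by_unit.get(pair_unit(x, y), by_unit.get(pair_unit(y, x)))

    for c in members - {a, b}:
        s_ab, s_ac, s_bc = series(a, b), series(a, c), series(b, c)
        if s_ab is None or s_ac is None or s_bc is None:
            continue
        out = {}
        for loc in s_ab.index:
            if loc in s_ac.index and loc in s_bc.index:
                la, lb, _ = lsbl(float(s_ab[loc]), float(s_ac[loc]),
                                 float(s_bc[loc]))
                out[loc] = (la, lb)
        return out
    return {}


def run_scan(table: WindowStatTable, config: ScanConfig,
             blacklist=None, gaps=None) -> ScanResult:
    """Full outlier scan of a window-statistic table.

    Filters low-S windows, assigns empirical P-values per distribution key
    (pooling all autosomes per key), calls per-key candidate regions per
    chromosome, LSBL-assigns pair regions, collapses to joint regions and
    applies the blacklist/gap exclusion.
    """
    table = filter_min_segsites(table, config.min_S)
    df = table.df.copy()
    df = df[np.isfinite(df["value"].astype(float))]
    df["chrom_class"] = df["chrom"].map(chrom_class)

    candidates: dict[DistributionKey, list[CandidateRegion]] = {}
    all_regions: list[CandidateRegion] = []
    for (unit, stat, cls), g in df.groupby(["unit", "statistic", "chrom_class"]):
        if stat in LD_STATS and cls == X:
            continue
        if len(g) < 2:
            log.warning("skipping %s/%s/%s: fewer than 2 values",
                        unit, stat, cls)
            continue
        key = DistributionKey(unit, stat, cls)
        p = empirical_pvalues(g["value"].to_numpy(float), TAIL_MODES[stat])
        g = g.assign(p=p)
        key_regions: list[CandidateRegion] = []
        for chrom, gc in g.groupby("chrom"):
            wps = [WindowPValue(chrom, int(r.start), int(r.end), key,
                                float(r.value), float(r.p))
                   for r in gc.itertuples()]
            key_regions.extend(call_regions(wps, config))
        if "-" in unit and key_regions:
            pair = tuple(unit.split("-"))
            lsbl_map = _lsbl_windows(df, pair, config.pairs)
            for r in key_regions:
                assign_pair_population(r, lsbl_map)
        if key_regions:
            candidates[key] = key_regions
            all_regions.extend(key_regions)

    joint = collapse_regions(all_regions, config)
    n_before = len(joint)
    joint = exclusion_filter(joint, blacklist=blacklist, gaps=gaps)
    return ScanResult(candidates=candidates, joint=joint,
                      n_candidate=len(all_regions),
                      n_joint_before_exclusion=n_before)
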