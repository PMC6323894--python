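"""Outlier-scan machinery: key enumeration, empirical P-values, the
seed/extension/gap region caller (vs exhaustive enumeration), LSBL
assignment, collapsing, exclusion and MKT attachment."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.mkt import GeneModel, MKTCounts, MKTResult
from sweepscan.scan import (CandidateRegion, DistributionKey, JointRegion,
                            ScanConfig, Signal, WindowPValue,
                            assign_pair_population, attach_mkt, call_regions,
                            collapse_regions, empirical_pvalues,
                            enumerate_distribution_keys, exclusion_filter,
                            filter_min_segsites)
from sweepscan.stats_table import WindowStatTable


def paper_config(**kw):
    return ScanConfig(**kw)


def simple_config(**kw):
    base = dict(populations=("A", "B"), metapopulations={"A": "EUR", "B": "AFR"},
                pairs=(("A", "B"),))
    base.update(kw)
    return ScanConfig(**base)


# ---------------------------------------------------------------------------
# distribution stratification
# ---------------------------------------------------------------------------

class TestKeys:
    def test_default_counts(self):
        keys = enumerate_distribution_keys(paper_config())
        auto = [k for k in keys if k.chrom_class == "autosome"]
        x = [k for k in keys if k.chrom_class == "X"]
        assert len(auto) == 116
        assert len(x) == 91

    def test_single_population_no_pairs(self):
        cfg = ScanConfig(populations=("CEU",), pairs=(),
                         metapopulations={"CEU": "EUR"})
        keys = enumerate_distribution_keys(cfg)
        assert len([k for k in keys if k.chrom_class == "autosome"]) == 5
        assert len([k for k in keys if k.chrom_class == "X"]) == 4

    def test_ld_keys_never_on_x(self):
        keys = enumerate_distribution_keys(paper_config())
        assert not any(k.chrom_class == "X" and k.statistic in ("iHS", "XPEHH")
                       for k in keys)
        with pytest.raises(ValueError):
            DistributionKey("CEU", "iHS", "X")


class TestMinSegsites:
    def test_boundary(self):
        df = pd.DataFrame({
            "chrom": "1", "start": [0, 10_000, 20_000],
            "end": [10_000, 20_000, 30_000], "unit": "CEU",
            "statistic": "TajimaD", "value": [0.1, 0.2, 0.3],
            "S": [4, 5, 50]})
        out = filter_min_segsites(WindowStatTable(df), 5)
        assert list(out.df["S"]) == [5, 50]   # S=4 dropped, S=5 kept


class TestEmpiricalPvalues:
    def test_one_tailed_maximum(self):
        vals = np.arange(1, 10_001, dtype=float)
        p = empirical_pvalues(vals, "upper")
        assert p[-1] == pytest.approx(1 / 10_000)
        assert p[0] == 1.0

    def test_all_tied(self):
        p = empirical_pvalues(np.ones(50), "two")
        assert np.all(p == 1.0)

    def test_two_tailed_minimum(self):
        vals = np.arange(1, 10_001, dtype=float)
        p = empirical_pvalues(vals, "two")
        assert p[0] == pytest.approx(2 / 10_000)
        assert p[-1] == pytest.approx(2 / 10_000)

    def test_nan_passthrough_and_small_m(self):
        p = empirical_pvalues(np.array([1.0, np.nan, 2.0]), "upper")
        assert np.isnan(p[1]) and np.isfinite(p[0])
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([1.0]), "upper")

    def test_tail_counting_bound(self, rng):
        vals = rng.normal(size=500)
        vals[rng.integers(0, 500, 40)] = 0.0   # ties
        for tail in ("upper", "two"):
            p = empirical_pvalues(vals, tail)
            for q in (0.001, 0.01, 0.05, 0.2):
                assert (p < q).sum() <= int(np.ceil(q * 500)) + 40


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

KEY = DistributionKey("CEU", "TajimaD", "autosome")


def wps(pairs, key=KEY, chrom="1"):
    """[(start, p), ...] -> WindowPValue list with 10-kb windows."""
    return [WindowPValue(chrom, s, s + 10_000, key, 0.0, p) for s, p in pairs]


def oracle_regions(windows, seed_p, extend_p, max_gap):
    """Exhaustive enumeration of maximal valid intervals.

    Every sub-interval of the analyzed-window list is tested against the
    three defining predicates (all members extendable, at least one seed,
    all internal unanalyzed stretches < max_gap); maximal survivors are
    returned as (start, end) spans.
    """
    w = sorted(windows, key=lambda x: x.start)
    n = len(w)
    valid = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i, n):
            members = w[i:j + 1]
            if any(m.p >= extend_p for m in members):
                continue
            if not any(m.p < seed_p for m in members):
                continue
            gaps_ok = all(b.start - a.end < max_gap
                          for a, b in zip(members, members[1:]))
            if gaps_ok:
                valid[i, j] = True
    out = []
    for i in range(n):
        for j in range(i, n):
            if valid[i, j] and not (i > 0 and valid[i - 1, j]) \
                    and not (j < n - 1 and valid[i, j + 1]):
                out.append((w[i].start, w[j].end))
    return sorted(out)


class TestCallRegions:
    CFG = ScanConfig(populations=("CEU",), pairs=())

    def test_hand_traced_example(self):
        regions = call_regions(
            wps([(0, 0.5), (10_000, 0.004), (20_000, 0.0001),
                 (30_000, 0.004), (40_000, 0.5)]), self.CFG)
        assert [(r.start, r.end) for r in regions] == [(10_000, 40_000)]
        assert regions[0].seed_windows == [(20_000, 30_000)]

    def test_no_seed_no_region(self):
        assert call_regions(wps([(0, 0.004), (10_000, 0.004)]), self.CFG) == []

    def test_gap_boundary_20kb_blocks(self):
        # seed at window k; k+1..k+2 unanalyzed (exactly 20 kb); k+3 at 0.004
        regions = call_regions(
            wps([(0, 0.0001), (30_000, 0.004)]), self.CFG)
        assert [(r.start, r.end) for r in regions] == [(0, 10_000)]

    def test_gap_19999_does_not_block(self):
        regions = call_regions(
            [WindowPValue("1", 0, 10_000, KEY, 0.0, 0.0001),
             WindowPValue("1", 29_999, 39_999, KEY, 0.0, 0.004)], self.CFG)
        assert [(r.start, r.end) for r in regions] == [(0, 39_999)]

    def test_above_extend_terminates_even_within_gap(self):
        regions = call_regions(
            wps([(0, 0.0001), (10_000, 0.9), (20_000, 0.0001)]), self.CFG)
        assert [(r.start, r.end) for r in regions] == [(0, 10_000),
                                                       (20_000, 30_000)]

    def test_equivalence_with_enumeration_oracle(self, rng):
        cfg = self.CFG
        for _ in range(150):
            n_slots = int(rng.integers(2, 100))
            analyzed = rng.random(n_slots) > 0.25
            p = 10 ** rng.uniform(-5, 0, size=n_slots)
            windows = [WindowPValue("1", s * 10_000, (s + 1) * 10_000, KEY,
                                    0.0, float(p[s]))
                       for s in range(n_slots) if analyzed[s]]
            got = sorted((r.start, r.end) for r in call_regions(windows, cfg))
            want = oracle_regions(windows, cfg.seed_p, cfg.extend_p,
                                  cfg.max_unanalyzed_gap)
            assert got == want

    def test_region_invariants(self, rng):
        cfg = self.CFG
        for _ in range(30):
            n_slots = int(rng.integers(2, 60))
            p = 10 ** rng.uniform(-5, 0, size=n_slots)
            windows = wps([(s * 10_000, float(p[s])) for s in range(n_slots)])
            for r in call_regions(windows, cfg):
                assert r.seed_windows
                assert all(m.p < cfg.extend_p for m in r.members)


class TestAssignment:
    def region(self, members, key=DistributionKey("A-B", "FST", "autosome")):
        ms = [WindowPValue("1", s, s + 10_000, key, 0.0, 0.001) for s in members]
        return CandidateRegion("1", ms[0].start, ms[-1].end, key,
                               [(ms[0].start, ms[0].end)], ms)

    def test_larger_branch_wins(self):
        r = assign_pair_population(self.region([0]), {("1", 0): (0.3, 0.1)})
        assert r.assigned_population == "A"
        r = assign_pair_population(self.region([0]), {("1", 0): (0.1, 0.3)})
        assert r.assigned_population == "B"

    def test_tie_goes_to_first_and_flagged(self):
        r = assign_pair_population(self.region([0]), {("1", 0): (0.2, 0.2)})
        assert r.assigned_population == "A"
        assert r.assignment_tied

    def test_mean_over_windows(self):
        r = assign_pair_population(
            self.region([0, 10_000]),
            {("1", 0): (0.6, 0.1), ("1", 10_000): (0.0, 0.9)})
        # means: A = 0.3, B = 0.5
        assert r.assigned_population == "B"

    def test_undetermined_without_lsbl(self):
        r = assign_pair_population(self.region([0]), {})
        assert r.assigned_population == "undetermined"


class TestCollapse:
    CFG = simple_config()

    def region(self, start, end, key, p=1e-4):
        m = WindowPValue("1", start, start + 10_000, key, 1.0, p)
        return CandidateRegion("1", start, end, key, [(start, start + 10_000)],
                               [m])

    def test_overlap_union(self):
        k = DistributionKey("A", "TajimaD", "autosome")
        joint = collapse_regions([self.region(0, 30_000, k),
                                  self.region(20_000, 50_000,
                                              DistributionKey("B", "TajimaD",
                                                              "autosome"))],
                                 self.CFG)
        assert len(joint) == 1
        assert (joint[0].start, joint[0].end) == (0, 50_000)
        assert joint[0].metapopulations == {"EUR", "AFR"}

    def test_book_ended_not_merged(self):
        k = DistributionKey("A", "TajimaD", "autosome")
        joint = collapse_regions([self.region(0, 10_000, k),
                                  self.region(10_000, 20_000, k)], self.CFG)
        assert len(joint) == 2

    def test_three_keys_one_joint_region(self):
        keys = [DistributionKey("A", "TajimaD", "autosome"),
                DistributionKey("A", "FayWuH", "autosome"),
                DistributionKey("A", "iHS", "autosome")]
        joint = collapse_regions([self.region(0, 10_000, k) for k in keys],
                                 self.CFG)
        assert len(joint) == 1
        assert len(joint[0].signals) == 3
        assert joint[0].signature_types == {"SFS", "LD"}

    def test_no_overlap_after_collapse(self, rng):
        k = DistributionKey("A", "TajimaD", "autosome")
        regions = [self.region(int(s) * 10_000, (int(s) + int(l)) * 10_000, k)
                   for s, l in zip(rng.integers(0, 50, 30),
                                   rng.integers(1, 5, 30))]
        joint = sorted(collapse_regions(regions, self.CFG),
                       key=lambda r: r.start)
        for a, b in zip(joint, joint[1:]):
            assert a.end <= b.start
        assert all(r.signals for r in joint)


class TestExclusion:
    def joint(self, start, end):
        return JointRegion("1", start, end,
                           [Signal("A", "TajimaD", -2.0, 1e-4)],
                           {"SFS"}, {"EUR"}, {"A"})

    def test_half_inside_blacklist_retained(self):
        kept = exclusion_filter([self.joint(0, 20_000)],
                                blacklist=np.array([[0, 10_000]]))
        assert len(kept) == 1

    def test_fully_inside_blacklist_removed(self):
        kept = exclusion_filter([self.joint(1_000, 9_000)],
                                blacklist=np.array([[0, 10_000]]))
        assert kept == []

    def test_fully_inside_fragmented_blacklist_removed(self):
        kept = exclusion_filter([self.joint(1_000, 9_000)],
                                blacklist=np.array([[0, 5_000], [5_000, 10_000]]))
        assert kept == []

    def test_one_bp_gap_overlap_removed(self):
        kept = exclusion_filter([self.joint(0, 10_001)],
                                gaps=np.array([[10_000, 20_000]]))
        assert kept == []

    def test_book_ended_gap_retained(self):
        kept = exclusion_filter([self.joint(0, 10_000)],
                                gaps=np.array([[10_000, 20_000]]))
        assert len(kept) == 1


class TestAttachMkt:
    def gene(self, start, end):
        length = ((end - start) // 3) * 3
        return GeneModel("g1", "1", [(start, start + length)], "+")

    def result(self, selected=True):
        counts = MKTCounts(Pn=1, Ps=5, Dn=8, Ds=2, Pn_low=1, Pn_high=0,
                           Ps_low=2, Ps_high=3)
        return MKTResult(counts, 0.9, 0.9, 0.01, selected)

    def joint(self, start, end):
        return JointRegion("1", start, end,
                           [Signal("A", "TajimaD", -2.0, 1e-4)],
                           {"SFS"}, {"EUR"}, {"A"})

    def test_overlapping_gene_adds_signature(self):
        j = [self.joint(0, 10_000)]
        attach_mkt(j, [(self.gene(5_000, 6_000), "A", self.result())])
        assert "ProteinChanges" in j[0].signature_types
        assert "g1" in j[0].genes
        assert any(s.statistic == "Alpha" for s in j[0].signals)

    def test_metapopulations_never_extended(self):
        j = [self.joint(0, 10_000)]
        attach_mkt(j, [(self.gene(0, 9_000), "B", self.result())])
        assert j[0].metapopulations == {"EUR"}

    def test_gene_spanning_two_regions_marks_both(self):
        j = [self.joint(0, 10_000), self.joint(20_000, 30_000)]
        attach_mkt(j, [(self.gene(5_000, 25_000), "A", self.result())])
        assert all("ProteinChanges" in r.signature_types for r in j)

    def test_non_selected_gene_ignored(self):
        j = [self.joint(0, 10_000)]
        attach_mkt(j, [(self.gene(0, 9_000), "A", self.result(False))])
        assert j[0].signature_types == {"SFS"}
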