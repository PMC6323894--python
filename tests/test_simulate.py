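"""Wright-Fisher simulator, window-table generator and annotation fixtures."""

import numpy as np
import pytest

from sweepscan.scan import DistributionKey, ScanConfig, call_regions, \
    empirical_pvalues, TAIL_MODES, WindowPValue
from sweepscan.simulate import (SimulationConfig, SweepSpec,
                                simulate_populations, synth_annotations,
                                synth_window_table)
from sweepscan.annotate import pct_overlap, AnnotationTrack


def tiny_config(**kw):
    base = dict(n_populations=2, diploid_size=30, sequence_length=20_000,
                n_sites=80, mu=1e-4, rho=2e-8, split_generations=60, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePopulations:
    def test_no_mutation_all_monomorphic(self):
        res = simulate_populations(tiny_config(mu=0.0, outgroup_divergence=0.0))
        for panel in res.panels.values():
            assert panel.n_sites == 0

    def test_determinism(self):
        r1 = simulate_populations(tiny_config(seed=42))
        r2 = simulate_populations(tiny_config(seed=42))
        for pop in r1.panels:
            assert np.array_equal(r1.panels[pop].alleles, r2.panels[pop].alleles)
            assert np.array_equal(r1.panels[pop].positions,
                                  r2.panels[pop].positions)
        assert np.array_equal(r1.outgroup, r2.outgroup)
        assert r1.reference == r2.reference

    def test_different_seed_differs(self):
        r1 = simulate_populations(tiny_config(seed=1))
        r2 = simulate_populations(tiny_config(seed=2))
        assert r1.reference != r2.reference

    def test_allele_count_conservation(self):
        res = simulate_populations(tiny_config(seed=3))
        for panel in res.panels.values():
            d, ne = panel.derived_counts()
            seg = (d > 0) & (d < ne)
            assert np.all(d[seg] >= 1)
            assert np.all(d[seg] <= panel.n - 1)

    def test_panels_share_coordinates(self):
        res = simulate_populations(tiny_config(seed=4))
        pops = list(res.panels)
        assert np.array_equal(res.panels[pops[0]].positions,
                              res.panels[pops[1]].positions)
        assert len(res.outgroup) == res.panels[pops[0]].n_sites

    def test_sweep_site_out_of_range(self):
        with pytest.raises(ValueError):
            tiny_config(sweep=SweepSpec(0, 10_000, 0.05))

    def test_neutral_sweep_records_truth(self):
        res = simulate_populations(
            tiny_config(sweep=SweepSpec(0, 40, 0.0), seed=5))
        assert len(res.truth.planted_intervals) == 1
        chrom, start, end, pop, mech = res.truth.planted_intervals[0]
        assert mech == "sweep"
        assert pop == "pop0"
        assert 0 <= start < end <= 20_000
        assert 0.0 <= res.truth.sweep_final_frequency[0] <= 1.0

    def test_selection_raises_focal_frequency(self):
        """Selection-vs-neutral contrast: the derived allele at the focal
        site ends higher in the focal population than elsewhere in at
        least 18 of 20 seeds."""
        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_populations=3, diploid_size=100, sequence_length=50_000,
                n_sites=200, mu=1e-4, rho=2e-8, split_generations=130,
                sweep=SweepSpec(0, 100, 0.05), seed=seed)
            res = simulate_populations(cfg)
            site = 100
            col = np.searchsorted(
                res.panels["pop0"].positions, res.grid_positions[site])
            if col == res.panels["pop0"].n_sites or \
                    res.panels["pop0"].positions[col] != res.grid_positions[site]:
                continue  # focal allele absent everywhere
            f0 = res.panels["pop0"].alleles[:, col].mean()
            others = max(res.panels["pop1"].alleles[:, col].mean(),
                         res.panels["pop2"].alleles[:, col].mean())
            wins += f0 > others
        assert wins >= 18

    def test_neutral_pi_self_consistency(self):
        """Mean per-site pi over 50 replicates within 3 SE of the
        simulator's own neutral expectation from 500 replicates."""
        def mean_pi(seed):
            cfg = SimulationConfig(
                n_populations=1, diploid_size=25, sequence_length=10_000,
                n_sites=50, mu=2e-4, rho=0.0, split_generations=10,
                outgroup_divergence=0.0, seed=seed)
            res = simulate_populations(cfg)
            panel = res.panels["pop0"]
            if panel.n_sites == 0:
                return 0.0
            d, ne = panel.derived_counts()
            pi = 2.0 * d * (ne - d) / (ne * (ne - 1))
            return float(pi.sum()) / cfg.n_sites

        ref = np.array([mean_pi(10_000 + i) for i in range(500)])
        obs = np.array([mean_pi(20_000 + i) for i in range(50)])
        se = np.sqrt(ref.var(ddof=1) / 50)
        assert abs(obs.mean() - ref.mean()) <= 3 * se


class TestSynthWindowTable:
    KEY = DistributionKey("CEU", "FST", "autosome")
    KEY2 = DistributionKey("CEU", "TajimaD", "autosome")

    def test_null_quantiles(self):
        table, _ = synth_window_table(1000, [self.KEY], seed=1,
                                      low_s_fraction=0.0)
        vals = table.df["value"].to_numpy()
        assert len(vals) == 1000
        # continuous iid draws: expected count below the 0.0005 quantile
        # of the standard normal is ~0.5
        from scipy import stats
        assert (vals < stats.norm.ppf(0.0005)).sum() <= 4

    def test_planted_extreme_is_most_extreme(self):
        table, truth = synth_window_table(
            1000, [self.KEY], planted=[(5, self.KEY, 0.0001)], seed=2)
        df = table.df
        # upper-tail key: the planted window holds the maximum
        assert df.loc[df["value"].idxmax(), "start"] == 5 * 10_000
        assert truth.planted_intervals[0][4] == "outlier_SFS"

    def test_planted_pvalue_matches_request(self):
        table, _ = synth_window_table(
            10_000, [self.KEY, self.KEY2],
            planted=[(7, self.KEY, 0.004), (9, self.KEY2, 0.004)], seed=3,
            low_s_fraction=0.0)
        for key, w in ((self.KEY, 7), (self.KEY2, 9)):
            g = table.df[table.df["statistic"] == key.statistic]
            p = empirical_pvalues(g["value"].to_numpy(), TAIL_MODES[key.statistic])
            got = p[(g["start"] == w * 10_000).to_numpy()][0]
            assert got == pytest.approx(0.004, abs=1e-9)

    def test_adjacent_plants_yield_one_region(self):
        """Seed at 0.0001 flanked by 0.004 plants -> exactly one region
        covering the three windows under the default caller thresholds."""
        key = self.KEY
        table, _ = synth_window_table(
            10_000, [key],
            planted=[(4, key, 0.004), (5, key, 0.0001), (6, key, 0.004)],
            seed=4, low_s_fraction=0.0)
        g = table.df
        p = empirical_pvalues(g["value"].to_numpy(), "upper")
        wps = [WindowPValue("1", int(r.start), int(r.end), key,
                            float(r.value), float(pp))
               for r, pp in zip(g.itertuples(), p)]
        regions = call_regions(wps, ScanConfig(populations=("CEU",), pairs=()))
        covering = [r for r in regions if r.start <= 40_000 and r.end >= 70_000]
        assert len(covering) == 1
        assert covering[0].start == 40_000 and covering[0].end == 70_000

    def test_duplicate_planting_rejected(self):
        with pytest.raises(ValueError):
            synth_window_table(100, [self.KEY],
                               planted=[(1, self.KEY, 0.01),
                                        ((1, 2), self.KEY, 0.02)])

    def test_missing_windows_and_low_s(self):
        table, _ = synth_window_table(100, [self.KEY], seed=5,
                                      low_s_fraction=0.1,
                                      missing_windows=[3, 4])
        starts = set(table.df["start"])
        assert 30_000 not in starts and 40_000 not in starts
        assert (table.df["S"] < 5).sum() == 10

    def test_determinism(self):
        t1, _ = synth_window_table(200, [self.KEY], seed=6)
        t2, _ = synth_window_table(200, [self.KEY], seed=6)
        assert t1.df.equals(t2.df)


class TestSynthAnnotations:
    def test_zero_density_empty(self):
        bundle = synth_annotations(
            1_000_000, densities={k: 0.0 for k in
                                  ["cpg_islands", "vista_enhancers", "tfbs",
                                   "oreganno", "phylop", "gerp", "phastcons",
                                   "invfest", "dgv", "repeatmasker", "segdup",
                                   "trf", "archaic", "blacklist", "gaps",
                                   "publications", "genes"]}, seed=1)
        assert all(len(t.intervals) == 0 for t in bundle.tracks.values())
        assert len(bundle.gaps) == 0 and len(bundle.blacklist) == 0
        for t in bundle.tracks.values():
            assert pct_overlap(0, 10_000, t) == 0.0

    def test_full_coverage_track(self):
        track = AnnotationTrack("archaic", "introgression",
                                np.array([[0, 1_000_000]]))
        assert pct_overlap(123, 456_789, track) == 100.0

    def test_gaps_blacklist_disjoint(self):
        bundle = synth_annotations(2_000_000, seed=3)
        for gs, ge in bundle.gaps:
            for bs, be in bundle.blacklist:
                assert min(ge, be) - max(gs, bs) <= 0

    def test_gene_models_valid(self):
        bundle = synth_annotations(2_000_000, seed=4)
        assert bundle.gene_models
        for g in bundle.gene_models:
            assert g.cds_length % 3 == 0
            assert g.strand in "+-"

    def test_determinism_byte_identical_bed(self, tmp_path):
        from sweepscan.io import write_bed
        paths = []
        for k in (0, 1):
            bundle = synth_annotations(500_000, seed=9)
            path = tmp_path / f"bl{k}.bed"
            write_bed(path, "1", bundle.blacklist)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            synth_annotations(0)
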