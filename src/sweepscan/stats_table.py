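"""The per-window statistic table — the pipeline's tabular intermediate.

One row per (10-kb window, population-or-pair, statistic) with the value and
the window's segregating-site count S.  Single-population statistics are
iHS, Tajima's D, Fu & Li's D and F and Fay & Wu's H; pair statistics are
XP-EHH and F_ST.  X-class windows never carry iHS or XP-EHH rows.  Pair
rows record S = min over the two member populations, so the downstream
minimum-S filter enforces the rule that both members must pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehh import ihs_scores, xpehh_scores
from .fst import fst_window
from .panel import HaplotypePanel
from .sfs import fay_wu_h, fu_li_tests, site_summaries, tajimas_d
from .windows import AUTOSOME, GenomicWindow, windowize_scores, X

SINGLE_POP_STATS = ("iHS", "TajimaD", "FuLiD", "FuLiF", "FayWuH")
PAIR_STATS = ("XPEHH", "FST")
LD_STATS = frozenset({"iHS", "XPEHH"})
SFS_STATS = frozenset({"TajimaD", "FuLiD", "FuLiF", "FayWuH", "FST"})
ALL_STATS = SINGLE_POP_STATS + PAIR_STATS

COLUMNS = ["chrom", "start", "end", "unit", "statistic", "value", "S"]


def pair_unit(pop_a: str, pop_b: str) -> str:
    return f"{pop_a}-{pop_b}"


@dataclass
class WindowStatTable:
    """Thin wrapper over a DataFrame with the canonical column schema."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"window table missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["chrom", "start", "unit", "statistic"])
        if dup.any():
            raise ValueError("duplicate (window, unit, statistic) rows")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "WindowStatTable":
        if not rows:
            return cls(pd.DataFrame(columns=COLUMNS))
        return cls(pd.DataFrame(rows))


@dataclass
class StatsConfig:
    window_size: int = 10_000
    statistics: tuple[str, ...] = ALL_STATS
    maf_min: float = 0.05
    ihs_bins: int = 20
    truncation: float = 0.05
    max_gap_bp: int = 200_000
    windowize_mode: str = "mean_abs"


def build_window_stat_table(panels: dict[str, HaplotypePanel],
                            pairs: list[tuple[str, str]],
                            windows: list[GenomicWindow],
                            config: StatsConfig | None = None) -> WindowStatTable:
    """Compute every computable (window, unit, statistic) row.

    ``panels`` maps population label to its panel (shared coordinates are
    required for pair statistics); ``pairs`` are ordered population pairs.
    Values that are undefined (e.g. S = 0, or no scored SNP in the window)
    are emitted as NaN rows so that coverage stays explicit.
    """
    cfg = config or StatsConfig()
    rows: list[dict] = []
    if not panels:
        return WindowStatTable.from_rows(rows)

    summaries: dict[str, list] = {}
    for pop, panel in panels.items():
        summaries[pop] = [site_summaries(panel, w) for w in windows]

    stats = set(cfg.statistics)

    for pop, panel in panels.items():
        per_window_ihs = None
        if "iHS" in stats and any(w.chrom_class == AUTOSOME for w in windows):
            scores = ihs_scores(panel, maf_min=cfg.maf_min, n_bins=cfg.ihs_bins,
                                truncation=cfg.truncation,
                                max_gap_bp=cfg.max_gap_bp)
            per_window_ihs = windowize_scores(panel.positions, scores, windows,
                                              mode=cfg.windowize_mode)
        for k, w in enumerate(windows):
            summ = summaries[pop][k]
            base = {"chrom": w.chrom, "start": w.start, "end": w.end,
                    "unit": pop, "S": summ.S}
            if "TajimaD" in stats:
                rows.append({**base, "statistic": "TajimaD",
                             "value": tajimas_d(summ)})
            if {"FuLiD", "FuLiF"} & stats:
                d, f = fu_li_tests(summ)
                if "FuLiD" in stats:
                    rows.append({**base, "statistic": "FuLiD", "value": d})
                if "FuLiF" in stats:
                    rows.append({**base, "statistic": "FuLiF", "value": f})
            if "FayWuH" in stats:
                rows.append({**base, "statistic": "FayWuH",
                             "value": fay_wu_h(summ)})
            if "iHS" in stats and w.chrom_class != X:
                rows.append({**base, "statistic": "iHS",
                             "value": float(per_window_ihs[k])
                             if per_window_ihs is not None else np.nan})

    for pop_a, pop_b in pairs:
        pa, pb = panels[pop_a], panels[pop_b]
        unit = pair_unit(pop_a, pop_b)
        per_window_xp = None
        if "XPEHH" in stats and any(w.chrom_class == AUTOSOME for w in windows):
            scores = xpehh_scores(pa, pb, truncation=cfg.truncation,
                                  max_gap_bp=cfg.max_gap_bp)
            per_window_xp = windowize_scores(pa.positions, scores, windows,
                                             mode=cfg.windowize_mode)
        for k, w in enumerate(windows):
            s_min = min(summaries[pop_a][k].S, summaries[pop_b][k].S)
            base = {"chrom": w.chrom, "start": w.start, "end": w.end,
                    "unit": unit, "S": s_min}
            if "FST" in stats:
                sl_a = pa.site_slice(w.start, w.end)
                da, na = pa.derived_counts()
                db, nb = pb.derived_counts()
                val = fst_window((da[sl_a], na[sl_a]), (db[sl_a], nb[sl_a]))
                rows.append({**base, "statistic": "FST", "value": val})
            if "XPEHH" in stats and w.chrom_class != X:
                rows.append({**base, "statistic": "XPEHH",
                             "value": float(per_window_xp[k])
                             if per_window_xp is not None else np.nan})

    return WindowStatTable.from_rows(rows)
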