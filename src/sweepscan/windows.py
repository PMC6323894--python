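"""Non-overlapping genomic windows and SNP-score windowization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WINDOW_SIZE = 10_000

AUTOSOME = "autosome"
X = "X"

#: chromosome labels treated as X-class
_X_NAMES = {"X", "chrX", "x", "23"}


def chrom_class(chrom: str) -> str:
    return X if str(chrom) in _X_NAMES else AUTOSOME


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int          # 0-based, inclusive
    end: int            # exclusive
    chrom_class: str = AUTOSOME

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def window_partition(chrom_length: int, window_size: int = WINDOW_SIZE,
                     chrom: str = "1") -> list[GenomicWindow]:
    """Tile ``[0, chrom_length)`` with consecutive non-overlapping windows.

    The final partial window is kept iff its length is at least half the
    window size; shorter remainders are dropped.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    cls = chrom_class(chrom)
    full = chrom_length // window_size
    out = [GenomicWindow(chrom, i * window_size, (i + 1) * window_size, cls)
           for i in range(full)]
    rem = chrom_length - full * window_size
    if rem * 2 >= window_size and rem > 0:
        out.append(GenomicWindow(chrom, full * window_size, chrom_length, cls))
    return out


def windowize_scores(positions: np.ndarray, scores: np.ndarray,
                     windows: list[GenomicWindow],
                     mode: str = "mean_abs") -> np.ndarray:
    """Aggregate per-SNP scores into per-window values.

    ``mode`` is ``mean_abs`` (default) or ``max_abs``; NaN scores are
    ignored.  Windows with no scored site yield NaN.
    """
    if mode not in ("mean_abs", "max_abs"):
        raise ValueError(f"unknown windowization mode {mode!r}")
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    positions, scores = positions[ok], np.abs(scores[ok])
    out = np.full(len(windows), np.nan)
    for k, w in enumerate(windows):
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="left")
        if hi > lo:
            seg = scores[lo:hi]
            out[k] = seg.max() if mode == "max_abs" else seg.mean()
    return out
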