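"""Structural and functional annotation of candidate regions.

Fifteen per-region metrics in five categories, each computed from an
interval track by one of four styles:

* percentage of region bases overlapping the track's interval union
  (mappability as its complement against the blacklist; phastCons
  elements; the five structural-variation tracks; archaic introgression);
* element count plus the number of SNPs inside the overlapping elements
  (the four regulation tracks);
* percentage of bases whose per-base score exceeds a threshold, strictly
  (PhyloP and GERP constrained bases, threshold 2);
* distance in Mb to the closest assembly gap.

Publication intervals are cross-referenced by any-overlap and reported as
deduplicated identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import as_intervals, distance_bp, intersect_length, union

CONSTRAINT_THRESHOLD = 2.0

CATEGORIES = ("sequencing", "regulation", "comparative", "structural",
              "introgression", "publications")

#: metric name -> (category, style); style in {pct, inverse_pct, count,
#: constrained, distance}
METRIC_REGISTRY = {
    "mappability": ("sequencing", "inverse_pct"),        # vs blacklist
    "distance_to_gap": ("sequencing", "distance"),       # vs gaps
    "cpg_islands": ("regulation", "count"),
    "vista_enhancers": ("regulation", "count"),
    "tfbs": ("regulation", "count"),
    "oreganno": ("regulation", "count"),
    "phylop": ("comparative", "constrained"),
    "gerp": ("comparative", "constrained"),
    "phastcons": ("comparative", "pct"),
    "invfest": ("structural", "pct"),
    "dgv": ("structural", "pct"),
    "repeatmasker": ("structural", "pct"),
    "segdup": ("structural", "pct"),
    "trf": ("structural", "pct"),
    "archaic": ("introgression", "pct"),
}


@dataclass
class AnnotationTrack:
    name: str
    category: str
    intervals: np.ndarray                  # (k, 2) sorted, 0-based half-open
    scores: np.ndarray | None = None       # per-interval score (score tracks)
    ids: list | None = None                # per-interval identifier

    def __post_init__(self):
        order = np.argsort(np.asarray(self.intervals, dtype=np.int64)[:, 0],
                           kind="stable") if len(self.intervals) else []
        self.intervals = as_intervals(self.intervals)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)[order]
        if self.ids is not None:
            self.ids = [self.ids[i] for i in order]
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown track category {self.category!r}")


@dataclass
class AnnotationBundle:
    """Everything the annotation stage consumes, with known ground truth."""

    gene_models: list = field(default_factory=list)
    tracks: dict = field(default_factory=dict)        # name -> AnnotationTrack
    gaps: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    blacklist: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    publications: AnnotationTrack | None = None

    def __post_init__(self):
        self.gaps = as_intervals(self.gaps)
        self.blacklist = as_intervals(self.blacklist)


@dataclass
class RegionAnnotation:
    chrom: str
    start: int
    end: int
    pct_metrics: dict = field(default_factory=dict)       # name -> percentage
    count_metrics: dict = field(default_factory=dict)     # name -> (count, snps)
    distance_to_gap: float | None = None                  # Mb
    publications: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# primitive metrics
# ---------------------------------------------------------------------------

def pct_overlap(start: int, end: int, track: AnnotationTrack) -> float:
    """Percentage of region bases covered by the union of track intervals."""
    if end <= start:
        raise ValueError("zero-length region")
    return 100.0 * intersect_length(start, end, track.intervals) / (end - start)


def count_elements_and_snps(start: int, end: int, track: AnnotationTrack,
                            snp_positions) -> tuple[int, int]:
    """(elements overlapping the region, SNPs inside those elements).

    Elements are counted on any overlap (half-open: book-ended elements
    are excluded); the SNP count covers the full extent of every
    overlapping element, not only its intersection with the region.
    """
    snp_positions = np.sort(np.asarray(snp_positions, dtype=np.int64))
    count = snps = 0
    hit = []
    for s, e in track.intervals:
        if min(end, e) - max(start, s) > 0:
            count += 1
            hit.append((s, e))
    for s, e in union(hit) if hit else []:
        lo = np.searchsorted(snp_positions, s, side="left")
        hi = np.searchsorted(snp_positions, e, side="left")
        snps += int(hi - lo)
    return count, snps


def distance_to_closest_gap(start: int, end: int, gaps) -> float | None:
    """Distance in Mb to the closest gap; 0 on overlap, None with no gaps."""
    d = distance_bp(start, end, gaps)
    return None if d is None else d / 1e6


def constrained_fraction(start: int, end: int, track: AnnotationTrack,
                         threshold: float = CONSTRAINT_THRESHOLD) -> float:
    """Percentage of region bases with per-base score strictly > threshold.

    The track's intervals carry scores (fixed- or variable-step);
    uncovered bases count as unconstrained.
    """
    if end <= start:
        raise ValueError("zero-length region")
    if track.scores is None:
        raise ValueError(f"track {track.name!r} has no scores")
    passing = [iv for iv, sc in zip(track.intervals, track.scores)
               if sc > threshold]
    covered = intersect_length(start, end, passing) if passing else 0
    return 100.0 * covered / (end - start)


def crossref_publications(start: int, end: int,
                          track: AnnotationTrack) -> list:
    """Deduplicated identifiers of publication intervals overlapping >= 1 bp."""
    if track is None or track.ids is None:
        return []
    seen, out = set(), []
    for (s, e), ident in zip(track.intervals, track.ids):
        if min(end, e) - max(start, s) > 0 and ident not in seen:
            seen.add(ident)
            out.append(ident)
    return out


# ---------------------------------------------------------------------------
# the 15-metric report
# ---------------------------------------------------------------------------

def annotate_region(chrom: str, start: int, end: int,
                    bundle: AnnotationBundle,
                    snp_positions=()) -> RegionAnnotation:
    """All fifteen metrics for one region, each in its registry style.

    A metric whose track is absent from the bundle is left missing, not
    set to zero.
    """
    ann = RegionAnnotation(chrom=chrom, start=start, end=end)
    for name, (category, style) in METRIC_REGISTRY.items():
        if style == "distance":
            if len(bundle.gaps):
                ann.distance_to_gap = distance_to_closest_gap(
                    start, end, bundle.gaps)
            continue
        if style == "inverse_pct":
            # an absent/empty blacklist leaves the metric missing rather
            # than asserting perfect mappability
            if len(bundle.blacklist):
                bl = AnnotationTrack(name="blacklist", category="sequencing",
                                     intervals=bundle.blacklist)
                ann.pct_metrics[name] = 100.0 - pct_overlap(start, end, bl)
            continue
        track = bundle.tracks.get(name)
        if track is None:
            continue
        if style == "pct":
            ann.pct_metrics[name] = pct_overlap(start, end, track)
        elif style == "constrained":
            ann.pct_metrics[name] = constrained_fraction(start, end, track)
        elif style == "count":
            ann.count_metrics[name] = count_elements_and_snps(
                start, end, track, snp_positions)
    if bundle.publications is not None:
        ann.publications = crossref_publications(start, end,
                                                 bundle.publications)
    return ann
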