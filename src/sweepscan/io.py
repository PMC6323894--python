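"""Readers and writers for the pipeline's on-disk formats.

VCF (phased GT, INFO/AA ancestral allele) via cyvcf2 for reading and plain
text for writing; genetic maps and window-statistic tables as TSV; interval
tracks as BED; gene models as GFF3 (read through gffutils); outgroup
sequences as FASTA (Biopython).  Coordinates are 0-based half-open
everywhere except inside VCF records (1-based, per the standard).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mkt import GeneModel
from .panel import HaplotypePanel
from .scan import JointRegion
from .stats_table import COLUMNS, LD_STATS, WindowStatTable
from .windows import X, chrom_class

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(panels: dict, path, contig_length: int | None = None) -> None:
    """Write the populations' phased haplotypes as one multi-sample VCF.

    All panels must share coordinates; consecutive haplotype pairs form
    diploid samples named ``<pop>_<index>``.  INFO/AA carries the ancestral
    allele; genotypes are phased ("|").
    """
    pops = list(panels)
    first = panels[pops[0]]
    for p in pops[1:]:
        if not np.array_equal(panels[p].positions, first.positions):
            raise ValueError("panels must share site coordinates")
    samples = []
    for pop in pops:
        if panels[pop].n % 2:
            raise ValueError("odd haplotype count cannot form diploids")
        samples += [f"{pop}_{k}" for k in range(panels[pop].n // 2)]
    chrom = first.chrom
    length = contig_length or int(first.positions[-1]) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(first.n_sites):
            ref = first.ref_alleles[j] if first.ref_alleles is not None else "A"
            alt = first.alt_alleles[j] if first.alt_alleles is not None else "T"
            anc_flag = int(first.ancestral_is_ref[j])
            aa = ref if anc_flag == 1 else (alt if anc_flag == 0 else ".")
            gts = []
            for pop in pops:
                al = panels[pop].alleles[:, j]
                for k in range(0, len(al), 2):
                    a0 = "." if al[k] < 0 else str(int(al[k]))
                    a1 = "." if al[k + 1] < 0 else str(int(al[k + 1]))
                    gts.append(f"{a0}|{a1}")
            fh.write(f"{chrom}\t{int(first.positions[j]) + 1}\t.\t{ref}\t{alt}"
                     f"\t.\tPASS\tAA={aa}\tGT\t" + "\t".join(gts) + "\n")


def read_haplotypes(vcf_path, popmap: dict, map_path=None) -> dict:
    """Read phased biallelic SNVs into one panel per population.

    ``popmap`` maps sample name to population label.  Multiallelic records
    are skipped (counted in the log); an unphased genotype is an error
    naming the record; a missing INFO/AA leaves the site unpolarized with
    a warning.  With ``map_path`` set, genetic positions are interpolated
    from the genetic map.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise ValueError(f"samples not in population map: {unknown}")
    cols = {pop: [s_i for s_i, s in enumerate(samples) if popmap[s] == pop]
            for pop in dict.fromkeys(popmap.values())}
    positions, refs, alts, anc = [], [], [], []
    haps = {pop: [] for pop in cols}
    n_multi = n_unpolarized = 0
    chrom = None
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        chrom = var.CHROM
        aa = var.INFO.get("AA")
        if aa is None or aa.upper() not in (var.REF.upper(), var.ALT[0].upper()):
            anc.append(-1)
            if aa is None:
                n_unpolarized += 1
        else:
            anc.append(1 if aa.upper() == var.REF.upper() else 0)
        positions.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gts = var.genotypes  # [a0, a1, phased] per sample
        for pop, idxs in cols.items():
            row = []
            for si in idxs:
                a0, a1, phased = gts[si][0], gts[si][1], gts[si][2]
                if not phased and a0 >= 0 and a1 >= 0 and a0 != a1:
                    raise ValueError(
                        f"unphased genotype at {var.CHROM}:{var.POS} "
                        f"sample {samples[si]}")
                row += [a0 if a0 >= 0 else -1, a1 if a1 >= 0 else -1]
            haps[pop].append(row)
    if n_multi:
        log.info("skipped %d non-biallelic/non-SNV records", n_multi)
    if n_unpolarized:
        log.warning("%d sites without INFO/AA left unpolarized", n_unpolarized)
    positions = np.asarray(positions, dtype=np.int64)
    gpos = None
    if map_path is not None:
        gmap = read_genetic_map(map_path)
        gpos = np.interp(positions, gmap["pos"].to_numpy(),
                         gmap["cM"].to_numpy())
    panels = {}
    for pop, rows in haps.items():
        panels[pop] = HaplotypePanel(
            alleles=np.asarray(rows, dtype=np.int8).T,
            positions=positions, population=pop, chrom=chrom or "1",
            genetic_positions=gpos,
            ancestral_is_ref=np.asarray(anc, dtype=np.int8),
            ref_alleles=np.asarray(refs), alt_alleles=np.asarray(alts))
    return panels


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def write_genetic_map(chrom: str, positions, cm, path) -> None:
    pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
                  "cM": np.asarray(cm, dtype=float)}) \
        .to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "pos", "cM"]
    if list(df.columns) != expected:
        raise ValueError(f"genetic map must have columns {expected}")
    return df


# ---------------------------------------------------------------------------
# window-statistic table
# ---------------------------------------------------------------------------

def write_window_table(table: WindowStatTable, path) -> None:
    df = table.df.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_window_table(path) -> WindowStatTable:
    """Read a TSV window table; "NA" is missing; duplicates and LD rows on
    the X are rejected; malformed lines raise with the line number."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"],
                         keep_default_na=False,
                         dtype={"chrom": str, "unit": str, "statistic": str})
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed window table {path}: {err}") from err
    if list(df.columns) != COLUMNS:
        raise ValueError(f"window table must have columns {COLUMNS}")
    for ln, row in enumerate(df.itertuples(), start=2):
        if not (isinstance(row.start, (int, np.integer)) or
                float(row.start).is_integer()):
            raise ValueError(f"{path}:{ln}: non-integer window start")
        if row.statistic in LD_STATS and chrom_class(row.chrom) == X:
            raise ValueError(f"{path}:{ln}: {row.statistic} row on the X")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["S"] = df["S"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return WindowStatTable(df)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(path, chrom, intervals, names=None, scores=None) -> None:
    ivs = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(ivs):
            row = [str(chrom), str(int(s)), str(int(e))]
            if names is not None:
                row.append(str(names[i]))
                if scores is not None:
                    row.append(str(scores[i]))
            fh.write("\t".join(row) + "\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df.columns = names[: df.shape[1]]
    return df


def bed_intervals_by_chrom(path) -> dict:
    df = read_bed(path)
    return {chrom: g[["start", "end"]].to_numpy(dtype=np.int64)
            for chrom, g in df.groupby("chrom")}


def write_truth_bed(truth, path) -> None:
    """Planted truth intervals as BED with name "mechanism:population"."""
    with open(path, "w") as fh:
        for chrom, s, e, unit, mech in truth.planted_intervals:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{mech}:{unit}\n")


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def write_gff3(genes: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(f"{g.chrom}\t.\tgene\t{start + 1}\t{end}\t.\t{g.strand}"
                     f"\t.\tID={g.gene_id}\n")
            phase = 0
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            for s, e in cds:
                fh.write(f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}"
                         f"\t{phase}\tParent={g.gene_id}\n")
                phase = (3 - ((e - s) - phase) % 3) % 3
    # phase bookkeeping follows the GFF3 spec: bases to the next codon start


def read_gff3_genes(path) -> list:
    """Gene models (CDS intervals per gene) from a GFF3 file."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except EmptyInputError:
        return []
    genes = []
    for gene in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        if not cds:
            continue
        genes.append(GeneModel(gene_id=gene.id, chrom=gene.seqid,
                               cds=sorted(cds), strand=gene.strand))
    return genes


def write_fasta(name: str, sequence: str, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")],
                str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# region reports
# ---------------------------------------------------------------------------

def bed_score(min_p: float) -> int:
    """Phred-style region score: round(-10 log10 p), capped at 1000."""
    if not (min_p > 0):
        return 1000
    return min(1000, int(round(-10.0 * math.log10(min_p))))


def _region_record(r: JointRegion, annotation=None) -> dict:
    rec = {
        "chrom": r.chrom, "start": int(r.start), "end": int(r.end),
        "signals": [{"unit": s.unit, "statistic": s.statistic,
                     "value": None if not np.isfinite(s.value) else float(s.value),
                     "p": float(s.p)} for s in r.signals],
        "signature_types": sorted(r.signature_types),
        "metapopulations": sorted(r.metapopulations),
        "populations": sorted(r.assigned_populations),
        "genes": list(r.genes),
        "sources": list(r.sources),
    }
    if annotation is not None:
        rec["annotation"] = {
            "pct": {k: round(v, 6) for k, v in
                    sorted(annotation.pct_metrics.items())},
            "counts": {k: list(v) for k, v in
                       sorted(annotation.count_metrics.items())},
            "distance_to_gap_mb": annotation.distance_to_gap,
            "publications": list(annotation.publications),
        }
    return rec


def write_regions(joint: list, outdir, annotations: list | None = None,
                  prefix: str = "regions") -> None:
    """Joint regions as BED (score = capped phred of min p), TSV and JSON.

    Field order is deterministic; identical inputs give byte-identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{prefix}.bed", "w") as fh:
        for r in joint:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{','.join(sorted(r.signature_types))}\t"
                     f"{bed_score(r.min_p)}\n")
    rows = []
    for r in joint:
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "signals": ";".join(f"{s.unit}:{s.statistic}={s.value:.4g}"
                                f"(p={s.p:.3g})" for s in r.signals),
            "signatures": ",".join(sorted(r.signature_types)),
            "metapopulations": ",".join(sorted(r.metapopulations)),
            "populations": ",".join(sorted(r.assigned_populations)),
            "genes": ",".join(r.genes),
            "sources": ",".join(r.sources),
        })
    pd.DataFrame(rows, columns=["chrom", "start", "end", "signals",
                                "signatures", "metapopulations",
                                "populations", "genes", "sources"]) \
        .to_csv(outdir / f"{prefix}.tsv", sep="\t", index=False)
    ann = annotations or [None] * len(joint)
    report = [_region_record(r, a) for r, a in zip(joint, ann)]
    with open(outdir / f"{prefix}.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# annotation bundles
# ---------------------------------------------------------------------------

def write_annotation_bundle(bundle, outdir) -> None:
    """Serialize an AnnotationBundle as BED tracks + GFF3 gene models.

    Score tracks (per-interval scores) use BED5 with the score column;
    publications use BED4 with the identifier as name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = "1"
    for name, track in bundle.tracks.items():
        if track.scores is not None:
            write_bed(outdir / f"{name}.bed", chrom, track.intervals,
                      names=["."] * len(track.intervals),
                      scores=[f"{s:.6g}" for s in track.scores])
        else:
            write_bed(outdir / f"{name}.bed", chrom, track.intervals)
    write_bed(outdir / "blacklist.bed", chrom, bundle.blacklist)
    write_bed(outdir / "gaps.bed", chrom, bundle.gaps)
    if bundle.publications is not None:
        write_bed(outdir / "publications.bed", chrom,
                  bundle.publications.intervals,
                  names=bundle.publications.ids)
    write_gff3(bundle.gene_models, outdir / "genes.gff3")


def read_annotation_bundle(indir):
    """Read back a bundle written by :func:`write_annotation_bundle`."""
    from .annotate import METRIC_REGISTRY, AnnotationBundle, AnnotationTrack

    indir = Path(indir)
    empty = np.zeros((0, 2), dtype=np.int64)

    def ivs_of(path):
        if not path.exists() or path.stat().st_size == 0:
            return None
        return read_bed(path)

    tracks = {}
    for name, (category, style) in METRIC_REGISTRY.items():
        if style in ("distance", "inverse_pct"):
            continue
        df = ivs_of(indir / f"{name}.bed")
        if df is None:
            tracks[name] = AnnotationTrack(
                name=name, category=category, intervals=empty,
                scores=np.zeros(0) if style == "constrained" else None)
            continue
        ivs = df[["start", "end"]].to_numpy(dtype=np.int64)
        scores = df["score"].to_numpy(dtype=float) \
            if style == "constrained" and "score" in df.columns else None
        tracks[name] = AnnotationTrack(name=name, category=category,
                                       intervals=ivs, scores=scores)
    df = ivs_of(indir / "blacklist.bed")
    blacklist = df[["start", "end"]].to_numpy(np.int64) if df is not None else empty
    df = ivs_of(indir / "gaps.bed")
    gaps = df[["start", "end"]].to_numpy(np.int64) if df is not None else empty
    df = ivs_of(indir / "publications.bed")
    if df is not None:
        publications = AnnotationTrack(
            name="publications", category="publications",
            intervals=df[["start", "end"]].to_numpy(np.int64),
            ids=list(df["name"]))
    else:
        publications = AnnotationTrack(name="publications",
                                       category="publications",
                                       intervals=empty, ids=[])
    genes = read_gff3_genes(indir / "genes.gff3") \
        if (indir / "genes.gff3").exists() else []
    return AnnotationBundle(gene_models=genes, tracks=tracks, gaps=gaps,
                            blacklist=blacklist, publications=publications)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
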