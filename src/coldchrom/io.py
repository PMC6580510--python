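"""Readers and writers for the standard interchange formats.

Internal coordinates are 0-based half-open (BED convention); GFF3 I/O
converts to/from 1-based closed coordinates at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, GenomicInterval
from .bivalent import FragmentTrack
from .dhs import DHS, CutSiteTrack, rescale_score


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- chrom sizes

def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, s in chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")


# ------------------------------------------------------------------- cut BED

def write_cut_bed(track: CutSiteTrack, path) -> None:
    """One 6-column BED record per cut (1-bp interval)."""
    name = track.sample or "cut"
    with open(path, "w") as fh:
        for chrom in sorted(track.cuts):
            for p in track.cuts[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{name}\t0\t+\n")


def _read_table(path, usecols, names):
    try:
        return pd.read_csv(path, sep="\t", header=None, usecols=usecols,
                           names=names, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)


def read_cut_bed(path, chrom_sizes: dict[str, int], sample: str = "") -> CutSiteTrack:
    df = _read_table(path, [0, 1], ["chrom", "start"])
    cuts = {c: sub["start"].to_numpy(np.int64)
            for c, sub in df.groupby("chrom")}
    return CutSiteTrack(cuts, chrom_sizes, sample=sample)


# --------------------------------------------------------------------- BEDPE

def write_fragments_bedpe(track: FragmentTrack, path) -> None:
    """Fragments as BEDPE: the two records are the fragment halves."""
    name = track.channel or "frag"
    with open(path, "w") as fh:
        for chrom in sorted(track.fragments):
            for s, e in track.fragments[chrom]:
                mid = (s + e) // 2
                fh.write(f"{chrom}\t{s}\t{mid}\t{chrom}\t{mid}\t{e}"
                         f"\t{name}\t0\t+\t-\n")


def read_fragments_bedpe(path, chrom_sizes: dict[str, int],
                         channel: str = "", condition: str = "") -> FragmentTrack:
    df = _read_table(path, [0, 1, 5], ["chrom", "start", "end"])
    frags = {c: sub[["start", "end"]].to_numpy(np.int64)
             for c, sub in df.groupby("chrom")}
    return FragmentTrack(frags, chrom_sizes, channel=channel, condition=condition)


# ---------------------------------------------------------------------- GFF3

def write_gff3(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in ann.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tcoldchrom\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tcoldchrom\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i + 1};"
                         f"Parent={g.gene_id}\n")


def read_gff3(path, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene/exon features (one representative model per gene)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    if chrom_sizes is None:
        chrom_sizes = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _, end = line.split()[:4]
                    chrom_sizes[chrom] = int(end)
        if not chrom_sizes:
            raise FormatError("no ##sequence-region directives; "
                              "pass chrom_sizes explicitly")
    genes = []
    for feat in db.features_of_type("gene"):
        start0, end0 = feat.start - 1, feat.end
        exons = [(e.start - 1, e.end) for e in
                 db.children(feat, featuretype="exon")]
        if not exons:
            exons = [(start0, end0)]
        if feat.strand == "+":
            tss, tts = start0, end0
        else:
            tss, tts = end0, start0
        genes.append(GeneModel(feat.id, feat.seqid, feat.strand, tss, tts, exons))
    return GenomeAnnotation(genes, chrom_sizes)


# ------------------------------------------------------------- intervals/DHS

def write_bed_intervals(intervals: list[GenomicInterval], path,
                        names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    df = _read_table(path, [0, 1, 2], ["chrom", "start", "end"])
    return [GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()]


def write_dhs_bed(dhss: list[DHS], path, threshold: float = np.inf) -> None:
    """DHSs as BED6 (name=sample, score scaled to the calling threshold)."""
    with open(path, "w") as fh:
        for d in dhss:
            score = rescale_score(d, threshold)
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                     f"\t{d.sample or 'DHS'}\t{score}\t.\n")


def write_summit_bed(dhss: list[DHS], path) -> None:
    with open(path, "w") as fh:
        for d in dhss:
            fh.write(f"{d.interval.chrom}\t{d.summit}\t{d.summit + 1}"
                     f"\t{d.sample or 'summit'}\t{d.summit_count}\t.\n")


def write_bedgraph(density: np.ndarray, chrom: str, path, decimals: int = 6) -> None:
    """Per-bp density as run-length-compressed bedGraph."""
    vals = np.round(np.asarray(density, float), decimals)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [vals.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            if vals[s] != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{decimals}g}\n")


def extract_sequences(intervals: list[GenomicInterval], fasta_path,
                      out_fasta) -> None:
    """Write interval sequences to FASTA (requires pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    with open(out_fasta, "w") as fh:
        for iv in intervals:
            seq = fa[iv.chrom][iv.start:iv.end].seq
            fh.write(f">{iv.chrom}:{iv.start}-{iv.end}\n{seq}\n")


def write_tracks(objects, fmt: str, path, **kwargs) -> None:
    """Single-dispatch writer over the supported interchange formats.

    fmt: one of bed (intervals), bed6 (DHSs), bedpe, cuts, gff3,
    bedgraph, summits.
    """
    writers = {
        "bed": write_bed_intervals,
        "bed6": write_dhs_bed,
        "bedpe": write_fragments_bedpe,
        "cuts": write_cut_bed,
        "gff3": write_gff3,
        "bedgraph": write_bedgraph,
        "summits": write_summit_bed,
    }
    if fmt not in writers:
        raise FormatError(f"unknown format {fmt!r}; expected one of "
                          f"{sorted(writers)}")
    if fmt == "bedgraph":
        return write_bedgraph(objects, kwargs.pop("chrom"), path, **kwargs)
    return writers[fmt](objects, path, **kwargs)


# ----------------------------------------------------------------------- TSV

def write_labels_tsv(labels, path) -> None:
    t = labels.table.copy()
    t["body_bumps"] = [",".join(map(str, b)) for b in t["body_bumps"]]
    t.to_csv(path, sep="\t")


def read_labels_tsv(path):
    from .synthetic import TruthLabels

    t = pd.read_csv(path, sep="\t", index_col="gene_id")
    t["body_bumps"] = [
        [int(x) for x in str(b).split(",") if x and x != "nan"]
        for b in t["body_bumps"].fillna("")]
    return TruthLabels(t)
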