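"""Gene annotation model and position/feature classification.

Coordinates are 0-based half-open throughout (BED convention); GFF3 I/O
converts to/from 1-based closed at the boundary.

A gene is represented by a single gene model (one representative
transcript): a strand, a TSS/TTS pair, and a sorted list of exon
intervals.  For a minus-strand gene the TSS is stored as the *exclusive*
genomic end boundary of the gene, so the gene body is always the
half-open interval ``[min(tss, tts), max(tss, tts))`` and the 1-kb
upstream window of a minus-strand gene with ``tss = 5000`` is
``[5000, 6000)``.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# feature labels, coarse set
UPSTREAM1K = "upstream1k"
EXON = "exon"
INTRON = "intron"
DOWNSTREAM1K = "downstream1k"
INTERGENIC = "intergenic"
# refined additions (mutually exclusive with the coarse flank labels:
# TSS200 is the 200 bp nearest the TSS, upstream1k the remaining 200-1000 bp)
TSS200 = "TSS200"
TTS200 = "TTS200"
INTERGENIC_1TO5K = "intergenic_1to5k"

COARSE_LABELS = (UPSTREAM1K, EXON, INTRON, DOWNSTREAM1K, INTERGENIC)
REFINED_LABELS = (TSS200, UPSTREAM1K, EXON, INTRON, TTS200, DOWNSTREAM1K,
                  INTERGENIC_1TO5K, INTERGENIC)

# precedence: genic evidence wins, then upstream, then downstream.
_RANK = {
    EXON: 0,
    INTRON: 1,
    TSS200: 2,
    UPSTREAM1K: 2,
    TTS200: 3,
    DOWNSTREAM1K: 3,
    INTERGENIC_1TO5K: 8,
    INTERGENIC: 9,
}


class AnnotationError(ValueError):
    """Invalid annotation input (unknown chromosome, bad gene model...)."""


class SizingError(ValueError):
    """Not enough genomic space to satisfy a placement request."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tts:
            raise AnnotationError(f"{self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise AnnotationError(f"{self.gene_id}: - strand requires tss > tts")
        self.exons = sorted(tuple(e) for e in self.exons)
        lo, hi = self.start, self.end
        prev_end = lo
        for s, e in self.exons:
            if s < prev_end or e > hi or s >= e:
                raise AnnotationError(f"{self.gene_id}: bad exon ({s}, {e})")
            prev_end = e

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def upstream_window(self, size: int = 1000, offset: int = 0) -> tuple[int, int]:
        """Genomic (start, end) of the window ``[offset, offset+size)`` bp
        5' of the TSS, in transcription orientation."""
        if self.strand == "+":
            return self.tss - offset - size, self.tss - offset
        return self.tss + offset, self.tss + offset + size

    def downstream_window(self, size: int = 1000, offset: int = 0) -> tuple[int, int]:
        if self.strand == "+":
            return self.tts + offset, self.tts + offset + size
        return self.tts - offset - size, self.tts - offset

    def tss_distance(self, pos: int) -> int:
        return abs(pos - self.tss)


class GenomeAnnotation:
    """A set of gene models with per-chromosome lookup indexes."""

    def __init__(self, genes: list[GeneModel], chrom_sizes: dict[str, int]):
        self.genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self._by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_sizes}
        for g in self.genes:
            if g.chrom not in self._by_chrom:
                raise AnnotationError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise AnnotationError(f"gene {g.gene_id} extends past chromosome end")
            self._by_chrom[g.chrom].append(g)
        for c in self._by_chrom:
            self._by_chrom[c].sort(key=lambda g: (g.start, g.gene_id))
        # sorted starts + running max end -> windowed candidate queries
        self._starts = {c: [g.start for g in gs] for c, gs in self._by_chrom.items()}
        self._index = {g.gene_id: g for g in self.genes}

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._index[gene_id]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        if chrom not in self._by_chrom:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        return self._by_chrom[chrom]

    def genes_near(self, chrom: str, pos: int, radius: int) -> list[GeneModel]:
        """Genes whose span extended by ``radius`` covers ``pos``."""
        gs = self.genes_on(chrom)
        starts = self._starts[chrom]
        hi = bisect_right(starts, pos + radius)
        out = []
        for g in gs[:hi]:
            if g.end + radius > pos:
                out.append(g)
        return out


def _feature_of(gene: GeneModel, pos: int, refined: bool) -> str | None:
    """Feature label of ``pos`` relative to one gene, or None if unrelated."""
    if gene.start <= pos < gene.end:
        for s, e in gene.exons:
            if s <= pos < e:
                return EXON
        return INTRON
    s, e = gene.upstream_window(1000)
    if s <= pos < e:
        if refined:
            s2, e2 = gene.upstream_window(200)
            return TSS200 if s2 <= pos < e2 else UPSTREAM1K
        return UPSTREAM1K
    s, e = gene.downstream_window(1000)
    if s <= pos < e:
        if refined:
            s2, e2 = gene.downstream_window(200)
            return TTS200 if s2 <= pos < e2 else DOWNSTREAM1K
        return DOWNSTREAM1K
    if refined:
        su, eu = gene.upstream_window(4000, offset=1000)
        sd, ed = gene.downstream_window(4000, offset=1000)
        if su <= pos < eu or sd <= pos < ed:
            return INTERGENIC_1TO5K
    return None


def classify_position_with_gene(ann: GenomeAnnotation, chrom: str, pos: int,
                                refined: bool = False) -> tuple[str, str | None]:
    """Classify a base position against the annotation.

    Returns ``(label, gene_id)``; gene_id is None for plain intergenic.
    Precedence when the windows of several genes overlap:
    exon > intron > upstream > downstream (> 1-5 kb band > intergenic);
    ties among same-rank genes broken by distance to TSS then gene_id.
    """
    if chrom not in ann.chrom_sizes:
        raise AnnotationError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < ann.chrom_sizes[chrom]:
        raise AnnotationError(f"position {pos} outside {chrom}")
    radius = 5000 if refined else 1000
    best: tuple[int, int, str] | None = None
    best_label = INTERGENIC
    for g in ann.genes_near(chrom, pos, radius):
        lab = _feature_of(g, pos, refined)
        if lab is None:
            continue
        key = (_RANK[lab], g.tss_distance(pos), g.gene_id)
        if best is None or key < best:
            best = key
            best_label = lab
    if best is None:
        return INTERGENIC, None
    return best_label, best[2]


def classify_position(ann: GenomeAnnotation, chrom: str, pos: int,
                      refined: bool = False) -> str:
    return classify_position_with_gene(ann, chrom, pos, refined)[0]


def assign_dhs_feature(ann: GenomeAnnotation, dhs, refined: bool = False) -> str:
    """Assign a DHS to a genomic feature by its summit position alone."""
    return classify_position(ann, dhs.interval.chrom, dhs.summit, refined)


def assign_dhs_feature_with_gene(ann: GenomeAnnotation, dhs,
                                 refined: bool = False) -> tuple[str, str | None]:
    return classify_position_with_gene(ann, dhs.interval.chrom, dhs.summit, refined)


class GeneTooShortError(ValueError):
    pass


def _segment_bins(a: float, b: float, n: int) -> list[tuple[int, int]]:
    """Partition the oriented segment a->b into n half-open genomic bins,
    returned in the a->b order. Handles descending (minus-strand) segments."""
    bounds = np.rint(np.linspace(a, b, n + 1)).astype(int)
    out = []
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        out.append((min(lo, hi), max(lo, hi)))
    return out


def gene_body_bins(gene: GeneModel, n_bins: int = 100,
                   flank: int = 1000) -> list[tuple[int, int]]:
    """3*n_bins half-open intervals (upstream flank, body, downstream flank),
    ordered 5'->3' in transcription orientation.

    Body bins partition [TSS, TTS) with widths differing by <= 1 bp; each
    flank is partitioned into n_bins equal windows.  Genes shorter than
    n_bins raise :class:`GeneTooShortError`.
    """
    if gene.length < n_bins:
        raise GeneTooShortError(
            f"{gene.gene_id}: length {gene.length} < {n_bins} bins")
    if gene.strand == "+":
        up = _segment_bins(gene.tss - flank, gene.tss, n_bins)
        body = _segment_bins(gene.tss, gene.tts, n_bins)
        down = _segment_bins(gene.tts, gene.tts + flank, n_bins)
    else:
        up = _segment_bins(gene.tss + flank, gene.tss, n_bins)
        body = _segment_bins(gene.tss, gene.tts, n_bins)
        down = _segment_bins(gene.tts, gene.tts - flank, n_bins)
    return up + body + down


def select_random_intergenic(ann: GenomeAnnotation,
                             template_lengths: list[int],
                             min_dist: int = 2000,
                             seed: int = 0) -> list[GenomicInterval]:
    """Random control intervals at least ``min_dist`` bp from every gene.

    One interval is drawn per template length, uniformly over all eligible
    placements, so the output matches the template set in number and
    lengths one-to-one.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    # eligible space: complement of (gene span +- min_dist) per chromosome
    free: list[tuple[str, int, int]] = []
    for chrom, size in sorted(ann.chrom_sizes.items()):
        cursor = 0
        for g in ann.genes_on(chrom):
            lo = max(0, g.start - min_dist)
            if lo > cursor:
                free.append((chrom, cursor, lo))
            cursor = max(cursor, g.end + min_dist)
        if cursor < size:
            free.append((chrom, cursor, size))
    out: list[GenomicInterval] = []
    for length in template_lengths:
        slots = [(c, s, e) for c, s, e in free if e - s >= length]
        if not slots:
            raise SizingError(
                f"no intergenic slot of length {length} at distance {min_dist}")
        weights = np.array([e - s - length + 1 for _, s, e in slots], float)
        i = rng.choice(len(slots), p=weights / weights.sum())
        c, s, e = slots[i]
        start = int(s + rng.integers(0, e - s - length + 1))
        out.append(GenomicInterval(c, start, start + length))
    return out
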