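"""ChIP signal quantification and dual-order sequential-ChIP bivalent calls.

A fragment track stores paired-end fragments; the signal position of a
fragment is its midpoint.  Single-mark levels are normalized to interval
length, to sequencing depth (per bp per million mapped fragments) and to
an input track.  Bivalent levels are quantified from sequential-ChIP
channels (K4-K27 normalized to K4-noAb; K27-K4 normalized to K27-noAb)
over gene bodies, and a gene is called bivalent when, being active, its
bivalent level increases from RT to cold in BOTH antibody orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, GenomeAnnotation
from .metagene import SignalError, normalize_signal

EPS = 0.01  # pseudo-signal floor on denominators

SEQUENTIAL_PAIRS = {"K4-K27": "K4-noAb", "K27-K4": "K27-noAb"}
CHANNELS = ("K4me3", "K27me3", "K4me1", "H4ac", "input",
            "K4-K27", "K4-noAb", "K27-K4", "K27-noAb")


class ChannelError(ValueError):
    pass


@dataclass
class FragmentTrack:
    """Paired-end fragments for one ChIP channel (0-based half-open)."""

    fragments: dict[str, np.ndarray]  # chrom -> (n, 2) start/end
    chrom_sizes: dict[str, int]
    channel: str = ""
    condition: str = ""

    def __post_init__(self):
        clean, mids = {}, {}
        for chrom, arr in self.fragments.items():
            if chrom not in self.chrom_sizes:
                raise ChannelError(f"fragments on unknown chromosome {chrom!r}")
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and (arr[:, 0] >= arr[:, 1]).any():
                raise ChannelError(f"fragment with start >= end on {chrom}")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            clean[chrom] = arr[order]
            mids[chrom] = np.sort((arr[:, 0] + arr[:, 1]) // 2)
        self.fragments = clean
        self._midpoints = mids

    @property
    def library_size(self) -> int:
        return int(sum(len(v) for v in self.fragments.values()))

    def event_positions(self, chrom: str) -> np.ndarray:
        """Sorted fragment midpoints (the signal positions)."""
        return self._midpoints.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        mid = self.event_positions(chrom)
        return int(np.searchsorted(mid, end) - np.searchsorted(mid, start))


def chip_signal(track: FragmentTrack, interval: GenomicInterval,
                input_track: FragmentTrack, eps: float = EPS) -> float:
    """Input-normalized modification level over an interval.

    norm(track)/max(norm(input), eps), with norm = midpoints per bp per
    million mapped fragments.
    """
    if track.library_size == 0 or input_track.library_size == 0:
        raise SignalError("zero library size")
    s = normalize_signal(track.count_in(interval.chrom, interval.start, interval.end),
                         len(interval), track.library_size)
    s_in = normalize_signal(
        input_track.count_in(interval.chrom, interval.start, interval.end),
        len(interval), input_track.library_size)
    return s / max(s_in, eps)


def signal_ratio(track_cold: FragmentTrack, track_rt: FragmentTrack,
                 input_cold: FragmentTrack, input_rt: FragmentTrack,
                 interval: GenomicInterval, eps: float = EPS) -> float:
    """Cold/RT ratio of input-normalized signal over an interval."""
    s_cold = chip_signal(track_cold, interval, input_cold, eps)
    s_rt = chip_signal(track_rt, interval, input_rt, eps)
    return s_cold / max(s_rt, eps)


def bivalent_score(seq_track: FragmentTrack, noab_track: FragmentTrack,
                   gene: GeneModel, eps: float = EPS) -> float:
    """Bivalent level of a gene body from one sequential-ChIP order.

    The sequential channel is normalized to its matching first-antibody
    no-antibody control (K4-K27 with K4-noAb, K27-K4 with K27-noAb), to
    interval length and to depth.
    """
    expected = SEQUENTIAL_PAIRS.get(seq_track.channel)
    if expected is None:
        raise ChannelError(f"{seq_track.channel!r} is not a sequential channel")
    if noab_track.channel != expected:
        raise ChannelError(
            f"channel pairing mismatch: {seq_track.channel} requires {expected}, "
            f"got {noab_track.channel!r}")
    return chip_signal(seq_track, gene.body, noab_track, eps)


@dataclass
class BivalentCall:
    gene_id: str
    b_k4k27: dict[str, float] = field(default_factory=dict)  # {"RT": s, "cold": s}
    b_k27k4: dict[str, float] = field(default_factory=dict)
    is_bivalent: bool = False


def score_bivalent_genes(tracks: dict[tuple[str, str], FragmentTrack],
                         genes, eps: float = EPS) -> pd.DataFrame:
    """Dual-order bivalent scores for every gene, both conditions.

    ``tracks`` maps (channel, condition) -> FragmentTrack and must
    contain the four sequential channels for both "RT" and "cold".
    """
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    for ch in SEQUENTIAL_PAIRS:
        for cond in ("RT", "cold"):
            for c in (ch, SEQUENTIAL_PAIRS[ch]):
                if (c, cond) not in tracks:
                    raise ChannelError(f"missing channel {c!r} for condition {cond!r}")
    rows = []
    for gene in genes:
        row = {"gene_id": gene.gene_id}
        for ch, key in (("K4-K27", "k4k27"), ("K27-K4", "k27k4")):
            for cond in ("RT", "cold"):
                row[f"{key}_{cond}"] = bivalent_score(
                    tracks[(ch, cond)], tracks[(SEQUENTIAL_PAIRS[ch], cond)],
                    gene, eps)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def call_bivalent(active_genes, scores: pd.DataFrame,
                  min_fold: float = 1.0) -> pd.DataFrame:
    """Call bivalent genes from dual-order sequential-ChIP scores.

    A gene is bivalent when it is active and its bivalent level rose
    from RT to cold in both antibody orders (cold > min_fold * RT; the
    default min_fold = 1.0 is the strict "increased" rule).  Returns the
    scores table with an ``is_bivalent`` column; the called set is
    ``df[df.is_bivalent]`` and the "remaining active genes" its
    complement within the active set.
    """
    active = {g.gene_id if isinstance(g, GeneModel) else g for g in active_genes}
    df = scores.copy()
    df["is_active"] = df.index.isin(active)
    df["is_bivalent"] = (
        df["is_active"]
        & (df["k4k27_cold"] > min_fold * df["k4k27_RT"])
        & (df["k27k4_cold"] > min_fold * df["k27k4_RT"])
    )
    return df


def mark_class(k4_signal: float, k27_signal: float,
               enrich_threshold: float = 1.5) -> str:
    """Classify a gene by which input-normalized marks exceed a threshold."""
    k4 = k4_signal >= enrich_threshold
    k27 = k27_signal >= enrich_threshold
    if k4 and k27:
        return "both"
    if k4:
        return "K4-only"
    if k27:
        return "K27-only"
    return "neither"


def mark_class_table(tracks: dict[tuple[str, str], FragmentTrack],
                     genes, condition: str,
                     enrich_threshold: float = 1.5) -> pd.DataFrame:
    """Per-gene K4me3/K27me3 gene-body signals and mark class in one condition."""
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    for ch in ("K4me3", "K27me3", "input"):
        if (ch, condition) not in tracks:
            raise ChannelError(f"missing channel {ch!r} for condition {condition!r}")
    inp = tracks[("input", condition)]
    rows = []
    for gene in genes:
        k4 = chip_signal(tracks[("K4me3", condition)], gene.body, inp)
        k27 = chip_signal(tracks[("K27me3", condition)], gene.body, inp)
        rows.append({"gene_id": gene.gene_id, "k4": k4, "k27": k27,
                     "mark_class": mark_class(k4, k27, enrich_threshold)})
    return pd.DataFrame(rows).set_index("gene_id")
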