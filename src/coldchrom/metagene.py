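"""Normalized signal quantification and metagene (TSS->TTS) profiles.

Signal is events (DNase cuts, or ChIP fragment midpoints) per bp per
million mapped events.  Metagene matrices hold one row per gene and 300
columns: 100 upstream-flank bins, 100 gene-body bins, 100
downstream-flank bins, ordered 5'->3' in transcription orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, GenomeAnnotation, GeneTooShortError, gene_body_bins

logger = logging.getLogger(__name__)


class SignalError(ValueError):
    pass


def normalize_signal(count: float, length: float, library_size: float) -> float:
    """Events per bp per million mapped events: count/length/(library/1e6)."""
    if length <= 0:
        raise SignalError("interval length must be positive")
    if library_size <= 0:
        raise SignalError("library size must be positive")
    return count / length / (library_size / 1e6)


@dataclass
class MetageneMatrix:
    gene_ids: list[str]
    values: np.ndarray  # genes x 300
    sample: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] % 3 != 0:
            raise SignalError("metagene matrix must be genes x 3*n_bins")
        if self.values.shape[0] != len(self.gene_ids):
            raise SignalError("gene_ids / values shape mismatch")
        if (self.values < 0).any():
            raise SignalError("negative signal")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1] // 3

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"))


def metagene_profile(track, genes, bins: int = 100, flank: int = 1000,
                     sample: str | None = None) -> MetageneMatrix:
    """Per-gene binned normalized signal over [TSS-flank, TTS+flank).

    ``track`` is anything exposing ``event_positions(chrom)`` (sorted) and
    ``library_size`` — a cut-site track or a fragment track (midpoints).
    Genes shorter than ``bins`` bp are excluded with a warning.
    """
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    lib = track.library_size
    ids, rows = [], []
    skipped = 0
    for gene in genes:
        try:
            intervals = gene_body_bins(gene, n_bins=bins, flank=flank)
        except GeneTooShortError:
            skipped += 1
            continue
        pos = track.event_positions(gene.chrom)
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        lengths = ends - starts
        if lib > 0:
            row = counts / lengths / (lib / 1e6)
        else:
            row = np.zeros(len(intervals))
        ids.append(gene.gene_id)
        rows.append(row)
    if skipped:
        logger.warning("metagene_profile: skipped %d genes shorter than %d bp",
                       skipped, bins)
    values = np.vstack(rows) if rows else np.empty((0, 3 * bins))
    return MetageneMatrix(ids, values, sample=sample or getattr(track, "sample", ""))


def plot_mean_profiles(matrices: dict[str, MetageneMatrix], out_png,
                       n_bins: int = 100) -> None:
    """Line plot of mean metagene profiles, one curve per labeled matrix
    (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, mg in matrices.items():
        ax.plot(mg.mean_profile(), label=label)
    for x in (n_bins, 2 * n_bins):
        ax.axvline(x, color="grey", lw=0.5, ls="--")
    ax.set_xticks([0, n_bins, 2 * n_bins, 3 * n_bins])
    ax.set_xticklabels(["-1 kb", "TSS", "TTS", "+1 kb"])
    ax.set_ylabel("signal per bp per million events")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)


def expression_quartiles(expr: pd.DataFrame, sample: str,
                         expressed_threshold: float = 1.0) -> list[list[str]]:
    """Split the expressed genes of one sample into 4 FPKM quartiles.

    Returns [q1, q2, q3, q4] gene-id lists ordered low -> high expression.
    A gene's quartile is determined by the rank of the first occurrence of
    its FPKM value, so ties always fall in the lower quartile.
    """
    if sample not in expr.columns:
        raise SignalError(f"sample {sample!r} not in expression table")
    sub = expr.loc[expr[sample] > expressed_threshold, sample]
    groups: list[list[str]] = [[], [], [], []]
    if sub.empty:
        return groups
    values = sub.to_numpy(float)
    order = np.sort(values)
    first_rank = np.searchsorted(order, values, side="left")
    q = np.minimum((first_rank * 4) // len(values), 3)
    for gid, qi in zip(sub.index, q):
        groups[int(qi)].append(gid)
    return groups


def genic_sensitivity(track, gene: GeneModel) -> float:
    """Normalized signal over the gene body [TSS, TTS)."""
    count = track.count_in(gene.chrom, gene.start, gene.end)
    return normalize_signal(count, gene.length, track.library_size)


def sensitivity_change(track_a, track_b, genes, eps: float = 0.01):
    """Per-gene log2 gene-body signal ratio between two tracks.

    Returns ``(table, summary)``: a DataFrame with per-gene signals and
    ``log2_ratio = log2((sA+eps)/(sB+eps))``, and a summary dict with the
    median ratio, the paired Wilcoxon signed-rank p across genes, and the
    unpaired rank-sum p between the two signal sets.
    """
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    genes = list(genes)
    if not genes:
        raise SignalError("empty gene set")
    sa = np.array([genic_sensitivity(track_a, g) for g in genes])
    sb = np.array([genic_sensitivity(track_b, g) for g in genes])
    log2r = np.log2((sa + eps) / (sb + eps))
    table = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "signal_a": sa, "signal_b": sb, "log2_ratio": log2r,
    }).set_index("gene_id")
    if np.allclose(sa, sb):
        p_paired = 1.0
    else:
        p_paired = float(stats.wilcoxon(sa, sb, zero_method="wilcox").pvalue)
    if np.allclose(np.sort(sa), np.sort(sb)):
        p_ranksum = 1.0
    else:
        p_ranksum = float(stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue)
    summary = {
        "n_genes": len(genes),
        "median_log2_ratio": float(np.median(log2r)),
        "p_signed_rank": p_paired,
        "p_rank_sum": p_ranksum,
    }
    return table, summary
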