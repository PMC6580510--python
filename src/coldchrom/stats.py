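"""Gene-class definitions, DE intersection, association tables, and the
statistical tests used throughout the analysis (pooled two-proportion z
test with two-tailed probability, Wilcoxon rank-sum, windowed Pearson
correlation)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GenomeAnnotation
from .dhs import DHS

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 12  # exact enumeration up to this pooled sample size


def percent(x: float, n: float, decimals: int = 1) -> float:
    """Percentage x/n rounded to the reporting precision (1 decimal)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * x / n, decimals)


def active_genes(expr: pd.DataFrame, sample_a: str, sample_b: str) -> set[str]:
    """Genes with FPKM > 1 in both samples."""
    for s in (sample_a, sample_b):
        if s not in expr.columns:
            raise KeyError(f"sample {s!r} not in expression table")
    mask = (expr[sample_a] > 1.0) & (expr[sample_b] > 1.0)
    return set(expr.index[mask])


def silenced_genes(expr: pd.DataFrame, samples=None) -> set[str]:
    """Constitutively silenced genes: FPKM == 0 in every listed sample."""
    cols = list(samples) if samples is not None else list(expr.columns)
    mask = (expr[cols] == 0).all(axis=1)
    return set(expr.index[mask])


def intersect_de(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                 fdr: float = 0.01) -> pd.DataFrame:
    """DEGs supported by both callers with consistent direction.

    Each table needs columns gene_id, direction ('up'/'down'), fdr; the
    result keeps genes present in both with the same direction and
    FDR < ``fdr`` in each.  Direction conflicts are dropped and logged.
    """
    a = calls_a.loc[calls_a["fdr"] < fdr, ["gene_id", "direction"]]
    b = calls_b.loc[calls_b["fdr"] < fdr, ["gene_id", "direction"]]
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    conflicts = merged[merged["direction_a"] != merged["direction_b"]]
    if len(conflicts):
        logger.warning("intersect_de: dropped %d direction conflicts: %s",
                       len(conflicts), list(conflicts["gene_id"])[:10])
    keep = merged[merged["direction_a"] == merged["direction_b"]]
    return (keep.rename(columns={"direction_a": "direction"})
            [["gene_id", "direction"]].reset_index(drop=True))


@dataclass
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_two_tailed: float


def proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Pooled two-proportion z test with two-tailed normal probability.

    Degenerate tables (pooled proportion 0 or 1) return z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        logger.warning("proportion_ztest: degenerate pooled proportion %s", p_pool)
        return ProportionTestResult(x1, n1, x2, n2, 0.0, 1.0)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ProportionTestResult(x1, n1, x2, n2, float(z), float(min(p, 1.0)))


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by full enumeration of rank assignments when the pooled
    sample size is <= 12; normal approximation with tie correction and
    continuity correction otherwise.  Returns (U statistic of sample a,
    two-tailed p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _rank_sum_u(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(u_obs), 1.0
    n = a.size + b.size
    if n <= EXACT_RANKSUM_MAX_N:
        us = []
        idx = range(n)
        for pick in combinations(idx, a.size):
            mask = np.zeros(n, bool)
            mask[list(pick)] = True
            us.append(_rank_sum_u(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        tol = 1e-9
        p_le = np.mean(us <= u_obs + tol)
        p_ge = np.mean(us >= u_obs - tol)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_obs), float(p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(u_obs), float(res.pvalue)


def _events_by_chrom(track) -> dict[str, np.ndarray]:
    if isinstance(track, dict):
        return {c: np.asarray(v) for c, v in track.items()}
    return {c: track.event_positions(c) for c in track.chrom_sizes}


def window_density_correlation(track_a, track_b, window: int,
                               chrom_sizes: dict[str, int] | None = None
                               ) -> tuple[float, float]:
    """Pearson correlation of event counts in non-overlapping windows.

    Accepts tracks (cut-site or fragment) or plain {chrom: positions}
    dicts plus explicit chromosome sizes.  Returns (r, p).
    """
    if chrom_sizes is None:
        chrom_sizes = getattr(track_a, "chrom_sizes", None)
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required for plain position dicts")
    ev_a = _events_by_chrom(track_a)
    ev_b = _events_by_chrom(track_b)
    counts_a, counts_b = [], []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        edges = np.arange(0, size + window, window)
        edges[-1] = max(edges[-1], size)
        counts_a.append(np.histogram(ev_a.get(chrom, []), bins=edges)[0])
        counts_b.append(np.histogram(ev_b.get(chrom, []), bins=edges)[0])
    xa = np.concatenate(counts_a).astype(float)
    xb = np.concatenate(counts_b).astype(float)
    if xa.size < 3:
        raise ValueError("need at least 3 windows")
    r, p = sps.pearsonr(xa, xb)
    return float(r), float(p)


@dataclass
class CategoryCountTable:
    """Counts and percentages of genes per (gene class x feature category),
    with pairwise two-proportion z tests between classes attached."""

    counts: pd.DataFrame          # classes x categories, integer counts
    class_sizes: dict[str, int]
    tests: pd.DataFrame | None = None

    @property
    def percentages(self) -> pd.DataFrame:
        out = self.counts.astype(float).copy()
        for cls in out.index:
            n = self.class_sizes[cls]
            out.loc[cls] = [percent(v, n) if n else 0.0 for v in self.counts.loc[cls]]
        return out


def dhs_gene_association(specific_set: list[DHS], ann: GenomeAnnotation,
                         gene_classes: dict[str, set[str]],
                         refined: bool = True) -> CategoryCountTable:
    """Association between condition-specific DHSs and gene classes.

    For each feature category, counts the genes of each class (e.g. up-,
    down-, constitutively regulated) harboring >= 1 specific DHS whose
    summit resolves to that gene in that category, and attaches pairwise
    pooled z tests between classes per category.
    """
    from .annotation import assign_dhs_feature_with_gene

    hits: dict[str, set[str]] = {}
    for d in specific_set:
        label, gid = assign_dhs_feature_with_gene(ann, d, refined=refined)
        if gid is not None:
            hits.setdefault(label, set()).add(gid)
    categories = sorted(hits) if hits else []
    counts = pd.DataFrame(0, index=list(gene_classes), columns=categories, dtype=int)
    for cat in categories:
        for cls, members in gene_classes.items():
            counts.loc[cls, cat] = len(hits[cat] & members)
    sizes = {cls: len(m) for cls, m in gene_classes.items()}
    rows = []
    for cat in categories:
        for c1, c2 in combinations(gene_classes, 2):
            if sizes[c1] and sizes[c2]:
                res = proportion_ztest(int(counts.loc[c1, cat]), sizes[c1],
                                       int(counts.loc[c2, cat]), sizes[c2])
                rows.append({"category": cat, "class_1": c1, "class_2": c2,
                             "z": res.z, "p_two_tailed": res.p_two_tailed})
    tests = pd.DataFrame(rows) if rows else None
    return CategoryCountTable(counts=counts, class_sizes=sizes, tests=tests)
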