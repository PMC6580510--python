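"""DNase I hypersensitive site (DHS) calling.

The caller follows the kernel-density philosophy of DNase-seq hotspot
detection: every cut site contributes a Gaussian kernel (sd = bandwidth)
to a per-bp density profile, and DHSs are maximal runs of bases whose
density exceeds a threshold.  The threshold is set empirically: cut
positions are re-placed uniformly over the effective genome in repeated
Monte-Carlo simulations, and the threshold is the smallest density t at
which the expected number of null bases at or above t is at most
``fdr`` times the number of observed bases at or above t.

The summit of a DHS is the single base with the most cut events inside
the interval (leftmost on ties); feature assignment downstream uses only
the summit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import signal

from .annotation import GenomicInterval

_SQRT2PI = float(np.sqrt(2.0 * np.pi))
_KERNEL_TRUNC = 7.0  # kernel support in sd units; tail mass < 1e-11


class TrackError(ValueError):
    pass


@dataclass
class CutSiteTrack:
    """Per-chromosome DNase I cut positions (single-bp events).

    ``cuts`` maps chromosome -> sorted int64 positions (one entry per
    mapped cut).  ``library_size`` is the total number of cuts and
    ``effective_genome`` the mappable length used for null placement and
    density normalization (defaults to the summed chromosome sizes).
    """

    cuts: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    effective_genome: int | None = None
    sample: str = ""

    def __post_init__(self):
        clean = {}
        for chrom, pos in self.cuts.items():
            if chrom not in self.chrom_sizes:
                raise TrackError(f"cuts on unknown chromosome {chrom!r}")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (arr.min() < 0 or arr.max() >= self.chrom_sizes[chrom]):
                raise TrackError(f"cut position out of bounds on {chrom}")
            clean[chrom] = np.sort(arr)
        self.cuts = clean
        if self.effective_genome is None:
            self.effective_genome = int(sum(self.chrom_sizes.values()))

    @property
    def library_size(self) -> int:
        return int(sum(len(v) for v in self.cuts.values()))

    def event_positions(self, chrom: str) -> np.ndarray:
        return self.cuts.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.event_positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass
class DHS:
    interval: GenomicInterval
    summit: int
    summit_count: int
    peak_density: float
    read_density: float
    sample: str = ""

    def __post_init__(self):
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit outside DHS interval")


@dataclass
class CallerParams:
    bandwidth: float = 300.0
    fdr: float = 0.05
    n_null: int = 20
    min_length: int = 50
    merge_gap: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")


def gaussian_kernel(bandwidth: float) -> np.ndarray:
    """Discrete Gaussian kernel sampled per bp, truncated at 7 sd.

    Values are the Gaussian pdf itself (not renormalized), so a single
    cut yields a profile maximum of 1/(sqrt(2*pi)*bandwidth) and the
    profile of n cuts integrates to ~n.
    """
    radius = int(np.ceil(_KERNEL_TRUNC * bandwidth))
    x = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-0.5 * (x / bandwidth) ** 2) / (_SQRT2PI * bandwidth)


def kde_density(track: CutSiteTrack, bandwidth: float, chrom: str) -> np.ndarray:
    """Per-bp kernel density profile of cut sites on one chromosome."""
    if chrom not in track.chrom_sizes:
        raise TrackError(f"unknown chromosome {chrom!r}")
    length = track.chrom_sizes[chrom]
    pos = track.event_positions(chrom)
    if pos.size == 0:
        return np.zeros(length)
    counts = np.bincount(pos, minlength=length).astype(float)
    kernel = gaussian_kernel(bandwidth)
    dens = signal.oaconvolve(counts, kernel, mode="same")
    return np.maximum(dens, 0.0)


def _uniform_track(rng: np.random.Generator, n: int,
                   chrom_sizes: dict[str, int]) -> CutSiteTrack:
    """n cut sites placed uniformly over the concatenated chromosomes."""
    sizes = np.array([chrom_sizes[c] for c in chrom_sizes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    flat = rng.integers(0, offsets[-1], size=n)
    cuts = {}
    for i, chrom in enumerate(chrom_sizes):
        sel = flat[(flat >= offsets[i]) & (flat < offsets[i + 1])]
        cuts[chrom] = sel - offsets[i]
    return CutSiteTrack(cuts, dict(chrom_sizes))


def null_threshold(track: CutSiteTrack, params: CallerParams) -> float:
    """Empirical-FDR density threshold from uniform-placement simulations.

    Returns the smallest positive density t with
    ``E[null bases >= t] / (observed bases >= t) <= fdr``; +inf when no
    such t exists (the observed track is indistinguishable from null).
    """
    if track.library_size == 0:
        return np.inf
    obs = np.sort(np.concatenate(
        [kde_density(track, params.bandwidth, c) for c in track.chrom_sizes]))
    rng = np.random.default_rng(params.seed)
    null_parts = []
    for _ in range(params.n_null):
        sim = _uniform_track(rng, track.library_size, track.chrom_sizes)
        sim.effective_genome = track.effective_genome
        for c in track.chrom_sizes:
            null_parts.append(kde_density(sim, params.bandwidth, c))
    null = np.sort(np.concatenate(null_parts))

    cand = np.unique(obs)
    cand = cand[cand > 0]
    if cand.size == 0:
        return np.inf
    obs_ge = obs.size - np.searchsorted(obs, cand, side="left")
    null_ge = (null.size - np.searchsorted(null, cand, side="left")) / params.n_null
    ok = null_ge / np.maximum(obs_ge, 1) <= params.fdr
    if not ok.any():
        return np.inf
    return float(cand[ok].min())


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True in a boolean vector."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def call_dhs(track: CutSiteTrack, params: CallerParams,
             sample_id: str = "", threshold: float | None = None) -> list[DHS]:
    """Call DHSs on all chromosomes of a cut-site track.

    DHSs are maximal runs of bases with density >= threshold; runs closer
    than ``merge_gap`` are merged and runs shorter than ``min_length``
    dropped.  Output sorted by (chrom, start).
    """
    if threshold is None:
        threshold = null_threshold(track, params)
    if not np.isfinite(threshold):
        return []
    out: list[DHS] = []
    for chrom in sorted(track.chrom_sizes):
        pos = track.event_positions(chrom)
        if pos.size == 0:
            continue
        dens = kde_density(track, params.bandwidth, chrom)
        runs = _runs_above(dens >= threshold)
        if params.merge_gap > 0 and runs:
            merged = [runs[0]]
            for s, e in runs[1:]:
                if s - merged[-1][1] < params.merge_gap:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            runs = merged
        counts = np.bincount(pos, minlength=track.chrom_sizes[chrom])
        for s, e in runs:
            if e - s < params.min_length:
                continue
            window = counts[s:e]
            summit = int(s + np.argmax(window))  # argmax is leftmost on ties
            n_cuts = int(window.sum())
            out.append(DHS(
                interval=GenomicInterval(chrom, int(s), int(e)),
                summit=summit,
                summit_count=int(counts[summit]),
                peak_density=float(dens[s:e].max()),
                read_density=n_cuts / (e - s),
                sample=sample_id,
            ))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def _trees(dhss: list[DHS]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for d in dhss:
        trees.setdefault(d.interval.chrom, IntervalTree()).addi(
            d.interval.start, d.interval.end, d)
    return trees


def consensus_dhs(rep1: list[DHS], rep2: list[DHS],
                  union_coords: bool = True) -> list[DHS]:
    """Replicate-consensus DHSs: rep1 sites with >= 1 bp overlap in rep2.

    Each retained rep1 DHS yields one consensus record whose interval is
    the union of the rep1 interval with all overlapping rep2 intervals
    (or the rep1 coordinates when ``union_coords`` is False); the summit
    comes from the replicate with the larger summit count (rep1 on ties).
    """
    trees = _trees(rep2)
    out: list[DHS] = []
    for d1 in rep1:
        tree = trees.get(d1.interval.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(d1.interval.start, d1.interval.end),
                      key=lambda iv: (iv.begin, iv.end))
        if not hits:
            continue
        partners = [iv.data for iv in hits]
        best2 = max(partners, key=lambda d: d.summit_count)
        if union_coords:
            start = min([d1.interval.start] + [p.interval.start for p in partners])
            end = max([d1.interval.end] + [p.interval.end for p in partners])
        else:
            start, end = d1.interval.start, d1.interval.end
        winner = best2 if best2.summit_count > d1.summit_count else d1
        out.append(DHS(
            interval=GenomicInterval(d1.interval.chrom, start, end),
            summit=winner.summit,
            summit_count=winner.summit_count,
            peak_density=max(d1.peak_density, best2.peak_density),
            read_density=winner.read_density,
            sample=d1.sample,
        ))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def specific_dhs(set_a: list[DHS], set_b: list[DHS]) -> list[DHS]:
    """Condition-specific subset of ``set_a``: zero-bp overlap with ``set_b``."""
    trees = _trees(set_b)
    out = []
    for d in set_a:
        tree = trees.get(d.interval.chrom)
        if tree is not None and tree.overlap(d.interval.start, d.interval.end):
            continue
        out.append(d)
    return out


def top_dhs_regions(dhss: list[DHS], k: int = 1000,
                    halfwidth: int = 50) -> list[GenomicInterval]:
    """Summit-centered windows of the top-k DHSs by read density.

    Ranking is by read density descending, ties by summit count then
    coordinate; each emitted interval is [summit-halfwidth,
    summit+halfwidth).
    """
    if not dhss:
        raise ValueError("empty DHS list")
    ranked = sorted(dhss, key=lambda d: (-d.read_density, -d.summit_count,
                                         d.interval.chrom, d.interval.start))
    out = []
    for d in ranked[:min(k, len(ranked))]:
        out.append(GenomicInterval(d.interval.chrom,
                                   d.summit - halfwidth, d.summit + halfwidth))
    return out


def rescale_score(dhs: DHS, threshold: float) -> int:
    """BED score column: 1000 * min(1, peak_density / threshold)."""
    if not np.isfinite(threshold) or threshold <= 0:
        return 0
    return int(round(1000 * min(1.0, dhs.peak_density / threshold)))
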