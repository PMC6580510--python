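"""Synthetic chromatin dataset with planted structure.

Emulates the structure of the study design this package analyzes: a
small multi-chromosome genome with non-overlapping annotated genes, two
replicates x three DNase-seq samples (RT tubers, cold tubers, leaves),
nine ChIP channels per condition (four single marks, input, and the
four sequential-ChIP channels K4-K27 / K4-noAb / K27-K4 / K27-noAb),
and an expression table with two differential-expression caller outputs.

Planted ground truth (recoverable from :class:`TruthLabels` without
re-simulation):

* expression class per gene — up, down, constitutive, or silenced;
* promoter DNase hotspots for every expressed gene (Gaussian bump of
  sd 75 bp centered 100 bp upstream of the TSS, weight = expression
  quartile);
* cold-only gene-body DNase hotspots (``genic_dhs_cold_only``) for
  upregulated, bivalent and a share of the remaining active genes;
* a bivalent H3K4me3-H3K27me3 state, in cold only, for ~30% of active
  genes: their gene-body nucleosomes emit in both single-mark channels
  and in both sequential-ChIP orders.

All channels share one fixed nucleosome grid (180 bp spacing), and the
no-antibody controls re-emit the first antibody's nucleosome
distribution scaled by ``carryover_rate`` on top of uniform background.
Every random draw is tied to the master seed through a stable
per-(sample, replicate, channel) sub-seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, SizingError
from .bivalent import CHANNELS, ChannelError, FragmentTrack
from .dhs import CutSiteTrack

CONDITIONS = ("RT", "cold", "leaf")

MIN_GENE_GAP = 2000          # bp between adjacent genes (intergenic controls)
PROMOTER_OFFSET = 100        # bump center, bp upstream of the TSS
HOTSPOT_SD = 75.0            # bp, DNase hotspot shape
N_BODY_BUMPS = 2             # cold gene-body hotspots per planted gene
FRACTION_SILENCED = 0.25
FRACTION_UP = 0.20
FRACTION_DOWN = 0.20
FRACTION_BIVALENT_OF_ACTIVE = 0.30
FRACTION_EXTRA_GENIC_COLD = 0.60   # of non-up, non-bivalent active genes

# DNase read-mass split (background, promoters, cold gene bodies)
DNASE_MASS = {"RT": (0.65, 0.35, 0.0),
              "leaf": (0.65, 0.35, 0.0),
              "cold": (0.45, 0.35, 0.20)}

# ChIP nucleosome mark weights (added to a uniform base weight of 1.0
# per nucleosome).  Chosen so input-normalized gene-body levels land on
# the intended side of the mark-class threshold and reproduce the
# planted directions (silenced genes lose, active genes gain K27me3 in
# cold; bivalent genes gain strongly).
K4_ACTIVE = 3.0
K27_SILENCED_RT = 2.0
K27_SILENCED_COLD = 1.8
K27_ACTIVE_COLD = 1.0
K27_BIVALENT_COLD = 2.5
K4ME1_ACTIVE = 0.3
K4ME1_BIVALENT_COLD = 2.0
H4AC_ACTIVE = 2.0
BIVALENT_SEQ = 6.0           # sequential-channel weight on bivalent bodies, cold

FRAGMENT_LEN_MEAN = 150.0    # mononucleosome fragments
FRAGMENT_LEN_SD = 12.0
MIDPOINT_JITTER_SD = 20.0


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (1000, 4000)
    nucleosome_spacing: int = 180
    dnase_depth: int = 400_000
    chip_depth: int = 200_000
    carryover_rate: float = 0.10
    fdr_nominal: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.nucleosome_spacing) <= 0:
            raise SimulationError("all counts must be positive")
        if self.n_genes < 0 or self.dnase_depth < 0 or self.chip_depth < 0:
            raise SimulationError("counts must be non-negative")
        lo, hi = self.gene_length_range
        if not 100 <= lo <= hi:
            raise SimulationError("gene_length_range must satisfy 100 <= lo <= hi")
        if not 0 <= self.carryover_rate < 0.5:
            raise SimulationError("carryover_rate must be in [0, 0.5)")
        if not 0 < self.fdr_nominal < 1:
            raise SimulationError("fdr_nominal must be in (0, 1)")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


def _rng(seed: int, label: str) -> np.random.Generator:
    """Sub-seeded generator, stable across runs and platforms."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass
class TruthLabels:
    """Planted per-gene ground truth.

    ``table`` columns: expression_class, bivalent_planted, promoter_dhs,
    genic_dhs_cold_only, fpkm_RT, fpkm_cold, fpkm_leaf (noise-free
    planted levels), body_bumps (cold hotspot centers).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        silenced = t["expression_class"] == "silenced"
        if (t.loc[silenced, ["fpkm_RT", "fpkm_cold", "fpkm_leaf"]] != 0).any().any():
            raise SimulationError("silenced genes must have zero FPKM everywhere")
        if (t["bivalent_planted"] & silenced).any():
            raise SimulationError("bivalent genes cannot be silenced")

    @property
    def active(self) -> set[str]:
        return set(self.table.index[self.table["expression_class"] != "silenced"])

    @property
    def bivalent(self) -> set[str]:
        return set(self.table.index[self.table["bivalent_planted"]])

    def genes_in_class(self, cls: str) -> set[str]:
        return set(self.table.index[self.table["expression_class"] == cls])


def nucleosome_centers(cfg: SimConfig, chrom: str) -> np.ndarray:
    """Fixed nucleosome grid shared by all ChIP channels."""
    spacing = cfg.nucleosome_spacing
    return np.arange(spacing // 2, cfg.chrom_length, spacing, dtype=np.int64)


def generate_annotation(cfg: SimConfig) -> tuple[GenomeAnnotation, TruthLabels]:
    """Non-overlapping gene models plus planted truth labels."""
    rng = _rng(cfg.seed, "annotation")
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gidx = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = MIN_GENE_GAP
        for _ in range(n_here):
            gap = int(rng.integers(MIN_GENE_GAP, 2 * MIN_GENE_GAP))
            length = int(rng.integers(cfg.gene_length_range[0],
                                      cfg.gene_length_range[1] + 1))
            start = cursor + (gap - MIN_GENE_GAP)
            end = start + length
            if end + MIN_GENE_GAP > cfg.chrom_length:
                raise SizingError(
                    f"chromosome {chrom} too short for {n_here} genes "
                    f"at >= {MIN_GENE_GAP} bp spacing")
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _draw_exons(rng, start, end)
            tss, tts = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"gene{gidx:04d}", chrom, strand, tss, tts, exons))
            gidx += 1
            cursor = end + MIN_GENE_GAP
    ann = GenomeAnnotation(genes, cfg.chrom_sizes)
    labels = _plant_labels(cfg, ann, rng)
    return ann, labels


def _draw_exons(rng: np.random.Generator, start: int, end: int
                ) -> list[tuple[int, int]]:
    """1-3 exons; k exons -> 2k-1 alternating exon/intron segments."""
    length = end - start
    k = int(rng.integers(1, 4))
    if k == 1 or length < 2 * k * 50:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(50, length - 50), size=2 * (k - 1),
                              replace=False))
    bounds = [0] + list(cuts) + [length]
    return [(start + bounds[2 * i], start + bounds[2 * i + 1]) for i in range(k)]


def _plant_labels(cfg: SimConfig, ann: GenomeAnnotation,
                  rng: np.random.Generator) -> TruthLabels:
    ids = [g.gene_id for g in ann.genes]
    n = len(ids)
    order = rng.permutation(n)
    n_sil = int(round(FRACTION_SILENCED * n))
    n_up = int(round(FRACTION_UP * n))
    n_down = int(round(FRACTION_DOWN * n))
    classes = np.array(["constitutive"] * n, dtype=object)
    classes[order[:n_sil]] = "silenced"
    classes[order[n_sil:n_sil + n_up]] = "up"
    classes[order[n_sil + n_up:n_sil + n_up + n_down]] = "down"

    active = classes != "silenced"
    bivalent = np.zeros(n, bool)
    act_idx = np.flatnonzero(active)
    n_biv = int(round(FRACTION_BIVALENT_OF_ACTIVE * act_idx.size))
    bivalent[rng.choice(act_idx, size=n_biv, replace=False)] = True

    genic_cold = (classes == "up") | bivalent
    rest = np.flatnonzero(active & ~genic_cold)
    genic_cold[rest[rng.random(rest.size) < FRACTION_EXTRA_GENIC_COLD]] = True

    # planted (noise-free) expression levels; active genes stay > 1 after
    # observation noise, fold changes have median >= 1.5 by construction
    fpkm_rt = np.zeros(n)
    fpkm_cold = np.zeros(n)
    fpkm_leaf = np.zeros(n)
    for i in range(n):
        if classes[i] == "silenced":
            continue
        fold = 2.0 ** np.clip(rng.normal(1.2, 0.4), 0.3, 3.0)
        base = 1.5 + rng.lognormal(1.0, 1.0)
        if classes[i] == "up":
            fpkm_rt[i], fpkm_cold[i] = base, base * fold
        elif classes[i] == "down":
            fpkm_cold[i], fpkm_rt[i] = base, base * fold
        else:
            fpkm_rt[i] = base
            fpkm_cold[i] = base * 2.0 ** np.clip(rng.normal(0.0, 0.05), -0.1, 0.1)
        fpkm_leaf[i] = 1.5 + rng.lognormal(1.0, 1.0)

    # cold gene-body hotspot centers on internal nucleosomes, fixed per genome
    bumps: list[list[int]] = []
    for i, g in enumerate(ann.genes):
        if not genic_cold[i]:
            bumps.append([])
            continue
        grid = nucleosome_centers(cfg, g.chrom)
        inner = grid[(grid >= g.start + 300) & (grid < g.end - 300)]
        if inner.size == 0:
            inner = np.array([(g.start + g.end) // 2])
        k = min(N_BODY_BUMPS, inner.size)
        bumps.append(sorted(int(x) for x in
                            rng.choice(inner, size=k, replace=False)))

    table = pd.DataFrame({
        "expression_class": classes,
        "bivalent_planted": bivalent,
        "promoter_dhs": active,
        "genic_dhs_cold_only": genic_cold,
        "fpkm_RT": fpkm_rt,
        "fpkm_cold": fpkm_cold,
        "fpkm_leaf": fpkm_leaf,
        "body_bumps": bumps,
    }, index=pd.Index(ids, name="gene_id"))
    return TruthLabels(table)


def _promoter_weights(ann: GenomeAnnotation, labels: TruthLabels,
                      condition: str) -> np.ndarray:
    """Per-gene promoter hotspot weight: the expression quartile (1-4)."""
    t = labels.table
    fpkm = t[f"fpkm_{condition}"].to_numpy()
    w = np.zeros(len(t))
    expressed = fpkm > 1.0
    if expressed.any():
        vals = fpkm[expressed]
        order = np.sort(vals)
        first = np.searchsorted(order, vals, side="left")
        q = np.minimum((first * 4) // vals.size, 3) + 1
        w[expressed] = q
    w[~t["promoter_dhs"].to_numpy()] = 0.0
    return w


def simulate_dnase(cfg: SimConfig, ann: GenomeAnnotation, labels: TruthLabels,
                   condition: str, replicate: int | str = 1) -> CutSiteTrack:
    """One DNase-seq replicate: uniform background + promoter hotspots
    (all conditions) + gene-body hotspots (cold only, planted genes)."""
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    rng = _rng(cfg.seed, f"dnase|{condition}|{replicate}")
    chrom_sizes = cfg.chrom_sizes
    cuts: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
    if cfg.dnase_depth == 0:
        return CutSiteTrack({c: np.empty(0, np.int64) for c in chrom_sizes},
                            chrom_sizes, sample=f"{condition}_rep{replicate}")
    frac_bg, frac_prom, frac_body = DNASE_MASS[condition]
    n_bg, n_prom, n_body = rng.multinomial(
        cfg.dnase_depth, [frac_bg, frac_prom, frac_body])
    # reads with no eligible target revert to background (conservation)
    t = labels.table
    if not (_promoter_weights(ann, labels, condition) > 0).any():
        n_bg, n_prom = n_bg + n_prom, 0
    if n_body and not t["genic_dhs_cold_only"].any():
        n_bg, n_body = n_bg + n_body, 0

    # uniform background over the concatenated genome
    sizes = np.array(list(chrom_sizes.values()), dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(sizes)])
    flat = rng.integers(0, offs[-1], size=n_bg)
    for i, chrom in enumerate(chrom_sizes):
        cuts[chrom].append(flat[(flat >= offs[i]) & (flat < offs[i + 1])] - offs[i])

    genes = ann.genes
    gene_chrom = np.array([g.chrom for g in genes])
    pw = _promoter_weights(ann, labels, condition)
    if n_prom and pw.sum() > 0:
        pick = rng.choice(len(genes), size=n_prom, p=pw / pw.sum())
        centers = np.array([
            g.tss - PROMOTER_OFFSET if g.strand == "+" else g.tss + PROMOTER_OFFSET
            for g in genes])
        pos = np.rint(centers[pick] + rng.normal(0, HOTSPOT_SD, n_prom)).astype(np.int64)
        for chrom in chrom_sizes:
            mask = gene_chrom[pick] == chrom
            cuts[chrom].append(np.clip(pos[mask], 0, chrom_sizes[chrom] - 1))

    if n_body:
        t = labels.table
        bw = np.where(t["genic_dhs_cold_only"],
                      np.where(t["bivalent_planted"], 2.0, 1.0), 0.0)
        if bw.sum() > 0:
            pick = rng.choice(len(genes), size=n_body, p=bw / bw.sum())
            all_bumps = t["body_bumps"].to_list()
            centers = np.array([
                all_bumps[j][int(rng.integers(0, len(all_bumps[j])))] for j in pick],
                dtype=np.int64)
            starts = np.array([genes[j].start for j in pick], dtype=np.int64)
            ends = np.array([genes[j].end for j in pick], dtype=np.int64)
            pos = np.clip(
                np.rint(centers + rng.normal(0, HOTSPOT_SD, n_body)).astype(np.int64),
                starts, ends - 1)
            for chrom in chrom_sizes:
                mask = gene_chrom[pick] == chrom
                cuts[chrom].append(pos[mask])

    final = {c: np.sort(np.concatenate(v)) if v else np.empty(0, np.int64)
             for c, v in cuts.items()}
    return CutSiteTrack(final, chrom_sizes, sample=f"{condition}_rep{replicate}")


def _gene_mark_extras(labels: TruthLabels, channel: str, condition: str,
                      carryover: float) -> np.ndarray:
    """Per-gene added nucleosome weight for one channel in one condition."""
    t = labels.table
    active = (t["expression_class"] != "silenced").to_numpy()
    silenced = ~active
    bivalent = t["bivalent_planted"].to_numpy()
    cold = condition == "cold"

    k4 = np.where(active, K4_ACTIVE, 0.0)
    if cold:
        k27 = np.where(silenced, K27_SILENCED_COLD,
                       np.where(bivalent, K27_BIVALENT_COLD, K27_ACTIVE_COLD))
    else:
        k27 = np.where(silenced, K27_SILENCED_RT, 0.0)
    biv = np.where(bivalent & cold, BIVALENT_SEQ, 0.0)

    if channel == "K4me3":
        return k4
    if channel == "K27me3":
        return k27
    if channel == "K4me1":
        out = np.where(active, K4ME1_ACTIVE, 0.0)
        if cold:
            out = out + np.where(bivalent, K4ME1_BIVALENT_COLD, 0.0)
        return out
    if channel == "H4ac":
        return np.where(active, H4AC_ACTIVE, 0.0)
    if channel == "input":
        return np.zeros(len(t))
    if channel == "K4-K27":
        return carryover * k4 + biv
    if channel == "K4-noAb":
        return carryover * k4
    if channel == "K27-K4":
        return carryover * k27 + biv
    if channel == "K27-noAb":
        return carryover * k27
    raise ChannelError(f"unknown channel {channel!r}")


def simulate_chip(cfg: SimConfig, ann: GenomeAnnotation, labels: TruthLabels,
                  channel: str, condition: str) -> FragmentTrack:
    """One ChIP / sequential-ChIP channel: ~150 bp fragments centered on
    the fixed nucleosome grid, sampled with per-nucleosome weights of
    1.0 (background) plus the gene's mark weight."""
    if channel not in CHANNELS:
        raise ChannelError(f"unknown channel {channel!r}")
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    rng = _rng(cfg.seed, f"chip|{condition}|{channel}")
    chrom_sizes = cfg.chrom_sizes
    extras = _gene_mark_extras(labels, channel, condition, cfg.carryover_rate)

    all_centers, all_weights = [], []
    chrom_of = []
    for chrom in chrom_sizes:
        centers = nucleosome_centers(cfg, chrom)
        w = np.ones(centers.size)
        for g, extra in zip(ann.genes, extras):
            if extra and g.chrom == chrom:
                lo = np.searchsorted(centers, g.start)
                hi = np.searchsorted(centers, g.end)
                w[lo:hi] += extra
        all_centers.append(centers)
        all_weights.append(w)
        chrom_of.extend([chrom] * centers.size)
    centers = np.concatenate(all_centers)
    weights = np.concatenate(all_weights)
    chrom_of = np.array(chrom_of)

    frags: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
    if cfg.chip_depth > 0:
        counts = rng.multinomial(cfg.chip_depth, weights / weights.sum())
        mids0 = np.repeat(centers, counts)
        chroms = np.repeat(chrom_of, counts)
        mids = mids0 + np.rint(rng.normal(0, MIDPOINT_JITTER_SD, mids0.size)).astype(np.int64)
        lens = np.clip(np.rint(rng.normal(FRAGMENT_LEN_MEAN, FRAGMENT_LEN_SD,
                                          mids0.size)), 100, 220).astype(np.int64)
        starts = mids - lens // 2
        ends = starts + lens
        for chrom in chrom_sizes:
            mask = chroms == chrom
            s = np.clip(starts[mask], 0, chrom_sizes[chrom] - 2)
            e = np.clip(ends[mask], 2, chrom_sizes[chrom])
            e = np.maximum(e, s + 2)
            frags[chrom].append(np.stack([s, e], axis=1))
    final = {c: (np.concatenate(v) if v else np.empty((0, 2), np.int64))
             for c, v in frags.items()}
    return FragmentTrack(final, chrom_sizes, channel=channel, condition=condition)


def simulate_chip_set(cfg: SimConfig, ann: GenomeAnnotation, labels: TruthLabels,
                      conditions=("RT", "cold"), channels=CHANNELS
                      ) -> dict[tuple[str, str], FragmentTrack]:
    """All requested (channel, condition) fragment tracks."""
    return {(ch, cond): simulate_chip(cfg, ann, labels, ch, cond)
            for cond in conditions for ch in channels}


def mark_truth(labels: TruthLabels, condition: str) -> pd.DataFrame:
    """Planted K4me3/K27me3 gene states implied by the weight tables."""
    t = labels.table
    active = t["expression_class"] != "silenced"
    if condition == "cold":
        k27 = ~active | t["bivalent_planted"]
    else:
        k27 = ~active
    cls = np.where(active & k27, "both",
                   np.where(active, "K4-only",
                            np.where(k27, "K27-only", "neither")))
    return pd.DataFrame({"k4_marked": active, "k27_marked": k27,
                         "mark_class": cls}, index=t.index)


def simulate_expression(cfg: SimConfig, labels: TruthLabels
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Observed FPKM table (samples RT, cold, leaf) plus two DE caller
    tables whose intersection is exactly the planted DEG set.

    Each caller reports every planted up/down gene at FDR < 0.01 and a
    disjoint set of caller-specific false positives drawn from the
    constitutive genes, so the two-caller intersection rule removes all
    false positives.
    """
    rng = _rng(cfg.seed, "expression")
    t = labels.table
    expr = pd.DataFrame(index=t.index)
    for cond in CONDITIONS:
        true = t[f"fpkm_{cond}"].to_numpy()
        noise = 2.0 ** rng.normal(0, 0.05, len(t))
        obs = true * noise
        obs[true == 0] = 0.0
        expr[cond] = obs

    planted = t[t["expression_class"].isin(["up", "down"])]
    const = list(t.index[t["expression_class"] == "constitutive"])
    n_fp = max(1, len(const) // 20)
    fp_pool = list(rng.permutation(const))
    fp_a, fp_b = fp_pool[:n_fp], fp_pool[n_fp:2 * n_fp]

    def caller_table(fp: list[str]) -> pd.DataFrame:
        rows = []
        for gid, cls in planted["expression_class"].items():
            rows.append({"gene_id": gid, "direction": cls,
                         "fdr": 10.0 ** -rng.uniform(2.1, 6.0)})
        for gid in fp:
            rows.append({"gene_id": gid,
                         "direction": "up" if rng.random() < 0.5 else "down",
                         "fdr": 10.0 ** -rng.uniform(2.1, 4.0)})
        # non-significant entries, shared but filtered by the FDR cut
        for gid in const[: n_fp]:
            rows.append({"gene_id": gid,
                         "direction": "up" if rng.random() < 0.5 else "down",
                         "fdr": rng.uniform(0.02, 0.9)})
        return pd.DataFrame(rows).drop_duplicates("gene_id", keep="first")

    return expr, caller_table(fp_a), caller_table(fp_b)
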