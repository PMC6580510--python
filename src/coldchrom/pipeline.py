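"""End-to-end pipeline: simulate (or load) -> call DHSs -> consensus and
condition-specific sets -> feature classification -> metagene profiles ->
bivalent calls -> statistics report.

The pipeline is deterministic given the run seed: every stage derives
its randomness from it, and the emitted ``stats.json`` is byte-identical
across runs of the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, io, metagene, stats
from .bivalent import call_bivalent, mark_class_table, score_bivalent_genes
from .dhs import CallerParams, call_dhs, consensus_dhs, null_threshold, specific_dhs, top_dhs_regions
from .synthetic import SimConfig, simulate_chip_set, simulate_dnase, simulate_expression
from .synthetic import generate_annotation as _generate_annotation

logger = logging.getLogger(__name__)

REQUIRED_BIVALENT_CHANNELS = ("K4-K27", "K4-noAb", "K27-K4", "K27-noAb")


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` is true (synthetic inputs from ``sim``) or all
    needed real-input paths are present: ``gff3``, ``chrom_sizes``,
    ``dnase_beds`` per (condition, replicate), ``chip_bedpes`` per
    (channel, condition), ``expression_tsv`` and two DE tables.
    """

    outdir: str = "results"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    conditions: tuple[str, ...] = ("RT", "cold")
    replicates: tuple[int, ...] = (1, 2)
    stages: tuple[str, ...] = ("dhs", "classify", "profile", "bivalent", "stats")
    # real-input paths (used when simulate=False)
    gff3: str | None = None
    chrom_sizes_path: str | None = None
    dnase_beds: dict = field(default_factory=dict)       # (condition, rep) -> path
    chip_bedpes: dict = field(default_factory=dict)      # (channel, condition) -> path
    expression_tsv: str | None = None
    de_tables: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        caller = CallerParams(**raw.pop("caller", {}))
        raw["dnase_beds"] = {tuple(k.split("/")): v
                             for k, v in raw.get("dnase_beds", {}).items()}
        raw["chip_bedpes"] = {tuple(k.split("/")): v
                              for k, v in raw.get("chip_bedpes", {}).items()}
        for key in ("conditions", "replicates", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, caller=caller, **raw)

    def validate(self) -> None:
        if self.simulate:
            return
        if not self.gff3:
            raise PipelineConfigError("real-input mode requires a gff3 path")
        for cond in self.conditions:
            for rep in self.replicates:
                if (cond, str(rep)) not in {(c, str(r)) for c, r in self.dnase_beds}:
                    raise PipelineConfigError(
                        f"missing DNase BED for condition {cond!r} replicate {rep}")
        if "bivalent" in self.stages:
            for ch in REQUIRED_BIVALENT_CHANNELS:
                for cond in ("RT", "cold"):
                    if (ch, cond) not in {(c, k) for c, k in self.chip_bedpes}:
                        raise PipelineConfigError(
                            f"bivalent stage enabled but channel {ch!r} "
                            f"({cond}) is missing")


def _timed(name: str, t0: float) -> None:
    logger.info("stage %-10s %6.1f s", name, time.perf_counter() - t0)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the statistics report dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    t0 = time.perf_counter()
    if cfg.simulate:
        ann, labels = _generate_annotation(cfg.sim)
        io.write_gff3(ann, out / "annotation.gff3")
        io.write_labels_tsv(labels, out / "truth_labels.tsv")
        expr, de_a, de_b = simulate_expression(cfg.sim, labels)
        expr.to_csv(out / "expression.tsv", sep="\t")
        de_a.to_csv(out / "de_caller_a.tsv", sep="\t", index=False)
        de_b.to_csv(out / "de_caller_b.tsv", sep="\t", index=False)
        dnase = {}
        for cond in cfg.conditions:
            for rep in cfg.replicates:
                track = simulate_dnase(cfg.sim, ann, labels, cond, rep)
                dnase[(cond, rep)] = track
                io.write_cut_bed(track, out / f"dnase_{cond}_rep{rep}.bed")
    else:
        chrom_sizes = (io.read_chrom_sizes(cfg.chrom_sizes_path)
                       if cfg.chrom_sizes_path else None)
        ann = io.read_gff3(cfg.gff3, chrom_sizes)
        labels = None
        expr = (pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
                if cfg.expression_tsv else None)
        de_a = de_b = None
        if cfg.de_tables:
            de_a = pd.read_csv(cfg.de_tables[0], sep="\t")
            de_b = pd.read_csv(cfg.de_tables[1], sep="\t")
        dnase = {(c, r): io.read_cut_bed(p, ann.chrom_sizes, sample=f"{c}_rep{r}")
                 for (c, r), p in cfg.dnase_beds.items()}
    _timed("inputs", t0)

    # gene classes
    if expr is not None and de_a is not None:
        degs = stats.intersect_de(de_a, de_b)
        up = set(degs.loc[degs["direction"] == "up", "gene_id"])
        down = set(degs.loc[degs["direction"] == "down", "gene_id"])
        active = stats.active_genes(expr, "RT", "cold")
        silenced = stats.silenced_genes(expr)
        constitutive = active - up - down
        report["gene_classes"] = {
            "n_active": len(active), "n_silenced": len(silenced),
            "n_up": len(up), "n_down": len(down),
            "n_constitutive": len(constitutive),
        }
    else:
        up = down = constitutive = active = silenced = set()

    consensus: dict[str, list] = {}
    thresholds: dict[str, float] = {}
    spec_cold = spec_rt = None
    if "dhs" in cfg.stages:
        t0 = time.perf_counter()
        for cond in cfg.conditions:
            reps = []
            for rep in cfg.replicates:
                track = dnase[(cond, rep)]
                params = dataclasses.replace(
                    cfg.caller,
                    seed=cfg.caller.seed + zlib.crc32(f"{cond}|{rep}".encode()) % 10000)
                thr = null_threshold(track, params)
                thresholds[f"{cond}_rep{rep}"] = thr
                called = call_dhs(track, params, sample_id=f"{cond}_rep{rep}",
                                  threshold=thr)
                io.write_dhs_bed(called, out / f"dhs_{cond}_rep{rep}.bed", thr)
                reps.append(called)
            cons = consensus_dhs(reps[0], reps[1]) if len(reps) > 1 else reps[0]
            consensus[cond] = cons
            io.write_dhs_bed(cons, out / f"dhs_{cond}_consensus.bed")
            io.write_summit_bed(cons, out / f"dhs_{cond}_summits.bed")
            report.setdefault("dhs_counts", {})[cond] = {
                f"rep{r + 1}": len(reps[r]) for r in range(len(reps))}
            report["dhs_counts"][cond]["consensus"] = len(cons)
        if {"RT", "cold"} <= set(cfg.conditions):
            spec_cold = specific_dhs(consensus["cold"], consensus["RT"])
            spec_rt = specific_dhs(consensus["RT"], consensus["cold"])
            io.write_dhs_bed(spec_cold, out / "dhs_cold_specific.bed")
            io.write_dhs_bed(spec_rt, out / "dhs_RT_specific.bed")
            report["specific_dhs"] = {
                "cold_specific": len(spec_cold), "RT_specific": len(spec_rt),
                "pct_cold_specific": stats.percent(len(spec_cold),
                                                   max(len(consensus["cold"]), 1)),
                "pct_RT_specific": stats.percent(len(spec_rt),
                                                 max(len(consensus["RT"]), 1)),
            }
            if spec_cold:
                top = top_dhs_regions(spec_cold, k=1000, halfwidth=50)
                io.write_bed_intervals(top, out / "top_cold_specific_regions.bed")
        _timed("dhs", t0)

    if "classify" in cfg.stages and consensus:
        t0 = time.perf_counter()
        dist = {}
        for cond, dhss in consensus.items():
            labels_count: dict[str, int] = {}
            for d in dhss:
                lab = annotation.assign_dhs_feature(ann, d)
                labels_count[lab] = labels_count.get(lab, 0) + 1
            n = max(len(dhss), 1)
            dist[cond] = {lab: {"count": c, "pct": stats.percent(c, n)}
                          for lab, c in sorted(labels_count.items())}
        report["dhs_feature_distribution"] = dist
        if spec_cold is not None and up:
            classes = {"up": up, "down": down, "constitutive": constitutive}
            assoc = stats.dhs_gene_association(spec_cold, ann, classes)
            assoc.counts.to_csv(out / "association_cold_specific_counts.tsv", sep="\t")
            assoc.percentages.to_csv(out / "association_cold_specific_pct.tsv", sep="\t")
            if assoc.tests is not None:
                assoc.tests.to_csv(out / "association_cold_specific_tests.tsv",
                                   sep="\t", index=False)
            report["association_cold_specific_pct"] = {
                cls: dict(row) for cls, row in assoc.percentages.iterrows()}
        _timed("classify", t0)

    if "profile" in cfg.stages and {"RT", "cold"} <= {c for c, _ in dnase}:
        t0 = time.perf_counter()
        act_genes = [ann[g] for g in sorted(active)] if active else list(ann.genes)
        for cond in ("RT", "cold"):
            mg = metagene.metagene_profile(dnase[(cond, cfg.replicates[0])], act_genes)
            pd.DataFrame({"bin": np.arange(mg.values.shape[1]),
                          "mean_signal": mg.mean_profile()}).to_csv(
                out / f"metagene_dnase_{cond}.tsv", sep="\t", index=False)
        table, summary = metagene.sensitivity_change(
            dnase[("cold", cfg.replicates[0])], dnase[("RT", cfg.replicates[0])],
            act_genes)
        table.to_csv(out / "sensitivity_change_cold_vs_RT.tsv", sep="\t")
        report["sensitivity_change_cold_vs_RT"] = summary
        _timed("profile", t0)

    if "bivalent" in cfg.stages:
        t0 = time.perf_counter()
        if cfg.simulate:
            chip = simulate_chip_set(cfg.sim, ann, labels)
        else:
            chip = {(ch, cond): io.read_fragments_bedpe(p, ann.chrom_sizes, ch, cond)
                    for (ch, cond), p in cfg.chip_bedpes.items()}
        act_genes = [ann[g] for g in sorted(active)] if active else list(ann.genes)
        scores = score_bivalent_genes(chip, ann.genes)
        calls = call_bivalent(active or {g.gene_id for g in ann.genes}, scores)
        calls.to_csv(out / "bivalent_calls.tsv", sep="\t")
        n_biv = int(calls["is_bivalent"].sum())
        n_act = int(calls["is_active"].sum())
        report["bivalent"] = {
            "n_bivalent": n_biv, "n_active": n_act,
            "pct_of_active": stats.percent(n_biv, max(n_act, 1)),
        }
        if ("K4me3", "cold") in chip and ("input", "cold") in chip:
            mc = mark_class_table(chip, act_genes, "cold")
            mc.to_csv(out / "mark_class_cold.tsv", sep="\t")
            report["mark_class_cold"] = mc["mark_class"].value_counts().to_dict()
        _timed("bivalent", t0)

    if "stats" in cfg.stages:
        report["thresholds"] = {k: (v if np.isfinite(v) else None)
                                for k, v in thresholds.items()}
        if len(dnase) >= 2 and {"RT"} <= {c for c, _ in dnase}:
            reps = [dnase[("RT", r)] for r in cfg.replicates[:2]]
            if len(reps) == 2:
                r, p = stats.window_density_correlation(reps[0], reps[1], window=100)
                report["replicate_coverage_correlation_RT"] = {"r": r, "window_bp": 100}

    manifest = {
        "package": "coldchrom", "version": __version__,
        "config": _config_dict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "stats.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["dnase_beds"] = {f"{c}/{r}": str(v) for (c, r), v in cfg.dnase_beds.items()}
    d["chip_bedpes"] = {f"{c}/{k}": str(v) for (c, k), v in cfg.chip_bedpes.items()}
    return d
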