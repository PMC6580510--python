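import numpy as np
import pytest

from coldchrom.annotation import GeneModel, GenomeAnnotation
from coldchrom.synthetic import (
    SimConfig,
    generate_annotation,
    simulate_chip_set,
    simulate_dnase,
    simulate_expression,
)


@pytest.fixture(scope="session")
def sim_cfg():
    """Default study conditions, fixed seed."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    return generate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def dnase_tracks(sim_cfg, sim_genome):
    ann, labels = sim_genome
    return {(cond, rep): simulate_dnase(sim_cfg, ann, labels, cond, rep)
            for cond in ("RT", "cold") for rep in (1, 2)}


@pytest.fixture(scope="session")
def chip_tracks(sim_cfg, sim_genome):
    ann, labels = sim_genome
    return simulate_chip_set(sim_cfg, ann, labels)


@pytest.fixture(scope="session")
def expression_tables(sim_cfg, sim_genome):
    _, labels = sim_genome
    return simulate_expression(sim_cfg, labels)


@pytest.fixture
def toy_annotation():
    """Three genes on one 20-kb chromosome.

    geneA: + strand [2000, 3000), exon [2000,2400) + [2700,3000)
    geneB: - strand [4000, 5000)  (tss boundary = 5000)
    geneC: + strand [5800, 7000), single exon; its upstream window
           [4800, 5800) overlaps geneB's upstream window [5000, 6000).
    """
    genes = [
        GeneModel("geneA", "chr1", "+", 2000, 3000,
                  [(2000, 2400), (2700, 3000)]),
        GeneModel("geneB", "chr1", "-", 5000, 4000, [(4000, 5000)]),
        GeneModel("geneC", "chr1", "+", 5800, 7000, [(5800, 7000)]),
    ]
    return GenomeAnnotation(genes, {"chr1": 20000})


def brute_force_overlaps(set_a, set_b):
    """O(n*m) overlap oracle: indices of set_a overlapping >= 1 bp of set_b."""
    hit = set()
    for i, a in enumerate(set_a):
        for b in set_b:
            if (a.interval.chrom == b.interval.chrom
                    and a.interval.start < b.interval.end
                    and b.interval.start < a.interval.end):
                hit.add(i)
    return hit


def random_dhs_list(rng, n, chrom="chr1", span=100_000):
    from coldchrom.annotation import GenomicInterval
    from coldchrom.dhs import DHS

    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 500))
        length = int(rng.integers(60, 400))
        summit = int(rng.integers(s, s + length))
        out.append(DHS(GenomicInterval(chrom, s, s + length), summit,
                       int(rng.integers(1, 50)),
                       float(rng.uniform(0.1, 5.0)),
                       float(rng.uniform(0.01, 2.0))))
    return out
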