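"""Shared fixtures: deterministic toy genomes, regions, and simulated pools."""

from __future__ import annotations

import numpy as np
import pytest

from vexseq.config import DesignConfig
from vexseq.design_pool import GenomicExon, TestRegion, extract_test_region

TestRegion.__test__ = False  # domain class, not a test case
from vexseq.simulate import SimulationConfig, _scrub_motifs, simulate_pool
from vexseq.util import revcomp

MOTIFS = {"CTGCAG", "TCTAGA", "ACTAGT", "CAATTG"}
MOTIFS |= {revcomp(m) for m in MOTIFS}


def make_toy_locus(seed: int = 0, strand: str = "+", exon_len: int = 70):
    """A single-chromosome genome with one canonical, motif-free exon.

    Returns (genome dict, GenomicExon); the chromosome holds context + 50-nt
    upstream intron ending AG + exon + 20-nt downstream intron starting GT
    + context, laid out on the requested strand.
    """
    cfg = DesignConfig()
    rng = np.random.default_rng(seed)
    ctx = cfg.flank_context
    total = ctx + cfg.min_up_flank + exon_len + cfg.min_down_flank + ctx
    sense = [str(b) for b in rng.choice(list("ACGT"), size=total)]
    a3 = ctx + cfg.min_up_flank
    d5 = a3 + exon_len
    sense[a3 - 2], sense[a3 - 1] = "A", "G"
    sense[d5], sense[d5 + 1] = "G", "T"
    _scrub_motifs(sense, MOTIFS, {a3 - 2, a3 - 1, d5, d5 + 1}, rng)
    sense_str = "".join(sense)
    pad = 5
    plus = sense_str if strand == "+" else revcomp(sense_str)
    genome = {"chrT": "A" * pad + plus + "A" * pad}
    start = pad + a3 + 1 if strand == "+" else pad + (total - a3 - exon_len) + 1
    exon = GenomicExon("toy", "chrT", start, start + exon_len - 1, strand)
    return genome, exon


@pytest.fixture(scope="session")
def design_cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def toy_plus():
    genome, exon = make_toy_locus(seed=11, strand="+")
    return genome, exon, extract_test_region(exon, genome)


@pytest.fixture(scope="session")
def toy_minus():
    genome, exon = make_toy_locus(seed=12, strand="-")
    return genome, exon, extract_test_region(exon, genome)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated pool with controls and two conditions."""
    cfg = SimulationConfig(
        n_exons=4, variants_per_exon=3, n_molecules_per_barcode=60,
    )
    return cfg, simulate_pool(cfg, seed=7)
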