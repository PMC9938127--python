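"""Shared fixtures: one deterministic synthetic study reused across tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from pyfaidx import Fasta

from tfabt.annotation import build_promoters
from tfabt.pwm import compute_threshold
from tfabt.simulate import SimulationConfig, simulate_genome_and_annotation, simulate_pwms
from tfabt.variants import build_catalog

# exact consensus sites for PWMs 0..9 embedded in the promoters of genes 0..9,
# so loss-direction drivers can be planted on those pairs
EMBEDDED_SITES = [(i, i, True) for i in range(10)]
WORLD_SEED = 7


@dataclass
class SimWorld:
    config: SimulationConfig
    pwms: list
    gene_table: object
    genome: Fasta
    promoters: dict
    thresholds: dict
    catalog: object
    fasta_path: str
    gtf_path: str


@pytest.fixture(scope="session")
def sim_world(tmp_path_factory) -> SimWorld:
    """A 50-gene, 20-PWM synthetic study with its altered-TFBS catalog."""
    outdir = tmp_path_factory.mktemp("world")
    cfg = SimulationConfig(seed=WORLD_SEED, embedded_sites=list(EMBEDDED_SITES))
    pwms = simulate_pwms(cfg)
    fasta = str(outdir / "genome.fa")
    gtf = str(outdir / "annotation.gtf")
    gene_table = simulate_genome_and_annotation(cfg, pwms, fasta, gtf)
    genome = Fasta(fasta)
    thresholds = {p.pwm_id: compute_threshold(p) for p in pwms}
    promoters = build_promoters(gtf, chrom_sizes={c: len(genome[c]) for c in genome.keys()})
    catalog = build_catalog(genome, promoters, pwms, thresholds)
    return SimWorld(
        config=cfg, pwms=pwms, gene_table=gene_table, genome=genome,
        promoters=promoters, thresholds=thresholds, catalog=catalog,
        fasta_path=fasta, gtf_path=gtf,
    )
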