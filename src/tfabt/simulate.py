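"""Deterministic synthetic fixtures for the whole pipeline.

The generator produces every input the burden test and the microarray
analytics consume: a toy genome with annotated protein-coding genes (FASTA +
GENCODE-dialect GTF), random high-information PWMs with consensus sites
embedded at known promoter positions, cohort mutation tables whose background
events are drawn from the same substitution-frequency process the burden
test's null assumes (plus optional planted site-altering excesses for chosen
gene/PWM pairs), ChIP-seq-style allele read counts, and probe tables with
planted allele-specific binding shifts and Gaussian replicate noise.

All randomness flows from a single seeded generator, forked hierarchically
per component, so outputs are byte-identical across runs with the same
config and adding one component does not perturb another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfabt.pwm import PWM, BASES
from tfabt.cascade import N_REPLICATES, ORIENTATIONS, PROBE_COLUMNS, PROBE_LEN

_COMP = str.maketrans("ACGT", "TGCA")

# Default substitution spectrum: transitions elevated, C>T dominant, loosely
# patterned on somatic SNV spectra in solid tumors.  Keys (ref, alt).
DEFAULT_SUBSTITUTION_FREQS: dict[tuple[str, str], float] = {
    ("C", "T"): 0.25, ("G", "A"): 0.25,
    ("C", "A"): 0.05, ("G", "T"): 0.05,
    ("C", "G"): 0.04, ("G", "C"): 0.04,
    ("T", "C"): 0.08, ("A", "G"): 0.08,
    ("T", "A"): 0.04, ("A", "T"): 0.04,
    ("T", "G"): 0.04, ("A", "C"): 0.04,
}


@dataclass
class PlantedDriver:
    """An excess of site-altering events planted on one gene/PWM pair."""

    gene_index: int
    pwm_index: int
    direction: str = "loss"
    excess_events: int = 5


@dataclass
class SimulationConfig:
    seed: int = 0

    # genome / annotation
    genome_length: int = 260_000
    n_genes: int = 50
    gene_spacing: int = 5_000
    gene_length: int = 1_000
    cds_offset: int = 200     # CDS start relative to TSS
    cds_length: int = 600
    promoter_upstream: int = 2_000
    promoter_downstream: int = 250
    chrom_name: str = "chrS"
    gc_content: float = 0.41

    # PWMs
    n_pwms: int = 20
    pwm_length: int = 8
    consensus_prob: float = 0.9

    # where to embed (near-)consensus sites: list of (gene_index, pwm_index,
    # exact) — exact sites feed loss drivers, one-mismatch sites gain drivers
    embedded_sites: list[tuple[int, int, bool]] = field(default_factory=list)

    # cohort
    cancer_type: str = "SIM"
    n_donors: int = 30
    events_per_promoter: int = 30
    substitution_freqs: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_FREQS)
    )
    planted_drivers: list[PlantedDriver] = field(default_factory=list)

    # CASCADE probes
    n_loci: int = 50
    n_planted_loci: int = 10
    effect_z: float = 3.0
    base_z: float = 3.0
    replicate_sd: float = 0.5
    background_log_mean: float = 7.0
    background_log_sd: float = 0.8
    n_background_probes: int = 500

    def validate(self) -> None:
        need = self.n_genes * self.gene_spacing + self.promoter_upstream
        if self.genome_length < need:
            raise ValueError(f"genome_length {self.genome_length} too short for {self.n_genes} genes (need {need})")
        for d in self.planted_drivers:
            if d.direction not in ("gain", "loss"):
                raise ValueError(f"unknown driver direction {d.direction!r}")


def _rng(config: SimulationConfig, component: str) -> np.random.Generator:
    # stable across processes (unlike hash()), so same seed => same bytes
    tag = zlib.crc32(component.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def simulate_pwms(config: SimulationConfig) -> list[PWM]:
    """Random high-information PWMs: one consensus base at ``consensus_prob``."""
    rng = _rng(config, "pwms")
    pwms = []
    for i in range(config.n_pwms):
        cons = rng.integers(0, 4, size=config.pwm_length)
        w = config.consensus_prob
        probs = np.full((config.pwm_length, 4), (1 - w) / 3)
        probs[np.arange(config.pwm_length), cons] = w
        pwms.append(PWM.from_counts(f"PWM{i:03d}", probs, tf_name=f"TF{i:03d}"))
    return pwms


def _one_mismatch(site: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(site)))
    base = site[pos]
    alt = rng.choice([b for b in BASES if b != base])
    return site[:pos] + alt + site[pos + 1:]


def simulate_genome_and_annotation(
    config: SimulationConfig,
    pwms: list[PWM],
    fasta_path: str,
    gtf_path: str,
) -> pd.DataFrame:
    """Write a toy genome (FASTA) and annotation (GTF); return the gene table.

    Genes alternate strands along one chromosome; each gene's CDS lies inside
    the gene body and — given the promoter extent — overlaps the next gene's
    upstream window, exercising coding-sequence subtraction.  Embedded sites
    (exact or one-mismatch consensus of a chosen PWM) are written into the
    promoter sequence at a fixed offset upstream of the TSS and recorded in
    the returned table's ``embedded`` column.
    """
    config.validate()
    rng = _rng(config, "genome")
    p = [(1 - config.gc_content) / 2, config.gc_content / 2, config.gc_content / 2, (1 - config.gc_content) / 2]
    genome = rng.choice(list(BASES), size=config.genome_length, p=p)

    genes = []
    for g in range(config.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        anchor = config.promoter_upstream + 500 + g * config.gene_spacing
        if strand == "+":
            tss1 = anchor + 1                      # 1-based
            start1, end1 = tss1, tss1 + config.gene_length - 1
            cds1 = (start1 + config.cds_offset, start1 + config.cds_offset + config.cds_length - 1)
        else:
            tss1 = anchor + config.gene_length
            start1, end1 = anchor + 1, tss1
            cds1 = (end1 - config.cds_offset - config.cds_length + 1, end1 - config.cds_offset)
        genes.append({
            "gene_index": g, "gene_id": f"G{g:04d}", "gene_name": f"GENE{g:04d}",
            "strand": strand, "tss": tss1, "start": start1, "end": end1,
            "cds_start": cds1[0], "cds_end": cds1[1], "embedded": [],
        })

    site_rng = _rng(config, "sites")
    for gene_index, pwm_index, exact in config.embedded_sites:
        gene = genes[gene_index]
        pwm = pwms[pwm_index]
        site = pwm.consensus if exact else _one_mismatch(pwm.consensus, site_rng)
        offset = 300 + 31 * (pwm_index % 20)  # fixed distance upstream of the TSS
        if gene["strand"] == "+":
            start0 = gene["tss"] - 1 - offset
        else:
            start0 = gene["tss"] - 1 + offset - len(site) + 1
            site = site.translate(_COMP)[::-1]
        genome[start0:start0 + len(site)] = list(site)
        gene["embedded"].append((pwm.pwm_id, start0 + 1, exact))

    with open(fasta_path, "w") as fh:
        fh.write(f">{config.chrom_name}\n")
        seq = "".join(genome)
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")

    with open(gtf_path, "w") as fh:
        for gene in genes:
            attrs = (
                f'gene_id "{gene["gene_id"]}"; gene_name "{gene["gene_name"]}"; '
                f'gene_type "protein_coding";'
            )
            tattrs = attrs + f' transcript_id "{gene["gene_id"]}.t1"; transcript_type "protein_coding";'
            c = config.chrom_name
            fh.write(f'{c}\ttfabt_sim\tgene\t{gene["start"]}\t{gene["end"]}\t.\t{gene["strand"]}\t.\t{attrs}\n')
            fh.write(f'{c}\ttfabt_sim\ttranscript\t{gene["start"]}\t{gene["end"]}\t.\t{gene["strand"]}\t.\t{tattrs}\n')
            fh.write(f'{c}\ttfabt_sim\texon\t{gene["start"]}\t{gene["end"]}\t.\t{gene["strand"]}\t.\t{tattrs}\n')
            fh.write(f'{c}\ttfabt_sim\tCDS\t{gene["cds_start"]}\t{gene["cds_end"]}\t.\t{gene["strand"]}\t0\t{tattrs}\n')
    return pd.DataFrame(genes)


# ---------------------------------------------------------------------------
# Cohort mutations
# ---------------------------------------------------------------------------

def simulate_cohort_mutations(
    config: SimulationConfig,
    promoters: dict,
    catalog: pd.DataFrame,
    genome,
    gene_table: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cohort mutation table: background NCVs plus planted driver events.

    Background events in each promoter are drawn cell-by-cell from the
    configured substitution frequencies (position weighted by its reference
    base's total mutability) — exactly the null process the burden test
    models.  Planted events are sampled, with replacement, from catalog cells
    that the target PWM calls in the target direction under all three
    schemes; a driver whose target pair has no such cell is a config error.
    """
    from tfabt.burden import MutationFrequencyModel, promoter_cell_weights

    if rng is None:
        rng = _rng(config, "mutations")
    fm = MutationFrequencyModel(config.cancer_type, "base", dict(config.substitution_freqs))
    donors = [f"D{d:04d}" for d in range(config.n_donors)]
    rows = []
    for gene_id in sorted(promoters):
        weights = promoter_cell_weights(promoters[gene_id], genome, fm)
        if weights.empty:
            continue
        n_events = config.events_per_promoter
        idx = rng.choice(len(weights), size=n_events, p=weights["weight"].to_numpy())
        for i in idx:
            cell = weights.iloc[int(i)]
            rows.append((rng.choice(donors), config.cancer_type, cell["chrom"], int(cell["pos"]),
                         cell["ref"], cell["alt"]))

    gene_ids = sorted(promoters)
    for driver in config.planted_drivers:
        if gene_table is not None:
            gene_id = gene_table.iloc[driver.gene_index]["gene_id"]
        else:
            gene_id = gene_ids[driver.gene_index]
        pwm_id = f"PWM{driver.pwm_index:03d}"
        prom = promoters[gene_id]
        in_prom = catalog.apply(lambda r: prom.contains(r["chrom"], r["pos"]), axis=1) if not catalog.empty else pd.Series(dtype=bool)
        cells = catalog[
            in_prom
            & (catalog["pwm_id"] == pwm_id)
            & (catalog["call_scheme1"] == driver.direction)
            & (catalog["call_scheme2"] == driver.direction)
            & (catalog["call_scheme3"] == driver.direction)
        ]
        if cells.empty:
            raise ValueError(
                f"planted driver ({gene_id}, {pwm_id}, {driver.direction}) has no altering catalog cell"
            )
        idx = rng.choice(len(cells), size=driver.excess_events)
        for i in idx:
            cell = cells.iloc[int(i)]
            rows.append((rng.choice(donors), config.cancer_type, cell["chrom"], int(cell["pos"]),
                         cell["ref"], cell["alt"]))
    df = pd.DataFrame(rows, columns=["donor_id", "cancer_type", "chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos", "alt", "donor_id"], kind="mergesort").reset_index(drop=True)


def simulate_allele_counts(
    catalog: pd.DataFrame,
    config: SimulationConfig,
    depth: int = 50,
    imbalance_fraction: float = 0.5,
    effect_p: float = 0.9,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ChIP-seq-style allele read counts at catalog loci.

    A random half of the loci get a true allelic imbalance whose direction
    matches the catalog's gain/loss call (a binding loss puts ``effect_p`` of
    the reads on the reference allele); the rest are balanced.
    """
    if rng is None:
        rng = _rng(config, "chipseq")
    loci = catalog.drop_duplicates(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    rows = []
    for _, r in loci.iterrows():
        call = r["call_scheme1"] if r["call_scheme1"] != "none" else (
            r["call_scheme2"] if r["call_scheme2"] != "none" else r["call_scheme3"]
        )
        imbalanced = rng.random() < imbalance_fraction
        if imbalanced and call == "loss":
            p_ref = effect_p
        elif imbalanced and call == "gain":
            p_ref = 1 - effect_p
        else:
            p_ref = 0.5
            imbalanced = False
        ref_reads = int(rng.binomial(depth, p_ref))
        rows.append((r["chrom"], int(r["pos"]), r["ref"], r["alt"], ref_reads, depth - ref_reads, imbalanced))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "true_imbalance"])


# ---------------------------------------------------------------------------
# CASCADE probe tables
# ---------------------------------------------------------------------------

def _z_to_fluorescence(z: np.ndarray, config: SimulationConfig) -> np.ndarray:
    return np.exp(config.background_log_mean + z * config.background_log_sd)


def simulate_cascade_probes(
    config: SimulationConfig,
    cof: str = "COF1",
    sv_seed_motif: str | None = "GCAGGATGTTCCGGAAGTCACTGCAT",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict]:
    """Probe table for two replicate experiments plus background vectors.

    Ref/Alt design: ``n_loci`` loci, the first ``n_planted_loci`` with a
    planted allele effect (ref z = base_z + effect_z, alt z = base_z), the
    rest with equal allele means; every (allele, register, orientation) cell
    carries 5 replicate probes with Gaussian replicate noise in z units.

    Single-variant design: when ``sv_seed_motif`` is given, one locus
    ("SVLOCUS") receives seed + 3x26 variant probes whose true z-scores
    follow an additive energy model over a planted core (an ETS-like GGAA
    element inside the 26-mer), so the delta-z/PPM pipeline should recover
    the planted consensus.

    Returns (probe_df, backgrounds, truth).
    """
    if rng is None:
        rng = _rng(config, "cascade")
    experiments = ("exp1", "exp2")
    backgrounds = {
        exp: np.exp(rng.normal(config.background_log_mean, config.background_log_sd, config.n_background_probes))
        for exp in experiments
    }
    rows = []
    truth_effect = {}
    for li in range(config.n_loci):
        locus = f"L{li:04d}"
        planted = li < config.n_planted_loci
        truth_effect[locus] = config.effect_z if planted else 0.0
        for exp in experiments:
            for allele in ("ref", "alt"):
                mean_z = config.base_z + (config.effect_z if (planted and allele == "ref") else 0.0)
                for reg in (-5, 0, 5):
                    for ori in ORIENTATIONS:
                        z = mean_z + rng.normal(0.0, config.replicate_sd, N_REPLICATES)
                        vals = _z_to_fluorescence(z, config)
                        for rep in range(N_REPLICATES):
                            rows.append((locus, allele, reg, ori, rep + 1, exp, cof, vals[rep]))

    truth_sv = None
    if sv_seed_motif is not None:
        seed = sv_seed_motif.upper()
        if len(seed) != PROBE_LEN:
            raise ValueError(f"seed motif must be {PROBE_LEN} nt")
        core = seed.find("GGAA")
        core_positions = set(range(max(core, 0), max(core, 0) + 8)) if core >= 0 else set()
        z_seed = config.base_z + config.effect_z
        sv_true = {}
        for i in range(PROBE_LEN):
            for b in BASES:
                if b == seed[i]:
                    continue
                penalty = config.effect_z if i in core_positions else 0.2
                sv_true[(i + 1, b)] = z_seed - penalty
        for exp in experiments:
            z = z_seed + rng.normal(0.0, config.replicate_sd, N_REPLICATES)
            for rep, v in enumerate(_z_to_fluorescence(z, config)):
                rows.append(("SVLOCUS", "seed", 0, "fwd", rep + 1, exp, cof, v))
            for (pos, b), true_z in sorted(sv_true.items()):
                z = true_z + rng.normal(0.0, config.replicate_sd, N_REPLICATES)
                for rep, v in enumerate(_z_to_fluorescence(z, config)):
                    rows.append(("SVLOCUS", f"sv{pos:02d}{b}", 0, "fwd", rep + 1, exp, cof, v))
        truth_sv = {"seed_sequence": seed, "z_seed": z_seed, "sv_true": sv_true,
                    "core_positions": sorted(core_positions)}

    probe_df = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    truth = {"effect_by_locus": truth_effect, "sv": truth_sv}
    return probe_df, backgrounds, truth
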