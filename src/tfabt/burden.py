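"""The TF-aware burden test (TFA-BT).

For a promoter B and a PWM A, the number of cohort NCVs in B that alter A's
binding sites in a given direction follows Binomial(n, p) under the null,
where n is the total number of NCV events observed in B across patients and
p is the probability that a single random NCV in B (drawn according to the
cohort's substitution-frequency spectrum) alters A.  The alteration
probability is

    p = sum_{i=1..L, j in bases} F(B_i, M_j) * C(A, B_i, M_j)

with F the per-cell mutation probability (renormalized to sum to 1 over the
promoter) and C the altered-TFBS catalog indicator.  P-values are upper
binomial tails, corrected per cohort and scheme with Benjamini-Hochberg, and
an association is only reported when significant under all three calling
schemes independently.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tfabt.annotation import Promoter, fetch_interval

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

MUTATION_COLUMNS = ["donor_id", "cancer_type", "chrom", "pos", "ref", "alt"]
FDR_CUTOFF = 0.01
SCHEMES = (1, 2, 3)
DIRECTIONS = ("gain", "loss")


@dataclass
class MutationFrequencyModel:
    """Relative substitution frequencies of a cancer type.

    ``base`` mode keys the 12 (ref, alt) substitution classes;
    ``trinucleotide`` mode keys (pyrimidine-centric trinucleotide context,
    alt base) with 96 classes.
    """

    cancer_type: str
    context_mode: str = "base"
    probs: dict[tuple[str, str], float] = field(default_factory=dict)

    def cell_weight(self, context: str, alt: str) -> float:
        """Unnormalized weight of mutating the given context to ``alt``."""
        if self.context_mode == "base":
            return self.probs.get((context[len(context) // 2], alt), 0.0)
        mid = len(context) // 2
        tri = context[mid - 1: mid + 2]
        if len(tri) < 3 or any(c not in BASES for c in tri):
            return 0.0
        if tri[1] in "AG":  # strand-collapse to the pyrimidine strand
            tri = tri.translate(_COMP)[::-1]
            alt = alt.translate(_COMP)
        return self.probs.get((tri, alt), 0.0)


def read_mutations_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df[MUTATION_COLUMNS].copy()


def read_mutations_vcf(path: str, sample_table: pd.DataFrame | str) -> pd.DataFrame:
    """Read SNVs from a VCF; donor and cancer type come from a sidecar table.

    The sidecar maps the VCF ``DONOR`` INFO field (or, failing that, the file
    name) to donor_id and cancer_type via columns donor_id, cancer_type.
    Multi-nucleotide and symbolic alleles are skipped.
    """
    import pysam

    if isinstance(sample_table, str):
        sample_table = pd.read_csv(sample_table, sep="\t")
    info = sample_table.set_index("donor_id")["cancer_type"].to_dict()
    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            donor = rec.info.get("DONOR", None)
            if donor is None:
                continue
            donor = donor if isinstance(donor, str) else donor[0]
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt:
                    continue
                if rec.ref not in BASES or alt not in BASES:
                    continue
                rows.append((donor, info.get(donor, "unknown"), rec.chrom, rec.pos, rec.ref, alt))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def estimate_mutation_frequencies(
    mutations: pd.DataFrame,
    genome: Fasta | None = None,
    context_mode: str = "base",
    cancer_type: str = "",
) -> MutationFrequencyModel:
    """Relative substitution frequencies observed in a mutation table.

    In trinucleotide mode the genome is required to recover each mutation's
    flanking bases, and contexts are collapsed onto the pyrimidine strand.
    """
    if context_mode not in ("base", "trinucleotide"):
        raise ValueError(f"unknown context mode {context_mode!r}")
    if mutations.empty:
        raise ValueError("cannot estimate frequencies from an empty mutation table")
    counts: dict[tuple[str, str], int] = {}
    if context_mode == "base":
        for ref, alt in zip(mutations["ref"], mutations["alt"]):
            if ref in BASES and alt in BASES and ref != alt:
                counts[(ref, alt)] = counts.get((ref, alt), 0) + 1
    else:
        if genome is None:
            raise ValueError("trinucleotide mode requires the genome")
        for chrom, pos, ref, alt in zip(
            mutations["chrom"], mutations["pos"], mutations["ref"], mutations["alt"]
        ):
            tri = fetch_interval(genome, str(chrom), int(pos) - 2, int(pos) + 1)
            if len(tri) < 3 or any(c not in BASES for c in tri) or ref not in BASES or alt not in BASES:
                continue
            if tri[1] in "AG":
                tri = tri.translate(_COMP)[::-1]
                alt = alt.translate(_COMP)
            counts[(tri, alt)] = counts.get((tri, alt), 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no usable single-nucleotide substitutions")
    probs = {k: v / total for k, v in counts.items()}
    return MutationFrequencyModel(cancer_type=cancer_type, context_mode=context_mode, probs=probs)


# ---------------------------------------------------------------------------
# Eq.-style alteration probability and the binomial tail
# ---------------------------------------------------------------------------

def _context_weight_table(freq_model: MutationFrequencyModel) -> np.ndarray:
    """(64, 4) lookup of cell weights for every trinucleotide context and alt."""
    table = np.zeros((64, 4))
    for idx, tri in enumerate(itertools.product(BASES, repeat=3)):
        ctx = "".join(tri)
        for j, alt in enumerate(BASES):
            if alt == ctx[1]:
                continue
            table[idx, j] = freq_model.cell_weight(ctx, alt)
    return table


def promoter_cell_weights(
    promoter: Promoter, genome: Fasta, freq_model: MutationFrequencyModel
) -> pd.DataFrame:
    """Per (position, alt) mutation weights F over one promoter.

    Returns a frame with chrom, pos (1-based), ref, alt, weight; weights are
    renormalized to sum to 1 over the promoter, so they are the distribution
    of a single random NCV in this promoter under the frequency model.
    """
    from tfabt.pwm import encode_sequence

    table = _context_weight_table(freq_model)
    frames = []
    for chrom, start, end in promoter.intervals:
        seq = fetch_interval(genome, chrom, start - 1, end + 1)  # 1bp flank for context
        enc = encode_sequence(seq)
        L = end - start
        ref_idx = enc[1:L + 1]
        if freq_model.context_mode == "base":
            valid = ref_idx >= 0
        else:
            valid = (enc[:L] >= 0) & (ref_idx >= 0) & (enc[2:L + 2] >= 0)
        tri_idx = np.clip(enc[:L], 0, 3) * 16 + np.clip(ref_idx, 0, 3) * 4 + np.clip(enc[2:L + 2], 0, 3)
        w = table[tri_idx]  # (L, 4)
        w[~valid] = 0.0
        pos_grid = np.repeat(np.arange(start + 1, end + 1), 4)
        ref_grid = np.repeat(np.clip(ref_idx, 0, 3), 4)
        alt_grid = np.tile(np.arange(4), L)
        w_flat = w.ravel()
        keep = w_flat > 0
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos_grid[keep],
            "ref": np.array(list(BASES))[ref_grid[keep]],
            "alt": np.array(list(BASES))[alt_grid[keep]],
            "weight": w_flat[keep],
        }))
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "weight"])
    )
    if not df.empty:
        df["weight"] = df["weight"] / df["weight"].sum()
    return df


def promoter_alteration_probability(
    promoter: Promoter,
    pwm_id: str,
    direction: str,
    scheme: int,
    freq_model: MutationFrequencyModel,
    catalog: pd.DataFrame,
    genome: Fasta,
) -> float:
    """Probability that one random promoter NCV alters the PWM as specified."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    weights = promoter_cell_weights(promoter, genome, freq_model)
    if weights.empty:
        return 0.0
    sub = catalog[(catalog["pwm_id"] == pwm_id) & (catalog[f"call_scheme{scheme}"] == direction)]
    merged = weights.merge(sub[["chrom", "pos", "alt"]], on=["chrom", "pos", "alt"], how="inner")
    return float(merged["weight"].sum())


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 <= p <= 1):
        raise ValueError("require 0 <= p <= 1")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def assign_mutational_signature(signature_probs: dict[str, float]) -> str | None:
    """Return the signature whose probability exceeds 0.5, else None.

    The rule is a strict inequality: a 0.5/0.5 split is unassigned.
    """
    if not signature_probs:
        return None
    best = max(signature_probs, key=signature_probs.get)
    return best if signature_probs[best] > 0.5 else None


def overlap_enrichment(N: int, K: int, n: int, k: int) -> dict[str, float]:
    """Overlap statistics of two subsets of a universe of size N.

    Returns the overlap as a percentage of each set, the fold enrichment over
    the expectation K*n/N, and the upper-tail hypergeometric p-value P(X >= k).
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise ValueError("inconsistent counts: require k <= min(K, n) and K, n <= N")
    expected = K * n / N
    return {
        "pct_of_set2": 100.0 * k / n if n else 0.0,
        "pct_of_set1": 100.0 * k / K if K else 0.0,
        "fold": k / expected if expected > 0 else float("nan"),
        "hypergeometric_pvalue": float(stats.hypergeom.sf(k - 1, N, K, n)),
    }


# ---------------------------------------------------------------------------
# The burden test proper
# ---------------------------------------------------------------------------

def _assign_promoters(mutations: pd.DataFrame, promoters: dict[str, Promoter]) -> pd.DataFrame:
    """Attach gene_id to each mutation inside a promoter; others are dropped.

    A mutation inside overlapping promoters of two genes yields one event row
    per gene (promoters are merged within, not across, genes).
    """
    import pyranges as pr

    empty = mutations.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    if mutations.empty:
        return empty
    iv_rows = [
        (chrom, start, end, gid)
        for gid, p in promoters.items()
        for chrom, start, end in p.intervals
    ]
    if not iv_rows:
        return empty
    ivs = pr.PyRanges(pd.DataFrame(iv_rows, columns=["Chromosome", "Start", "End", "gene_id"]))
    mdf = mutations.reset_index(drop=True)
    mgr = pr.PyRanges(pd.DataFrame({
        "Chromosome": mdf["chrom"],
        "Start": mdf["pos"] - 1,
        "End": mdf["pos"],
        "row": np.arange(len(mdf)),
    }))
    joined = mgr.join(ivs).df
    if joined.empty:
        return empty
    out = mdf.loc[joined["row"].to_numpy()].copy()
    out["gene_id"] = joined["gene_id"].to_numpy()
    return out.reset_index(drop=True)


def run_tfa_bt(
    mutations: pd.DataFrame,
    promoters: dict[str, Promoter],
    catalog: pd.DataFrame,
    genome: Fasta,
    cohorts: dict[str, pd.Series | None] | None = None,
    context_mode: str = "base",
    fdr_cutoff: float = FDR_CUTOFF,
    freq_models: dict[str, MutationFrequencyModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the burden test per cohort and emit significant driver NCV calls.

    Parameters
    ----------
    mutations:
        Table with donor_id, cancer_type, chrom, pos (1-based), ref, alt.
    cohorts:
        Mapping cohort name -> boolean mask over ``mutations`` (None = all
        rows).  Defaults to one cohort per cancer type plus ``pan-cancer``.
    freq_models:
        Optional pre-computed substitution-frequency models per cohort;
        estimated from each cohort's mutations when absent.

    Returns
    -------
    (burden, calls):
        ``burden`` has one row per tested (cohort, gene, PWM, direction,
        scheme) with n, k, p_alter, pvalue and BH q-value (pairs with k = 0
        are not tested).  ``calls`` lists the observed NCVs promoted to
        driver calls: their promoter/PWM/direction is significant at
        q < ``fdr_cutoff`` under all three schemes and the NCV itself alters
        that PWM per the catalog.
    """
    if cohorts is None:
        cohorts = {str(ct): mutations["cancer_type"] == ct for ct in sorted(mutations["cancer_type"].unique())}
        if len(cohorts) > 1:
            cohorts["pan-cancer"] = None

    burden_rows = []
    call_rows = []
    call_cols = ["pwm_id", "chrom", "pos", "alt", "call_scheme1", "call_scheme2", "call_scheme3"]
    for cohort, mask in sorted(cohorts.items()):
        muts = mutations if mask is None else mutations[mask]
        muts = _assign_promoters(muts, promoters)
        if muts.empty:
            logger.warning("cohort %s has no promoter mutations", cohort)
            continue
        if freq_models and cohort in freq_models:
            fm = freq_models[cohort]
        else:
            fm = estimate_mutation_frequencies(
                mutations if mask is None else mutations[mask],
                genome=genome, context_mode=context_mode, cancer_type=cohort,
            )

        hits = muts.merge(
            catalog[["chrom", "pos", "ref", "alt", "pwm_id",
                     "call_scheme1", "call_scheme2", "call_scheme3"]],
            on=["chrom", "pos", "ref", "alt"], how="inner",
        )
        n_by_gene = muts.groupby("gene_id").size()

        # per-gene alteration probabilities: weights merged with the catalog once
        p_alter_cache: dict[str, dict[tuple[str, str, int], float]] = {}

        def gene_p_alter(gene_id: str) -> dict[tuple[str, str, int], float]:
            if gene_id not in p_alter_cache:
                weights = promoter_cell_weights(promoters[gene_id], genome, fm)
                probs: dict[tuple[str, str, int], float] = {}
                if not weights.empty:
                    m = weights.merge(catalog, on=["chrom", "pos", "ref", "alt"], how="inner")
                    for scheme in SCHEMES:
                        col = f"call_scheme{scheme}"
                        g = m[m[col].isin(DIRECTIONS)].groupby(["pwm_id", col])["weight"].sum()
                        for (pwm_id, direction), w in g.items():
                            probs[(pwm_id, direction, scheme)] = float(w)
                p_alter_cache[gene_id] = probs
            return p_alter_cache[gene_id]

        # k per (gene, pwm, direction, scheme), counting events (donor occurrences)
        tested: dict[int, list] = {s: [] for s in SCHEMES}
        for scheme in SCHEMES:
            col = f"call_scheme{scheme}"
            sub = hits[hits[col].isin(DIRECTIONS)]
            if sub.empty:
                continue
            grp = sub.groupby(["gene_id", "pwm_id", col]).size()
            for (gene_id, pwm_id, direction), k in grp.items():
                n = int(n_by_gene[gene_id])
                p_alt = gene_p_alter(gene_id).get((pwm_id, direction, scheme), 0.0)
                pval = binomial_upper_tail(int(k), n, p_alt)
                tested[scheme].append([gene_id, pwm_id, direction, int(k), n, p_alt, pval])

        # BH family: every testable triple — p_alter > 0 in any mutated
        # promoter — not just those with observed altering events.  Triples
        # with k = 0 carry p = 1; dropping them would condition the family on
        # the outcome and anti-conservatively shrink the q-values.
        family_size = {s: 0 for s in SCHEMES}
        for gene_id in n_by_gene.index:
            for (_, _, scheme) in gene_p_alter(gene_id):
                family_size[scheme] += 1

        sig_by_scheme: dict[int, set] = {}
        for scheme in SCHEMES:
            rows = tested[scheme]
            if rows:
                pvals = [r[6] for r in rows]
                n_pad = max(family_size[scheme], len(pvals)) - len(pvals)
                padded = np.concatenate([pvals, np.ones(n_pad)])
                qvals = multipletests(padded, method="fdr_bh")[1][: len(pvals)]
            else:
                qvals = []
            sig = set()
            for r, q in zip(rows, qvals):
                burden_rows.append([cohort, scheme, *r, float(q)])
                if q < fdr_cutoff:
                    sig.add((r[0], r[1], r[2]))
            sig_by_scheme[scheme] = sig
        sig_all = sig_by_scheme[1] & sig_by_scheme[2] & sig_by_scheme[3]
        if not sig_all:
            continue

        recurrence = muts.groupby(["chrom", "pos", "ref", "alt"]).size()
        for gene_id, pwm_id, direction in sorted(sig_all):
            ncvs = hits[(hits["gene_id"] == gene_id) & (hits["pwm_id"] == pwm_id)]
            dir_mask = (
                (ncvs["call_scheme1"] == direction)
                | (ncvs["call_scheme2"] == direction)
                | (ncvs["call_scheme3"] == direction)
            )
            for _, r in ncvs[dir_mask].drop_duplicates(["chrom", "pos", "ref", "alt"]).iterrows():
                call_rows.append([
                    cohort, gene_id, pwm_id, direction,
                    r["chrom"], int(r["pos"]), r["ref"], r["alt"],
                    r["call_scheme1"] == direction,
                    r["call_scheme2"] == direction,
                    r["call_scheme3"] == direction,
                    int(recurrence[(r["chrom"], r["pos"], r["ref"], r["alt"])]),
                ])

    burden = pd.DataFrame(
        burden_rows,
        columns=["cohort", "scheme", "gene_id", "pwm_id", "direction", "k", "n", "p_alter", "pvalue", "qvalue"],
    )
    calls = pd.DataFrame(
        call_rows,
        columns=["cohort", "gene_id", "pwm_id", "direction", "chrom", "pos", "ref", "alt",
                 "sig_scheme1", "sig_scheme2", "sig_scheme3", "recurrence"],
    )
    burden = burden.sort_values(["cohort", "scheme", "gene_id", "pwm_id", "direction"]).reset_index(drop=True)
    calls = calls.sort_values(["cohort", "gene_id", "pwm_id", "direction", "chrom", "pos", "alt"]).reset_index(drop=True)
    return burden, calls
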