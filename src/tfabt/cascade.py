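"""Cofactor-recruitment microarray (CASCADE-style) analytics.

Protein-binding microarrays report how strongly a transcriptional cofactor is
recruited to each DNA probe.  Fluorescence is standardized against a set of
background probes (z-scores in log-fluorescence space), differential
recruitment between reference and alternate alleles is tested per probe
sequence with Student's t-tests and aggregated with Fisher's method, and
binding-modulating variants (bmVars) must jointly satisfy a magnitude, a
signal and a significance criterion in both replicate experiments.

Single-variant probe scans of a 26-mer locus yield two motif
representations: a median-centered delta-z matrix (an energy-like matrix)
and a position probability matrix from a softmax with a signal-dependent
inverse-temperature beta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
PROBE_LEN = 26
REGISTERS = (0, -5, 5)  # preference order for tie-breaking
ORIENTATIONS = ("fwd", "rev")
N_REPLICATES = 5

MAX_Z_CUTOFF = 2.0
DELTA_Z_CUTOFF = 2.0
AGG_P_CUTOFF = 1e-3

PROBE_COLUMNS = ["locus_id", "allele", "register", "orientation", "replicate", "experiment", "cof", "value"]


@dataclass
class DifferentialBindingResult:
    locus_id: str
    cof: str
    experiment: str
    delta_z: float          # mean z(ref) - mean z(alt) over all 30+30 probes
    aggregate_p: float      # Fisher-combined over the 6 per-sequence t-tests
    max_allele_z: float     # larger of the two allele mean z-scores
    passes: bool


@dataclass
class DeltaZMatrix:
    locus_id: str
    cof: str
    seed_sequence: str
    z_seed: float
    values: np.ndarray  # (26, 4); NaN rows where variant probes were missing


@dataclass
class PPMMatrix:
    locus_id: str
    cof: str
    probs: np.ndarray  # (26, 4), rows sum to 1
    beta: float


# ---------------------------------------------------------------------------
# z-score transform
# ---------------------------------------------------------------------------

def zscore_transform(values: np.ndarray, background_values: np.ndarray) -> np.ndarray:
    """Standardize fluorescence against background probes in log space.

    z = (log v - mean(log background)) / sd(log background).  Non-positive
    fluorescence values cannot be log-transformed; they come back as NaN with
    a warning so callers can exclude the records.
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.shape[0] < 10:
        raise ValueError("need at least 10 background probes")
    if (bg <= 0).any():
        raise ValueError("background fluorescence must be positive")
    log_bg = np.log(bg)
    mu, sd = log_bg.mean(), log_bg.std(ddof=1)
    if sd == 0:
        raise ValueError("background fluorescence has zero variance")
    vals = np.asarray(values, dtype=float)
    out = np.full(vals.shape, np.nan)
    ok = vals > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} non-positive fluorescence value(s) excluded", stacklevel=2)
    out[ok] = (np.log(vals[ok]) - mu) / sd
    return out


def fisher_combine(pvalues) -> float:
    """Fisher's method: survival of chi-square(2m) at -2 * sum(log p)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-value clamped to smallest positive float", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# Ref/Alt differential binding
# ---------------------------------------------------------------------------

def read_probe_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    return df


def refalt_test(slice_df: pd.DataFrame, z_col: str = "z") -> DifferentialBindingResult:
    """Differential-binding statistics for one locus x cofactor x experiment.

    ``slice_df`` must contain z-scores (column ``z_col``) for both alleles in
    all six (register, orientation) sequence cells, five replicates each.
    Each cell is tested with an equal-variance two-sided Student's t-test
    (5 vs 5, 8 df); the six p-values are Fisher-combined; the magnitude is
    the difference of the allele mean z-scores over all 30 probes each.
    """
    locus = str(slice_df["locus_id"].iloc[0])
    cof = str(slice_df["cof"].iloc[0]) if "cof" in slice_df else ""
    exp = str(slice_df["experiment"].iloc[0]) if "experiment" in slice_df else ""
    pvals = []
    for reg in sorted(set(slice_df["register"])):
        for ori in ORIENTATIONS:
            cell = slice_df[(slice_df["register"] == reg) & (slice_df["orientation"] == ori)]
            ref = cell.loc[cell["allele"] == "ref", z_col].to_numpy()
            alt = cell.loc[cell["allele"] == "alt", z_col].to_numpy()
            if len(ref) != N_REPLICATES or len(alt) != N_REPLICATES:
                raise ValueError(f"locus {locus}: missing replicates in cell ({reg}, {ori})")
            pvals.append(stats.ttest_ind(ref, alt, equal_var=True).pvalue)
    ref_all = slice_df.loc[slice_df["allele"] == "ref", z_col].to_numpy()
    alt_all = slice_df.loc[slice_df["allele"] == "alt", z_col].to_numpy()
    delta = float(ref_all.mean() - alt_all.mean())
    max_z = float(max(ref_all.mean(), alt_all.mean()))
    agg = fisher_combine(pvals)
    passes = (max_z > MAX_Z_CUTOFF) and (abs(delta) > DELTA_Z_CUTOFF) and (agg < AGG_P_CUTOFF)
    return DifferentialBindingResult(locus, cof, exp, delta, agg, max_z, passes)


def refalt_analysis(
    probe_df: pd.DataFrame,
    backgrounds: dict[str, np.ndarray],
    value_col: str = "value",
) -> pd.DataFrame:
    """Vectorized Ref/Alt analysis of a whole probe table.

    ``backgrounds`` maps experiment id to its background-probe fluorescence
    vector.  Returns one row per (locus, cof, experiment) with delta_z,
    aggregate_p, max_allele_z, passes, and a ``bmvar`` flag per (locus, cof)
    requiring a pass in both (all) experiments.
    """
    df = probe_df[probe_df["allele"].isin(["ref", "alt"])].copy()
    parts = []
    for exp, grp in df.groupby("experiment", sort=True):
        g = grp.copy()
        g["z"] = zscore_transform(g[value_col].to_numpy(), backgrounds[str(exp)])
        parts.append(g)
    df = pd.concat(parts, ignore_index=True)

    cell = df.groupby(["locus_id", "cof", "experiment", "register", "orientation", "allele"])["z"]
    stats_df = cell.agg(["mean", "var", "count"]).reset_index()
    wide = stats_df.pivot_table(
        index=["locus_id", "cof", "experiment", "register", "orientation"],
        columns="allele", values=["mean", "var", "count"],
    )
    m_ref, m_alt = wide[("mean", "ref")], wide[("mean", "alt")]
    v_ref, v_alt = wide[("var", "ref")], wide[("var", "alt")]
    n_ref, n_alt = wide[("count", "ref")], wide[("count", "alt")]
    if (n_ref != N_REPLICATES).any() or (n_alt != N_REPLICATES).any():
        raise ValueError("every (locus, allele, register, orientation) cell needs exactly 5 replicates")
    sp2 = ((n_ref - 1) * v_ref + (n_alt - 1) * v_alt) / (n_ref + n_alt - 2)
    tstat = (m_ref - m_alt) / np.sqrt(sp2 * (1 / n_ref + 1 / n_alt))
    dfree = n_ref + n_alt - 2
    pvals = 2 * stats.t.sf(np.abs(tstat), dfree)
    cells = wide.index.to_frame(index=False)[["locus_id", "cof", "experiment"]]
    cells["pvalue"] = np.clip(pvals, np.finfo(float).tiny, 1.0)

    fisher = cells.groupby(["locus_id", "cof", "experiment"]).agg(
        n_cells=("pvalue", "size"), sum_log=("pvalue", lambda s: float(np.log(s).sum()))
    )
    fisher["aggregate_p"] = stats.chi2.sf(-2 * fisher["sum_log"], 2 * fisher["n_cells"])

    allele_means = df.groupby(["locus_id", "cof", "experiment", "allele"])["z"].mean().unstack("allele")
    summary = fisher.join(allele_means)
    summary["delta_z"] = summary["ref"] - summary["alt"]
    summary["max_allele_z"] = summary[["ref", "alt"]].max(axis=1)
    summary["passes"] = (
        (summary["max_allele_z"] > MAX_Z_CUTOFF)
        & (summary["delta_z"].abs() > DELTA_Z_CUTOFF)
        & (summary["aggregate_p"] < AGG_P_CUTOFF)
    )
    summary = summary.reset_index()[
        ["locus_id", "cof", "experiment", "delta_z", "aggregate_p", "max_allele_z", "passes"]
    ]
    bmvar = summary.groupby(["locus_id", "cof"])["passes"].all().rename("bmvar")
    summary = summary.merge(bmvar.reset_index(), on=["locus_id", "cof"], how="left")
    return summary.sort_values(["locus_id", "cof", "experiment"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Seed selection and motif construction
# ---------------------------------------------------------------------------

def select_seed(slice_df: pd.DataFrame, z_col: str = "z") -> tuple[str, int, str]:
    """Choose the (allele, register, orientation) seed for the variant scan.

    The register/orientation cell with the largest absolute ref-vs-alt
    t-statistic wins; within that cell the allele with the larger mean
    z-score is the seed.  Ties prefer forward orientation, then register 0,
    then -5 over +5.
    """
    best = None
    for ori in ORIENTATIONS:
        for reg in REGISTERS:
            cell = slice_df[(slice_df["register"] == reg) & (slice_df["orientation"] == ori)]
            if cell.empty:
                continue
            ref = cell.loc[cell["allele"] == "ref", z_col].to_numpy()
            alt = cell.loc[cell["allele"] == "alt", z_col].to_numpy()
            t = abs(stats.ttest_ind(ref, alt, equal_var=True).statistic)
            # preference order encodes the tie-break: earlier cells win ties
            if best is None or t > best[0] + 1e-12:
                allele = "ref" if ref.mean() >= alt.mean() else "alt"
                best = (t, allele, reg, ori)
    if best is None:
        raise ValueError("no complete cells to select a seed from")
    return best[1], best[2], best[3]


def delta_z_matrix(
    seed_sequence: str,
    z_seed: float,
    sv_z: dict[tuple[int, str], float],
    locus_id: str = "",
    cof: str = "",
) -> DeltaZMatrix:
    """Median-centered delta-z matrix from a single-variant probe scan.

    ``sv_z`` maps (position 1..26, variant base) to the variant probe's
    z-score; the seed base at each position carries ``z_seed``.  Positions
    missing any variant probe are NaN-filled and excluded from motifs.
    """
    if len(seed_sequence) != PROBE_LEN:
        raise ValueError(f"seed sequence must be {PROBE_LEN} nt")
    values = np.full((PROBE_LEN, 4), np.nan)
    for i in range(PROBE_LEN):
        seed_base = seed_sequence[i]
        row = np.full(4, np.nan)
        complete = True
        for j, base in enumerate(BASES):
            if base == seed_base:
                row[j] = z_seed
            else:
                z = sv_z.get((i + 1, base))
                if z is None:
                    complete = False
                else:
                    row[j] = z
        if complete:
            values[i] = row - np.median(row)
        else:
            logger.warning("locus %s position %d: missing variant probe; excluded", locus_id, i + 1)
    return DeltaZMatrix(locus_id=locus_id, cof=cof, seed_sequence=seed_sequence, z_seed=z_seed, values=values)


def beta_schedule(z_seed: float) -> float:
    """Inverse temperature for the PPM softmax; continuous in z_seed.

    beta = 4 for z_seed < 0, 4 - z_seed/2 on [0, 6], and 1 above 6.
    """
    if z_seed < 0:
        return 4.0
    if z_seed <= 6:
        return 4.0 - z_seed / 2.0
    return 1.0


def ppm_from_z(
    z_matrix: np.ndarray,
    z_seed: float,
    locus_id: str = "",
    cof: str = "",
) -> PPMMatrix:
    """Position probability matrix: row-wise softmax of z with scheduled beta."""
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[1] != 4:
        raise ValueError("z matrix must have shape (positions, 4)")
    beta = beta_schedule(z_seed)
    shifted = beta * (z - np.nanmax(z, axis=1, keepdims=True))
    e = np.exp(shifted)
    probs = e / np.nansum(e, axis=1, keepdims=True)
    return PPMMatrix(locus_id=locus_id, cof=cof, probs=probs, beta=beta)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_delta_z_tsv(matrices: list[DeltaZMatrix], path: str) -> None:
    rows = []
    for m in matrices:
        for i in range(m.values.shape[0]):
            rows.append((m.locus_id, m.cof, i + 1, *m.values[i]))
    pd.DataFrame(rows, columns=["locus_id", "cof", "position", "A", "C", "G", "T"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_meme(ppms: list[PPMMatrix], path: str, background: np.ndarray | None = None) -> None:
    """Write PPMs in MEME minimal motif format (NaN rows dropped)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in ppms:
            rows = m.probs[~np.isnan(m.probs).any(axis=1)]
            if rows.shape[0] == 0:
                continue
            name = f"{m.locus_id}_{m.cof}" if m.cof else m.locus_id
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {rows.shape[0]} nsites= 20 E= 0\n")
            for r in rows:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*r))
            fh.write("\n")
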