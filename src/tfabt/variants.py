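"""Ref/alt PWM scoring, gain/loss calls and altered-TFBS catalogs.

A single-nucleotide variant alters a TF's binding when the best-site score of
the surrounding sequence crosses, or moves far across, the PWM's significance
threshold.  Three calling schemes are supported:

1. exactly one allele's best-site score passes the threshold;
2. at least one allele passes and the score difference exceeds 2 (natural-log
   units);
3. same as 2 with a difference exceeding 3.

Scheme thresholds 2 and 3 were chosen in the source method by benchmarking
against ChIP-seq allelic imbalance; :func:`benchmark_schemes` reproduces that
calibration on tabulated allele read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from tfabt.annotation import Promoter, fetch_interval, fetch_window
from tfabt.pwm import PWM, BASES, ScoreThreshold, best_site_score, encode_sequence

logger = logging.getLogger(__name__)

SCHEME_DIFF = {2: 2.0, 3: 3.0}
_EPS = 1e-9

CATALOG_COLUMNS = [
    "chrom", "pos", "ref", "alt", "pwm_id", "ref_score", "alt_score",
    "call_scheme1", "call_scheme2", "call_scheme3",
]


class DataIntegrityError(ValueError):
    """Reference allele does not match the genome."""


@dataclass
class AlteredTfbsRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    pwm_id: str
    ref_score: float
    alt_score: float
    threshold: float
    calls: dict[int, str]  # scheme -> gain | loss | none


@dataclass
class AllelicImbalanceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    pvalue: float
    direction: str | None  # ref_higher | alt_higher | None when balanced


def call_differential_binding(ref_score: float, alt_score: float, threshold: float) -> dict[int, str]:
    """Per-scheme gain/loss/none calls from best-site scores and a threshold.

    NaN scores (windows full of ambiguous bases) yield 'none' everywhere.
    """
    calls = {1: "none", 2: "none", 3: "none"}
    if not (np.isfinite(ref_score) and np.isfinite(alt_score)):
        return calls
    ref_pass = ref_score >= threshold - _EPS
    alt_pass = alt_score >= threshold - _EPS
    direction = "gain" if alt_score > ref_score else ("loss" if ref_score > alt_score else "none")
    if ref_pass != alt_pass:
        calls[1] = "gain" if alt_pass else "loss"
    diff = abs(ref_score - alt_score)
    if (ref_pass or alt_pass) and direction != "none":
        if diff > SCHEME_DIFF[2]:
            calls[2] = direction
        if diff > SCHEME_DIFF[3]:
            calls[3] = direction
    return calls


def score_variant(
    genome: Fasta,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    pwm: PWM,
    threshold: ScoreThreshold | float,
) -> AlteredTfbsRecord:
    """Best-site scores for the reference and alternate alleles at one locus."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("alt allele must differ from ref")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide variants are supported")
    n = pwm.length
    window = fetch_window(genome, chrom, pos, n)
    if window[n - 1] != ref:
        raise DataIntegrityError(
            f"{chrom}:{pos} reference mismatch: genome has {window[n - 1]!r}, record says {ref!r}"
        )
    alt_window = window[: n - 1] + alt + window[n:]
    thr = threshold.threshold if isinstance(threshold, ScoreThreshold) else float(threshold)
    ref_site = best_site_score(window, pwm)
    alt_site = best_site_score(alt_window, pwm)
    ref_score = ref_site.score if ref_site else float("nan")
    alt_score = alt_site.score if alt_site else float("nan")
    return AlteredTfbsRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, pwm_id=pwm.pwm_id,
        ref_score=ref_score, alt_score=alt_score, threshold=thr,
        calls=call_differential_binding(ref_score, alt_score, thr),
    )


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

def _interval_catalog(
    seq_ext: str, chrom: str, start: int, pwm: PWM, threshold: float
) -> list[tuple]:
    """Sparse altered-TFBS rows for one 0-based interval.

    ``seq_ext`` is the interval sequence extended by n-1 real (or N-padded)
    flanking bases on each side, so every window overlapping an interval
    position is available.  For each position and alternate base the best-site
    score is obtained incrementally: an allele change at offset c inside a
    window shifts that window's score by the difference of the two column
    log-odds, so no window is rescored from scratch.
    """
    n = pwm.length
    enc = encode_sequence(seq_ext)
    L = len(seq_ext) - 2 * (n - 1)
    if L <= 0:
        return []
    los = {"+": pwm.log_odds, "-": pwm.reverse_complement_log_odds()}
    if not np.isfinite(threshold):
        return []

    # per-strand window scores over the extended sequence (NaN where invalid)
    n_win = len(seq_ext) - n + 1
    win = np.lib.stride_tricks.sliding_window_view(enc, n)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    W = {}
    for strand, lo in los.items():
        scores = lo[np.arange(n)[None, :], safe].sum(axis=1)
        scores[~valid] = -np.inf
        W[strand] = scores

    qs = np.arange(n - 1, n - 1 + L)  # extended coords of interval positions
    center_ok = enc[qs] >= 0

    # ref best-site score per position: max over the n windows covering it, both strands
    # cover[c] selects window starting at q - c
    cover_idx = qs[:, None] - np.arange(n)[None, :]  # (L, n)
    in_range = (cover_idx >= 0) & (cover_idx < n_win)
    safe_idx = np.clip(cover_idx, 0, n_win - 1)
    ref_best = np.full(L, -np.inf)
    # alt best per (position, base): updated window scores
    alt_best = np.full((L, 4), -np.inf)
    for strand, lo in los.items():
        Wmat = np.where(in_range, W[strand][safe_idx], -np.inf)  # (L, n)
        ref_best = np.maximum(ref_best, Wmat.max(axis=1))
        # column hit by the center position in a window starting at q-c is c
        ref_col = lo[np.arange(n)[None, :], np.where(center_ok, enc[qs], 0)[:, None]]  # (L, n)
        for b in range(4):
            delta = lo[np.arange(n), b][None, :] - ref_col  # (L, n)
            upd = Wmat + delta
            alt_best[:, b] = np.maximum(alt_best[:, b], upd.max(axis=1))

    # vectorized calls over all (position, alt) cells; emit only altering cells
    rs = ref_best[:, None]                      # (L, 1)
    as_ = alt_best                              # (L, 4)
    finite = np.isfinite(rs) & np.isfinite(as_)
    ref_pass = rs >= threshold - _EPS
    alt_pass = as_ >= threshold - _EPS
    diff = as_ - rs
    with np.errstate(invalid="ignore"):
        gain_dir = diff > 0
        loss_dir = diff < 0
    s1 = finite & (ref_pass != alt_pass)
    base2 = finite & (ref_pass | alt_pass)
    s2 = base2 & (np.abs(diff) > SCHEME_DIFF[2])
    s3 = base2 & (np.abs(diff) > SCHEME_DIFF[3])
    ref_base = np.where(center_ok, enc[qs], -1)
    is_alt = np.arange(4)[None, :] != ref_base[:, None]
    usable = is_alt & center_ok[:, None]
    any_call = usable & (s1 | s2 | s3)
    pi, bi = np.nonzero(any_call)

    def _call(sel, gain, loss):
        out = np.full(pi.shape, "none", dtype=object)
        out[sel[pi, bi] & gain[pi, bi]] = "gain"
        out[sel[pi, bi] & loss[pi, bi]] = "loss"
        return out

    base_arr = np.array(list(BASES))
    rows = list(zip(
        [chrom] * len(pi),
        (start + pi + 1).tolist(),
        base_arr[ref_base[pi]],
        base_arr[bi],
        [pwm.pwm_id] * len(pi),
        ref_best[pi].tolist(),
        alt_best[pi, bi].tolist(),
        _call(s1, gain_dir, loss_dir),
        _call(s2, gain_dir, loss_dir),
        _call(s3, gain_dir, loss_dir),
    ))
    return rows


def build_catalog(
    genome: Fasta,
    promoters: dict[str, Promoter] | list[tuple[str, int, int]],
    pwms: list[PWM],
    thresholds: dict[str, ScoreThreshold | float],
) -> pd.DataFrame:
    """Sparse altered-TFBS catalog over the given regions.

    Every (position, alternate allele, PWM) cell whose ref/alt best-site
    scores trigger a gain or loss under any scheme is emitted; silent cells
    are omitted.  Output is deterministically ordered by
    (chrom, pos, alt, pwm_id).
    """
    if isinstance(promoters, dict):
        intervals = sorted({iv for p in promoters.values() for iv in p.intervals})
    else:
        intervals = sorted(promoters)
    rows: list[tuple] = []
    for chrom, start, end in intervals:
        for pwm in pwms:
            thr = thresholds[pwm.pwm_id]
            thr_val = thr.threshold if isinstance(thr, ScoreThreshold) else float(thr)
            n = pwm.length
            seq_ext = fetch_interval(genome, chrom, start - (n - 1), end + (n - 1))
            rows.extend(_interval_catalog(seq_ext, chrom, start, pwm, thr_val))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df = df.sort_values(["chrom", "pos", "alt", "pwm_id"], kind="mergesort").reset_index(drop=True)
    return df.drop_duplicates(subset=["chrom", "pos", "alt", "pwm_id"]).reset_index(drop=True)


def write_catalog(catalog: pd.DataFrame, path: str) -> None:
    catalog.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_catalog(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# ChIP-seq allelic imbalance and scheme benchmarking
# ---------------------------------------------------------------------------

def allelic_imbalance_test(
    ref_reads: int, alt_reads: int, chrom: str = "", pos: int = 0, ref: str = "", alt: str = ""
) -> AllelicImbalanceCall:
    """Two-sided exact binomial test of allele read counts against p0 = 0.5."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        raise ValueError("zero total reads")
    p = stats.binomtest(ref_reads, total, 0.5, alternative="two-sided").pvalue
    direction = None
    if ref_reads > alt_reads:
        direction = "ref_higher"
    elif alt_reads > ref_reads:
        direction = "alt_higher"
    return AllelicImbalanceCall(chrom, pos, ref, alt, ref_reads, alt_reads, float(p), direction)


def _f_value(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def benchmark_schemes(
    imbalance: pd.DataFrame,
    catalog: pd.DataFrame,
    diff_grid: range = range(0, 8),
    p_cutoff: float = 0.01,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-TF F-values for candidate calling schemes against allelic imbalance.

    ``imbalance`` needs columns chrom, pos, ref, alt, ref_reads, alt_reads.
    Loci with >= ``min_reads`` total reads are used; those with binomial
    p < ``p_cutoff`` are the positives, and a prediction only counts as a true
    positive when its gain/loss direction matches the imbalance direction
    (a binding gain should put more reads on the alternate allele).

    Candidates are the threshold-only scheme ('pass') plus one scheme per
    score-difference cutoff in ``diff_grid``.
    """
    imb = imbalance.copy()
    imb["total"] = imb["ref_reads"] + imb["alt_reads"]
    imb = imb[imb["total"] >= min_reads].copy()
    if imb.empty or catalog.empty:
        logger.warning("empty intersection between imbalance calls and catalog")
        return pd.DataFrame(columns=["pwm_id", "scheme", "tp", "fp", "fn", "tn", "f_value", "accuracy"])
    imb["pvalue"] = [
        stats.binomtest(int(r), int(t), 0.5).pvalue for r, t in zip(imb["ref_reads"], imb["total"])
    ]
    imb["is_pos"] = imb["pvalue"] < p_cutoff
    imb["imb_dir"] = np.where(
        imb["ref_reads"] > imb["alt_reads"], "loss",  # more ref reads: alt allele binds less
        np.where(imb["alt_reads"] > imb["ref_reads"], "gain", "none"),
    )
    merged = imb.merge(catalog, on=["chrom", "pos", "ref", "alt"], how="inner")
    if merged.empty:
        logger.warning("empty intersection between imbalance calls and catalog")
        return pd.DataFrame(columns=["pwm_id", "scheme", "tp", "fp", "fn", "tn", "f_value", "accuracy"])

    thr_pass = merged["call_scheme1"] != "none"
    diff = merged["alt_score"] - merged["ref_score"]
    any_pass = thr_pass | (merged["call_scheme2"] != "none") | (merged["call_scheme3"] != "none")
    rows = []
    schemes: list[tuple[str, pd.Series]] = [("pass", merged["call_scheme1"])]
    for d in diff_grid:
        pred = pd.Series(
            np.where(any_pass & (diff.abs() > d), np.where(diff > 0, "gain", "loss"), "none"),
            index=merged.index,
        )
        schemes.append((f"diff>{d}", pred))
    for pwm_id, grp_idx in merged.groupby("pwm_id").groups.items():
        sub = merged.loc[grp_idx]
        for name, pred_all in schemes:
            pred = pred_all.loc[grp_idx]
            predicted = pred != "none"
            tp = int(((pred == sub["imb_dir"]) & sub["is_pos"]).sum())
            fp = int((predicted & ~((pred == sub["imb_dir"]) & sub["is_pos"])).sum())
            fn = int((sub["is_pos"] & ~((pred == sub["imb_dir"]) & sub["is_pos"])).sum())
            tn = int((~predicted & ~sub["is_pos"]).sum())
            acc = (tp + tn) / len(sub) if len(sub) else 0.0
            rows.append((pwm_id, name, tp, fp, fn, tn, _f_value(tp, fp, fn), acc))
    out = pd.DataFrame(rows, columns=["pwm_id", "scheme", "tp", "fp", "fn", "tn", "f_value", "accuracy"])
    return out.sort_values(["pwm_id", "f_value"], ascending=[True, False]).reset_index(drop=True)
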