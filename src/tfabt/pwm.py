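"""Position weight matrices: parsing, log-odds scoring and exact thresholds.

A PWM models a TF's binding specificity as independent per-position base
probabilities.  A candidate site ``s`` of the same length ``n`` is scored as
the natural-log likelihood ratio against a background base composition ``b``::

    F(s, M) = sum_i log( M[s_i, i] / b[s_i] )

Scores from different PWMs are comparable only through their background tail
probability, so each PWM carries an exact score threshold for a target
p-value ``alpha``: the smallest achievable score whose probability under the
background model is at most ``alpha``.  The tail distribution is computed
exactly by dynamic programming over a discretized score grid (the classic
TFM-pvalue construction), not by sampling.
"""

from __future__ import annotations

import glob
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_BACKGROUND = np.full(4, 0.25)
DEFAULT_ALPHA = 1e-4
DEFAULT_GRANULARITY = 1e-3


class PWMParseError(ValueError):
    """Raised when a matrix file cannot be interpreted as a PWM."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0..T=3); anything else becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PWM:
    """A per-position base-probability matrix plus its background model.

    ``probs`` has shape (n, 4) with columns ordered A, C, G, T; every row sums
    to 1 and all entries are strictly positive after pseudocount
    renormalization, so log-odds are always finite.
    """

    pwm_id: str
    probs: np.ndarray
    tf_name: str = ""
    tf_family: str = ""
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise PWMParseError(f"{self.pwm_id}: matrix must have shape (n>=1, 4)")
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise PWMParseError(f"{self.pwm_id}: background must be a positive probability vector")
        if (probs <= 0).any():
            raise PWMParseError(f"{self.pwm_id}: probabilities must be strictly positive (apply pseudocount)")
        if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise PWMParseError(f"{self.pwm_id}: rows must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_counts(
        cls,
        pwm_id: str,
        matrix: np.ndarray,
        *,
        tf_name: str = "",
        tf_family: str = "",
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        """Build a PWM from a counts or frequency matrix of shape (n, 4).

        Columns are first normalized to probabilities, then a pseudocount is
        added to every entry and rows renormalized, guaranteeing finite logs.
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise PWMParseError(f"{pwm_id}: expected an (n, 4) matrix, got {matrix.shape}")
        sums = matrix.sum(axis=1)
        if (sums <= 0).any() or not np.isfinite(matrix).all() or (matrix < 0).any():
            raise PWMParseError(f"{pwm_id}: each position must have non-negative entries with a positive sum")
        probs = matrix / sums[:, None]
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1)[:, None]
        bg = DEFAULT_BACKGROUND.copy() if background is None else np.asarray(background, dtype=float)
        return cls(pwm_id=pwm_id, probs=probs, tf_name=tf_name, tf_family=tf_family,
                   background=bg, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(n, 4) natural-log odds matrix log(probs / background)."""
        return np.log(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement_log_odds(self) -> np.ndarray:
        """Log-odds of the reverse-complement motif, for minus-strand scoring."""
        return self.log_odds[::-1, _COMPLEMENT_IDX]


@dataclass(frozen=True)
class ScoreThreshold:
    """Minimal score whose background tail probability is <= alpha.

    ``threshold`` is reported on the undiscretized score scale: it is the
    smallest achievable real score whose discretized value reaches the grid
    threshold found by the dynamic program.  ``math.inf`` means no achievable
    score has tail probability <= alpha (e.g. an uninformative PWM).
    """

    pwm_id: str
    alpha: float
    threshold: float
    granularity: float


@dataclass(frozen=True)
class SiteScore:
    """Best log-odds site overlapping a genomic position."""

    score: float
    offset: int  # 0-based start of the winning n-mer within the 2n-1 window
    strand: str  # '+' or '-'


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_cisbp_file(path: str, pseudocount: float) -> PWM:
    """Parse one CIS-BP text table: header 'Pos A C G T', one row per position."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("pos", "position"):
                continue
            try:
                rows.append([float(x) for x in parts[-4:]])
            except ValueError as exc:
                raise PWMParseError(f"{path}: unparseable row {line!r}") from exc
    pwm_id = os.path.splitext(os.path.basename(path))[0]
    if not rows:
        raise PWMParseError(f"{pwm_id}: empty matrix file {path}")
    return PWM.from_counts(pwm_id, np.array(rows), pseudocount=pseudocount)


def load_pwms(path: str, dialect: str = "cisbp", pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Load PWMs from ``path`` and return them sorted by ``pwm_id``.

    Parameters
    ----------
    path:
        A single matrix file, or a directory of ``*.txt`` matrix files for the
        ``cisbp`` dialect; a (multi-)motif file for the ``jaspar`` dialect.
    dialect:
        ``cisbp`` — whitespace tables with a ``Pos A C G T`` header, one file
        per motif (probabilities or counts; both are renormalized).
        ``jaspar`` — JASPAR-style count matrices, parsed with Bio.motifs.
    """
    if dialect not in ("cisbp", "jaspar"):
        raise ValueError(f"unknown PWM dialect: {dialect!r}")
    pwms: list[PWM] = []
    if dialect == "cisbp":
        if os.path.isdir(path):
            files = sorted(glob.glob(os.path.join(path, "*.txt")))
            if not files:
                raise FileNotFoundError(f"no *.txt matrix files under {path}")
        else:
            files = [path]
        for f in files:
            pwms.append(_parse_cisbp_file(f, pseudocount))
    else:
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
        for m in records:
            counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)], dtype=float)
            pwm_id = m.matrix_id or m.name
            pwms.append(PWM.from_counts(pwm_id, counts, tf_name=m.name or "", pseudocount=pseudocount))
    pwms.sort(key=lambda p: p.pwm_id)
    return pwms


def write_pwms_tsv(pwms: list[PWM], path: str) -> None:
    """Write PWMs to the internal TSV (pwm_id, position, A, C, G, T)."""
    rows = []
    for p in sorted(pwms, key=lambda x: x.pwm_id):
        for i in range(p.length):
            rows.append((p.pwm_id, i + 1, *p.probs[i]))
    pd.DataFrame(rows, columns=["pwm_id", "position", "A", "C", "G", "T"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_pwms_tsv(path: str) -> list[PWM]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for pwm_id, grp in df.groupby("pwm_id", sort=True):
        grp = grp.sort_values("position")
        probs = grp[["A", "C", "G", "T"]].to_numpy(dtype=float)
        # already pseudocounted on write; renormalize defensively
        probs = probs / probs.sum(axis=1)[:, None]
        out.append(PWM(pwm_id=str(pwm_id), probs=probs))
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_sequence(seq: str, pwm: PWM) -> float:
    """Score a length-n sequence with the log-odds sum; NaN if s has non-ACGT.

    A NaN return is the "undefined score" signal for ambiguous bases; a wrong
    length is a caller error and raises.
    """
    idx = encode_sequence(seq)
    if idx.shape[0] != pwm.length:
        raise ValueError(f"sequence length {idx.shape[0]} != PWM length {pwm.length}")
    if (idx < 0).any():
        return math.nan
    return float(pwm.log_odds[np.arange(pwm.length), idx].sum())


def window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of every length-n window of an encoded sequence; NaN where the
    window contains an ambiguous base."""
    n = log_odds.shape[0]
    L = encoded.shape[0]
    if L < n:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(encoded, n)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = log_odds[np.arange(n)[None, :], safe].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def best_site_score(genome_window: str, pwm: PWM) -> SiteScore | None:
    """Best score among the 4n-2 oriented n-mers overlapping the center base.

    ``genome_window`` must have length 2n-1 (pad with N at chromosome edges).
    Windows containing N are skipped.  Ties prefer the forward strand, then
    the leftmost offset.  Returns None when every candidate window is invalid.
    """
    n = pwm.length
    if len(genome_window) != 2 * n - 1:
        raise ValueError(f"window length {len(genome_window)} != 2n-1 = {2 * n - 1}")
    enc = encode_sequence(genome_window)
    fwd = window_scores(enc, pwm.log_odds)
    rev = window_scores(enc, pwm.reverse_complement_log_odds())
    best: SiteScore | None = None
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in range(scores.shape[0]):
            s = scores[off]
            if np.isnan(s):
                continue
            if best is None or s > best.score + 1e-12:
                best = SiteScore(score=float(s), offset=off, strand=strand)
    return best


# ---------------------------------------------------------------------------
# Exact score thresholds
# ---------------------------------------------------------------------------

def _rounded_columns(pwm: PWM, granularity: float) -> np.ndarray:
    """Per-position log-odds rounded to integer grid units."""
    return np.rint(pwm.log_odds / granularity).astype(np.int64)


def score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY) -> tuple[np.ndarray, np.ndarray]:
    """Exact background distribution of the discretized score.

    Returns (grid, prob) where ``grid`` holds integer grid values (multiply by
    ``granularity`` for scores) and ``prob`` the corresponding probabilities
    under independent background draws at each position.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    r = _rounded_columns(pwm, granularity)
    bg = pwm.background
    lo = int(r.min(axis=1).sum())
    hi = int(r.max(axis=1).sum())
    # dist[k] = P(sum == lo_partial + k); grown column by column
    dist = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.length):
        cmin, cmax = int(r[i].min()), int(r[i].max())
        new = np.zeros(dist.shape[0] + (cmax - cmin), dtype=float)
        for b in range(4):
            off = int(r[i, b]) - cmin
            new[off:off + dist.shape[0]] += bg[b] * dist
        dist = new
        cur_lo += cmin
    assert cur_lo == lo and dist.shape[0] == hi - lo + 1
    grid = np.arange(lo, hi + 1)
    return grid, dist


def _min_real_score_at_or_above(pwm: PWM, granularity: float, grid_threshold: int) -> float:
    """Smallest achievable real score among sequences whose discretized score
    reaches ``grid_threshold`` (min-plus dynamic program)."""
    r = _rounded_columns(pwm, granularity)
    lo_real = pwm.log_odds
    minreal = np.array([0.0])
    cur_lo = 0
    for i in range(pwm.length):
        cmin, cmax = int(r[i].min()), int(r[i].max())
        new = np.full(minreal.shape[0] + (cmax - cmin), np.inf)
        for b in range(4):
            off = int(r[i, b]) - cmin
            cand = minreal + lo_real[i, b]
            seg = new[off:off + minreal.shape[0]]
            np.minimum(seg, cand, out=seg)
        minreal = new
        cur_lo += cmin
    grid = np.arange(cur_lo, cur_lo + minreal.shape[0])
    mask = grid >= grid_threshold
    if not mask.any():
        return math.inf
    return float(minreal[mask].min())


def compute_threshold(
    pwm: PWM,
    alpha: float = DEFAULT_ALPHA,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreThreshold:
    """Exact score threshold at significance level ``alpha``.

    Dynamic programming yields the full discretized score distribution under
    the background; the grid threshold is the smallest grid score whose upper
    tail is <= alpha, and the reported threshold is the smallest achievable
    real score whose discretized value reaches that grid score.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    grid, prob = score_distribution(pwm, granularity)
    tail = np.cumsum(prob[::-1])[::-1]
    ok = tail <= alpha + 1e-15
    if not ok.any():
        return ScoreThreshold(pwm.pwm_id, alpha, math.inf, granularity)
    g = int(grid[np.argmax(ok)])
    thr = _min_real_score_at_or_above(pwm, granularity, g)
    return ScoreThreshold(pwm.pwm_id, alpha, thr, granularity)


def write_thresholds(thresholds: list[ScoreThreshold], path: str) -> None:
    pd.DataFrame(
        [(t.pwm_id, t.alpha, t.threshold, t.granularity) for t in thresholds],
        columns=["pwm_id", "alpha", "threshold", "granularity"],
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_thresholds(path: str) -> dict[str, ScoreThreshold]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.pwm_id): ScoreThreshold(str(r.pwm_id), float(r.alpha), float(r.threshold), float(r.granularity))
        for r in df.itertuples()
    }
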