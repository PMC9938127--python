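"""Promoter construction from gene annotation and coordinate-safe sequence access.

Promoters are windows around the transcription start sites (TSS) of
protein-coding transcripts: by default 2000 bp upstream through 250 bp
downstream, oriented by the transcript strand.  Windows from alternative TSSs
of the same gene are merged so recurrent mutations are not double-counted,
and coding sequence (CDS) intervals are subtracted so the burden test only
ever sees non-coding positions.

All internal coordinates are 0-based half-open; variant positions at the I/O
boundary follow the 1-based VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 250


@dataclass
class Promoter:
    """Merged, coding-subtracted promoter intervals of one gene."""

    gene_id: str
    gene_name: str
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    tss_list: list[tuple[int, str]] = field(default_factory=list)  # (1-based pos, strand)

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        p0 = pos - 1
        return any(c == chrom and s <= p0 < e for c, s, e in self.intervals)


def _is_protein_coding(feature) -> bool:
    for key in ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype"):
        vals = feature.attributes.get(key)
        if vals:
            return "protein_coding" in vals
    return False


def _attr(feature, key: str, default: str = "") -> str:
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def promoter_window(tss0: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """0-based half-open window around a 0-based TSS, oriented by strand."""
    if strand == "+":
        return tss0 - upstream, tss0 + downstream
    return tss0 - downstream, tss0 + upstream


def build_promoters(
    annotation: str | gffutils.FeatureDB,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, Promoter]:
    """Build merged, CDS-subtracted promoters for every protein-coding gene.

    Parameters
    ----------
    annotation:
        Path to a GENCODE-dialect GTF file, or an open ``gffutils.FeatureDB``.
    upstream, downstream:
        Promoter extent in bp relative to each TSS, in transcript orientation.
    chrom_sizes:
        Optional chromosome lengths used to clip windows to chromosome bounds.

    Returns a dict keyed by gene_id; genes whose promoter is entirely coding
    are dropped with a warning.
    """
    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        with open(annotation) as fh:
            has_features = any(line.strip() and not line.startswith("#") for line in fh)
        if not has_features:
            return {}
        db = gffutils.create_db(
            annotation, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )

    win_rows = []
    tss_by_gene: dict[str, list[tuple[int, str]]] = {}
    name_by_gene: dict[str, str] = {}
    for t in db.features_of_type("transcript"):
        if not _is_protein_coding(t):
            continue
        gene_id = _attr(t, "gene_id")
        if not gene_id:
            continue
        if t.strand not in ("+", "-"):
            logger.warning("transcript %s has no strand; skipped", _attr(t, "transcript_id", t.id))
            continue
        tss1 = t.start if t.strand == "+" else t.end  # 1-based first transcribed base
        start, end = promoter_window(tss1 - 1, t.strand, upstream, downstream)
        start = max(start, 0)
        if chrom_sizes and t.seqid in chrom_sizes:
            end = min(end, chrom_sizes[t.seqid])
        if end <= start:
            continue
        win_rows.append((t.seqid, start, end, gene_id))
        tss_by_gene.setdefault(gene_id, []).append((tss1, t.strand))
        name_by_gene.setdefault(gene_id, _attr(t, "gene_name", gene_id))

    cds_rows = [(c.seqid, c.start - 1, c.end) for c in db.features_of_type("CDS")]
    cds_gr = (
        pr.PyRanges(pd.DataFrame(cds_rows, columns=["Chromosome", "Start", "End"])).merge()
        if cds_rows
        else None
    )

    promoters: dict[str, Promoter] = {}
    if not win_rows:
        return promoters
    win_df = pd.DataFrame(win_rows, columns=["Chromosome", "Start", "End", "gene_id"])
    for gene_id, grp in win_df.groupby("gene_id", sort=True):
        gr = pr.PyRanges(grp[["Chromosome", "Start", "End"]]).merge()
        if cds_gr is not None:
            gr = gr.subtract(cds_gr)
        df = gr.df if hasattr(gr, "df") else pd.DataFrame()
        if df.empty:
            logger.warning("promoter of gene %s fully overlaps coding sequence; dropped", gene_id)
            continue
        df = df.sort_values(["Chromosome", "Start"])
        intervals = [(str(r.Chromosome), int(r.Start), int(r.End)) for r in df.itertuples()]
        promoters[gene_id] = Promoter(
            gene_id=gene_id,
            gene_name=name_by_gene.get(gene_id, gene_id),
            intervals=intervals,
            tss_list=sorted(set(tss_by_gene.get(gene_id, []))),
        )
    return promoters


def fetch_window(genome: Fasta, chrom: str, center: int, n: int) -> str:
    """Uppercased 2n-1 window centered on a 1-based position, N-padded at edges."""
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    chrom_len = len(genome[chrom])
    c0 = center - 1
    if not (0 <= c0 < chrom_len):
        raise ValueError(f"position {center} outside chromosome {chrom} (length {chrom_len})")
    start = c0 - (n - 1)
    end = c0 + n
    left_pad = max(0, -start)
    right_pad = max(0, end - chrom_len)
    seq = genome[chrom][max(start, 0):min(end, chrom_len)].seq.upper()
    return "N" * left_pad + seq + "N" * right_pad


def fetch_interval(genome: Fasta, chrom: str, start: int, end: int) -> str:
    """Uppercased sequence for a 0-based half-open interval, N-padded at edges."""
    chrom_len = len(genome[chrom])
    left_pad = max(0, -start)
    right_pad = max(0, end - chrom_len)
    seq = genome[chrom][max(start, 0):min(end, chrom_len)].seq.upper()
    return "N" * left_pad + seq + "N" * right_pad


def write_bed(promoters: dict[str, Promoter], path: str) -> None:
    """Write promoter intervals as BED4 (name = gene_id)."""
    rows = []
    for gene_id in sorted(promoters):
        for chrom, start, end in promoters[gene_id].intervals:
            rows.append((chrom, start, end, gene_id))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, gene_id in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene_id}\n")


def read_bed(path: str) -> dict[str, Promoter]:
    """Read a BED4 file back into Promoter objects (no TSS metadata)."""
    out: dict[str, Promoter] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, gene_id = line.split()[:4]
            out.setdefault(gene_id, Promoter(gene_id, gene_id, [])).intervals.append(
                (chrom, int(start), int(end))
            )
    for p in out.values():
        p.intervals.sort()
    return out
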