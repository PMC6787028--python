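"""Reading gene annotation and read alignments; writing BED/GTF/TSV outputs.

GTF input is 1-based closed and converted to the package's 0-based half-open
convention on read. BED is consumed and produced natively 0-based half-open.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils
import numpy as np
import pandas as pd
import pysam

from .models import GeneModel, GenomeInterval, genome_to_transcript, transcript_to_genome

log = logging.getLogger(__name__)

__all__ = [
    "ReadAlignment",
    "read_gene_models",
    "read_alignments",
    "alignments_to_frame",
    "read_alignment_frame",
    "write_gene_models_gtf",
    "write_alignment_frame_bed",
]


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned fragment: spliced genomic blocks plus sample labels."""

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    sample: str
    replicate: int
    name: str = ""

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


class GTFParseError(ValueError):
    pass


def _validate_gtf(path: str) -> None:
    """Cheap structural pass so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GTFParseError(f"{path}:{lineno}: bad coordinate range {start}-{end}")


def read_gene_models(path: str) -> list[GeneModel]:
    """Parse a GTF into one :class:`GeneModel` per gene.

    When a gene carries several transcripts the longest one (by summed exon
    length) is kept; ties break on transcript_id for determinism. Transcripts
    without exon features are skipped with a warning.
    """
    _validate_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}  # transcript -> (gene_id, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            continue
        tid = tids[0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gene, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        # GTF 1-based closed -> 0-based half-open
        target.setdefault(tid, []).append((feat.seqid, feat.start - 1, feat.end))

    # group transcripts per gene, keep the longest
    by_gene: dict[str, list[str]] = {}
    for tid, (gene, _) in meta.items():
        by_gene.setdefault(gene, []).append(tid)

    models: list[GeneModel] = []
    for gene in sorted(by_gene):
        candidates = []
        for tid in by_gene[gene]:
            if tid not in exons:
                warnings.warn(f"transcript {tid} has no exon features; skipped")
                continue
            length = sum(e - s for _, s, e in exons[tid])
            candidates.append((length, tid))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, tid = candidates[0]
        _, strand = meta[tid]
        blocks = sorted(exons[tid], key=lambda b: b[1])
        ivs = [GenomeInterval(c, s, e, strand) for c, s, e in blocks]
        model = GeneModel(gene, tid, strand, ivs)
        if tid in cds:
            cds_blocks = sorted(cds[tid], key=lambda b: b[1])
            g_lo = cds_blocks[0][1]
            g_hi = cds_blocks[-1][2] - 1
            t_lo = genome_to_transcript(model, g_lo)
            t_hi = genome_to_transcript(model, g_hi)
            if t_lo is None or t_hi is None:
                warnings.warn(f"transcript {tid}: CDS outside exons; ignored")
            else:
                model.cds_start = min(t_lo, t_hi)
                model.cds_end = max(t_lo, t_hi) + 1
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# alignments


def _parse_bed_line(line: str, lineno: int, path: str) -> tuple[str, list[tuple[int, int]], str, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED needs >=3 fields")
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    if start < 0 or end < start:
        raise ValueError(f"{path}:{lineno}: bad BED coordinates {start}-{end}")
    name = fields[3] if len(fields) > 3 else f"rec{lineno}"
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
    if len(fields) >= 12:  # BED12 spliced blocks
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"{path}:{lineno}: blockCount mismatch")
        blocks = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
    else:
        blocks = [(start, end)]
    return chrom, blocks, strand, name


def read_alignments(path: str, sample: str, replicate: int) -> Iterator[ReadAlignment]:
    """Stream alignments from a BED6/BED12 or SAM file with sample labels.

    Unmapped SAM records are skipped; duplicate-flagged SAM records are
    excluded from counting (BED carries no duplicate flag).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, blocks, strand, name = _parse_bed_line(line, lineno, path)
                yield ReadAlignment(chrom, tuple(blocks), strand, sample, replicate, name)
    elif ext == ".sam":
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_duplicate:
                    continue
                blocks = tuple((s, e) for s, e in rec.get_blocks())
                if not blocks:
                    continue
                strand = "-" if rec.is_reverse else "+"
                yield ReadAlignment(
                    rec.reference_name, blocks, strand, sample, replicate, rec.query_name or ""
                )
    else:
        raise ValueError(f"unknown alignment format {ext!r} (expected .bed or .sam)")


def alignments_to_frame(alignments: Iterable[ReadAlignment]) -> pd.DataFrame:
    """Columnar block table (chrom, start, end, read_id) for fast counting.

    ``read_id`` enumerates alignment *records*, so the number of distinct ids
    equals the library total.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    rids: list[int] = []
    strands: list[str] = []
    for rid, aln in enumerate(alignments):
        for s, e in aln.blocks:
            chroms.append(aln.chrom)
            starts.append(s)
            ends.append(e)
            rids.append(rid)
            strands.append(aln.strand)
    return pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype="str"),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "read_id": np.asarray(rids, dtype=np.int64),
            "strand": pd.array(strands, dtype="str"),
        }
    )


def read_alignment_frame(path: str, sample: str = "sample", replicate: int = 1) -> pd.DataFrame:
    """Load a BED/SAM file directly into the columnar block table."""
    return alignments_to_frame(read_alignments(path, sample, replicate))


# ---------------------------------------------------------------------------
# writers


def write_gene_models_gtf(models: Iterable[GeneModel], path: str) -> None:
    """Write models as GTF (1-based closed), including exon and CDS features."""
    with open(path, "w") as out:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = (m.genomic_start + 1, m.genomic_end)
            for ftype, s, e in [("gene", *span), ("transcript", *span)]:
                out.write(
                    f"{m.chrom}\tmeripeak\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for exon in m.exons:
                out.write(
                    f"{m.chrom}\tmeripeak\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.has_cds:
                for blk in transcript_to_genome(m, m.cds_start, m.cds_end):
                    out.write(
                        f"{m.chrom}\tmeripeak\tCDS\t{blk.start + 1}\t{blk.end}\t.\t"
                        f"{m.strand}\t0\t{attrs}\n"
                    )


def write_alignment_frame_bed(frame: pd.DataFrame, path: str) -> None:
    """Write a columnar block table as BED12 (one record per read)."""
    with open(path, "w") as out:
        if frame.empty:
            return
        df = frame.sort_values(["read_id", "start"], kind="stable")
        rid = df["read_id"].to_numpy()
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        chroms = df["chrom"].to_numpy()
        strands = df["strand"].to_numpy() if "strand" in df else np.full(len(df), "+")
        uniq, first, nblocks = np.unique(rid, return_index=True, return_counts=True)
        lines = []
        for u, f0, nb in zip(uniq, first, nblocks):
            cs = int(starts[f0])
            ce = int(ends[f0 + nb - 1])
            sizes = ",".join(str(int(ends[f0 + j] - starts[f0 + j])) for j in range(nb))
            offs = ",".join(str(int(starts[f0 + j] - cs)) for j in range(nb))
            lines.append(
                f"{chroms[f0]}\t{cs}\t{ce}\tfrag{u}\t0\t{strands[f0]}\t{cs}\t{cs}\t0\t"
                f"{nb}\t{sizes},\t{offs},\n"
            )
        out.writelines(lines)
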