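"""Transcript models and transcript <-> genome coordinate conversion.

All internal coordinates are 0-based half-open. Transcript coordinates run
5' -> 3' in the sense of the transcript: for a minus-strand gene, transcript
position 0 is the genomically *rightmost* exonic base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GenomeInterval", "GeneModel", "transcript_to_genome", "genome_to_transcript"]


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One transcript standing in for its gene.

    ``exons`` are sorted by genomic start and non-overlapping, all on the
    same chromosome and strand. ``cds_start``/``cds_end`` are transcript
    coordinates (0-based half-open); they may be absent (``None``) for
    non-coding transcripts. Annotations can carry partial CDSs, so the CDS
    length is not required to be a multiple of 3.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: list[GenomeInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    # cumulative exon lengths on the genomic (plus) axis, cached lazily
    _cum: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: gene model needs >=1 exon")
        exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chromosomes")
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if self.cds_start is not None or self.cds_end is not None:
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.transcript_id}: partial CDS bounds")
            if not (0 <= self.cds_start < self.cds_end <= self.transcript_length):
                raise ValueError(f"{self.transcript_id}: CDS out of transcript bounds")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def genomic_start(self) -> int:
        return self.exons[0].start

    @property
    def genomic_end(self) -> int:
        return self.exons[-1].end

    def _cumlens(self) -> np.ndarray:
        """Plus-axis transcript offset of each exon start (len n_exons + 1)."""
        if self._cum is None:
            lens = np.fromiter((len(e) for e in self.exons), dtype=np.int64)
            self._cum = np.concatenate([[0], np.cumsum(lens)])
        return self._cum


def transcript_to_genome(model: GeneModel, t_start: int, t_end: int) -> list[GenomeInterval]:
    """Project the transcript interval [t_start, t_end) to genomic blocks.

    Blocks are returned in ascending genomic order; their lengths sum to
    ``t_end - t_start``. For minus-strand models transcript coordinate 0 maps
    to the genomically rightmost exonic base.
    """
    L = model.transcript_length
    if not (0 <= t_start < t_end <= L):
        raise IndexError(
            f"transcript interval [{t_start}, {t_end}) outside [0, {L}) "
            f"for {model.transcript_id}"
        )
    # work on the plus axis (5'->3' walking exons left to right genomically)
    if model.strand == "-":
        a, b = L - t_end, L - t_start
    else:
        a, b = t_start, t_end
    cum = model._cumlens()
    blocks: list[GenomeInterval] = []
    i = int(np.searchsorted(cum, a, side="right")) - 1
    pos = a
    while pos < b:
        exon = model.exons[i]
        take = min(b, cum[i + 1]) - pos
        g0 = exon.start + (pos - int(cum[i]))
        blocks.append(GenomeInterval(model.chrom, int(g0), int(g0 + take), model.strand))
        pos += take
        i += 1
    return blocks


def genome_to_transcript(model: GeneModel, g_pos: int) -> Optional[int]:
    """Transcript coordinate of an exonic genomic base; ``None`` off-exon."""
    if g_pos < 0:
        raise ValueError("genomic position must be >= 0")
    cum = model._cumlens()
    for i, exon in enumerate(model.exons):
        if exon.start <= g_pos < exon.end:
            plus_t = int(cum[i]) + (g_pos - exon.start)
            if model.strand == "-":
                return model.transcript_length - 1 - plus_t
            return plus_t
    return None
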