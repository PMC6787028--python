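"""Ribosome-profiling counting and translation efficiency (TE).

Footprint reads are counted only when their 5' end (in transcript
coordinates, strand-aware) falls inside the CDS trimmed by 20 nt at each
end — i.e. in [cds_start + trim, cds_end - trim) — which avoids the
initiation and termination pile-ups. TE is the size-normalized ratio of
ribosome-bound to total mRNA counts, reported on a log2 scale with a
pseudocount guarding zeros.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ReadAlignment
from .models import GeneModel, genome_to_transcript

log = logging.getLogger(__name__)

__all__ = ["trimmed_cds_count", "translation_efficiency", "compute_te"]


def _five_prime_end(aln: ReadAlignment, model_strand: str) -> int:
    """Genomic position of the read's 5' base on the transcript strand."""
    if model_strand == "+":
        return aln.blocks[0][0]
    return aln.blocks[-1][1] - 1


def trimmed_cds_count(
    model: GeneModel, alignments: Iterable[ReadAlignment], trim: int = 20
) -> Optional[int]:
    """Count reads whose 5' end lies in [cds_start + trim, cds_end - trim).

    Returns ``None`` (and logs) when the model lacks a CDS or the CDS is too
    short to trim on both sides.
    """
    if not model.has_cds or model.cds_end - model.cds_start <= 2 * trim:
        log.warning("%s: CDS absent or shorter than 2 x %d nt; not counted", model.gene_id, trim)
        return None
    lo, hi = model.cds_start + trim, model.cds_end - trim
    n = 0
    for aln in alignments:
        if aln.chrom != model.chrom:
            continue
        t = genome_to_transcript(model, _five_prime_end(aln, model.strand))
        if t is not None and lo <= t < hi:
            n += 1
    return n


def translation_efficiency(
    ribo: float,
    rna: float,
    ribo_total: Optional[float] = None,
    rna_total: Optional[float] = None,
    pseudocount: float = 0.5,
) -> float:
    """log2 TE of one gene from ribosome and total-mRNA counts.

    Counts are first rescaled to the mean library size (so equal library
    sizes leave counts untouched and common rescaling cancels), then
    te = log2((ribo + pseudocount) / (rna + pseudocount)).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (ribo_total is None) != (rna_total is None):
        raise ValueError("provide both library totals or neither")
    if ribo_total is not None:
        if ribo_total <= 0 or rna_total <= 0:
            raise ValueError("library totals must be > 0")
        ref = (ribo_total + rna_total) / 2.0
        ribo = ribo * ref / ribo_total
        rna = rna * ref / rna_total
    return float(np.log2((ribo + pseudocount) / (rna + pseudocount)))


def compute_te(
    models: Sequence[GeneModel],
    ribo_alignments: Iterable[ReadAlignment],
    rna_alignments: Iterable[ReadAlignment],
    trim: int = 20,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene trimmed-CDS counts and log2 TE for a ribo/RNA library pair.

    Library totals are the full record counts of each input. Genes whose CDS
    cannot be trimmed get NA counts and are excluded from TE.
    """
    ribo_list = list(ribo_alignments)
    rna_list = list(rna_alignments)
    ribo_total, rna_total = len(ribo_list), len(rna_list)
    rows = []
    for model in models:
        rc = trimmed_cds_count(model, ribo_list, trim)
        mc = trimmed_cds_count(model, rna_list, trim)
        te = (
            translation_efficiency(rc, mc, max(ribo_total, 1), max(rna_total, 1), pseudocount)
            if rc is not None and mc is not None
            else np.nan
        )
        rows.append((model.gene_id, rc, mc, te))
    return pd.DataFrame(rows, columns=["gene_id", "ribo_count", "rna_count", "te_log2"])
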