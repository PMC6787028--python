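"""Peak annotation: transcript-region labels, metagene profiles, per-gene
peak-count summaries, and overlap comparisons between peak sets.

Region assignment and metagene placement both use the peak *midpoint* in
transcript coordinates, the standard proxy for an m6A site position.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calling import Peak
from .models import GeneModel

log = logging.getLogger(__name__)

__all__ = [
    "RegionScheme",
    "MetageneProfile",
    "assign_region",
    "metagene_profile",
    "peaks_per_gene",
    "compare_peak_sets",
]


@dataclass(frozen=True)
class RegionScheme:
    """Transcript-region zones: TSS/Stop windows around the start/stop codon
    take precedence over plain 5'UTR/CDS/3'UTR labels."""

    tss_halfwidth: int = 100
    stop_halfwidth: int = 100
    labels: tuple[str, ...] = ("TSS", "5UTR", "CDS", "Stop", "3UTR")

    def __post_init__(self) -> None:
        if self.tss_halfwidth < 0 or self.stop_halfwidth < 0:
            raise ValueError("halfwidths must be >= 0")


@dataclass
class MetageneProfile:
    """Peak-midpoint density over a length-normalized composite transcript."""

    bins_per_region: tuple[int, int, int]
    density: np.ndarray
    n_peaks: int

    @property
    def regions(self) -> list[str]:
        b5, bc, b3 = self.bins_per_region
        return ["5UTR"] * b5 + ["CDS"] * bc + ["3UTR"] * b3

    @property
    def cds_stop_junction(self) -> int:
        """Index of the first 3'UTR bin (the CDS/3'UTR boundary)."""
        return self.bins_per_region[0] + self.bins_per_region[1]


def assign_region(peak: Peak, model: GeneModel, scheme: RegionScheme = RegionScheme()) -> str:
    """Label a peak by its midpoint: TSS / Stop zones first, else UTR/CDS."""
    if not model.has_cds:
        log.warning("%s lacks a CDS; peak labelled noncoding", model.gene_id)
        return "noncoding"
    mid = (peak.t_start + peak.t_end) // 2
    if abs(mid - model.cds_start) <= scheme.tss_halfwidth:
        return "TSS"
    if abs(mid - model.cds_end) <= scheme.stop_halfwidth:
        return "Stop"
    if mid < model.cds_start:
        return "5UTR"
    if mid >= model.cds_end:
        return "3UTR"
    return "CDS"


def metagene_profile(
    peaks: Sequence[Peak],
    models: dict[str, GeneModel],
    bins_per_region: tuple[int, int, int] = (20, 50, 30),
) -> MetageneProfile:
    """Histogram peak midpoints on the normalized 5'UTR/CDS/3'UTR axis.

    Each region of each transcript is rescaled to a fixed number of bins
    (default 20/50/30); the returned density sums to 1 when any peak exists.
    """
    b5, bc, b3 = bins_per_region
    counts = np.zeros(b5 + bc + b3, dtype=float)
    n_used = 0
    for p in peaks:
        model = models[p.gene_id]
        if not model.has_cds:
            log.warning("%s lacks a CDS; peak skipped in metagene", p.gene_id)
            continue
        mid = (p.t_start + p.t_end) // 2
        u5 = model.cds_start
        cds_len = model.cds_end - model.cds_start
        u3 = model.transcript_length - model.cds_end
        if mid < model.cds_start:
            b = min(int(mid / u5 * b5), b5 - 1) if u5 > 0 else 0
        elif mid < model.cds_end:
            b = b5 + min(int((mid - model.cds_start) / cds_len * bc), bc - 1)
        else:
            b = b5 + bc + (min(int((mid - model.cds_end) / u3 * b3), b3 - 1) if u3 > 0 else 0)
        counts[b] += 1
        n_used += 1
    if n_used:
        counts /= counts.sum()
    return MetageneProfile(bins_per_region, counts, n_used)


def peaks_per_gene(peaks: Sequence[Peak]) -> tuple[dict[int, int], Optional[float]]:
    """Histogram {k peaks: number of genes} over genes with >=1 peak, and the
    fraction of those genes carrying one or two peaks."""
    per_gene = Counter(p.gene_id for p in peaks)
    hist = Counter(per_gene.values())
    total = sum(hist.values())
    frac = (hist.get(1, 0) + hist.get(2, 0)) / total if total else None
    return dict(sorted(hist.items())), frac


def compare_peak_sets(
    set_a: Sequence[Peak], set_b: Sequence[Peak]
) -> dict[str, Optional[float]]:
    """Fraction of A's genes and peaks recovered in B (A is the query set).

    ``gene_overlap_frac`` = |genes(A) and genes(B)| / |genes(A)|;
    ``peak_overlap_frac`` = fraction of A peaks overlapping any same-gene B
    peak by >=1 nt in transcript coordinates.
    """
    genes_a = {p.gene_id for p in set_a}
    if not genes_a:
        return {"gene_overlap_frac": None, "peak_overlap_frac": None}
    genes_b = {p.gene_id for p in set_b}
    b_by_gene: dict[str, list[tuple[int, int]]] = {}
    for p in set_b:
        b_by_gene.setdefault(p.gene_id, []).append((p.t_start, p.t_end))
    hit = sum(
        1
        for p in set_a
        if any(p.t_start < e and s < p.t_end for s, e in b_by_gene.get(p.gene_id, []))
    )
    return {
        "gene_overlap_frac": len(genes_a & genes_b) / len(genes_a),
        "peak_overlap_frac": hit / len(set_a),
    }
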