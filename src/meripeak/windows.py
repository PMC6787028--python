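"""Non-overlapping transcript windows and per-window read counting.

Each transcript is tiled with discrete non-overlapping windows (25 nt by
default) from its 5' end; a trailing partial window is dropped. A read
increments a window's count when any of its genomic blocks overlaps any of
the window's genomic blocks by >=1 bp; a spliced 125-bp fragment therefore
touches several consecutive windows, and each touched window counts it once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .io import ReadAlignment, alignments_to_frame
from .models import GeneModel, GenomeInterval, transcript_to_genome

log = logging.getLogger(__name__)

__all__ = ["WindowRecord", "LibraryTotals", "build_windows", "count_reads", "filter_windows"]

SampleKey = tuple[str, int]  # (sample label, replicate index)


@dataclass
class WindowRecord:
    """One transcript window with its genomic projection and counts."""

    gene_id: str
    window_index: int
    t_start: int
    t_end: int
    genomic_blocks: list[GenomeInterval]
    counts: dict[SampleKey, int] = field(default_factory=dict)

    def total_count(self) -> int:
        return sum(self.counts.values())


class LibraryTotals(dict):
    """Map (sample, replicate) -> number of alignment records in the library."""


def build_windows(model: GeneModel, width: int = 25) -> list[WindowRecord]:
    """Tile a transcript with ``floor(L / width)`` windows of ``width`` nt."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    n = model.transcript_length // width
    out = []
    for i in range(n):
        t0, t1 = i * width, (i + 1) * width
        out.append(
            WindowRecord(model.gene_id, i, t0, t1, transcript_to_genome(model, t0, t1))
        )
    return out


# ---------------------------------------------------------------------------
# counting machinery


def _layered_blocks(blocks: list[tuple[int, int, int]]):
    """Partition (start, end, window_idx) blocks into layers of disjoint
    intervals so that each layer supports binary-search overlap queries.

    Window blocks from distinct genes can overlap genomically (nested or
    antisense loci), which a single sorted array cannot represent.
    """
    blocks = sorted(blocks)
    layers: list[list[tuple[int, int, int]]] = []
    last_end: list[int] = []
    for blk in blocks:
        for li, le in enumerate(last_end):
            if le <= blk[0]:
                layers[li].append(blk)
                last_end[li] = blk[1]
                break
        else:
            layers.append([blk])
            last_end.append(blk[1])
    out = []
    for layer in layers:
        arr = np.asarray(layer, dtype=np.int64)
        out.append((arr[:, 0], arr[:, 1], arr[:, 2]))
    return out


class _WindowIndex:
    def __init__(self, windows: list[WindowRecord]):
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for widx, w in enumerate(windows):
            for blk in w.genomic_blocks:
                per_chrom.setdefault(blk.chrom, []).append((blk.start, blk.end, widx))
        self.layers = {c: _layered_blocks(b) for c, b in per_chrom.items()}
        self.n_windows = len(windows)

    def count_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Per-window read counts for one library given its block table."""
        counts = np.zeros(self.n_windows, dtype=np.int64)
        if frame.empty:
            return counts
        pair_r: list[np.ndarray] = []
        pair_w: list[np.ndarray] = []
        for chrom, grp in frame.groupby("chrom", sort=False, observed=True):
            if chrom not in self.layers:
                continue
            rs = grp["start"].to_numpy(dtype=np.int64)
            re_ = grp["end"].to_numpy(dtype=np.int64)
            rid = grp["read_id"].to_numpy(dtype=np.int64)
            for starts, ends, wids in self.layers[chrom]:
                lo = np.searchsorted(ends, rs, side="right")
                hi = np.searchsorted(starts, re_, side="left")
                nhit = hi - lo
                mask = nhit > 0
                if not mask.any():
                    continue
                nh = nhit[mask]
                tot = int(nh.sum())
                base = np.repeat(lo[mask], nh)
                step = np.arange(tot) - np.repeat(np.cumsum(nh) - nh, nh)
                pair_w.append(wids[base + step])
                pair_r.append(np.repeat(rid[mask], nh))
        if not pair_w:
            return counts
        rids = np.concatenate(pair_r)
        wids = np.concatenate(pair_w)
        # one increment per (read, window) even when several blocks overlap
        key = rids * np.int64(self.n_windows) + wids
        uniq = np.unique(key)
        counts += np.bincount((uniq % self.n_windows).astype(np.int64), minlength=self.n_windows)
        return counts


AlignmentInput = Union[Iterable[ReadAlignment], Mapping[SampleKey, object]]


def _as_library_frames(alignments: AlignmentInput) -> dict[SampleKey, pd.DataFrame]:
    if isinstance(alignments, Mapping):
        frames: dict[SampleKey, pd.DataFrame] = {}
        for key, value in alignments.items():
            if isinstance(value, pd.DataFrame):
                frames[key] = value
            else:
                frames[key] = alignments_to_frame(value)
        return frames
    per_lib: dict[SampleKey, list[ReadAlignment]] = {}
    for aln in alignments:
        per_lib.setdefault((aln.sample, aln.replicate), []).append(aln)
    return {key: alignments_to_frame(alns) for key, alns in per_lib.items()}


def count_reads(
    windows: list[WindowRecord], alignments: AlignmentInput
) -> tuple[list[WindowRecord], LibraryTotals]:
    """Fill per-library counts on ``windows`` and tally library totals.

    ``alignments`` is either a stream of labelled :class:`ReadAlignment`
    objects or a mapping ``(sample, replicate) -> block table / stream``.
    Every alignment record contributes to its library total, including reads
    on chromosomes absent from the window set (which are logged).
    """
    index = _WindowIndex(windows)
    frames = _as_library_frames(alignments)
    totals = LibraryTotals()
    for key, frame in frames.items():
        n_records = int(frame["read_id"].nunique()) if not frame.empty else 0
        totals[key] = n_records
        unknown = (
            0
            if frame.empty
            else int(frame.loc[~frame["chrom"].isin(index.layers.keys()), "read_id"].nunique())
        )
        if unknown:
            log.info("%s rep %s: %d reads on chromosomes without windows", *key, unknown)
        vec = index.count_frame(frame)
        for widx, w in enumerate(windows):
            w.counts[key] = int(vec[widx])
    return windows, totals


def filter_windows(
    windows: list[WindowRecord], min_reads: int = 5, per_sample: bool = False
) -> list[WindowRecord]:
    """Drop windows with fewer than ``min_reads`` aligned reads.

    By default the threshold applies to the count pooled over all samples and
    replicates; ``per_sample=True`` instead requires at least one single
    library to reach the threshold.
    """
    if per_sample:
        return [w for w in windows if any(c >= min_reads for c in w.counts.values())]
    return [w for w in windows if w.total_count() >= min_reads]
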