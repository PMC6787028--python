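"""End-to-end peak calling: windows -> counts -> tests -> merged peaks."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import Peak, WindowTest, call_windows, merge_windows
from .models import GeneModel
from .windows import LibraryTotals, WindowRecord, build_windows, count_reads, filter_windows

__all__ = ["PeakCallResult", "run_peak_calling", "peaks_to_frame", "write_peaks_bed12"]


@dataclass
class PeakCallResult:
    windows: list[WindowRecord]  # windows surviving the read filter
    tests: list[WindowTest]
    peaks: list[Peak]
    totals: LibraryTotals


def run_peak_calling(
    models,
    alignments,
    *,
    window_width: int = 25,
    min_reads: int = 5,
    alpha: float = 0.05,
    min_peak_bp: int = 100,
    ip_label: str = "IP",
    input_label: str = "input",
    order: str = "combine-then-adjust",
) -> PeakCallResult:
    """Run the full windowed Fisher-exact peak-calling pipeline."""
    windows = [w for m in models for w in build_windows(m, window_width)]
    windows, totals = count_reads(windows, alignments)
    kept = filter_windows(windows, min_reads)
    tests = call_windows(
        kept, totals, alpha, ip_label=ip_label, input_label=input_label, order=order
    )
    peaks = merge_windows(tests, min_peak_bp)
    return PeakCallResult(kept, tests, peaks, totals)


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.gene_id,
                p.t_start,
                p.t_end,
                p.n_windows,
                p.fold,
                p.p_combined,
                p.q,
                p.score,
                p.region_label or "",
            )
            for p in peaks
        ],
        columns=[
            "gene_id",
            "t_start",
            "t_end",
            "n_windows",
            "fold",
            "p_combined",
            "q",
            "score",
            "region",
        ],
    )


def write_peaks_bed12(peaks: list[Peak], path: str) -> None:
    """BED12 peaks; score column = round(1000 * min(1, -log10(q) / 10))."""
    with open(path, "w") as out:
        for i, p in enumerate(peaks):
            blocks = p.genomic_blocks
            cs, ce = blocks[0].start, blocks[-1].end
            score = round(1000 * min(1.0, p.score / 10.0))
            sizes = ",".join(str(len(b)) for b in blocks)
            offs = ",".join(str(b.start - cs) for b in blocks)
            out.write(
                f"{blocks[0].chrom}\t{cs}\t{ce}\t{p.gene_id}_peak{i}\t{score}\t"
                f"{blocks[0].strand}\t{cs}\t{ce}\t0\t{len(blocks)}\t{sizes},\t{offs},\n"
            )
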