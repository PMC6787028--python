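"""Per-window enrichment testing and peak assembly.

The statistical unit is one 25-nt window. For each replicate pair, the
window's IP count k (of library total K) is compared with its input count m
(of total M) by a one-sided Fisher's exact test on the 2x2 table
[[k, K-k], [m, M-m]] with alternative "IP proportion > input proportion":
the upper hypergeometric tail. Per-replicate p-values are combined with
Fisher's method (-2 * sum(ln p) ~ chi-square with 2r df) and the combined
p-values are adjusted transcriptome-wide by Benjamini-Hochberg; windows with
q < alpha are significant. Maximal runs of consecutive significant windows
form peaks, and runs shorter than 100 bp are discarded.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GenomeInterval
from .windows import LibraryTotals, WindowRecord

log = logging.getLogger(__name__)

__all__ = [
    "WindowTest",
    "Peak",
    "fisher_window_test",
    "combine_replicates",
    "bh_adjust",
    "call_windows",
    "merge_windows",
    "evaluate_against_truth",
]

_TINY = np.finfo(float).tiny


@dataclass
class WindowTest:
    """Test results for one window across replicates."""

    window: WindowRecord
    tables: list[tuple[int, int, int, int]]  # per replicate (k, K, m, M)
    p_replicates: list[float]
    p_combined: float
    q: float = 1.0
    significant: bool = False

    @property
    def gene_id(self) -> str:
        return self.window.gene_id


@dataclass
class Peak:
    """A maximal run of consecutive significant windows (>= 100 bp)."""

    gene_id: str
    t_start: int
    t_end: int
    n_windows: int
    genomic_blocks: list[GenomeInterval]
    score: float  # -log10 of the best member q-value
    fold: float  # pooled (sum k / sum K) / (sum m / sum M)
    p_combined: float  # best member combined p
    q: float  # best member q
    region_label: Optional[str] = None

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def _fisher_sf(k, K, m, M):
    """Vectorized upper-tail hypergeometric p for tables [[k,K-k],[m,M-m]].

    Drawing K reads (the IP library) from the K+M pooled reads of which k+m
    hit the window: p = P(X >= k), X ~ Hypergeom(K+M, k+m, K).
    """
    k = np.asarray(k, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    M = np.asarray(M, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(k - 1, K + M, k + m, K)
    p = np.where((K == 0) | (M == 0), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def fisher_window_test(k: int, K: int, m: int, M: int) -> float:
    """One-sided Fisher's exact p for IP enrichment of a window.

    ``k`` of ``K`` IP reads and ``m`` of ``M`` input reads fall in the
    window; small p means the IP proportion exceeds the input proportion.
    Returns 1.0 (with a warning) when either library is empty.
    """
    if not (0 <= k <= K and 0 <= m <= M):
        raise ValueError(f"invalid table k={k} K={K} m={m} M={M}")
    if K + M == 0:
        raise ValueError("both libraries empty")
    if K == 0 or M == 0:
        warnings.warn("empty IP or input library; no enrichment evidence (p = 1)")
        return 1.0
    return float(_fisher_sf(k, K, m, M))


def combine_replicates(p_values: Sequence[float]) -> float:
    """Fisher's method: refer -2*sum(ln p) to chi-square with 2r df."""
    if len(p_values) == 0:
        raise ValueError("need at least one p-value")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        log.warning("p = 0 clamped to smallest positive float before combining")
        p = np.maximum(p, _TINY)
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * len(p)))


def bh_adjust(p_vector: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _paired_replicates(totals: LibraryTotals, ip_label: str, input_label: str) -> list[int]:
    ip_reps = sorted(r for s, r in totals if s == ip_label)
    in_reps = sorted(r for s, r in totals if s == input_label)
    if not ip_reps or ip_reps != in_reps:
        raise ValueError(
            f"IP/input replicates not paired: IP={ip_reps} input={in_reps}"
        )
    return ip_reps


def call_windows(
    windows: list[WindowRecord],
    totals: LibraryTotals,
    alpha: float = 0.05,
    *,
    ip_label: str = "IP",
    input_label: str = "input",
    order: str = "combine-then-adjust",
) -> list[WindowTest]:
    """Run the window tests transcriptome-wide and flag significant windows.

    ``order`` selects how replicate combination interacts with FDR control:

    - ``"combine-then-adjust"`` (default): combine raw per-replicate
      p-values with Fisher's method, then BH-adjust the combined p-values
      and call q < alpha.
    - ``"adjust-then-combine"``: BH-adjust each replicate's p-values
      transcriptome-wide first, then combine the adjusted values with
      Fisher's method and call the combined value < alpha.
    """
    if order not in ("combine-then-adjust", "adjust-then-combine"):
        raise ValueError(f"unknown order {order!r}")
    if not windows:
        return []
    reps = _paired_replicates(totals, ip_label, input_label)
    n = len(windows)
    k = np.zeros((len(reps), n), dtype=np.int64)
    m = np.zeros((len(reps), n), dtype=np.int64)
    K = np.zeros(len(reps), dtype=np.int64)
    M = np.zeros(len(reps), dtype=np.int64)
    for ri, rep in enumerate(reps):
        K[ri] = totals[(ip_label, rep)]
        M[ri] = totals[(input_label, rep)]
        for wi, w in enumerate(windows):
            k[ri, wi] = w.counts.get((ip_label, rep), 0)
            m[ri, wi] = w.counts.get((input_label, rep), 0)

    p_rep = np.vstack(
        [_fisher_sf(k[ri], K[ri], m[ri], M[ri]) for ri in range(len(reps))]
    )

    if order == "combine-then-adjust":
        x2 = -2.0 * np.sum(np.log(np.maximum(p_rep, _TINY)), axis=0)
        p_comb = stats.chi2.sf(x2, df=2 * len(reps))
        q = bh_adjust(p_comb)
        sig = q < alpha
    else:
        q_rep = np.vstack([bh_adjust(p_rep[ri]) for ri in range(len(reps))])
        x2 = -2.0 * np.sum(np.log(np.maximum(q_rep, _TINY)), axis=0)
        p_comb = stats.chi2.sf(x2, df=2 * len(reps))
        q = p_comb.copy()
        sig = p_comb < alpha

    out = []
    for wi, w in enumerate(windows):
        tables = [
            (int(k[ri, wi]), int(K[ri]), int(m[ri, wi]), int(M[ri]))
            for ri in range(len(reps))
        ]
        out.append(
            WindowTest(
                window=w,
                tables=tables,
                p_replicates=[float(p_rep[ri, wi]) for ri in range(len(reps))],
                p_combined=float(p_comb[wi]),
                q=float(q[wi]),
                significant=bool(sig[wi]),
            )
        )
    return out


def _merge_blocks(blocks: list[GenomeInterval]) -> list[GenomeInterval]:
    blocks = sorted(blocks, key=lambda b: b.start)
    merged: list[GenomeInterval] = []
    for b in blocks:
        if merged and b.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomeInterval(last.chrom, last.start, max(last.end, b.end), last.strand)
        else:
            merged.append(b)
    return merged


def merge_windows(tests: list[WindowTest], min_peak_bp: int = 100) -> list[Peak]:
    """Combine consecutive significant windows into peaks per gene.

    Runs spanning fewer than ``min_peak_bp`` transcript bases are discarded
    (100 bp = 4 windows at the default width). Peaks never cross gene
    boundaries, and "consecutive" is strict: one non-significant window
    breaks the run.
    """
    by_gene: dict[str, list[WindowTest]] = {}
    for t in tests:
        by_gene.setdefault(t.gene_id, []).append(t)
    peaks: list[Peak] = []
    for gene in by_gene:
        ts = sorted(by_gene[gene], key=lambda t: t.window.window_index)
        run: list[WindowTest] = []
        for t in ts + [None]:
            contiguous = (
                t is not None
                and t.significant
                and (not run or t.window.window_index == run[-1].window.window_index + 1)
            )
            if contiguous:
                run.append(t)
                continue
            if run:
                peak = _finalize_run(gene, run)
                if peak.length >= min_peak_bp:
                    peaks.append(peak)
            run = [t] if (t is not None and t.significant) else []
    peaks.sort(key=lambda p: (p.gene_id, p.t_start))
    return peaks


def _finalize_run(gene: str, run: list[WindowTest]) -> Peak:
    q_min = min(t.q for t in run)
    p_min = min(t.p_combined for t in run)
    k_sum = sum(tab[0] for t in run for tab in t.tables)
    m_sum = sum(tab[2] for t in run for tab in t.tables)
    K_sum = sum(tab[1] for tab in run[0].tables)
    M_sum = sum(tab[3] for tab in run[0].tables)
    ip_rate = k_sum / K_sum if K_sum else 0.0
    in_rate = m_sum / M_sum if M_sum else 0.0
    fold = ip_rate / in_rate if in_rate > 0 else math.inf
    blocks = _merge_blocks([b for t in run for b in t.window.genomic_blocks])
    return Peak(
        gene_id=gene,
        t_start=run[0].window.t_start,
        t_end=run[-1].window.t_end,
        n_windows=len(run),
        genomic_blocks=blocks,
        score=float(-math.log10(max(q_min, 1e-300))),
        fold=fold,
        p_combined=p_min,
        q=q_min,
    )


def _covered(span: tuple[int, int], others: list[tuple[int, int]]) -> int:
    s, e = span
    return sum(max(0, min(e, oe) - max(s, os_)) for os_, oe in others)


def evaluate_against_truth(peaks: list[Peak], truth) -> dict:
    """Recovery of planted peaks by the >=50%-span-coverage rule.

    A planted peak is recovered when called peaks of its gene cover >=50% of
    its transcript span; a called peak is a true positive when >=50% of its
    span lies inside planted intervals of its gene.
    """
    truth_by_gene: dict[str, list[tuple[int, int]]] = {}
    for rec in truth.peaks:
        truth_by_gene.setdefault(rec.gene_id, []).append((rec.t_start, rec.t_end))
    called_by_gene: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        called_by_gene.setdefault(p.gene_id, []).append((p.t_start, p.t_end))

    n_truth = sum(len(v) for v in truth_by_gene.values())
    recovered = 0
    for gene, spans in truth_by_gene.items():
        called = called_by_gene.get(gene, [])
        for span in spans:
            if _covered(span, called) * 2 >= (span[1] - span[0]):
                recovered += 1
    matched_flags = []
    tp = 0
    for p in peaks:
        spans = truth_by_gene.get(p.gene_id, [])
        ok = _covered((p.t_start, p.t_end), spans) * 2 >= p.length
        matched_flags.append(ok)
        tp += ok
    return {
        "recall": recovered / n_truth if n_truth else None,
        "precision": tp / len(peaks) if peaks else None,
        "n_truth": n_truth,
        "n_called": len(peaks),
        "matched": matched_flags,
    }
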