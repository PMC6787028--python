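"""Synthetic MeRIP-seq data: a toy transcriptome, planted m6A peaks, and
IP/input fragment alignments with known ground truth.

The generator emulates polyA-transcriptome fragment sequencing: per-gene
abundance is log-normal; fragments of ~125 bp (standard protocol; ~150 bp
for the low-input protocol) are placed on transcripts by sampling a fragment
*center*. In the input library centers are uniform along the transcript; in
the IP library the center density is multiplied by ``enrichment_fold``
inside planted peak intervals and renormalized, so gene-level abundance is
identical between IP and input except through the peaks themselves — the
exact signal the windowed Fisher test is meant to detect. Most methylated
transcripts carry one or two peaks and a tunable fraction of peaks sits
within +/-150 nt of the stop codon, mirroring the stop-codon enrichment
characteristic of m6A.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import write_alignment_frame_bed, write_gene_models_gtf
from .models import GeneModel, GenomeInterval

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthPeak",
    "SimulationTruth",
    "simulate_transcriptome",
    "plant_truth",
    "gene_expression",
    "simulate_reads",
    "write_dataset",
]

IP = "IP"
INPUT = "input"
_SAMPLES = (INPUT, IP)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic MeRIP-seq experiment.

    Defaults follow the biology being emulated: ~43% of expressed genes
    methylated, ~65% of methylated transcripts carrying one or two peaks,
    ~150-nt peaks biased toward the stop codon, ~125-bp fragments, and a
    single pseudo-chromosome transcriptome small enough for desk-scale runs.
    """

    n_genes: int = 200
    transcript_length_range: tuple[int, int] = (500, 3000)
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    frac_methylated: float = 0.427
    peaks_per_gene_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.12, 5: 0.08}
    )
    peak_width: int = 150
    enrichment_fold: float = 8.0
    stop_bias: float = 0.6
    fragment_length: tuple[float, float] = (125.0, 15.0)  # mean, sd
    min_fragment_length: int = 30
    reads_per_sample: int = 200_000
    n_replicates: int = 2
    seed: int = 0
    spacer: int = 1000
    chrom: str = "chrS"
    max_exons: int = 3
    intron_length_range: tuple[int, int] = (200, 500)

    def validate(self) -> None:
        lo, hi = self.transcript_length_range
        if lo < 3 * self.peak_width:
            raise ValueError(
                f"min transcript length {lo} < 3 x peak_width {self.peak_width}"
            )
        if hi < lo:
            raise ValueError("transcript_length_range must be (min, max)")
        for name in ("frac_methylated", "stop_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        total = sum(self.peaks_per_gene_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("peaks_per_gene_probs must sum to 1")


@dataclass(frozen=True)
class TruthPeak:
    gene_id: str
    t_start: int
    t_end: int
    enrichment_fold: float


@dataclass
class SimulationTruth:
    """Planted peak locations in transcript coordinates: the grading key."""

    peaks: list[TruthPeak]

    def by_gene(self) -> dict[str, list[TruthPeak]]:
        out: dict[str, list[TruthPeak]] = {}
        for p in self.peaks:
            out.setdefault(p.gene_id, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_id, p.t_start, p.t_end, p.enrichment_fold) for p in self.peaks],
            columns=["gene_id", "t_start", "t_end", "enrichment_fold"],
        )


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    # one seeded root; distinct deterministic streams per pipeline stage
    return np.random.default_rng(np.random.SeedSequence((config.seed, *key)))


def simulate_transcriptome(config: SimulationConfig) -> list[GeneModel]:
    """Lay ``n_genes`` non-overlapping genes along one pseudo-chromosome.

    Genes alternate randomly between strands, carry 1-3 exons separated by
    short introns, and have a CDS occupying the central ~60% of the
    transcript so that 5'UTR, CDS and 3'UTR are all nonempty.
    """
    config.validate()
    rng = _rng(config, 0)
    lo, hi = config.transcript_length_range
    models: list[GeneModel] = []
    cursor = config.spacer
    for gi in range(config.n_genes):
        L = int(rng.integers(lo, hi + 1))
        n_exons = int(rng.integers(1, config.max_exons + 1))
        # split transcript length into n_exons pieces of >= 50 nt
        while True:
            cuts = np.sort(rng.integers(50, L - 49, size=n_exons - 1)) if n_exons > 1 else np.array([], dtype=int)
            lens = np.diff(np.concatenate([[0], cuts, [L]]))
            if (lens >= 50).all():
                break
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        g = cursor
        ilo, ihi = config.intron_length_range
        for j, el in enumerate(lens):
            exons.append(GenomeInterval(config.chrom, g, g + int(el), strand))
            g += int(el)
            if j < len(lens) - 1:
                g += int(rng.integers(ilo, ihi + 1))
        cds_start = max(1, round(0.2 * L))
        cds_end = min(L - 1, round(0.8 * L))
        models.append(
            GeneModel(f"gene{gi:04d}", f"tx{gi:04d}", strand, exons, cds_start, cds_end)
        )
        cursor = g + config.spacer
    return models


def plant_truth(config: SimulationConfig, models: list[GeneModel]) -> SimulationTruth:
    """Select methylated genes and place non-overlapping peaks on them.

    ``stop_bias`` of the peaks are centered within +/-150 nt of the stop
    codon (clamped so the peak stays inside the transcript); the rest are
    uniform. Peaks within one gene keep >=100 nt between edges so distinct
    planted peaks remain distinct under the caller's merge rule; genes too
    short for their drawn peak count get fewer peaks, with a log message.
    """
    config.validate()
    rng = _rng(config, 1)
    n_meth = math.floor(config.frac_methylated * len(models))
    chosen = rng.choice(len(models), size=n_meth, replace=False) if n_meth else []
    ks = sorted(config.peaks_per_gene_probs)
    probs = np.array([config.peaks_per_gene_probs[k] for k in ks], dtype=float)
    w = config.peak_width
    half = w // 2
    peaks: list[TruthPeak] = []
    for gi in sorted(int(i) for i in chosen):
        model = models[gi]
        L = model.transcript_length
        n_peaks = int(rng.choice(ks, p=probs))
        placed: list[tuple[int, int]] = []
        for _ in range(n_peaks):
            for _attempt in range(50):
                use_stop = rng.random() < config.stop_bias
                if use_stop:
                    c_lo = max(half, model.cds_end - 150)
                    c_hi = min(L - (w - half), model.cds_end + 150)
                    if c_hi < c_lo:
                        c_lo, c_hi = half, L - (w - half)
                else:
                    c_lo, c_hi = half, L - (w - half)
                center = int(rng.integers(c_lo, c_hi + 1))
                t0, t1 = center - half, center + (w - half)
                if all(t0 - 100 >= pe or t1 + 100 <= ps for ps, pe in placed):
                    placed.append((t0, t1))
                    break
            else:
                log.info("%s: could not place peak %d/%d", model.gene_id, len(placed) + 1, n_peaks)
                break
        for t0, t1 in sorted(placed):
            peaks.append(TruthPeak(model.gene_id, t0, t1, config.enrichment_fold))
    return SimulationTruth(peaks)


def gene_expression(config: SimulationConfig, n_genes: int) -> np.ndarray:
    """Per-gene relative abundance, shared across samples and replicates."""
    rng = _rng(config, 2)
    expr = rng.lognormal(config.expression_mu, config.expression_sigma, size=n_genes)
    return expr / expr.sum()


def _sample_centers(
    rng: np.random.Generator,
    n: int,
    L: int,
    peaks: list[TruthPeak],
    fold: float,
) -> np.ndarray:
    """Fragment centers from the piecewise-constant enriched density."""
    if not peaks or fold == 1.0:
        return rng.uniform(0.0, L, size=n)
    edges = [0]
    weights = []
    for p in sorted(peaks, key=lambda p: p.t_start):
        if p.t_start > edges[-1]:
            weights.append(p.t_start - edges[-1])
            edges.append(p.t_start)
        weights.append((p.t_end - edges[-1]) * fold)
        edges.append(p.t_end)
    if edges[-1] < L:
        weights.append(L - edges[-1])
        edges.append(L)
    edges_arr = np.asarray(edges, dtype=float)
    wts = np.asarray(weights, dtype=float)
    seg = rng.choice(len(wts), size=n, p=wts / wts.sum())
    u = rng.uniform(0.0, 1.0, size=n)
    return edges_arr[seg] + u * (edges_arr[seg + 1] - edges_arr[seg])


def _project_gene(
    model: GeneModel, t0: np.ndarray, t1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized transcript->genome projection of fragments of one gene.

    Returns per-block (start, end, local read index). Single-exon spans are
    handled in bulk; the minority of junction-spanning fragments loop.
    """
    L = model.transcript_length
    if model.strand == "-":
        t0, t1 = L - t1, L - t0
    cum = model._cumlens()
    g_starts = np.fromiter((e.start for e in model.exons), dtype=np.int64)
    i0 = np.searchsorted(cum, t0, side="right") - 1
    i1 = np.searchsorted(cum, t1 - 1, side="right") - 1
    same = i0 == i1
    idx_same = np.nonzero(same)[0]
    bs = [g_starts[i0[same]] + (t0[same] - cum[i0[same]])]
    be = [g_starts[i0[same]] + (t1[same] - cum[i0[same]])]
    br = [idx_same]
    for ridx in np.nonzero(~same)[0]:
        a, b = int(t0[ridx]), int(t1[ridx])
        i = int(i0[ridx])
        pos = a
        while pos < b:
            take = min(b, int(cum[i + 1])) - pos
            g0 = int(g_starts[i]) + (pos - int(cum[i]))
            bs.append(np.array([g0]))
            be.append(np.array([g0 + take]))
            br.append(np.array([ridx]))
            pos += take
            i += 1
    return np.concatenate(bs), np.concatenate(be), np.concatenate(br)


def simulate_reads(
    config: SimulationConfig,
    models: list[GeneModel],
    truth: SimulationTruth,
    samples: tuple[str, ...] = _SAMPLES,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Generate fragment alignments per (sample, replicate).

    Returns block tables (chrom, start, end, read_id, strand) compatible
    with :func:`meripeak.windows.count_reads`; each distinct ``read_id`` is
    one fragment (one BED record).
    """
    config.validate()
    n_genes = len(models)
    out: dict[tuple[str, int], pd.DataFrame] = {}
    if n_genes == 0 or config.reads_per_sample == 0:
        empty = pd.DataFrame(
            {"chrom": [], "start": [], "end": [], "read_id": [], "strand": []}
        )
        for s in samples:
            for rep in range(1, config.n_replicates + 1):
                out[(s, rep)] = empty.copy()
        return out
    expr = gene_expression(config, n_genes)
    truth_by_gene = truth.by_gene()
    flen_mean, flen_sd = config.fragment_length
    n = config.reads_per_sample
    for s_idx, sample in enumerate(samples):
        enriched = sample == IP
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config, 3, s_idx, rep)
            gene_idx = rng.choice(n_genes, size=n, p=expr)
            order = np.argsort(gene_idx, kind="stable")
            sorted_genes, first = np.unique(gene_idx[order], return_index=True)
            starts_parts, ends_parts, rid_parts, strand_parts = [], [], [], []
            bounds = np.append(first, n)
            for gpos, gi in enumerate(sorted_genes):
                ridx = order[bounds[gpos] : bounds[gpos + 1]]
                model = models[int(gi)]
                L = model.transcript_length
                kreads = len(ridx)
                peaks = truth_by_gene.get(model.gene_id, []) if enriched else []
                centers = _sample_centers(rng, kreads, L, peaks, config.enrichment_fold)
                lens = np.rint(rng.normal(flen_mean, flen_sd, size=kreads)).astype(np.int64)
                lens = np.clip(lens, config.min_fragment_length, L)
                t0 = np.clip(np.rint(centers - lens / 2).astype(np.int64), 0, L - lens)
                t1 = t0 + lens
                b_s, b_e, b_r = _project_gene(model, t0, t1)
                starts_parts.append(b_s)
                ends_parts.append(b_e)
                rid_parts.append(ridx[b_r])
                strand_parts.append(np.full(len(b_s), model.strand, dtype="U1"))
            frame = pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "start": np.concatenate(starts_parts),
                    "end": np.concatenate(ends_parts),
                    "read_id": np.concatenate(rid_parts),
                    "strand": np.concatenate(strand_parts),
                }
            )
            out[(sample, rep)] = frame.sort_values(
                ["read_id", "start"], kind="stable"
            ).reset_index(drop=True)
    return out


def write_dataset(
    config: SimulationConfig,
    outdir: str,
    models: Optional[list[GeneModel]] = None,
    truth: Optional[SimulationTruth] = None,
) -> dict[str, str]:
    """Run the full generator and write GTF, truth TSV and per-library BED."""
    os.makedirs(outdir, exist_ok=True)
    if models is None:
        models = simulate_transcriptome(config)
    if truth is None:
        truth = plant_truth(config, models)
    paths = {"gtf": os.path.join(outdir, "models.gtf"), "truth": os.path.join(outdir, "truth.tsv")}
    write_gene_models_gtf(models, paths["gtf"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    frames = simulate_reads(config, models, truth)
    for (sample, rep), frame in frames.items():
        key = f"{sample}_rep{rep}"
        paths[key] = os.path.join(outdir, f"{key}.bed")
        write_alignment_frame_bed(frame, paths[key])
    return paths
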