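"""TSS-anchored signal matrices and run-off wave quantification.

Reproduces the reference-point heatmap computation used for DRB time
courses: per-position log2 ratio of an RPKM-scaled treatment track over
the untreated control, binned into a genes x bins matrix anchored at each
gene's TSS (default 5 kb upstream to 100 kb downstream, 100 bp bins,
strand-aware so bin 0 is always upstream in the direction of
transcription), with rows sortable by gene length.  On top of the matrix
sit two summaries for transcription-inhibition kinetics: a length-weighted
mean over the gene body, and the position of the Pol II run-off wavefront
(the far edge of the region cleared of signal), from which the elongation
rate is recovered by regressing front position on time.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneModel, SignalTrack
from .classifier import GeneZones

DEFAULT_UPSTREAM = 5_000
DEFAULT_DOWNSTREAM = 100_000
DEFAULT_BIN_SIZE = 100


@dataclass(frozen=True)
class SignalMatrix:
    """Genes x position-bins matrix of signal values anchored at the TSS.

    ``values[i, j]`` is the length-weighted mean signal of gene ``i`` over
    transcription-direction offsets ``[-upstream + j*bin_size,
    -upstream + (j+1)*bin_size)`` from its TSS; NaN where the window runs
    off the chromosome.
    """

    gene_ids: tuple[str, ...]
    gene_lengths: np.ndarray
    bin_size: int
    upstream: int
    downstream: int
    values: np.ndarray

    def __post_init__(self) -> None:
        n_bins = (self.upstream + self.downstream) // self.bin_size
        if self.values.shape != (len(self.gene_ids), n_bins):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {n_bins})"
            )
        if len(self.gene_lengths) != len(self.gene_ids):
            raise ValueError("gene_lengths length mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Transcription-direction offset of each bin start from the TSS."""
        return -self.upstream + np.arange(self.n_bins) * self.bin_size

    def downstream_slice(self) -> np.ndarray:
        """Columns at offsets >= 0 (TSS and downstream)."""
        return self.values[:, self.upstream // self.bin_size :]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def log2_compare(
    treatment: SignalTrack, control: SignalTrack, pseudocount: float = 1.0
) -> SignalTrack:
    """Per-position log2((treatment + p) / (control + p)) track.

    Both tracks are expected on comparable scales (e.g. RPKM-scaled).
    Runs are re-segmented at the union of the two tracks' breakpoints;
    positions covered by neither track map to log2(p/p) = 0 and stay
    implicit.  Negative input values are rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out_runs: list[tuple[str, int, int, float]] = []
    chroms = set(treatment.chromosomes()) | set(control.chromosomes())
    for chrom in sorted(chroms):
        t_starts, t_ends, t_vals = treatment.chrom_arrays(chrom)
        c_starts, c_ends, c_vals = control.chrom_arrays(chrom)
        if (t_vals < 0).any() or (c_vals < 0).any():
            raise ValueError(f"negative signal values on {chrom}")
        edges = np.unique(
            np.concatenate([t_starts, t_ends, c_starts, c_ends])
        )
        if edges.size < 2:
            continue
        seg_starts, seg_ends = edges[:-1], edges[1:]
        t_seg = _segment_values(seg_starts, t_starts, t_ends, t_vals)
        c_seg = _segment_values(seg_starts, c_starts, c_ends, c_vals)
        ratio = np.log2((t_seg + pseudocount) / (c_seg + pseudocount))
        for s, e, v in zip(seg_starts, seg_ends, ratio):
            if v != 0.0:
                out_runs.append((chrom, int(s), int(e), float(v)))
    return SignalTrack.from_runs(_coalesce(out_runs))


def _segment_values(
    seg_starts: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
) -> np.ndarray:
    """Track value at each segment start (segments never straddle runs)."""
    if starts.size == 0:
        return np.zeros(seg_starts.shape)
    idx = np.searchsorted(starts, seg_starts, side="right") - 1
    inside = (idx >= 0) & (seg_starts < ends[np.maximum(idx, 0)])
    return np.where(inside, values[np.maximum(idx, 0)], 0.0)


def _coalesce(
    runs: list[tuple[str, int, int, float]]
) -> list[tuple[str, int, int, float]]:
    out: list[tuple[str, int, int, float]] = []
    for run in runs:
        if out and out[-1][0] == run[0] and out[-1][2] == run[1] and out[-1][3] == run[3]:
            out[-1] = (run[0], out[-1][1], run[2], run[3])
        else:
            out.append(run)
    return out


def compute_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SignalMatrix:
    """Bin a track around each gene's TSS, oriented by transcription.

    For plus-strand genes bin ``j`` covers genomic
    ``[tss - upstream + j*b, tss - upstream + (j+1)*b)``; for minus-strand
    genes the window is reflected through the TSS so bin 0 is still the
    most upstream.  Bin values are length-weighted means with uncovered
    bases counting as 0.  Bins extending past position 0, or past the
    chromosome end when ``chrom_lengths`` is supplied, are NaN.
    """
    if (upstream + downstream) % bin_size:
        raise ValueError("upstream + downstream must be a multiple of bin_size")
    n_bins = (upstream + downstream) // bin_size
    values = np.full((len(genes), n_bins), np.nan)
    for i, gene in enumerate(genes):
        tss = gene.tss
        if gene.strand == "+":
            # bin edges left -> right; transcription direction = +
            edges = tss - upstream + np.arange(n_bins + 1) * bin_size
        else:
            # transcription-direction offset d maps to genomic tss - d, so
            # the bin at offsets [a, a+b) is genomic [tss-a-b+1, tss-a+1);
            # build ascending genomic edges, then reverse bin order below
            edges = tss + upstream + 1 - np.arange(n_bins + 1)[::-1] * bin_size
        integrals = track.integral(gene.chrom, np.maximum(edges, 0))
        sums = np.diff(integrals)
        bin_lo, bin_hi = edges[:-1], edges[1:]
        if gene.strand == "-":
            sums = sums[::-1]
            bin_lo, bin_hi = bin_lo[::-1], bin_hi[::-1]
        row = sums / bin_size
        out_of_bounds = bin_lo < 0
        if chrom_lengths is not None and gene.chrom in chrom_lengths:
            out_of_bounds |= bin_hi > chrom_lengths[gene.chrom]
        row[out_of_bounds] = np.nan
        values[i] = row
    return SignalMatrix(
        gene_ids=tuple(g.gene_id for g in genes),
        gene_lengths=np.array([g.length for g in genes], dtype=np.int64),
        bin_size=bin_size,
        upstream=upstream,
        downstream=downstream,
        values=values,
    )


def sort_by_region_length(
    matrix: SignalMatrix, ascending: bool = True
) -> SignalMatrix:
    """Reorder rows by gene length; stable, so ties keep input order."""
    key = matrix.gene_lengths if ascending else -matrix.gene_lengths
    order = np.argsort(key, kind="stable")
    return replace(
        matrix,
        gene_ids=tuple(matrix.gene_ids[i] for i in order),
        gene_lengths=matrix.gene_lengths[order],
        values=matrix.values[order],
    )


def body_signal_summary(track: SignalTrack, zones: GeneZones) -> float:
    """Length-weighted mean signal over the gene-body pieces (NaN if none)."""
    total_len = sum(len(piece) for piece in zones.body)
    if total_len == 0:
        return math.nan
    total = 0.0
    for piece in zones.body:
        total += track.mean_over(piece.chrom, piece.start, piece.end) * len(
            piece
        )
    return total / total_len


def wavefront_estimate(
    rel_profile: np.ndarray,
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold_fraction: float = 0.5,
) -> float:
    """Far edge of the cleared region, in bp downstream of the TSS.

    ``rel_profile`` holds a gene's treated/pre-treatment signal ratio in
    downstream bins starting at the TSS (bin ``j`` covers
    ``[j*bin_size, (j+1)*bin_size)``).  The front is the first downstream
    position where the ratio rises back above ``threshold_fraction``,
    linearly interpolated between bin centres.  NaN when the profile never
    drops below the threshold at the TSS (no clearing) or never recovers
    within the profile (front beyond the window).
    """
    rel = np.asarray(rel_profile, dtype=float)
    finite = np.nonzero(np.isfinite(rel))[0]
    if finite.size == 0:
        return math.nan
    rel = rel[: finite[-1] + 1]
    if not np.isfinite(rel[0]) or rel[0] >= threshold_fraction:
        return math.nan
    above = np.isfinite(rel) & (rel >= threshold_fraction)
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    c_prev = (i - 0.5) * bin_size
    r_prev, r_here = rel[i - 1], rel[i]
    if not np.isfinite(r_prev) or r_here == r_prev:
        return c_prev + 0.5 * bin_size
    return float(
        c_prev + (threshold_fraction - r_prev) / (r_here - r_prev) * bin_size
    )


def estimate_elongation_rate(
    fronts_by_time: Mapping[float, Sequence[float]],
) -> tuple[float, float]:
    """Elongation rate from front positions across time points.

    Regresses the per-time mean front position (bp) on time (min) by
    ordinary least squares; returns ``(rate_nt_per_min, intercept_bp)``.
    Non-finite fronts are ignored; at least two time points with data are
    required.
    """
    times: list[float] = []
    means: list[float] = []
    for t, fronts in sorted(fronts_by_time.items()):
        arr = np.asarray(list(fronts), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            times.append(float(t))
            means.append(float(arr.mean()))
    if len(times) < 2:
        raise ValueError("need front estimates at >= 2 time points")
    fit = stats.linregress(times, means)
    return float(fit.slope), float(fit.intercept)


# ---------------------------------------------------------------------------
# Matrix file dialect: gzip TSV with a JSON header line
# ---------------------------------------------------------------------------


def write_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    """Write a matrix as gzip TSV; line 1 is a ``#``-prefixed JSON header."""
    header = {
        "gene_ids": list(matrix.gene_ids),
        "gene_lengths": [int(x) for x in matrix.gene_lengths],
        "bin_size": matrix.bin_size,
        "upstream": matrix.upstream,
        "downstream": matrix.downstream,
    }
    with gzip.open(path, "wt") as handle:
        handle.write("#" + json.dumps(header) + "\n")
        for row in matrix.values:
            handle.write(
                "\t".join(
                    "nan" if not np.isfinite(v) else format(float(v), ".17g")
                    for v in row
                )
                + "\n"
            )


def read_matrix(path: str | Path) -> SignalMatrix:
    with gzip.open(path, "rt") as handle:
        first = handle.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        values = np.loadtxt(handle, delimiter="\t", ndmin=2)
    if values.size == 0:
        n_bins = (header["upstream"] + header["downstream"]) // header[
            "bin_size"
        ]
        values = np.empty((0, n_bins))
    return SignalMatrix(
        gene_ids=tuple(header["gene_ids"]),
        gene_lengths=np.array(header["gene_lengths"], dtype=np.int64),
        bin_size=header["bin_size"],
        upstream=header["upstream"],
        downstream=header["downstream"],
        values=values,
    )


def plot_heatmap(
    matrix: SignalMatrix,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render the matrix as a simple heatmap image (thin optional layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    extent = (-matrix.upstream / 1e3, matrix.downstream / 1e3, matrix.values.shape[0], 0)
    im = ax.imshow(
        matrix.values,
        aspect="auto",
        interpolation="nearest",
        cmap="RdBu_r",
        vmin=vmin,
        vmax=vmax,
        extent=extent,
    )
    ax.set_xlabel("distance from TSS (kb)")
    ax.set_ylabel("genes")
    fig.colorbar(im, ax=ax, label="signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
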