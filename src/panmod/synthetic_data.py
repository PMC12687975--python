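"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the study conditions end to end: a one-chromosome
gene annotation with isoforms and (optionally) clustered same-strand TSSs,
four peak sets (H3K9ac, H4K12ac, H3S10ph, H4S1ph) constructed so the
classifier's truth table yields a chosen label per gene plus intergenic
noise peaks, an expression table whose designated top isoform is known,
and DRB time-course coverage tracks in which a run-off wave clears Pol II
signal from each TSS at a fixed elongation rate and refills it after
washout.  Class quotas default to the proportions of the observed
classification of the human protein-coding gene set; the elongation rate
defaults to 2,000 nt/min, the in-vivo anchor for Pol II.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.Generator``; identical config gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    TranscriptIsoform,
    write_annotation,
    write_bedgraph,
    write_peaks,
)
from .classifier import (
    ACETYLATION_MARKS,
    PHOSPHORYLATION_MARKS,
    GeneClass,
    gene_zones,
)
from .isoform_selection import ExpressionTable, write_expression_table

#: Default class quotas: proportions of the seven classes in the observed
#: classification of the 19,989 human protein-coding genes.
TABLE_PROPORTION_QUOTAS: dict[str, float] = {
    "AC_DOMINATED": 5_009 / 19_989,
    "PH_DOMINATED": 1_480 / 19_989,
    "BOTH": 8_931 / 19_989,
    "PROM_AC_ONLY": 767 / 19_989,
    "PROM_PH_ONLY": 230 / 19_989,
    "PROM_BOTH": 3_437 / 19_989,
    "UNMODIFIED": 135 / 19_989,
}

ALL_MARKS = ACETYLATION_MARKS + PHOSPHORYLATION_MARKS


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    chrom: str = "chr1"
    chrom_length: int = 60_000_000
    #: log-uniform gene length bounds (bp)
    gene_length_bounds: tuple[int, int] = (5_000, 100_000)
    isoforms_per_gene: int = 2
    #: fraction of genes given a same-strand neighbour TSS within the window
    clustered_tss_fraction: float = 0.0
    tss_cluster_window: int = 100_000
    class_quotas: dict[str, float] = field(
        default_factory=lambda: dict(TABLE_PROPORTION_QUOTAS)
    )
    peak_width_bounds: tuple[int, int] = (200, 1_000)
    n_noise_peaks: int = 50
    #: fraction of genes given a wrong-family body peak ("confuser" mode)
    confuser_fraction: float = 0.0
    promoter_halfwidth: int = 200
    #: Pol II elongation rate, nt/min
    elongation_rate: float = 2_000.0
    inhibition_times: tuple[float, ...] = (5.0, 15.0, 30.0)
    recovery_times: tuple[float, ...] = (10.0, 30.0, 60.0)
    plateau_height: float = 10.0
    #: additive Gaussian noise sd on track values (0.05 x plateau)
    track_noise_sd: float = 0.5
    track_bin: int = 100
    n_samples: int = 3
    total_mapped_reads: float = 2e7
    #: fraction of genes expressed below the 0.1 mean-RPKM floor
    low_expression_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.class_quotas.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class quotas must sum to 1, got {total}")
        if self.elongation_rate <= 0:
            raise ValueError("elongation rate must be positive")
        for name in ("n_genes", "n_noise_peaks", "isoforms_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.gene_length_bounds
        if not (0 < lo <= hi):
            raise ValueError("bad gene length bounds")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one sub-operation."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class Annotation:
    isoforms: list[TranscriptIsoform]
    genes: list[GeneModel]
    #: gene ids with a same-strand TSS within the cluster window (truth)
    clustered_gene_ids: frozenset[str]


def _sample_length(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def gen_annotation(config: SimulationConfig) -> Annotation:
    """Place genes on one chromosome without body overlap.

    Non-clustered genes are spaced so that consecutive TSSs on the
    chromosome are more than the cluster window apart (so the clustered
    ground truth is exact); a ``clustered_tss_fraction`` of genes is laid
    out as same-strand pairs with TSSs within the window.
    """
    rng = config.rng(1)
    window = config.tss_cluster_window
    n = config.n_genes
    n_pairs = int(round(config.clustered_tss_fraction * n / 2))
    if 2 * n_pairs > n:
        raise ValueError("clustered_tss_fraction too large")

    genes: list[GeneModel] = []
    clustered: set[str] = set()
    cursor = 10_000  # margin so promoters never clip at 0
    pair_cap = max(config.gene_length_bounds[0], window // 2 - 5_000)

    def place(length: int, strand: str, gene_id: str) -> GeneModel:
        interval = GenomicInterval(
            config.chrom, cursor, cursor + length, strand
        )
        return GeneModel(gene_id=gene_id, interval=interval)

    gene_no = 0
    for _ in range(n_pairs):
        strand = "+" if rng.random() < 0.5 else "-"
        len1 = min(_sample_length(rng, config.gene_length_bounds), pair_cap)
        len2 = min(_sample_length(rng, config.gene_length_bounds), pair_cap)
        gap_max = window - max(len1, len2) - 500
        gap = int(rng.integers(500, max(gap_max, 501)))
        for length, offset in ((len1, 0), (len2, len1 + gap)):
            gene_no += 1
            gid = f"g{gene_no:05d}"
            interval = GenomicInterval(
                config.chrom, cursor + offset, cursor + offset + length, strand
            )
            genes.append(GeneModel(gene_id=gid, interval=interval))
            clustered.add(gid)
        cursor += len1 + gap + len2 + window + 1 + int(rng.integers(0, 20_000))

    for _ in range(n - 2 * n_pairs):
        gene_no += 1
        length = _sample_length(rng, config.gene_length_bounds)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(place(length, strand, f"g{gene_no:05d}"))
        cursor += length + window + 1 + int(rng.integers(0, 20_000))

    if cursor > config.chrom_length:
        raise ValueError(
            f"chromosome too short: need {cursor} bp, have {config.chrom_length}"
        )

    isoforms: list[TranscriptIsoform] = []
    for gene in genes:
        iv = gene.interval
        isoforms.append(
            TranscriptIsoform(gene.gene_id, f"{gene.gene_id}.t1", iv)
        )
        for k in range(1, config.isoforms_per_gene):
            # shorter isoform sharing the TSS: truncate the 3' end
            frac = rng.uniform(0.4, 0.9)
            length = max(2, int(round(len(iv) * frac)))
            if iv.strand == "+":
                sub = GenomicInterval(iv.chrom, iv.start, iv.start + length, "+")
            else:
                sub = GenomicInterval(iv.chrom, iv.end - length, iv.end, "-")
            isoforms.append(
                TranscriptIsoform(gene.gene_id, f"{gene.gene_id}.t{k + 1}", sub)
            )
    return Annotation(
        isoforms=isoforms, genes=genes, clustered_gene_ids=frozenset(clustered)
    )


def assign_labels(
    gene_ids: Sequence[str],
    quotas: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, GeneClass]:
    """Exact per-class quotas by largest remainder, randomly permuted."""
    n = len(gene_ids)
    classes = list(quotas)
    ideal = np.array([quotas[c] * n for c in classes])
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    pool = [
        GeneClass[classes[i]] for i in range(len(classes)) for _ in range(counts[i])
    ]
    order = rng.permutation(n)
    return {gene_ids[j]: pool[k] for k, j in enumerate(order)}


def _place_within(
    rng: np.random.Generator,
    zone: GenomicInterval,
    width_bounds: tuple[int, int],
    margin: int = 1,
) -> GenomicInterval:
    """A peak of sampled width strictly inside *zone*; retries then errors."""
    lo, hi = width_bounds
    for _ in range(20):
        width = int(rng.integers(lo, hi + 1))
        max_start = zone.end - width - margin
        if max_start >= zone.start + margin:
            start = int(rng.integers(zone.start + margin, max_start + 1))
            return GenomicInterval(zone.chrom, start, start + width)
        hi = max(lo, hi // 2)  # zone is tight: retry with narrower peaks
    raise ValueError(
        f"zone [{zone.start}, {zone.end}) too short for a peak of "
        f"width >= {width_bounds[0]}"
    )


def gen_peaks(
    genes: Sequence[GeneModel],
    labels: Mapping[str, GeneClass],
    config: SimulationConfig,
) -> dict[str, PeakSet]:
    """Peak sets for the four marks realising the target label per gene.

    Body peaks are placed strictly inside gene-body zones and promoter-only
    peaks strictly inside the TSS +/- ``promoter_halfwidth`` window, so the
    classification round-trip is exact.  Each family peak is attributed to
    one or both of the family's marks at random.  Intergenic noise peaks
    never come within ``promoter_halfwidth + 1`` bp of any gene.  With
    ``confuser_fraction > 0`` a fraction of genes also receive a
    wrong-family body peak (robustness probe; breaks the target label).
    """
    rng = config.rng(2)
    by_mark: dict[str, list[GenomicInterval]] = {m: [] for m in ALL_MARKS}

    def emit(family_marks: tuple[str, str], peak: GenomicInterval) -> None:
        choice = rng.integers(0, 3)  # first mark, second mark, or both
        targets = (
            family_marks if choice == 2 else (family_marks[int(choice)],)
        )
        for mark in targets:
            by_mark[mark].append(peak)

    prom_width_bounds = (
        min(100, config.promoter_halfwidth),
        2 * config.promoter_halfwidth - 20,
    )
    for gene in genes:
        label = labels[gene.gene_id]
        zones = gene_zones(gene, config.promoter_halfwidth)
        body_pieces = sorted(zones.body, key=len, reverse=True)

        def body_peak() -> GenomicInterval:
            return _place_within(rng, body_pieces[0], config.peak_width_bounds)

        def prom_peak() -> GenomicInterval:
            return _place_within(rng, zones.promoter, prom_width_bounds, margin=0)

        if label is GeneClass.AC_DOMINATED:
            emit(ACETYLATION_MARKS, body_peak())
            if rng.random() < 0.5:
                emit(ACETYLATION_MARKS, prom_peak())
        elif label is GeneClass.PH_DOMINATED:
            emit(PHOSPHORYLATION_MARKS, body_peak())
            if rng.random() < 0.5:
                emit(PHOSPHORYLATION_MARKS, prom_peak())
        elif label is GeneClass.BOTH:
            emit(ACETYLATION_MARKS, body_peak())
            emit(PHOSPHORYLATION_MARKS, body_peak())
        elif label is GeneClass.PROM_AC_ONLY:
            emit(ACETYLATION_MARKS, prom_peak())
        elif label is GeneClass.PROM_PH_ONLY:
            emit(PHOSPHORYLATION_MARKS, prom_peak())
        elif label is GeneClass.PROM_BOTH:
            emit(ACETYLATION_MARKS, prom_peak())
            emit(PHOSPHORYLATION_MARKS, prom_peak())
        # UNMODIFIED: no genic peaks

    if config.confuser_fraction > 0:
        n_confuse = int(round(config.confuser_fraction * len(genes)))
        for idx in rng.choice(len(genes), size=n_confuse, replace=False):
            gene = genes[idx]
            zones = gene_zones(gene, config.promoter_halfwidth)
            piece = sorted(zones.body, key=len, reverse=True)[0]
            wrong = (
                PHOSPHORYLATION_MARKS
                if labels[gene.gene_id] is GeneClass.AC_DOMINATED
                else ACETYLATION_MARKS
            )
            emit(wrong, _place_within(rng, piece, config.peak_width_bounds))

    # intergenic noise: anywhere further than promoter_halfwidth+1 from a gene
    pad = config.promoter_halfwidth + 1
    forbidden = PeakSet(
        "forbidden",
        [
            GenomicInterval(
                g.chrom, max(0, g.interval.start - pad), g.interval.end + pad
            )
            for g in genes
        ],
    ).normalized()
    gaps: list[GenomicInterval] = []
    prev_end = 0
    for iv in forbidden:
        if iv.start - prev_end > 3 * config.peak_width_bounds[1]:
            gaps.append(GenomicInterval(config.chrom, prev_end, iv.start))
        prev_end = iv.end
    if config.chrom_length - prev_end > 3 * config.peak_width_bounds[1]:
        gaps.append(
            GenomicInterval(config.chrom, prev_end, config.chrom_length)
        )
    if config.n_noise_peaks and not gaps:
        raise ValueError("no intergenic space left for noise peaks")
    gap_weights = np.array([len(g) for g in gaps], dtype=float)
    gap_weights /= gap_weights.sum() if gaps else 1.0
    for _ in range(config.n_noise_peaks):
        gap = gaps[int(rng.choice(len(gaps), p=gap_weights))]
        peak = _place_within(rng, gap, config.peak_width_bounds)
        by_mark[ALL_MARKS[int(rng.integers(0, len(ALL_MARKS)))]].append(peak)

    return {
        mark: PeakSet(mark, intervals).sorted()
        for mark, intervals in by_mark.items()
    }


@dataclass
class RunoffTracks:
    """Control plus per-time-point tracks of the clearing/refilling wave."""

    control: SignalTrack
    inhibition: dict[float, SignalTrack]
    recovery: dict[float, SignalTrack]

    def expected_front(self, t_min: float, rate: float) -> float:
        return rate * t_min


def _gene_track_runs(
    gene: GeneModel,
    cleared: tuple[int, int] | None,
    height: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, float]]:
    """Runs over one gene: plateau `height`, zeroed on the cleared span.

    ``cleared`` is a genomic half-open span inside the gene where the base
    signal is 0.  Values get additive Gaussian noise, floored at 0, drawn
    per bin of ``config.track_bin`` bp (bins split at the cleared edge).
    """
    iv = gene.interval
    edges = list(range(iv.start, iv.end, config.track_bin)) + [iv.end]
    if cleared is not None:
        for pos in cleared:
            if iv.start < pos < iv.end and pos not in edges:
                edges.append(pos)
    edges = sorted(set(edges))
    runs: list[tuple[str, int, int, float]] = []
    for s, e in zip(edges[:-1], edges[1:]):
        base = height
        if cleared is not None and s >= cleared[0] and e <= cleared[1]:
            base = 0.0
        value = max(0.0, base + rng.normal(0.0, config.track_noise_sd))
        runs.append((iv.chrom, s, e, value))
    return runs


def _cleared_span(
    gene: GeneModel, distance: float, inverted: bool
) -> tuple[int, int] | None:
    """Genomic span cleared (or, inverted, NOT yet refilled) at one time."""
    d = int(round(min(distance, gene.length)))
    iv = gene.interval
    if not inverted:
        if d <= 0:
            return None
        return (iv.start, iv.start + d) if gene.strand == "+" else (iv.end - d, iv.end)
    # recovery: signal restored on [TSS, TSS+d]; the remainder is cleared
    if d >= gene.length:
        return None
    return (iv.start + d, iv.end) if gene.strand == "+" else (iv.start, iv.end - d)


def gen_runoff_tracks(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> RunoffTracks:
    """DRB time-course coverage: clearing and refilling waves from each TSS.

    The untreated control is a plateau of ``plateau_height`` over every
    gene.  After ``t`` minutes of inhibition the span
    ``[TSS, TSS + v*t]`` (transcription direction, clipped at the TES) is
    cleared — initiation is fully blocked, so no new signal enters from
    the 5' end.  After ``t'`` minutes of recovery from a fully cleared
    state, signal is restored on ``[TSS, TSS + v*t']`` only.
    """
    rng = config.rng(3)
    v = config.elongation_rate

    def build(cleared_for: dict[str, tuple[int, int] | None]) -> SignalTrack:
        runs: list[tuple[str, int, int, float]] = []
        for gene in genes:
            runs.extend(
                _gene_track_runs(
                    gene,
                    cleared_for[gene.gene_id],
                    config.plateau_height,
                    config,
                    rng,
                )
            )
        return SignalTrack.from_runs(runs)

    control = build({g.gene_id: None for g in genes})
    inhibition = {
        t: build(
            {g.gene_id: _cleared_span(g, v * t, inverted=False) for g in genes}
        )
        for t in config.inhibition_times
    }
    recovery = {
        t: build(
            {g.gene_id: _cleared_span(g, v * t, inverted=True) for g in genes}
        )
        for t in config.recovery_times
    }
    return RunoffTracks(control=control, inhibition=inhibition, recovery=recovery)


def gen_expression(
    isoforms: Sequence[TranscriptIsoform], config: SimulationConfig
) -> tuple[ExpressionTable, dict[str, str]]:
    """Counts table whose designated top isoform per gene is known.

    The first isoform of each gene (``<gene>.t1``) is the designated
    maximum: it gets the largest counts in every sample.  A
    ``low_expression_fraction`` of genes is scaled below the 0.1
    mean-RPKM selection floor (their minor isoforms get zero counts).
    Returns the table and the gene -> designated isoform map.
    """
    rng = config.rng(4)
    by_gene: dict[str, list[TranscriptIsoform]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    gene_ids = list(by_gene)
    n_low = int(round(config.low_expression_fraction * len(gene_ids)))
    low = set(
        gene_ids[i]
        for i in rng.choice(len(gene_ids), size=n_low, replace=False)
    )

    samples = [f"S{k + 1}" for k in range(config.n_samples)]
    iso_ids: list[str] = []
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    designated: dict[str, str] = {}
    for gene_id, members in by_gene.items():
        designated[gene_id] = members[0].isoform_id
        if gene_id in low:
            top_rpkm = rng.uniform(0.01, 0.05)
        else:
            top_rpkm = max(0.5, rng.lognormal(mean=2.0, sigma=0.8))
        for rank, iso in enumerate(members):
            if rank == 0:
                target = top_rpkm
            elif gene_id in low:
                target = 0.0
            else:
                target = top_rpkm * rng.uniform(0.1, 0.4)
            per_sample = target * rng.uniform(0.8, 1.25, size=len(samples))
            counts = np.round(
                per_sample
                * (iso.length / 1e3)
                * (config.total_mapped_reads / 1e6)
            )
            iso_ids.append(iso.isoform_id)
            lengths.append(float(iso.length))
            rows.append(counts)

    counts_frame = pd.DataFrame(rows, index=iso_ids, columns=samples)
    table = ExpressionTable(
        counts=counts_frame,
        lengths=pd.Series(lengths, index=iso_ids),
        totals=pd.Series(config.total_mapped_reads, index=samples),
    )
    return table, designated


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write a full dataset plus a ground-truth manifest.

    Writes BED6 annotation and gene models, four peak BED files, an
    expression TSV, bedGraph tracks (control + each time point), and
    ``manifest.json`` with the true labels, elongation rate, expected
    wavefront per inhibition time, clustered-TSS gene ids and the
    designated top isoforms.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = gen_annotation(config)
    labels = assign_labels(
        [g.gene_id for g in annotation.genes], config.class_quotas, config.rng(5)
    )
    peaks = gen_peaks(annotation.genes, labels, config)
    expression, designated = gen_expression(annotation.isoforms, config)
    tracks = gen_runoff_tracks(annotation.genes, config)

    write_annotation(annotation.isoforms, outdir / "isoforms.bed")
    write_annotation(annotation.genes, outdir / "genes.bed")
    for mark, peakset in peaks.items():
        write_peaks(peakset, outdir / f"{mark}.bed")
    write_expression_table(expression, outdir / "expression.tsv")
    write_bedgraph(tracks.control, outdir / "control.bedgraph")
    for t, track in tracks.inhibition.items():
        write_bedgraph(track, outdir / f"drb_{t:g}min.bedgraph")
    for t, track in tracks.recovery.items():
        write_bedgraph(track, outdir / f"recovery_{t:g}min.bedgraph")

    manifest = {
        "config": asdict(config),
        "labels": {g: labels[g].value for g in sorted(labels)},
        "clustered_tss_gene_ids": sorted(annotation.clustered_gene_ids),
        "designated_max_isoform": designated,
        "elongation_rate_nt_per_min": config.elongation_rate,
        "expected_front_bp": {
            f"{t:g}": config.elongation_rate * t
            for t in config.inhibition_times
        },
        "gene_lengths": {g.gene_id: g.length for g in annotation.genes},
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
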