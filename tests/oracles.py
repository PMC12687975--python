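"""Independent brute-force oracles used by the property tests.

Each oracle answers the same question as a library routine by explicit
per-base / all-pairs enumeration on small instances, without sharing any
code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from panmod.genome_io import GeneModel, GenomicInterval, PeakSet


def base_mask(intervals, length: int) -> np.ndarray:
    """Boolean membership array over [0, length) for a set of intervals."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[max(0, iv.start) : min(length, iv.end)] = True
    return mask


def brute_force_flags(
    gene: GeneModel,
    ac_intervals,
    ph_intervals,
    promoter_halfwidth: int,
    chrom_length: int,
):
    """(body_ac, body_ph, prom_ac, prom_ph) by per-base set membership."""
    prom = set(
        range(
            max(0, gene.tss - promoter_halfwidth),
            min(chrom_length, gene.tss + promoter_halfwidth + 1),
        )
    )
    body = set(range(gene.interval.start, gene.interval.end)) - prom
    flags = []
    for intervals in (ac_intervals, ph_intervals):
        bases = set()
        for iv in intervals:
            bases.update(range(iv.start, iv.end))
        flags.append((bool(bases & body), bool(bases & prom)))
    (body_ac, prom_ac), (body_ph, prom_ph) = flags
    return body_ac, body_ph, prom_ac, prom_ph


def brute_force_clustered_filter(genes, window_bp: int):
    """All-pairs O(n^2) version of the same-strand TSS proximity filter."""
    kept = []
    for g in genes:
        crowded = any(
            o is not g
            and o.chrom == g.chrom
            and o.strand == g.strand
            and abs(o.tss - g.tss) <= window_bp
            for o in genes
        )
        if not crowded:
            kept.append(g)
    return kept


def merged_window_singletons(genes, window_bp: int):
    """Transitive-cluster variant: merge TSS windows of total width
    ``window_bp`` (with bookends) per chromosome and strand, keep genes in
    clusters of size one."""
    kept = []
    groups: dict[tuple[str, str], list] = {}
    for g in genes:
        groups.setdefault((g.chrom, g.strand), []).append(g)
    half = window_bp / 2
    for members in groups.values():
        members = sorted(members, key=lambda g: g.tss)
        clusters: list[list] = []
        for g in members:
            if clusters and g.tss - half <= clusters[-1][-1].tss + half:
                clusters[-1].append(g)
            else:
                clusters.append([g])
        for cluster in clusters:
            if len(cluster) == 1:
                kept.append(cluster[0])
    order = {id(g): i for i, g in enumerate(genes)}
    return sorted(kept, key=lambda g: order[id(g)])


def brute_force_merge(peaksets) -> list[GenomicInterval]:
    """Union of peaks by per-base painting, bookended runs coalesced."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ps in peaksets:
        for iv in ps:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        hi = max(iv.end for iv in by_chrom[chrom])
        mask = base_mask(by_chrom[chrom], hi)
        padded = np.concatenate(([False], mask, [False])).astype(int)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def brute_force_bin_mean(
    runs, chrom: str, lo: int, hi: int, chrom_length: int
) -> float:
    """Per-base mean of a run list over genomic [lo, hi), implicit zeros."""
    arr = np.zeros(chrom_length)
    for c, s, e, v in runs:
        if c == chrom:
            arr[s:e] = v
    return float(arr[lo:hi].mean())


def reflect_interval(iv: GenomicInterval, pivot: int) -> GenomicInterval:
    """Mirror [start, end) through a pivot: x -> pivot - x (half-open safe)."""
    flip = {"+": "-", "-": "+", ".": "."}
    return GenomicInterval(iv.chrom, pivot - iv.end, pivot - iv.start, flip[iv.strand])


def reflect_gene(gene: GeneModel, pivot: int) -> GeneModel:
    return GeneModel(gene.gene_id, reflect_interval(gene.interval, pivot))


def reflect_peaks(peaks: PeakSet, pivot: int) -> PeakSet:
    return PeakSet(
        peaks.mark_name, [reflect_interval(iv, pivot) for iv in peaks]
    ).sorted()


def shift_peaks(peaks: PeakSet, offset: int) -> PeakSet:
    return PeakSet(peaks.mark_name, [iv.shifted(offset) for iv in peaks]).sorted()


def random_classifier_instance(rng: np.random.Generator):
    """A small random genome: <= 50 short genes and <= 200 peaks on 100 kb."""
    chrom_length = 100_000
    n_genes = int(rng.integers(1, 51))
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(300, 5_000))
        # keep promoters clear of position 0 and the chromosome end so
        # clipping never kicks in (reflection symmetry holds exactly)
        start = int(rng.integers(300, chrom_length - length - 300))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                f"g{i}", GenomicInterval("chrT", start, start + length, strand)
            )
        )
    peaksets = {}
    for mark in ("H3K9ac", "H4K12ac", "H3S10ph", "H4S1ph"):
        n_peaks = int(rng.integers(0, 51))
        ivs = []
        for _ in range(n_peaks):
            width = int(rng.integers(20, 500))
            start = int(rng.integers(0, chrom_length - width))
            ivs.append(GenomicInterval("chrT", start, start + width))
        peaksets[mark] = PeakSet(mark, ivs).sorted()
    return chrom_length, genes, peaksets
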