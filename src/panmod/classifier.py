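"""Gene classification by histone-modification peaks.

Genes are partitioned into seven classes from peak calls of two mark
families — acetylation (H3K9ac, H4K12ac) and phosphorylation (H3S10ph,
H4S1ph).  Peaks are merged within each family; each gene is then split
into a promoter zone (TSS +/- 200 bp) and the remaining gene body, and four
boolean flags record whether any family peak overlaps each zone.  The
class label is a pure function of the flags:

=========  =========  ========  ========  =================
body_ac    body_ph    prom_ac   prom_ph   label
=========  =========  ========  ========  =================
T          F          any       any       AC_DOMINATED
F          T          any       any       PH_DOMINATED
T          T          any       any       BOTH
F          F          T         F         PROM_AC_ONLY
F          F          F         T         PROM_PH_ONLY
F          F          T         T         PROM_BOTH
F          F          F         F         UNMODIFIED
=========  =========  ========  ========  =================

Body modification takes precedence over promoter flags: promoter-only
classes are reserved for genes whose every peak is confined to the
TSS +/- 200 bp window.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, PeakSet

#: Marks making up each family; the family union, not any single mark,
#: defines presence of the modification type.
ACETYLATION_MARKS = ("H3K9ac", "H4K12ac")
PHOSPHORYLATION_MARKS = ("H3S10ph", "H4S1ph")

DEFAULT_PROMOTER_HALFWIDTH = 200


class GeneClass(enum.Enum):
    AC_DOMINATED = "AC_DOMINATED"
    PH_DOMINATED = "PH_DOMINATED"
    BOTH = "BOTH"
    PROM_AC_ONLY = "PROM_AC_ONLY"
    PROM_PH_ONLY = "PROM_PH_ONLY"
    PROM_BOTH = "PROM_BOTH"
    UNMODIFIED = "UNMODIFIED"


#: Classes counted as "modified" in the summary (everything but UNMODIFIED).
MODIFIED_CLASSES = tuple(c for c in GeneClass if c is not GeneClass.UNMODIFIED)


@dataclass(frozen=True)
class MarkFamilyPeaks:
    """Merged peaks of one mark family (acetylation or phosphorylation)."""

    family: str
    merged: PeakSet

    @classmethod
    def from_marks(
        cls, family: str, peaksets: Sequence[PeakSet]
    ) -> "MarkFamilyPeaks":
        return cls(family=family, merged=merge_peaks(peaksets, mark_name=family))


class Flags(NamedTuple):
    body_ac: bool
    body_ph: bool
    prom_ac: bool
    prom_ph: bool


@dataclass(frozen=True)
class GeneZones:
    """Promoter window and residual gene-body pieces of one gene."""

    gene_id: str
    promoter: GenomicInterval
    body: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    flags: Flags
    label: GeneClass


def merge_peaks(
    peaksets: Sequence[PeakSet], mark_name: str | None = None
) -> PeakSet:
    """Union of peak sets with overlapping or bookended intervals coalesced.

    Matches default ``bedtools merge`` behaviour: intervals touching
    end-to-start ([100,200) + [200,300)) become one interval.
    """
    if not peaksets:
        raise ValueError("need at least one peak set")
    if mark_name is None:
        mark_name = "+".join(p.mark_name for p in peaksets)
    pooled = PeakSet(
        mark_name, [iv for peaks in peaksets for iv in peaks.intervals]
    )
    return pooled.normalized()


def gene_zones(
    gene: GeneModel,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    chrom_length: int | None = None,
) -> GeneZones:
    """Split a gene into its promoter window and gene-body pieces.

    The promoter is TSS +/- ``promoter_halfwidth`` inclusive on both sides,
    i.e. the half-open window ``[tss - hw, tss + hw + 1)``, clipped to the
    chromosome.  The body is the gene interval minus the promoter: one
    piece for a TSS at a gene edge, up to two if the promoter falls
    strictly inside the gene (possible with unusual annotations), possibly
    none for genes shorter than the window.
    """
    chrom = gene.chrom
    prom_start = max(0, gene.tss - promoter_halfwidth)
    prom_end = gene.tss + promoter_halfwidth + 1
    if chrom_length is not None:
        prom_end = min(prom_end, chrom_length)
    promoter = GenomicInterval(chrom, prom_start, prom_end)

    body: list[GenomicInterval] = []
    giv = gene.interval
    if giv.start < prom_start:
        body.append(GenomicInterval(chrom, giv.start, min(giv.end, prom_start)))
    if giv.end > prom_end:
        body.append(GenomicInterval(chrom, max(giv.start, prom_end), giv.end))
    return GeneZones(gene_id=gene.gene_id, promoter=promoter, body=tuple(body))


def _max_overlap(peaks: PeakSet, target: GenomicInterval) -> int:
    """Largest single-peak overlap (bp) of a normalized peak set with target."""
    starts, ends = peaks.index_for(target.chrom)
    if starts.size == 0:
        return 0
    # peaks are sorted and disjoint, so ends are sorted too
    lo = int(np.searchsorted(ends, target.start, side="right"))
    hi = int(np.searchsorted(starts, target.end, side="left"))
    if hi <= lo:
        return 0
    overlap = np.minimum(ends[lo:hi], target.end) - np.maximum(
        starts[lo:hi], target.start
    )
    return int(overlap.max())


def _zone_flags(
    peaks: PeakSet,
    zones: GeneZones,
    min_overlap_bp: int,
    strict_containment: bool,
) -> tuple[bool, bool]:
    """(body_flag, prom_flag) for one mark family against one gene."""
    body_hit = any(
        _max_overlap(peaks, piece) >= min_overlap_bp for piece in zones.body
    )
    if strict_containment:
        prom_hit = any(
            zones.promoter.contains(iv)
            for iv in peaks
            if iv.chrom == zones.promoter.chrom
        )
    else:
        prom_hit = _max_overlap(peaks, zones.promoter) >= min_overlap_bp
    return body_hit, prom_hit


def assign_flags(
    zones: GeneZones,
    ac: MarkFamilyPeaks,
    ph: MarkFamilyPeaks,
    min_overlap_bp: int = 1,
    strict_containment: bool = False,
) -> Flags:
    """Overlap each family's merged peaks with the gene's zones.

    A flag is set when any merged peak overlaps the zone by at least
    ``min_overlap_bp``; a peak straddling the promoter boundary sets both
    the promoter and the body flag.  With ``strict_containment=True`` the
    promoter flag instead requires a peak fully inside the promoter
    window (sensitivity-analysis variant).
    """
    body_ac, prom_ac = _zone_flags(
        ac.merged, zones, min_overlap_bp, strict_containment
    )
    body_ph, prom_ph = _zone_flags(
        ph.merged, zones, min_overlap_bp, strict_containment
    )
    return Flags(body_ac, body_ph, prom_ac, prom_ph)


def classify_gene(flags: Flags) -> GeneClass:
    """Map the four zone flags to the single class label (truth table)."""
    if flags.body_ac and flags.body_ph:
        return GeneClass.BOTH
    if flags.body_ac:
        return GeneClass.AC_DOMINATED
    if flags.body_ph:
        return GeneClass.PH_DOMINATED
    if flags.prom_ac and flags.prom_ph:
        return GeneClass.PROM_BOTH
    if flags.prom_ac:
        return GeneClass.PROM_AC_ONLY
    if flags.prom_ph:
        return GeneClass.PROM_PH_ONLY
    return GeneClass.UNMODIFIED


def classify_genes(
    genes: Iterable[GeneModel],
    ac: MarkFamilyPeaks,
    ph: MarkFamilyPeaks,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    min_overlap_bp: int = 1,
    strict_containment: bool = False,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GeneClassification]:
    """Run zones -> flags -> label for every gene."""
    out: list[GeneClassification] = []
    for gene in genes:
        chrom_len = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        zones = gene_zones(gene, promoter_halfwidth, chrom_len)
        flags = assign_flags(zones, ac, ph, min_overlap_bp, strict_containment)
        out.append(
            GeneClassification(
                gene_id=gene.gene_id, flags=flags, label=classify_gene(flags)
            )
        )
    return out


def summarize(
    classifications: Iterable[GeneClassification],
) -> dict[GeneClass, int]:
    """Per-class gene counts (zero for absent classes)."""
    counter = Counter(c.label for c in classifications)
    return {cls: counter.get(cls, 0) for cls in GeneClass}


def aggregate_counts(
    counts: Mapping[GeneClass, int],
    total_protein_coding: int | None = None,
) -> dict[str, int]:
    """Headline aggregates of a per-class count table.

    Returns the modified total (sum over the six modified classes), the
    acetylation analysis set (acetylation-dominated plus both — the genes
    carrying body acetylation), the phosphorylation analysis set
    (phosphorylation-dominated plus both), and the unmodified remainder.
    When ``total_protein_coding`` is given, unmodified is the difference
    between it and the modified total; otherwise the UNMODIFIED count in
    ``counts`` is used.
    """
    modified_total = sum(int(counts.get(cls, 0)) for cls in MODIFIED_CLASSES)
    ac_set = int(counts.get(GeneClass.AC_DOMINATED, 0)) + int(
        counts.get(GeneClass.BOTH, 0)
    )
    ph_set = int(counts.get(GeneClass.PH_DOMINATED, 0)) + int(
        counts.get(GeneClass.BOTH, 0)
    )
    if total_protein_coding is not None:
        unmodified = int(total_protein_coding) - modified_total
    else:
        unmodified = int(counts.get(GeneClass.UNMODIFIED, 0))
    return {
        "modified_total": modified_total,
        "acetylation_analysis_set": ac_set,
        "phosphorylation_analysis_set": ph_set,
        "unmodified": unmodified,
    }


def summary_frame(
    counts: Mapping[GeneClass, int],
    total_protein_coding: int | None = None,
) -> pd.DataFrame:
    """Counts as a tidy table: one row per class plus the modified total."""
    agg = aggregate_counts(counts, total_protein_coding)
    rows = [
        {"class": cls.value, "genes": int(counts.get(cls, 0))}
        for cls in MODIFIED_CLASSES
    ]
    rows.append({"class": "TOTAL_MODIFIED", "genes": agg["modified_total"]})
    rows.append({"class": "UNMODIFIED", "genes": agg["unmodified"]})
    return pd.DataFrame(rows)


def classification_frame(
    classifications: Sequence[GeneClassification],
) -> pd.DataFrame:
    """Per-gene flags and label as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "body_ac": [int(c.flags.body_ac) for c in classifications],
            "body_ph": [int(c.flags.body_ph) for c in classifications],
            "prom_ac": [int(c.flags.prom_ac) for c in classifications],
            "prom_ph": [int(c.flags.prom_ph) for c in classifications],
            "label": [c.label.value for c in classifications],
        }
    )
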