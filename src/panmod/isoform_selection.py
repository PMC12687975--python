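"""Reduce an isoform-level annotation to one gene model per gene.

Mirrors the nascent-transcription preprocessing used for TSS-anchored
heatmaps: keep, per gene, the isoform with the highest mean RPKM across all
samples (requiring a minimum mean of 0.1 RPKM), then discard every gene
whose TSS lies within 100 kb of another gene's TSS on the same strand, so
that run-on signal windows are not contaminated by neighbouring genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, TranscriptIsoform

TOTALS_ROW_ID = "__totals__"


def rpkm(count: float, isoform_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if isoform_length_bp <= 0:
        raise ValueError("isoform length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return count / ((isoform_length_bp / 1e3) * (total_mapped_reads / 1e6))


@dataclass
class ExpressionTable:
    """Per-isoform read counts across samples, with library sizes.

    ``counts`` is an isoform x sample DataFrame of non-negative read
    counts; ``lengths`` gives each isoform's length in bp; ``totals`` the
    per-sample total mapped reads (library size), which must be at least
    the column sums of ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.astype(float).reindex(self.counts.index)
        self.totals = self.totals.astype(float).reindex(self.counts.columns)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValueError(f"missing lengths for isoforms {missing[:5]}")
        if (self.lengths <= 0).any():
            raise ValueError("isoform lengths must be positive")
        if self.totals.isna().any() or (self.totals <= 0).any():
            raise ValueError("per-sample totals must be positive")
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        short = self.totals < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                f"totals smaller than column sums for {list(self.totals.index[short])}"
            )

    def rpkm_matrix(self) -> pd.DataFrame:
        scale = (self.lengths.values[:, None] / 1e3) * (
            self.totals.values[None, :] / 1e6
        )
        return pd.DataFrame(
            self.counts.values / scale,
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def mean_rpkm(self) -> pd.Series:
        """Unweighted arithmetic mean RPKM across samples, per isoform."""
        return self.rpkm_matrix().mean(axis=1)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with columns isoform_id, length, then one column per sample.

    Library sizes come from a reserved row with isoform_id ``__totals__``;
    without it, column sums are used.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"isoform_id": str})
    frame = frame.set_index("isoform_id")
    if TOTALS_ROW_ID in frame.index:
        totals = frame.loc[TOTALS_ROW_ID].drop("length")
        frame = frame.drop(index=TOTALS_ROW_ID)
    else:
        totals = frame.drop(columns="length").sum(axis=0)
    return ExpressionTable(
        counts=frame.drop(columns="length"),
        lengths=frame["length"],
        totals=totals,
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    frame = table.counts.copy()
    frame.insert(0, "length", table.lengths)
    totals = table.totals.copy()
    totals["length"] = 0.0
    frame.loc[TOTALS_ROW_ID] = totals
    frame.index.name = "isoform_id"
    frame.reset_index().to_csv(path, sep="\t", index=False)


def select_max_isoform(
    isoforms: Iterable[TranscriptIsoform],
    expression: ExpressionTable,
    min_mean_rpkm: float = 0.1,
) -> list[GeneModel]:
    """Keep one gene model per gene: the isoform with the highest mean RPKM.

    Genes whose best isoform falls below ``min_mean_rpkm`` are dropped
    entirely.  Ties on mean RPKM go to the longer isoform, then to the
    lexicographically smaller isoform id, so the choice is deterministic.
    Output follows the input order of the winning isoforms.
    """
    isoforms = list(isoforms)
    means = expression.mean_rpkm()
    missing = [iso.isoform_id for iso in isoforms if iso.isoform_id not in means.index]
    if missing:
        raise KeyError(f"no expression entries for isoforms {missing[:5]}")

    best: dict[str, tuple[float, int, str, int]] = {}
    order: list[str] = []
    for pos, iso in enumerate(isoforms):
        mean = float(means[iso.isoform_id])
        # sort key: higher mean, then longer, then smaller id wins
        key = (mean, iso.length, _NegStr(iso.isoform_id), -pos)
        if iso.gene_id not in best:
            best[iso.gene_id] = (key, pos)  # type: ignore[assignment]
            order.append(iso.gene_id)
        elif key > best[iso.gene_id][0]:  # type: ignore[index]
            best[iso.gene_id] = (key, pos)  # type: ignore[assignment]

    models: list[GeneModel] = []
    for gene_id in order:
        key, pos = best[gene_id]  # type: ignore[misc]
        if key[0] >= min_mean_rpkm:
            models.append(GeneModel.from_isoform(isoforms[pos]))
    return models


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers smaller ids."""

    def __lt__(self, other: str) -> bool:  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:
        return str.__lt__(self, other)


def filter_clustered_tss(
    genes: Sequence[GeneModel], window_bp: int = 100_000
) -> list[GeneModel]:
    """Drop genes with another same-strand TSS within ``window_bp``.

    A gene survives iff no other gene on the same chromosome and strand has
    a TSS at distance <= ``window_bp`` (the boundary counts as clustered,
    matching merge-with-bookends semantics of window-based clustering).
    Input order is preserved; the filter is idempotent.
    """
    by_group: dict[tuple[str, str], list[int]] = {}
    for idx, gene in enumerate(genes):
        by_group.setdefault((gene.chrom, gene.strand), []).append(idx)

    keep = np.ones(len(genes), dtype=bool)
    for indices in by_group.values():
        indices = sorted(indices, key=lambda i: genes[i].tss)
        tss = [genes[i].tss for i in indices]
        for k, idx in enumerate(indices):
            near_prev = k > 0 and tss[k] - tss[k - 1] <= window_bp
            near_next = k + 1 < len(indices) and tss[k + 1] - tss[k] <= window_bp
            if near_prev or near_next:
                keep[idx] = False
    return [gene for idx, gene in enumerate(genes) if keep[idx]]
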