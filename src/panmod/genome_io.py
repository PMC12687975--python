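"""Genomic domain types and plain-text format I/O.

Every coordinate inside the package is 0-based half-open ``[start, end)``,
the BED/bedtools convention.  GTF input (1-based, fully closed) is shifted
on read and restored on write.  The TSS of a plus-strand gene is
``interval.start``; for a minus-strand gene it is ``interval.end - 1``
(the last covered base).

Formats handled: BED3/BED6/BED12 and narrowPeak (peaks), BED6/BED12 and a
minimal GTF dialect restricted to ``transcript`` records (annotations),
bedGraph (coverage tracks), and TSV result tables.  Binary formats (BAM,
bigWig) are out of scope; convert externally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Primary assembly chromosomes ("standard chromosomes") used as the
#: default whitelist when reading annotations.
STANDARD_CHROMOSOMES: tuple[str, ...] = tuple(
    f"chr{n}" for n in list(range(1, 23)) + ["X", "Y"]
)

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A malformed record in an input file; the message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Length in bp of the overlap with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand
        )


@dataclass(frozen=True)
class TranscriptIsoform:
    """One transcript isoform of a gene; strand is always + or -."""

    gene_id: str
    isoform_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("isoform strand must be + or -")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class GeneModel:
    """A single representative gene interval with strand-aware TSS/TES."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        if len(self.interval) < 2:
            raise ValueError("gene must span at least 2 bp so TSS != TES")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @classmethod
    def from_isoform(cls, isoform: TranscriptIsoform) -> "GeneModel":
        return cls(gene_id=isoform.gene_id, interval=isoform.interval)


@dataclass
class PeakSet:
    """A named collection of strandless intervals for one mark (or family).

    ``normalized()`` returns an equivalent set whose intervals are sorted by
    (chrom, start) with overlapping or bookended intervals coalesced — the
    invariant form all downstream overlap queries assume.
    """

    mark_name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.mark_name,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
        )

    def index_for(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, built lazily.

        Assumes the set is normalized (sorted, non-overlapping) and not
        mutated afterwards; used for fast overlap queries.
        """
        cache: dict[str, tuple[np.ndarray, np.ndarray]]
        cache = self.__dict__.setdefault("_index", {})
        if chrom not in cache:
            starts = np.array(
                [iv.start for iv in self.intervals if iv.chrom == chrom],
                dtype=np.int64,
            )
            ends = np.array(
                [iv.end for iv in self.intervals if iv.chrom == chrom],
                dtype=np.int64,
            )
            cache[chrom] = (starts, ends)
        return cache[chrom]

    def normalized(self) -> "PeakSet":
        """Sorted with overlapping/bookended intervals merged (gap <= 0)."""
        merged: list[GenomicInterval] = []
        for iv in self.sorted():
            if (
                merged
                and merged[-1].chrom == iv.chrom
                and iv.start <= merged[-1].end
            ):
                if iv.end > merged[-1].end:
                    merged[-1] = GenomicInterval(
                        iv.chrom, merged[-1].start, iv.end
                    )
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return PeakSet(self.mark_name, merged)


class SignalTrack:
    """Per-chromosome runs of (start, end, value) with implicit zeros.

    bedGraph semantics: runs within a chromosome are sorted and
    non-overlapping; any base not covered by a run has value 0.  Values are
    arbitrary signal densities (coverage, RPKM-scaled coverage, or log2
    ratios).  Queries are vectorised through a cumulative integral per
    chromosome, so window means over many bins are cheap.
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, items in by_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=np.float64)
            if np.any(starts >= ends):
                raise ValueError(f"empty run on {chrom}")
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"overlapping runs on {chrom}: "
                    f"[{starts[i]}, {ends[i]}) and [{starts[i+1]}, {ends[i+1]})"
                )
            track._runs[chrom] = (starts, ends, values)
        return track

    def chromosomes(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        if chrom not in self._runs:
            return iter(())
        starts, ends, values = self._runs[chrom]
        return (
            (int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)
        )

    def all_runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chromosomes():
            for s, e, v in self.runs(chrom):
                yield chrom, s, e, v

    def chrom_arrays(
        self, chrom: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._runs[chrom]

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack.from_runs(
            (c, s, e, v * factor) for c, s, e, v in self.all_runs()
        )

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            starts, ends, values = self._runs[chrom]
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum(values * (ends - starts)))
            )
        return self._cum[chrom]

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, p) for each position p."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._runs:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self._runs[chrom]
        cum = self._cumulative(chrom)
        idx = np.searchsorted(starts, positions, side="right") - 1
        result = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        inside = idx >= 0
        i = np.maximum(idx, 0)
        partial = np.clip(np.minimum(positions, ends[i]) - starts[i], 0, None)
        result = result + np.where(inside, values[i] * partial, 0.0)
        return result

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end) with implicit zeros."""
        if end <= start:
            raise ValueError("empty window")
        lo, hi = self.integral(chrom, np.array([start, end]))
        return float((hi - lo) / (end - start))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split()


def _iter_data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, _split_fields(line)


def _gene_id_from_name(name: str) -> str:
    # BED carries only one name column; the "<gene>.<isoform>" convention
    # (dot-separated, gene part before the last dot) recovers the gene id.
    head, sep, _tail = name.rpartition(".")
    return head if sep else name


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    chromosomes: Sequence[str] | None = STANDARD_CHROMOSOMES,
) -> list[TranscriptIsoform]:
    """Read an isoform-level annotation from BED6, BED12 or minimal GTF.

    Parameters
    ----------
    path
        Input file.  ``fmt`` is inferred from the extension when ``None``
        (``.gtf``/``.gff`` -> ``"gtf"``, else BED; BED6 vs BED12 is decided
        per record by column count).
    chromosomes
        Whitelist; records on other chromosomes are dropped.  Pass ``None``
        to keep everything.  Defaults to the primary assembly
        (chr1-22, chrX, chrY).

    Records with strand ``.`` are rejected; one summary warning reports how
    many were dropped.  Any other malformed record raises
    :class:`FormatError` naming the line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "bed"
    fmt = fmt.lower().replace("-min", "")
    whitelist = set(chromosomes) if chromosomes is not None else None

    isoforms: list[TranscriptIsoform] = []
    n_unstranded = 0
    for lineno, fields in _iter_data_lines(path):
        try:
            if fmt == "gtf":
                if len(fields) < 9:
                    raise ValueError("GTF record needs >= 9 fields")
                if fields[2] != "transcript":
                    continue
                chrom = fields[0]
                start = int(fields[3]) - 1  # 1-based closed -> 0-based open
                end = int(fields[4])
                strand = fields[6]
                attrs = _parse_gtf_attributes(" ".join(fields[8:]))
                gene_id = attrs.get("gene_id", "")
                isoform_id = attrs.get("transcript_id", "")
                if not gene_id or not isoform_id:
                    raise ValueError("missing gene_id/transcript_id attribute")
            else:
                if len(fields) < 6:
                    raise ValueError("BED annotation needs >= 6 columns")
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                isoform_id = fields[3]
                strand = fields[5]
                gene_id = _gene_id_from_name(isoform_id)
            if strand == ".":
                n_unstranded += 1
                continue
            if whitelist is not None and chrom not in whitelist:
                continue
            isoforms.append(
                TranscriptIsoform(
                    gene_id=gene_id,
                    isoform_id=isoform_id,
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if n_unstranded:
        warnings.warn(
            f"{path}: dropped {n_unstranded} record(s) with strand '.'",
            stacklevel=2,
        )
    seen: dict[str, int] = {}
    for iso in isoforms:
        seen[iso.isoform_id] = seen.get(iso.isoform_id, 0) + 1
    dupes = [k for k, n in seen.items() if n > 1]
    if dupes:
        raise FormatError(f"{path}: duplicate isoform id(s): {dupes[:5]}")
    return isoforms


def read_peaks(path: str | Path, mark_name: str | None = None) -> PeakSet:
    """Read peak calls from BED or narrowPeak; only chrom/start/end kept.

    Extra columns (name, score, summit offset, ...) are ignored.  Intervals
    come back sorted.  Zero-length or inverted intervals raise
    :class:`FormatError` with the offending line number.
    """
    path = Path(path)
    if mark_name is None:
        mark_name = path.stem
    intervals: list[GenomicInterval] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: needs >= 3 columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if start >= end:
            raise FormatError(
                f"{path}:{lineno}: empty or inverted interval "
                f"[{start}, {end})"
            )
        intervals.append(GenomicInterval(chrom, start, end))
    return PeakSet(mark_name, intervals).sorted()


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a bedGraph coverage track (0-based half-open runs).

    Overlapping runs are an error (the message names the positions).
    """
    path = Path(path)
    runs: list[tuple[str, int, int, float]] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: needs 4 columns")
        try:
            runs.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SignalTrack.from_runs(runs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in peaks:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_annotation(
    isoforms: Iterable[TranscriptIsoform | GeneModel],
    path: str | Path,
    fmt: str = "bed6",
) -> None:
    """Write isoforms or gene models as BED6 or minimal GTF."""
    fmt = fmt.lower().replace("-min", "")
    with open(path, "w") as handle:
        for rec in isoforms:
            iv = rec.interval
            name = getattr(rec, "isoform_id", None) or rec.gene_id
            if fmt == "gtf":
                gene_id = rec.gene_id
                handle.write(
                    f"{iv.chrom}\tpanmod\ttranscript\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{iv.strand}\t.\t"
                    f'gene_id "{gene_id}"; transcript_id "{name}";\n'
                )
            else:
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                    f"{iv.strand}\n"
                )


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in track.all_runs():
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame, path: str | Path
) -> None:
    """Write rows as a TSV with header; re-reading restores them exactly."""
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
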