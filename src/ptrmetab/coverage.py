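"""Windowed coverage profiles of one reference genome from SAM alignments.

A complete circular genome is split into equal "virtual contigs" so that a
contig-based growth estimator can run on it.  Alignments are filtered on
mapping length, mapping quality and mismatch ratio, per-base depth is
summarised in sliding windows per contig, and a contig is kept for a sample
only when every one of its windows has nonzero coverage.  Retained values are
log2 of the mean window coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "FilterThresholds",
    "VirtualContig",
    "split_virtual_contigs",
    "passes_filters",
    "windowed_coverage",
    "assemble_matrix",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one aligned read, as the filters see it."""

    reference_start: int  # 0-based
    aligned_length: int  # reference bases consumed
    mapq: int
    mismatch_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.aligned_length < 0:
            raise ValueError("aligned_length must be >= 0")
        if self.mismatch_count > self.aligned_length:
            raise ValueError("mismatch_count cannot exceed aligned_length")


@dataclass(frozen=True)
class FilterThresholds:
    """Alignment-quality thresholds; all three comparisons are inclusive."""

    min_length: int = 50
    min_mapq: int = 5
    max_mismatch_ratio: float = 0.03

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0.0 <= self.max_mismatch_ratio <= 1.0:
            raise ValueError("max_mismatch_ratio must be in [0, 1]")


@dataclass(frozen=True)
class VirtualContig:
    """Half-open interval [start, end) of the reference, 0-based."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def name(self) -> str:
        return f"c{self.index:02d}"


def split_virtual_contigs(genome_length: int, n_contigs: int = 20) -> list[VirtualContig]:
    """Tile ``[0, genome_length)`` with ``n_contigs`` near-equal intervals.

    The first ``genome_length % n_contigs`` contigs are one base longer, so
    contig sizes differ by at most 1 bp and the union covers the genome
    exactly.

    Raises
    ------
    ValueError
        If the genome is shorter than the number of contigs requested.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if genome_length < n_contigs:
        raise ValueError(
            f"genome too short: length {genome_length} cannot be split into "
            f"{n_contigs} virtual contigs"
        )
    base, extra = divmod(genome_length, n_contigs)
    contigs = []
    start = 0
    for i in range(n_contigs):
        end = start + base + (1 if i < extra else 0)
        contigs.append(VirtualContig(index=i, start=start, end=end))
        start = end
    return contigs


def passes_filters(record: AlignmentRecord, thresholds: FilterThresholds | None = None) -> bool:
    """True iff the record meets all three inclusive quality thresholds.

    A zero-length alignment is rejected outright, avoiding the undefined
    mismatch ratio.
    """
    t = thresholds or FilterThresholds()
    if record.aligned_length <= 0:
        return False
    if record.aligned_length < t.min_length:
        return False
    if record.mapq < t.min_mapq:
        return False
    return record.mismatch_count / record.aligned_length <= t.max_mismatch_ratio


def _iter_sam_records(sam_path: str | Path, sample_id: str) -> Iterable[AlignmentRecord]:
    """Yield primary mapped alignments as AlignmentRecord.

    Secondary, supplementary and unmapped records are excluded so each read
    contributes coverage at most once.  A record without the edit-distance
    (NM) tag is treated as mismatch-free, with a warning.
    """
    warned = False
    try:
        with pysam.AlignmentFile(str(sam_path), "r") as fh:
            for read in fh:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.has_tag("NM"):
                    nm = int(read.get_tag("NM"))
                else:
                    nm = 0
                    if not warned:
                        warnings.warn(
                            f"{sam_path}: records lack the NM edit-distance tag; "
                            "treating them as mismatch-free",
                            stacklevel=3,
                        )
                        warned = True
                yield AlignmentRecord(
                    reference_start=read.reference_start,
                    aligned_length=read.reference_length or 0,
                    mapq=read.mapping_quality,
                    mismatch_count=nm,
                    sample_id=sample_id,
                )
    except (ValueError, OSError) as exc:
        raise ValueError(f"failed to parse SAM file {sam_path}: {exc}") from exc


def depth_from_records(
    records: Iterable[AlignmentRecord],
    genome_length: int,
    thresholds: FilterThresholds | None = None,
) -> np.ndarray:
    """Per-base depth over [0, genome_length) from filtered records."""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    n_kept = 0
    for rec in records:
        if not passes_filters(rec, thresholds):
            continue
        start = max(rec.reference_start, 0)
        end = min(rec.reference_start + rec.aligned_length, genome_length)
        if end <= start:
            continue
        diff[start] += 1
        diff[end] -= 1
        n_kept += 1
    if n_kept == 0:
        raise ValueError("no alignments passed the quality filters")
    return np.cumsum(diff[:-1])


def _window_starts(contig: VirtualContig, window_size: int, window_step: int) -> range:
    return range(contig.start, contig.end - window_size + 1, window_step)


def windowed_coverage(
    sam_path: str | Path,
    contigs: Sequence[VirtualContig],
    thresholds: FilterThresholds | None = None,
    window_size: int | None = None,
    window_step: int | None = None,
    sample_id: str | None = None,
) -> pd.Series:
    """One coverage-matrix row: log2 mean window coverage per virtual contig.

    Windows slide within each contig (default size = contig length // 5,
    default step = size // 2).  A contig with any window of zero mean
    coverage is masked (NaN) for this sample; retained values are
    ``log2(mean over windows of the per-base window mean)``.

    Raises
    ------
    ValueError
        On unparseable SAM input, if no read passes the filters, or if every
        contig is masked (insufficient depth).
    """
    sample = sample_id or Path(sam_path).stem
    genome_length = contigs[-1].end
    smallest = min(c.length for c in contigs)
    if window_size is not None and window_size > smallest:
        raise ValueError(
            f"window_size {window_size} exceeds smallest contig size {smallest}"
        )
    depth = depth_from_records(_iter_sam_records(sam_path, sample), genome_length, thresholds)
    cumdepth = np.concatenate([[0], np.cumsum(depth)])

    values = np.full(len(contigs), np.nan)
    for i, contig in enumerate(contigs):
        ws = window_size if window_size is not None else max(contig.length // 5, 1)
        st = window_step if window_step is not None else max(ws // 2, 1)
        starts = np.fromiter(_window_starts(contig, ws, st), dtype=np.int64)
        means = (cumdepth[starts + ws] - cumdepth[starts]) / ws
        if np.all(means > 0):
            values[i] = np.log2(means.mean())
    if np.all(np.isnan(values)):
        raise ValueError(
            f"sample {sample}: every virtual contig has a zero-coverage window; "
            "sequencing depth is insufficient"
        )
    return pd.Series(values, index=[c.name for c in contigs], name=sample)


def assemble_matrix(rows: Mapping[str, pd.Series] | Sequence[pd.Series]) -> pd.DataFrame:
    """Stack per-sample rows into a complete samples x contigs matrix.

    Contigs masked in *any* sample are dropped globally (the downstream PCA
    needs a complete matrix); the dropped contig names are recorded in
    ``result.attrs['dropped_contigs']``.

    Raises
    ------
    ValueError
        With fewer than 3 samples, or if fewer than 4 contigs survive.
    """
    if isinstance(rows, Mapping):
        frame = pd.DataFrame({k: v for k, v in rows.items()}).T
    else:
        frame = pd.DataFrame({row.name: row for row in rows}).T
    if frame.shape[0] < 3:
        raise ValueError("PTR inference needs at least 3 samples")
    dropped = [c for c in frame.columns if frame[c].isna().any()]
    kept = frame.drop(columns=dropped)
    if kept.shape[1] < 4:
        raise ValueError(
            f"only {kept.shape[1]} virtual contigs survive masking "
            "(>= 4 required for distance inference)"
        )
    if dropped:
        warnings.warn(f"dropped {len(dropped)} masked contig(s): {dropped}", stacklevel=2)
    kept = kept.sort_index()
    kept.attrs["dropped_contigs"] = dropped
    return kept
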