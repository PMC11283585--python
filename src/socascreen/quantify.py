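"""From paired amplicon reads to per-array counts, rpm abundances and LFCs.

The screen readout is a fixed amplicon over the crRNA cassette, sequenced as
paired-end reads.  Pairs are merged by their exact suffix/prefix overlap
(minimum 31 nt — "more than 30 bp"), each merged read is assigned to the
unique array whose counting signature (spacer1 + DR + overlap + DR + spacer2)
it contains, and raw counts are normalised to reads per million (rpm).
Fold-change FC = final rpm / initial rpm and LFC = log2 FC quantify
depletion/enrichment over the screen interval.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .library import Category, LibraryDesign

__all__ = [
    "SampleInfo",
    "CountingStats",
    "merge_read_pair",
    "reverse_complement",
    "count_sample",
    "count_fastq_pair",
    "to_rpm",
    "compute_lfc",
    "collapse_sko_per_gene",
    "coverage_and_skew",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class SampleInfo:
    """One screen sample: condition (plasmid / cell / tumour), day, replicate."""

    sample_id: str
    condition: str
    timepoint_days: int = 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in {"plasmid", "cell", "tumour"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.timepoint_days < 0:
            raise ValueError("timepoint_days must be >= 0")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_read_pair(read1: str, read2: str, min_overlap: int = 31) -> str | None:
    """Merge a read pair by the longest exact suffix/prefix overlap.

    ``read2`` is reverse-complemented; the longest exact overlap between a
    suffix of ``read1`` and a prefix of rc(read2) with length >= ``min_overlap``
    joins the two.  Returns ``None`` when no qualifying overlap exists.  Any N
    inside a candidate overlap counts as a mismatch (N outside the overlap is
    kept as-is).
    """
    if not read1 or not read2:
        raise ValueError("reads must be non-empty")
    for read in (read1, read2):
        if not set(read) <= _VALID:
            raise ValueError("reads may only contain A/C/G/T/N")
    rc2 = reverse_complement(read2)
    max_ov = min(len(read1), len(rc2))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = read1[-ov:]
        if "N" not in tail and tail == rc2[:ov]:
            return read1 + rc2[ov:]
    return None


@dataclass
class CountingStats:
    """Per-sample assignment tallies for the QC report."""

    total: int = 0
    merged: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "merged": self.merged,
            "assigned": self.assigned,
            "unassigned": self.unassigned,
            "ambiguous": self.ambiguous,
        }


def _match_arrays(read: str, core: str, flank_index: dict) -> set[str]:
    """All array_ids whose signature is a substring of ``read``.

    Signatures share the constant core DR+overlap+DR, so every signature match
    sits at a core occurrence with a 20-nt spacer on each side."""
    n1, n2 = flank_index["n1"], flank_index["n2"]
    lookup = flank_index["pairs"]
    hits: set[str] = set()
    start = read.find(core)
    while start != -1:
        s1 = read[start - n1 : start]
        s2 = read[start + len(core) : start + len(core) + n2]
        if len(s1) == n1 and len(s2) == n2:
            array_id = lookup.get((s1, s2))
            if array_id is not None:
                hits.add(array_id)
        start = read.find(core, start + 1)
    return hits


def _flank_index(design: LibraryDesign) -> dict:
    pairs = {}
    for a in design.arrays:
        key = (a.pos1.spacer, a.pos2.spacer)
        if key in pairs:  # guaranteed unique by LibraryDesign invariant
            raise ValueError("duplicate spacer pair in design")
        pairs[key] = a.array_id
    n1 = len(next(iter(pairs))[0])
    n2 = len(next(iter(pairs))[1])
    return {"pairs": pairs, "n1": n1, "n2": n2}


def count_sample(
    merged_reads: Iterable[str], design: LibraryDesign
) -> tuple[pd.Series, CountingStats]:
    """Assign merged reads to arrays by exact signature match.

    Each read increments at most one array: the unique array whose signature
    is an exact substring (forward orientation first, then a reverse-complement
    retry of the whole read).  Reads matching zero or >= 2 arrays are discarded
    and tallied.  The returned Series covers every array (zeros included).
    """
    core = design.dr_sequence + design.overlap_sequence + design.dr_sequence
    index = _flank_index(design)
    counts = dict.fromkeys(design.array_ids, 0)
    stats = CountingStats()
    for read in merged_reads:
        stats.total += 1
        hits = _match_arrays(read, core, index)
        if not hits:
            hits = _match_arrays(reverse_complement(read), core, index)
        if len(hits) == 1:
            counts[hits.pop()] += 1
            stats.assigned += 1
        elif len(hits) == 0:
            stats.unassigned += 1
        else:
            stats.ambiguous += 1
    stats.merged = stats.total
    return pd.Series(counts, name="count", dtype=int), stats


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq_seqs(path: str | Path) -> Iterator[str]:
    # plain 4-line FASTQ reader; quality is irrelevant to exact counting
    with _open_maybe_gzip(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


def count_fastq_pair(
    fastq1: str | Path,
    fastq2: str | Path,
    design: LibraryDesign,
    min_overlap: int = 31,
) -> tuple[pd.Series, CountingStats]:
    """Merge a paired FASTQ and count arrays; unmergeable pairs are tallied."""
    n_pairs = 0
    merged_reads: list[str] = []
    for r1, r2 in zip(_iter_fastq_seqs(fastq1), _iter_fastq_seqs(fastq2), strict=True):
        n_pairs += 1
        m = merge_read_pair(r1, r2, min_overlap=min_overlap)
        if m is not None:
            merged_reads.append(m)
    counts, stats = count_sample(merged_reads, design)
    stats.merged = len(merged_reads)
    stats.total = n_pairs
    stats.unassigned += n_pairs - len(merged_reads)
    return counts, stats


def to_rpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Reads-per-million normalisation: count / column total * 1e6, per sample."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise ValueError("all-zero count column cannot be rpm-normalised")
        return counts / total * 1e6
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero count column(s): {bad}")
    return counts / totals * 1e6


def compute_lfc(
    final: pd.Series,
    initial: pd.Series,
    pseudocount_rpm: float = 1.0,
) -> pd.DataFrame:
    """FC = (final + pc) / (initial + pc) and LFC = log2 FC per array.

    The pseudocount (default 1 rpm) keeps dropout arrays finite.
    """
    if set(final.index) != set(initial.index):
        raise ValueError("final and initial columns must cover the same arrays")
    initial = initial.reindex(final.index)
    fc = (final + pseudocount_rpm) / (initial + pseudocount_rpm)
    return pd.DataFrame({"fc": fc, "lfc": np.log2(fc)})


def collapse_sko_per_gene(
    values: pd.DataFrame | pd.Series,
    design: LibraryDesign,
    statistic: str = "mean",
) -> pd.DataFrame | pd.Series:
    """Collapse SKO arrays to one value per targeting gene (mean or median).

    Mirrors taking the average over a gene's single-knockout arrays before
    comparing against its double-knockout partners.
    """
    if statistic not in {"mean", "median"}:
        raise ValueError("statistic must be 'mean' or 'median'")
    frame = values.to_frame() if isinstance(values, pd.Series) else values
    rows = {}
    for gene in design.targeting_genes():
        arrays = [a.array_id for a in design.sko_arrays_for(gene)]
        if not arrays:
            raise ValueError(f"gene {gene!r} has no SKO arrays")
        sub = frame.loc[arrays]
        rows[gene] = sub.mean(axis=0) if statistic == "mean" else sub.median(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    if isinstance(values, pd.Series):
        return out.iloc[:, 0].rename(values.name)
    return out


def coverage_and_skew(
    counts: pd.Series, detect_threshold: int = 1
) -> tuple[float, float]:
    """Library QC: detected fraction and p90/p10 count skew.

    coverage = fraction of arrays with count >= threshold; skew = 90th / 10th
    percentile of the counts (linear-interpolation percentiles); skew is NaN
    when the 10th percentile is zero.
    """
    if counts.empty:
        raise ValueError("empty count column")
    coverage = float((counts >= detect_threshold).mean())
    p10, p90 = np.percentile(counts.to_numpy(dtype=float), [10, 90])
    skew = float(p90 / p10) if p10 > 0 else float("nan")
    return coverage, skew
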