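"""FASTQ preprocessing: quality trimming, replicate removal, summaries.

Mirrors the QC stages of 454 shotgun pipelines: a dynamic-trim step that
keeps, for each read, the longest contiguous window containing at most
``max_below`` bases with Phred quality below ``phred_floor`` (reads whose
window is shorter than ``min_len`` are discarded), followed by removal of
artificial replicates (reads sharing an identical prefix, of which only
the longest is kept).  Host-genome screening is deliberately a
pass-through hook: it requires an external reference index and is out of
scope here.

Reads are Biopython ``SeqRecord`` objects with ``phred_quality`` letter
annotations (standard Phred+33 FASTQ as parsed by ``Bio.SeqIO``).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    """Quality-control parameters.

    phred_floor: minimum acceptable Phred score (default 15, ~3% error).
    max_below: maximum number of bases below the floor tolerated inside
        the retained window (default 5).
    min_len: minimum retained-window length in bp (default 50).
    dup_prefix_len: prefix length in bp used to detect artificial
        replicates (default 50).
    """

    phred_floor: int = 15
    max_below: int = 5
    min_len: int = 50
    dup_prefix_len: int = 50

    def __post_init__(self) -> None:
        if self.phred_floor < 0 or self.max_below < 0 or self.dup_prefix_len < 0:
            raise ValueError("QC parameters must be non-negative")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class QCSummary:
    """Per-sample read-set summary (lengths and GC as mean +/- sd)."""

    bp_count: int = 0
    seq_count: int = 0
    len_mean: float = 0.0
    len_sd: float = 0.0
    gc_mean: float = 0.0
    gc_sd: float = 0.0
    removed_quality: int = 0
    removed_duplicates: int = 0


def _longest_window(bad: list[bool], max_below: int) -> tuple[int, int]:
    """Leftmost longest [start, end) window with at most max_below True."""
    best_start, best_end = 0, 0
    start = 0
    n_bad = 0
    for end in range(len(bad)):
        if bad[end]:
            n_bad += 1
        while n_bad > max_below:
            if bad[start]:
                n_bad -= 1
            start += 1
        if end + 1 - start > best_end - best_start:
            best_start, best_end = start, end + 1
    return best_start, best_end


def qc_filter_reads(reads, params: QCParams | None = None):
    """Dynamic-trim each read and drop reads trimmed below ``min_len``.

    Returns ``(kept, removed_count)``; kept reads are trimmed
    ``SeqRecord`` slices in input order.  Raises ``ValueError`` if a
    read's quality string length does not match its sequence length.
    """
    params = params or QCParams()
    kept = []
    removed = 0
    for read in reads:
        quals = read.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(read.seq):
            raise ValueError(f"read {read.id}: quality length != sequence length")
        bad = [q < params.phred_floor for q in quals]
        start, end = _longest_window(bad, params.max_below)
        if end - start < params.min_len:
            removed += 1
        elif end - start == len(read.seq):
            kept.append(read)
        else:
            kept.append(read[start:end])
    return kept, removed


def dereplicate_reads(reads, params: QCParams | None = None):
    """Remove artificial replicates sharing an identical prefix.

    Among reads whose first ``dup_prefix_len`` bases are identical
    (reads shorter than the prefix length compared on their full
    length), only the longest is kept; on length ties the
    first-encountered read wins.  Returns ``(kept, removed_count)`` with
    kept reads in input order.
    """
    params = params or QCParams()
    reads = list(reads)
    best: dict[str, int] = {}  # prefix -> index of current keeper
    for i, read in enumerate(reads):
        key = str(read.seq)[: params.dup_prefix_len]
        j = best.get(key)
        if j is None or len(read.seq) > len(reads[j].seq):
            best[key] = i
    keep_idx = sorted(best.values())
    kept = [reads[i] for i in keep_idx]
    return kept, len(reads) - len(kept)


def screen_host_reads(reads, reference=None):
    """Host-genome screening hook.

    Screening against a host (e.g. human) genome needs an external
    aligner and reference index; when *reference* is ``None`` the step is
    skipped and logged, and reads pass through unchanged.
    """
    if reference is None:
        logger.info("host-genome screening skipped: no reference provided")
        return list(reads)
    raise NotImplementedError("host screening against a reference is not implemented")


def _gc_percent(seq: str) -> float | None:
    """GC% over unambiguous bases; None if the read has none."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def summarize_reads(reads, removed_quality: int = 0, removed_duplicates: int = 0) -> QCSummary:
    """Length/GC summary of a read set.

    GC% per read excludes ambiguous bases from numerator and denominator;
    reads with no unambiguous bases are excluded from the GC statistics.
    Standard deviations are sample sd (n-1); a single read (or an empty
    set) reports sd = 0 by convention.
    """
    lengths = []
    gcs = []
    for read in reads:
        lengths.append(len(read.seq))
        gc = _gc_percent(str(read.seq))
        if gc is not None:
            gcs.append(gc)
    if not lengths:
        return QCSummary(removed_quality=removed_quality, removed_duplicates=removed_duplicates)

    def _sd(xs):
        return statistics.stdev(xs) if len(xs) > 1 else 0.0

    return QCSummary(
        bp_count=sum(lengths),
        seq_count=len(lengths),
        len_mean=statistics.fmean(lengths),
        len_sd=_sd(lengths),
        gc_mean=statistics.fmean(gcs) if gcs else 0.0,
        gc_sd=_sd(gcs),
        removed_quality=removed_quality,
        removed_duplicates=removed_duplicates,
    )


def run_qc(reads, params: QCParams | None = None):
    """Full QC stage: quality trim, dereplicate, summarize.

    Returns ``(kept_reads, QCSummary)`` where the summary describes the
    surviving reads and records both removal tallies.
    """
    params = params or QCParams()
    trimmed, n_quality = qc_filter_reads(reads, params)
    kept, n_dup = dereplicate_reads(trimmed, params)
    summary = summarize_reads(kept, removed_quality=n_quality, removed_duplicates=n_dup)
    return kept, summary
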