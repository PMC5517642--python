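"""Raw sRNA-Seq reads -> weighted perfect-match hits.

Adapter-trimmed reads are collapsed to unique sequences, spike-in reads
are pulled out by their 13 nt core tags, and the remainder is aligned to
the genome requiring perfect matches on either strand.  A read with n
perfect-match loci contributes count/n to each locus (reads exceeding
``max_hits`` loci are discarded outright, mirroring bowtie ``-v 0 -m 100``
semantics).  Spike-in cores are genome-excluded by construction, so
tag-assigned reads cannot also be genome-matching; if one ever is, it is
discarded and logged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._util import revcomp, to_dna
from .io import SequenceRecord, SpikeInSheet

logger = logging.getLogger(__name__)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina/NEBNext small-RNA 3' adapter


@dataclass
class CollapsedRead:
    """A distinct trimmed read sequence with its occurrence count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.seq:
            raise ValueError("empty read sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One perfect-match locus of a collapsed read."""

    read_seq: str
    chrom: str
    start: int  # 0-based
    strand: str
    n_hits: int
    weight: float  # count / n_hits


@dataclass
class TrimStats:
    total_reads: int = 0
    trimmed_reads: int = 0
    discarded_no_adapter: int = 0
    discarded_length: int = 0


@dataclass
class LibraryStats:
    """Read accounting for one library.

    ``genome_matching_read_total`` sums counts of reads with >= 1 retained
    genome hit (spike-in reads excluded); it is the RPM denominator.
    """

    total_reads: int = 0
    trimmed_reads: int = 0
    genome_matching_read_total: float = 0.0
    spikein_read_total: float = 0.0

    @property
    def alignable_fraction_spikein(self) -> float:
        denom = self.genome_matching_read_total + self.spikein_read_total
        return self.spikein_read_total / denom if denom > 0 else 0.0


def trim_adapter(
    read,
    adapter: str,
    min_overlap: int = 8,
    min_len: int = 18,
    max_len: int = 30,
) -> Optional[str]:
    """Return the insert upstream of the 3' adapter, or None to discard.

    The leftmost full adapter occurrence wins; failing that, the longest
    terminal adapter *prefix* of >= ``min_overlap`` nt (a read running off
    the end of the adapter).  No mismatches are tolerated.  Inserts outside
    [min_len, max_len] are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = to_dna(read.seq if isinstance(read, SequenceRecord) else read)
    adapter = to_dna(adapter)
    idx = seq.find(adapter)
    if idx < 0:
        for k in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                idx = len(seq) - k
                break
    if idx < 0:
        return None
    insert = seq[:idx]
    if not (min_len <= len(insert) <= max_len):
        return None
    return insert


def trim_library(
    reads: Iterable,
    adapter: str,
    min_overlap: int = 8,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[list[str], TrimStats]:
    """Trim a whole library; returns the kept inserts and discard counts."""
    stats = TrimStats()
    inserts: list[str] = []
    for read in reads:
        stats.total_reads += 1
        seq = read.seq if isinstance(read, SequenceRecord) else read
        insert = trim_adapter(seq, adapter, min_overlap, min_len, max_len)
        if insert is None:
            full = to_dna(seq)
            ad = to_dna(adapter)
            if ad in full or any(
                full.endswith(ad[:k])
                for k in range(min_overlap, len(ad))
            ):
                stats.discarded_length += 1
            else:
                stats.discarded_no_adapter += 1
            continue
        stats.trimmed_reads += 1
        inserts.append(insert)
    return inserts, stats


def collapse_reads(inserts: Iterable[str]) -> list[CollapsedRead]:
    """Condense inserts to unique sequences with counts (most abundant
    first, ties by sequence)."""
    counter = Counter(to_dna(s) for s in inserts)
    return [
        CollapsedRead(seq, count)
        for seq, count in sorted(counter.items(), key=lambda p: (-p[1], p[0]))
    ]


class ExactMatchIndex:
    """Both-strand perfect-match lookup of short queries in a reference set.

    Built lazily per query batch: for every query length the reference is
    scanned once and only L-mers present in the query set are recorded, so
    memory stays proportional to the number of matching loci.
    """

    def __init__(self, references: Sequence[SequenceRecord]):
        self.references = [(rec.id, to_dna(rec.seq)) for rec in references]

    def find_all(
        self, queries: Sequence[str]
    ) -> dict[str, list[tuple[str, int, str]]]:
        """Map each query to its perfect-match loci (chrom, start, strand)."""
        hits: dict[str, list[tuple[str, int, str]]] = {q: [] for q in queries}
        by_len: dict[int, dict[str, list[tuple[str, str]]]] = {}
        for q in queries:
            # wanted L-mer on the forward reference -> (query, strand)
            lookup = by_len.setdefault(len(q), {})
            lookup.setdefault(q, []).append((q, "+"))
            lookup.setdefault(revcomp(q), []).append((q, "-"))
        for chrom, seq in self.references:
            for length, lookup in by_len.items():
                if length > len(seq):
                    continue
                for pos in range(len(seq) - length + 1):
                    word = seq[pos : pos + length]
                    if word in lookup:
                        for query, strand in lookup[word]:
                            hits[query].append((chrom, pos, strand))
        for q in hits:
            hits[q].sort()
        return hits


def align_perfect(
    reads: Sequence[CollapsedRead],
    references: Sequence[SequenceRecord],
    max_hits: int = 100,
) -> tuple[list[AlignmentHit], float]:
    """All perfect-match loci on both strands for each collapsed read.

    Returns the retained hits (sorted by chrom, start, read sequence) and
    the summed count of reads with >= 1 retained hit.  Reads with more
    than ``max_hits`` loci are discarded entirely.
    """
    index = ExactMatchIndex(references)
    loci = index.find_all([r.seq for r in reads])
    hits: list[AlignmentHit] = []
    aligned_total = 0.0
    for read in reads:
        read_loci = loci[read.seq]
        n = len(read_loci)
        if n == 0:
            continue
        if n > max_hits:
            logger.debug(
                "read %s discarded: %d loci > max_hits=%d",
                read.seq, n, max_hits,
            )
            continue
        aligned_total += read.count
        weight = read.count / n
        for chrom, start, strand in read_loci:
            hits.append(
                AlignmentHit(read.seq, chrom, start, strand, n, weight)
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.read_seq, h.strand))
    return hits, aligned_total


def validate_sheet_cores(sheet: SpikeInSheet) -> list[str]:
    """DNA-canonical cores; error if any core is a substring of another."""
    cores = [to_dna(c) for c in sheet.cores]
    for i, a in enumerate(cores):
        for j, b in enumerate(cores):
            if i != j and a in b:
                raise ValueError(
                    f"ambiguous spike-in sheet: core {sheet.set_ids[i]!r} is "
                    f"a substring of {sheet.set_ids[j]!r}"
                )
    return cores


def count_spikein_tags(
    reads: Sequence[CollapsedRead], sheet: SpikeInSheet
) -> tuple[dict[str, float], float]:
    """Assign reads to spike-in sets by 13 nt core tag.

    A read belongs to set S iff S's core occurs as a substring (U/T
    canonicalized).  Reads containing two distinct cores are discarded with
    a warning; their summed count is returned alongside the per-set counts.
    """
    cores = validate_sheet_cores(sheet)
    counts = {sid: 0.0 for sid in sheet.set_ids}
    ambiguous = 0.0
    for read in reads:
        matched = [
            sid for sid, core in zip(sheet.set_ids, cores) if core in read.seq
        ]
        if len(matched) == 1:
            counts[matched[0]] += read.count
        elif len(matched) > 1:
            ambiguous += read.count
            logger.warning(
                "read %s matches %d spike-in cores; discarded",
                read.seq, len(matched),
            )
    return counts, ambiguous


def split_spikein_reads(
    reads: Sequence[CollapsedRead], sheet: SpikeInSheet
) -> tuple[list[CollapsedRead], list[CollapsedRead]]:
    """Partition collapsed reads into (tagged spike-in, untagged) subsets."""
    cores = validate_sheet_cores(sheet)
    tagged, rest = [], []
    for read in reads:
        (tagged if any(c in read.seq for c in cores) else rest).append(read)
    return tagged, rest


def library_stats(
    trim: TrimStats, genome_aligned_total: float, spikein_counts: dict[str, float]
) -> LibraryStats:
    return LibraryStats(
        total_reads=trim.total_reads,
        trimmed_reads=trim.trimmed_reads,
        genome_matching_read_total=genome_aligned_total,
        spikein_read_total=float(sum(spikein_counts.values())),
    )


@dataclass
class PipelineResult:
    collapsed: list[CollapsedRead]
    hits: list[AlignmentHit]
    spikein_counts: dict[str, float]
    stats: LibraryStats
    ambiguous_spikein: float = 0.0
    genome_matching_seqs: set = field(default_factory=set)


def run_read_pipeline(
    reads: Iterable,
    genome: Sequence[SequenceRecord],
    sheet: Optional[SpikeInSheet] = None,
    adapter: str = DEFAULT_ADAPTER,
    max_hits: int = 100,
    min_overlap: int = 8,
    min_len: int = 18,
    max_len: int = 30,
) -> PipelineResult:
    """FASTQ records -> trimmed, collapsed, tag-counted and aligned library."""
    inserts, trim = trim_library(reads, adapter, min_overlap, min_len, max_len)
    collapsed = collapse_reads(inserts)
    if sheet is not None:
        tagged, untagged = split_spikein_reads(collapsed, sheet)
        spikein_counts, ambiguous = count_spikein_tags(tagged, sheet)
    else:
        untagged, spikein_counts, ambiguous = collapsed, {}, 0.0
    hits, aligned_total = align_perfect(untagged, genome, max_hits)
    stats = library_stats(trim, aligned_total, spikein_counts)
    return PipelineResult(
        collapsed=collapsed,
        hits=hits,
        spikein_counts=spikein_counts,
        stats=stats,
        ambiguous_spikein=ambiguous,
        genome_matching_seqs={h.read_seq for h in hits},
    )
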