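"""Class/family assignment of weighted hits and profile tables.

Assignment rules: a 20-22 nt read belongs to a mature miRNA/tasiRNA if it
lies on the sense strand within the annotated interval padded by 2 nt on
each side; a 20-24 nt read overlapping a transposon on either strand by
>= 1 nt is a siRNA, binned 20-22 vs 23-24 and split evenly across the
transposons it overlaps.  Family values are sums over members (miR169a/b/c
-> miR169); each transposon is its own siRNA family.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import FeatureAnnotation, MATURE_CLASSES
from .pipeline import AlignmentHit, CollapsedRead, LibraryStats

MATURE_LEN_RANGE = (20, 22)
SIRNA_BINS = {"siRNA_20_22": (20, 22), "siRNA_23_24": (23, 24)}
MATURE_PAD = 2
PROFILE_LEN_RANGE = range(18, 31)


@dataclass
class FamilyRecord:
    """Per-family abundance: relative (RPM) and, once normalized, absolute."""

    family_id: str
    sclass: str  # miRNA | tasiRNA | siRNA_20_22 | siRNA_23_24
    rpm: float
    mpu: Optional[float] = None


def mirna_family(name: str) -> str:
    """Strip the trailing locus letters: miR169a -> miR169."""
    return re.sub(r"[a-z]+$", "", name)


def _mature_trees(
    annotations: Sequence[FeatureAnnotation],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for feat in annotations:
        if feat.feature_class in MATURE_CLASSES:
            trees[(feat.chrom, feat.strand)][
                feat.start - MATURE_PAD : feat.end + MATURE_PAD
            ] = feat
    return trees


def assign_mature(
    hits: Sequence[AlignmentHit],
    annotations: Sequence[FeatureAnnotation],
) -> dict[str, float]:
    """Weighted counts per mature miRNA/tasiRNA feature.

    A hit accrues to mature M iff the read is 20-22 nt, on M's strand, and
    its interval lies within [M.start-2, M.end+2).
    """
    trees = _mature_trees(annotations)
    counts: dict[str, float] = defaultdict(float)
    lo, hi = MATURE_LEN_RANGE
    for hit in hits:
        length = len(hit.read_seq)
        if not lo <= length <= hi:
            continue
        tree = trees.get((hit.chrom, hit.strand))
        if tree is None:
            continue
        end = hit.start + length
        for iv in tree.overlap(hit.start, end):
            if iv.begin <= hit.start and end <= iv.end:
                counts[iv.data.feature_id] += hit.weight
    return dict(counts)


def assign_sirna(
    hits: Sequence[AlignmentHit],
    transposons: Sequence[FeatureAnnotation],
) -> dict[tuple[str, str], float]:
    """Weighted counts per (transposon, length bin) for 20-24 nt reads
    overlapping either strand by >= 1 nt; multi-transposon overlaps split
    the weight evenly."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in transposons:
        if feat.feature_class == "transposon":
            trees[feat.chrom][feat.start : feat.end] = feat.feature_id
    counts: dict[tuple[str, str], float] = defaultdict(float)
    for hit in hits:
        length = len(hit.read_seq)
        sbin = next(
            (b for b, (lo, hi) in SIRNA_BINS.items() if lo <= length <= hi),
            None,
        )
        if sbin is None:
            continue
        tree = trees.get(hit.chrom)
        if tree is None:
            continue
        overlapping = tree.overlap(hit.start, hit.start + length)
        if not overlapping:
            continue
        share = hit.weight / len(overlapping)
        for iv in overlapping:
            counts[(iv.data, sbin)] += share
    return dict(counts)


def aggregate_families(
    per_feature: Mapping[str, float], family_of: Mapping[str, str]
) -> dict[str, float]:
    """Sum member values into family totals; every feature must map."""
    out: dict[str, float] = defaultdict(float)
    for feature_id, value in per_feature.items():
        if feature_id not in family_of:
            raise KeyError(f"feature {feature_id!r} has no family mapping")
        out[family_of[feature_id]] += value
    return dict(out)


def per_precursor_counts(
    mature_counts: Mapping[str, float],
    annotations: Sequence[FeatureAnnotation],
) -> dict[str, float]:
    """Sum each precursor's mature children; precursors with no assigned
    reads report 0."""
    parent_of = {
        f.feature_id: f.parent_id
        for f in annotations
        if f.feature_class in MATURE_CLASSES
    }
    precursors = {
        f.feature_id
        for f in annotations
        if f.feature_class.endswith("_precursor")
    }
    totals = {pid: 0.0 for pid in precursors}
    for feature_id, value in mature_counts.items():
        parent = parent_of.get(feature_id)
        if parent is None:
            raise KeyError(f"mature feature {feature_id!r} has no parent link")
        if parent not in totals:
            raise KeyError(
                f"mature feature {feature_id!r} links to unknown precursor "
                f"{parent!r}"
            )
        totals[parent] += value
    return totals


@dataclass
class LengthProfile:
    """Per-length RPM and per (length, position) base frequencies."""

    rpm: pd.Series  # index: length 18..30
    base_freqs: dict[int, np.ndarray]  # length -> (length, 4) over ACGT


def length_base_profile(
    reads: Sequence[CollapsedRead],
    genome_matching_seqs: set,
    stats: LibraryStats,
) -> LengthProfile:
    """18-30 nt length distribution (RPM over genome-matching reads) and
    positional base frequencies weighted by read count."""
    total = stats.genome_matching_read_total
    rpm = pd.Series(0.0, index=list(PROFILE_LEN_RANGE))
    base_index = {b: i for i, b in enumerate("ACGT")}
    counts: dict[int, np.ndarray] = {}
    for read in reads:
        if read.seq not in genome_matching_seqs:
            continue
        length = len(read.seq)
        if length not in rpm.index:
            continue
        if total > 0:
            rpm[length] += read.count / total * 1e6
        mat = counts.setdefault(length, np.zeros((length, 4)))
        for pos, base in enumerate(read.seq):
            mat[pos, base_index[base]] += read.count
    base_freqs = {}
    for length, mat in counts.items():
        sums = mat.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        base_freqs[length] = mat / sums
    return LengthProfile(rpm=rpm, base_freqs=base_freqs)


def quantify_families(
    hits: Sequence[AlignmentHit],
    annotations: Sequence[FeatureAnnotation],
    stats: LibraryStats,
) -> pd.DataFrame:
    """Full per-family table (family_id, sclass, weighted count, RPM)."""
    total = stats.genome_matching_read_total
    if total <= 0:
        raise ValueError("genome_matching_read_total must be > 0 for RPM")

    class_of = {f.feature_id: f.feature_class for f in annotations}
    family_of = {
        f.feature_id: (
            mirna_family(f.family_id)
            if f.feature_class == "mirna_mature" and f.family_id != "."
            else f.family_id if f.family_id != "." else f.feature_id
        )
        for f in annotations
    }

    mature_counts = assign_mature(hits, annotations)
    rows = []
    for sclass, fclass in (("miRNA", "mirna_mature"), ("tasiRNA", "tasirna_mature")):
        sub = {
            fid: v for fid, v in mature_counts.items()
            if class_of[fid] == fclass
        }
        for family, value in sorted(aggregate_families(sub, family_of).items()):
            rows.append(
                FamilyRecord(family, sclass, value / total * 1e6)
            )
    sirna_counts = assign_sirna(hits, annotations)
    by_bin: dict[str, dict[str, float]] = defaultdict(dict)
    for (tid, sbin), value in sirna_counts.items():
        by_bin[sbin][tid] = value
    for sbin in sorted(by_bin):
        for tid, value in sorted(by_bin[sbin].items()):
            rows.append(FamilyRecord(tid, sbin, value / total * 1e6))
    return pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "sclass": r.sclass,
                "rpm": r.rpm,
                "mpu": r.mpu,
            }
            for r in rows
        ]
    )


def double_assignment_report(
    hits: Sequence[AlignmentHit],
    annotations: Sequence[FeatureAnnotation],
) -> float:
    """Total weight counted as both mature sRNA and siRNA (overlapping
    annotations); reported, never resolved."""
    mature_assigned = assign_mature(hits, annotations)
    trees = _mature_trees(annotations)
    sirna = assign_sirna(hits, annotations)
    if not mature_assigned or not sirna:
        return 0.0
    double = 0.0
    for hit in hits:
        length = len(hit.read_seq)
        if not MATURE_LEN_RANGE[0] <= length <= MATURE_LEN_RANGE[1]:
            continue
        tree = trees.get((hit.chrom, hit.strand))
        if tree is None:
            continue
        end = hit.start + length
        in_mature = any(
            iv.begin <= hit.start and end <= iv.end
            for iv in tree.overlap(hit.start, end)
        )
        if not in_mature:
            continue
        t_trees = {
            f.feature_id
            for f in annotations
            if f.feature_class == "transposon"
            and f.chrom == hit.chrom
            and f.start < end
            and hit.start < f.end
        }
        if t_trees:
            double += hit.weight
    return double
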