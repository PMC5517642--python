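"""Readers and writers for the external formats the tool touches.

All genomic intervals are stored 0-based half-open internally; dialect
conversion (GFF3 is 1-based inclusive) happens only here, at the I/O
boundary.  Sequences are stored as given (RNA oligos come with U, genomes
with T); comparison code canonicalizes via :mod:`srnaspike._util`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from ._util import to_dna

VALID_BASES = set("ACGTUN")
MATURE_CLASSES = {"mirna_mature", "tasirna_mature"}
FEATURE_CLASSES = {
    "mirna_precursor",
    "mirna_mature",
    "tasirna_precursor",
    "tasirna_mature",
    "transposon",
    "mrna",
}


class FormatError(ValueError):
    """Malformed input file; message names the offending line/record."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FeatureAnnotation:
    """A genomic feature in 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    family_id: str = "."
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"feature {self.feature_id!r}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(
                f"feature {self.feature_id!r}: unknown feature_class "
                f"{self.feature_class!r}"
            )
        if self.feature_class in MATURE_CLASSES and not self.parent_id:
            raise FormatError(
                f"feature {self.feature_id!r}: mature features need a parent_id"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SpikeInSheet:
    """The spike-in mix: one 13 nt core per set with its input molarity.

    ``molecules_per_ug`` is the number of molecules of that set added per
    microgram of total RNA (summed over the set's 21-mer variants).
    """

    set_ids: list = field(default_factory=list)
    cores: list = field(default_factory=list)
    molecules_per_ug: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.set_ids)
        if len(self.cores) != n or len(self.molecules_per_ug) != n:
            raise FormatError("spike-in sheet columns have unequal lengths")
        if n == 0:
            raise FormatError("spike-in sheet is empty")
        seen = set()
        for sid, core, amount in zip(
            self.set_ids, self.cores, self.molecules_per_ug
        ):
            if len(core) != 13:
                raise FormatError(
                    f"spike-in {sid!r}: core length {len(core)} != 13"
                )
            canon = to_dna(core)
            if set(canon) - set("ACGT"):
                raise FormatError(f"spike-in {sid!r}: non-ACGU core {core!r}")
            if canon in seen:
                raise FormatError(f"spike-in {sid!r}: duplicate core {core!r}")
            seen.add(canon)
            if not amount > 0:
                raise FormatError(
                    f"spike-in {sid!r}: molecules_per_ug must be > 0, "
                    f"got {amount}"
                )

    def __len__(self) -> int:
        return len(self.set_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": self.set_ids,
                "core": self.cores,
                "molecules_per_ug": self.molecules_per_ug,
            }
        )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file strictly.

    Duplicate ids, empty sequences and headerless leading content raise
    :class:`FormatError` naming the line number.  Multi-line sequences are
    concatenated; U and T are both accepted and preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: Optional[str] = None
    cur_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        if not chunks:
            raise FormatError(
                f"{path}: line {cur_line}: record {cur_id!r} has no sequence"
            )
        records.append(SequenceRecord(cur_id, "".join(chunks)))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: line {lineno}: empty header")
                name = header.split()[0]
                if name in seen:
                    raise FormatError(
                        f"{path}: line {lineno}: duplicate id {name!r}"
                    )
                seen.add(name)
                cur_id, cur_line, chunks = name, lineno, []
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence before first header"
                    )
                chunks.append(line.upper())
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Lazily read 4-line FASTQ records; truncated records raise with index."""
    with _open_text(path) as fh:
        idx = 0
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            if not head:
                continue
            idx += 1
            if not head.startswith("@"):
                raise FormatError(
                    f"{path}: record {idx}: header does not start with '@'"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: record {idx}: truncated record")
            if not plus.startswith("+"):
                raise FormatError(
                    f"{path}: record {idx}: missing '+' separator line"
                )
            try:
                yield SequenceRecord(head[1:].split()[0], seq, qual)
            except FormatError as exc:
                raise FormatError(f"{path}: record {idx}: {exc}") from None


def write_fastq(path, records: Iterable[SequenceRecord]) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def _parse_gff3_attributes(field9: str) -> dict:
    out = {}
    for part in field9.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_annotations(path, dialect: str = "gff3") -> list[FeatureAnnotation]:
    """Read feature annotations from GFF3 (1-based inclusive) or BED
    (0-based half-open), normalizing coordinates to 0-based half-open."""
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    feats: list[FeatureAnnotation] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 9:
                        raise FormatError("expected 9 tab-separated columns")
                    chrom, _src, ftype, start, end, _score, strand = cols[:7]
                    attrs = _parse_gff3_attributes(cols[8])
                    fid = attrs.get("ID")
                    if fid is None:
                        raise FormatError("missing ID attribute")
                    feats.append(
                        FeatureAnnotation(
                            feature_id=fid,
                            chrom=chrom,
                            start=int(start) - 1,
                            end=int(end),
                            strand=strand,
                            feature_class=ftype,
                            family_id=attrs.get("family_id", "."),
                            parent_id=attrs.get("Parent"),
                        )
                    )
                else:
                    if len(cols) < 6:
                        raise FormatError("expected >= 6 BED columns")
                    chrom, start, end, fid, _score, strand = cols[:6]
                    fclass = cols[6] if len(cols) > 6 else "mrna"
                    family = cols[7] if len(cols) > 7 else "."
                    parent = cols[8] if len(cols) > 8 else "."
                    feats.append(
                        FeatureAnnotation(
                            feature_id=fid,
                            chrom=chrom,
                            start=int(start),
                            end=int(end),
                            strand=strand,
                            feature_class=fclass,
                            family_id=family,
                            parent_id=None if parent == "." else parent,
                        )
                    )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return feats


def write_annotations(
    path, features: Sequence[FeatureAnnotation], dialect: str = "gff3"
) -> None:
    with _open_text(path, "wt") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = f"ID={f.feature_id}"
                if f.parent_id:
                    attrs += f";Parent={f.parent_id}"
                if f.family_id and f.family_id != ".":
                    attrs += f";family_id={f.family_id}"
                fh.write(
                    f"{f.chrom}\tsrnaspike\t{f.feature_class}\t{f.start + 1}\t"
                    f"{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
        elif dialect == "bed":
            for f in features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t"
                    f"{f.strand}\t{f.feature_class}\t{f.family_id}\t"
                    f"{f.parent_id or '.'}\n"
                )
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_spikein_sheet(path) -> SpikeInSheet:
    """Read and validate a spike-in mix sheet (TSV: set_id, core,
    molecules_per_ug)."""
    df = pd.read_csv(path, sep="\t", dtype={"set_id": str, "core": str})
    required = {"set_id", "core", "molecules_per_ug"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return SpikeInSheet(
        set_ids=df["set_id"].tolist(),
        cores=df["core"].tolist(),
        molecules_per_ug=df["molecules_per_ug"].astype(float).tolist(),
    )


def write_spikein_sheet(path, sheet: SpikeInSheet) -> None:
    sheet.as_frame().to_csv(path, sep="\t", index=False)


def write_table(path, df: pd.DataFrame) -> None:
    """Write an output table as TSV with '.' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
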