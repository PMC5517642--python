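"""Small shared helpers: alphabet handling and reverse complement."""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def to_dna(seq: str) -> str:
    """Canonicalize a nucleotide string to DNA (U -> T), uppercased."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Canonicalize a nucleotide string to RNA (T -> U), uppercased."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA)."""
    return to_dna(seq).translate(_DNA_COMPLEMENT)[::-1]
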