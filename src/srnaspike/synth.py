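"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the moving parts the pipeline depends on: a random
genome with planted miRNA hairpins (mature + loop + mismatched star),
phased tasiRNA loci and transposons carrying fixed siRNA species; a
spike-in mix whose molecules are spread uniformly over each set's 65,536
21-mer variants, each variant with its own lognormal ligation bias (the
cloning-bias mechanism that set-level averaging is meant to defeat); and
ERCC-like mRNA tables.  Every output is reproducible from (parameters,
seed), and the truth table records molecules-per-ug for every simulated
feature so recovery can be measured end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, to_dna
from .design import (
    CoreSequence,
    SpikeInCandidateSet,
    formulate_mix,
    hamming,
)
from .io import FeatureAnnotation, SequenceRecord, SpikeInSheet
from .pipeline import DEFAULT_ADAPTER

DNA = "ACGT"

# default endogenous abundance ranges (log10 molecules per ug total RNA);
# chosen so that the endogenous pool dwarfs the spike-in mix and the mix
# ends up a few percent of the library, and so miRNA families span the
# same decades as the spike-in dilution series
MIRNA_LOG10_MPU = (3.5, 6.0)
TASIRNA_LOG10_MPU = (3.0, 5.0)
SIRNA_LOG10_MPU = (4.0, 6.0)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sample."""

    genome: list[SequenceRecord]
    annotations: list[FeatureAnnotation]
    #: feature_id, family_id, feature_class, strand, seq (read-space DNA),
    #: molecules_per_ug
    features: pd.DataFrame
    precursor_mpu: pd.DataFrame  # transcript_id, molecules_per_ug
    pairs: list = field(default_factory=list)  # (family_id, transcript_id)
    seed: int = 0


def random_spikein_sheet(
    seed: int = 0,
    n_sets: int = 8,
    dynamic_range_log10: float = 4.0,
    max_molecules_per_ug: float = 1e6,
    min_core_hamming: int = 4,
) -> SpikeInSheet:
    """A synthetic spike-in mix: random mutually distinct 13 nt cores with
    the standard log-equispaced dilution series."""
    rng = np.random.default_rng(seed)
    cores: list[str] = []
    while len(cores) < n_sets:
        cand = "".join(rng.choice(list("ACGU"), size=13))
        if all(hamming(cand, c) >= min_core_hamming for c in cores):
            cores.append(cand)
    sets = [SpikeInCandidateSet(CoreSequence(c)) for c in cores]
    return formulate_mix(
        sets, dynamic_range_log10, max_molecules_per_ug
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in DNA if b != out[pos]])
    return "".join(out)


def _occurs_once(genome: str, seq: str) -> bool:
    return genome.count(seq) + genome.count(revcomp(seq)) == 1


def make_genome(
    n_mirna: int = 20,
    n_tasirna: int = 5,
    n_transposon: int = 10,
    size_bp: int = 60_000,
    seed: int = 0,
    spikein_sheet: Optional[SpikeInSheet] = None,
    sirna_species_per_te: int = 20,
    max_attempts: int = 20,
) -> SyntheticTruth:
    """Random genome with planted sRNA loci and ground-truth abundances.

    Every planted mature sequence occurs exactly once in the genome
    (counting both strands; miRNA star arms carry 3 substitutions so they
    do not duplicate the mature), and no spike-in core from the provided
    sheet occurs anywhere.  Infeasible packing raises.
    """
    mir_len, loop_len = 21, 15
    hairpin_len = 2 * mir_len + loop_len
    tas_registers = 4
    tas_len = 10 + tas_registers * 21 + 10
    te_len = 600
    lengths = (
        [hairpin_len] * n_mirna + [tas_len] * n_tasirna + [te_len] * n_transposon
    )
    if sum(lengths) + len(lengths) > size_bp:
        raise ValueError(
            f"features need {sum(lengths)} bp but genome is {size_bp} bp"
        )
    forbidden = (
        [to_dna(c) for c in spikein_sheet.cores] if spikein_sheet else []
    )
    forbidden += [revcomp(c) for c in forbidden]

    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 7919 * attempt)
        truth = _try_make_genome(
            rng, n_mirna, n_tasirna, n_transposon, size_bp,
            mir_len, loop_len, tas_registers, te_len,
            sirna_species_per_te, lengths, forbidden,
        )
        if truth is not None:
            truth.seed = seed
            return truth
    raise RuntimeError(
        f"could not build a clean synthetic genome in {max_attempts} attempts"
    )


def _try_make_genome(
    rng, n_mirna, n_tasirna, n_transposon, size_bp,
    mir_len, loop_len, tas_registers, te_len,
    sirna_species_per_te, lengths, forbidden,
) -> Optional[SyntheticTruth]:
    n_feat = len(lengths)
    leftover = size_bp - sum(lengths)
    gaps = rng.multinomial(leftover, np.full(n_feat + 1, 1 / (n_feat + 1)))
    starts = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += gaps[i]
        starts.append(pos)
        pos += length

    genome = list(_random_seq(rng, size_bp))
    annotations: list[FeatureAnnotation] = []
    feat_rows = []
    planted: list[str] = []  # sequences that must be genome-unique

    def put(start: int, seq: str) -> None:
        genome[start : start + len(seq)] = list(seq)

    idx = 0
    for i in range(n_mirna):
        start = starts[idx]; idx += 1
        mature = _random_seq(rng, mir_len)
        star = _mutate(rng, revcomp(mature), 3)
        put(start, mature + _random_seq(rng, loop_len) + star)
        pid, fid = f"MIR{101 + i}", f"miR{101 + i}a"
        annotations.append(FeatureAnnotation(
            pid, "chr1", start, start + 2 * mir_len + loop_len, "+",
            "mirna_precursor", family_id=f"miR{101 + i}",
        ))
        annotations.append(FeatureAnnotation(
            fid, "chr1", start, start + mir_len, "+",
            "mirna_mature", family_id=fid, parent_id=pid,
        ))
        mpu = 10 ** rng.uniform(*MIRNA_LOG10_MPU)
        feat_rows.append((fid, f"miR{101 + i}", "mirna_mature", "+", mature, mpu))
        planted.append(mature)

    for i in range(n_tasirna):
        start = starts[idx]; idx += 1
        length = 10 + tas_registers * 21 + 10
        pid = f"TAS{i + 1}"
        annotations.append(FeatureAnnotation(
            pid, "chr1", start, start + length, "+",
            "tasirna_precursor", family_id=pid,
        ))
        for j in range(tas_registers):
            reg_start = start + 10 + j * 21
            mature = genome[reg_start : reg_start + 21]
            mature = "".join(mature)
            fid = f"{pid}_siR{j + 1}"
            annotations.append(FeatureAnnotation(
                fid, "chr1", reg_start, reg_start + 21, "+",
                "tasirna_mature", family_id=pid, parent_id=pid,
            ))
            mpu = 10 ** rng.uniform(*TASIRNA_LOG10_MPU)
            feat_rows.append((fid, pid, "tasirna_mature", "+", mature, mpu))
            planted.append(mature)

    for i in range(n_transposon):
        start = starts[idx]; idx += 1
        tid = f"TE{i + 1}"
        annotations.append(FeatureAnnotation(
            tid, "chr1", start, start + te_len, "+",
            "transposon", family_id=tid,
        ))
        offsets = rng.choice(te_len - 30, size=sirna_species_per_te, replace=False)
        for j, off in enumerate(sorted(offsets)):
            length = int(rng.choice([20, 21, 22, 23, 24, 24, 24, 24, 23, 23]))
            strand = "+" if rng.random() < 0.5 else "-"
            sub = "".join(genome[start + off : start + off + length])
            seq = sub if strand == "+" else revcomp(sub)
            mpu = 10 ** rng.uniform(*SIRNA_LOG10_MPU)
            feat_rows.append(
                (f"{tid}_s{j + 1}", tid, "sirna_species", strand, seq, mpu)
            )
            planted.append(seq)

    genome_str = "".join(genome)
    for core in forbidden:
        if core in genome_str:
            return None
    for seq in planted:
        if not _occurs_once(genome_str, seq):
            return None

    features = pd.DataFrame(
        feat_rows,
        columns=[
            "feature_id", "family_id", "feature_class", "strand", "seq",
            "molecules_per_ug",
        ],
    )
    # precursor abundances: mature-family MPU over a ~2x stoichiometry
    fam_mpu = (
        features[features.feature_class.isin(["mirna_mature", "tasirna_mature"])]
        .groupby("family_id")["molecules_per_ug"].sum()
    )
    family_parent = {
        f.family_id: f.feature_id
        for f in annotations
        if f.feature_class.endswith("_precursor")
    }
    prec_rows, pairs = [], []
    for fam, mpu in fam_mpu.items():
        ratio = 10 ** rng.normal(np.log10(2.0), 0.3)
        tid = family_parent[fam]
        prec_rows.append((tid, mpu / ratio))
        pairs.append((fam, tid))
    precursor_mpu = pd.DataFrame(
        prec_rows, columns=["transcript_id", "molecules_per_ug"]
    )
    return SyntheticTruth(
        genome=[SequenceRecord("chr1", genome_str)],
        annotations=annotations,
        features=features,
        precursor_mpu=precursor_mpu,
        pairs=pairs,
    )


_MEMBER_CACHE: dict[tuple, list[str]] = {}


def spikein_members_dna(sheet: SpikeInSheet) -> list[list[str]]:
    """All 21-mer members per set, DNA alphabet (cached per core tuple)."""
    out = []
    for core in sheet.cores:
        key = (to_dna(core),)
        if key not in _MEMBER_CACHE:
            cand = SpikeInCandidateSet(CoreSequence(core))
            _MEMBER_CACHE[key] = [to_dna(m) for m in cand.members()]
        out.append(_MEMBER_CACHE[key])
    return out


def simulate_library(
    truth: Optional[SyntheticTruth],
    sheet: Optional[SpikeInSheet],
    depth: int = 200_000,
    bias_sd_log2: float = 1.0,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    endogenous_bias_sd_log2: float = 0.0,
    read_len: int = 50,
) -> list[SequenceRecord]:
    """Draw a library of exactly ``depth`` reads.

    Read probabilities are proportional to molecules x ligation bias.
    Spike-in molecules are spread uniformly over each set's 65,536
    members, each member with an independent lognormal bias of the given
    sd (log2 units); endogenous features get their own (default absent)
    bias.  Reads are insert + 3' adapter, truncated to ``read_len``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    mpu: list[float] = []
    n_endo = 0
    if truth is not None:
        seqs.extend(truth.features["seq"])
        mpu.extend(truth.features["molecules_per_ug"])
        n_endo = len(seqs)
    if sheet is not None:
        for amount, members in zip(
            sheet.molecules_per_ug, spikein_members_dna(sheet)
        ):
            seqs.extend(members)
            mpu.extend([amount / len(members)] * len(members))
    if not seqs:
        raise ValueError("nothing to simulate: no truth and no sheet")
    weights = np.asarray(mpu, dtype=float)
    bias = np.ones(len(seqs))

    def unit_mean_lognormal(sd_log2: float, n: int) -> np.ndarray:
        # efficiency relative to the library average: E[factor] = 1
        sigma = sd_log2 * np.log(2)
        return np.exp(rng.normal(0, sigma, n) - sigma**2 / 2)

    if n_endo and endogenous_bias_sd_log2 > 0:
        bias[:n_endo] = unit_mean_lognormal(endogenous_bias_sd_log2, n_endo)
    n_spike = len(seqs) - n_endo
    if n_spike and bias_sd_log2 > 0:
        bias[n_endo:] = unit_mean_lognormal(bias_sd_log2, n_spike)
    p = weights * bias
    p /= p.sum()
    counts = rng.multinomial(depth, p)
    reads: list[SequenceRecord] = []
    i = 0
    for seq, n in zip(seqs, counts):
        if n == 0:
            continue
        full = (seq + adapter)[:read_len]
        for _ in range(int(n)):
            reads.append(SequenceRecord(f"r{i}", full, "I" * len(full)))
            i += 1
    return reads


def make_mrna_tables(
    truth: SyntheticTruth,
    ercc_n: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    tpm_per_mpu: float = 1e-3,
    ercc_log10_range: tuple[float, float] = (2.0, 6.5),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ERCC-like calibration sheet plus a TPM table tied to the truth.

    ERCC known MPUs are log-spaced over >= 4 decades with
    TPM = tpm_per_mpu * MPU * 10^eps, eps ~ N(0, noise_sd); precursor
    transcripts get TPMs from their true MPUs the same way, plus a few
    sub-1-TPM decoys to exercise the detection filter.
    """
    if ercc_n < 2:
        raise ValueError("need >= 2 ERCC spike-ins")
    rng = np.random.default_rng(seed)
    ercc_mpu = np.logspace(*ercc_log10_range, ercc_n)
    ercc_ids = [f"ERCC-{i + 1:04d}" for i in range(ercc_n)]
    ercc_sheet = pd.DataFrame(
        {"ercc_id": ercc_ids, "molecules_per_ug": ercc_mpu}
    )
    rows = []
    for eid, m in zip(ercc_ids, ercc_mpu):
        rows.append((eid, tpm_per_mpu * m * 10 ** rng.normal(0, noise_sd)))
    for tid, m in zip(
        truth.precursor_mpu["transcript_id"],
        truth.precursor_mpu["molecules_per_ug"],
    ):
        rows.append((tid, tpm_per_mpu * m * 10 ** rng.normal(0, noise_sd)))
    for i in range(5):
        rows.append((f"DECOY{i + 1}", float(rng.uniform(0.05, 0.95))))
    tpm_table = pd.DataFrame(rows, columns=["transcript_id", "tpm"])
    return tpm_table, ercc_sheet


def expected_reads(
    truth: Optional[SyntheticTruth], sheet: Optional[SpikeInSheet], depth: int
) -> pd.Series:
    """Expected read count per endogenous family and spike-in set,
    ignoring bias (whose mean is shared across categories)."""
    parts = {}
    total = 0.0
    if truth is not None:
        fam = truth.features.groupby("family_id")["molecules_per_ug"].sum()
        parts.update(fam.to_dict())
        total += fam.sum()
    if sheet is not None:
        for sid, amount in zip(sheet.set_ids, sheet.molecules_per_ug):
            parts[sid] = amount
            total += amount
    return pd.Series(parts) / total * depth
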