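"""Spike-in oligo design.

The design recipe: build a position base-frequency matrix from the most
abundant endogenous miRNAs (positions 5-17 from the 5' end), sample 13 nt
core candidates from it, discard any core with a perfect match to the
genome on either strand, expand each survivor with every 4 nt flank on
both ends (4^8 = 65,536 21-mers per set), score secondary-structure MFE
distributions, and keep the sets whose MFE distribution best matches that
of endogenous miRNAs.  Mix amounts are a log10-equispaced dilution series
spanning the endogenous miRNA dynamic range.
"""

from __future__ import annotations

import itertools
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import revcomp, to_dna, to_rna
from .io import SequenceRecord, SpikeInSheet

RNA_ALPHABET = "ACGU"
#: core positions correspond to miRNA positions 5..17 from the 5' end
PWM_START, PWM_END = 5, 17
CORE_LEN = PWM_END - PWM_START + 1

#: simplified base-pair pseudo-energies (kcal/mol) for the internal backend
PAIR_ENERGY = {
    ("G", "C"): -1.0,
    ("C", "G"): -1.0,
    ("A", "U"): -0.8,
    ("U", "A"): -0.8,
    ("G", "U"): -0.5,
    ("U", "G"): -0.5,
}
MIN_HAIRPIN_LOOP = 3


class MFEBackendUnavailableError(RuntimeError):
    """Raised when the external RNAfold backend cannot be found."""


@dataclass
class BaseFrequencyMatrix:
    """Per-position base frequencies over {A,C,G,U} for the 13 core positions."""

    freqs: np.ndarray  # shape (13, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (CORE_LEN, 4):
            raise ValueError(
                f"frequency matrix must be {CORE_LEN}x4, got {self.freqs.shape}"
            )
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each column must sum to 1 within 1e-9")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs,
            columns=list(RNA_ALPHABET),
            index=[f"pos{PWM_START + i}" for i in range(CORE_LEN)],
        )


@dataclass
class CoreSequence:
    """A candidate 13 nt spike-in core (RNA alphabet)."""

    seq: str
    genome_clean: bool = False

    def __post_init__(self) -> None:
        self.seq = to_rna(self.seq)
        if len(self.seq) != CORE_LEN:
            raise ValueError(f"core must be {CORE_LEN} nt, got {len(self.seq)}")
        if set(self.seq) - set(RNA_ALPHABET):
            raise ValueError(f"core has non-ACGU characters: {self.seq}")


@dataclass
class SpikeInCandidateSet:
    """A core plus its flank expansion and (optionally) sampled MFE scores."""

    core: CoreSequence
    flank_len: int = 4
    mfe_values: Optional[np.ndarray] = None

    @property
    def member_count(self) -> int:
        return 4 ** (2 * self.flank_len)

    @property
    def member_length(self) -> int:
        return 2 * self.flank_len + CORE_LEN

    def members(self) -> Iterator[str]:
        """Enumerate all (5' flank, core, 3' flank) combinations."""
        flanks = [
            "".join(t)
            for t in itertools.product(RNA_ALPHABET, repeat=self.flank_len)
        ]
        for f5 in flanks:
            for f3 in flanks:
                yield f5 + self.core.seq + f3

    def sample_members(self, n: int, seed: int) -> list[str]:
        """Draw n members uniformly at random (with a fixed seed)."""
        rng = np.random.default_rng(seed)
        total = self.member_count
        n = min(n, total)
        idx = rng.choice(total, size=n, replace=False)
        n_flanks = 4**self.flank_len
        out = []
        for i in idx:
            f5, f3 = divmod(int(i), n_flanks)
            out.append(
                self._flank(f5) + self.core.seq + self._flank(f3)
            )
        return out

    def _flank(self, index: int) -> str:
        bases = []
        for _ in range(self.flank_len):
            index, r = divmod(index, 4)
            bases.append(RNA_ALPHABET[r])
        return "".join(reversed(bases))


@dataclass
class MFEDistribution:
    """A bag of minimum-free-energy scores with its provenance."""

    values: np.ndarray
    source: str = "endogenous_mirna"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("MFE distribution must be non-empty")


@dataclass
class DesignConfig:
    """Tunable parameters of the design run (defaults are the standard recipe)."""

    n_candidates: int = 1000
    flank_len: int = 4
    n_select: int = 8
    top_fraction: float = 0.5
    seed: int = 0
    mfe_backend: str = "internal"  # or "rnafold"
    mfe_sample_per_set: int = 2000
    min_core_hamming: int = 4
    temperature_c: float = 4.0


def build_frequency_matrix(
    mirnas: Sequence[tuple[str, float]], top_fraction: float = 0.5
) -> BaseFrequencyMatrix:
    """Tally base frequencies at miRNA positions 5-17 among the most
    abundant miRNAs.

    Parameters
    ----------
    mirnas
        ``(mature sequence, abundance)`` pairs; abundance in RPM (or any
        non-negative relative unit used only for ranking).
    top_fraction
        Fraction of the most abundant miRNAs to retain (default 0.5, i.e.
        the top 50%).  The tally over retained sequences is unweighted.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    usable = [
        (to_rna(seq), float(ab))
        for seq, ab in mirnas
        if len(seq) >= PWM_END
    ]
    if not usable:
        raise ValueError(f"no miRNA of length >= {PWM_END} provided")
    if any(ab < 0 for _, ab in usable):
        raise ValueError("abundances must be >= 0")
    usable.sort(key=lambda p: (-p[1], p[0]))
    n_keep = max(1, int(np.ceil(top_fraction * len(usable))))
    kept = [seq for seq, _ in usable[:n_keep]]
    counts = np.zeros((CORE_LEN, 4))
    base_index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for seq in kept:
        for j in range(CORE_LEN):
            counts[j, base_index[seq[PWM_START - 1 + j]]] += 1
    return BaseFrequencyMatrix(counts / counts.sum(axis=1, keepdims=True))


def sample_cores(
    matrix: BaseFrequencyMatrix,
    n: int,
    seed: int = 0,
    max_rounds: int = 50,
) -> list[CoreSequence]:
    """Draw n distinct 13 nt cores, each position independently from the
    matching matrix column."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[CoreSequence] = []
    for _ in range(max_rounds):
        need = n - len(out)
        if need == 0:
            break
        draws = np.empty((need, CORE_LEN), dtype="<U1")
        for j in range(CORE_LEN):
            draws[:, j] = rng.choice(
                list(RNA_ALPHABET), size=need, p=matrix.freqs[j]
            )
        for row in draws:
            seq = "".join(row)
            if seq not in seen:
                seen.add(seq)
                out.append(CoreSequence(seq))
    if len(out) < n:
        raise RuntimeError(
            f"could not sample {n} distinct cores after {max_rounds} rounds; "
            "matrix may be too degenerate"
        )
    return out[:n]


def filter_genome_matching(
    cores: Sequence[CoreSequence], genome: Sequence[SequenceRecord]
) -> list[CoreSequence]:
    """Retain cores with zero perfect matches to the genome on either strand."""
    chroms = [to_dna(rec.seq) for rec in genome]
    survivors = []
    for core in cores:
        dna = to_dna(core.seq)
        rc = revcomp(dna)
        hit = any(dna in chrom or rc in chrom for chrom in chroms)
        if not hit:
            survivors.append(CoreSequence(core.seq, genome_clean=True))
    return survivors


def expand_set(core: CoreSequence, flank_len: int = 4) -> SpikeInCandidateSet:
    """Expand a core with every flank pair over the 4-letter alphabet."""
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    return SpikeInCandidateSet(core=core, flank_len=flank_len)


def _encode_rna(seqs: Sequence[str]) -> np.ndarray:
    index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    return np.array(
        [[index[c] for c in to_rna(s)] for s in seqs], dtype=np.int8
    )


def _nussinov_batch(seqs: Sequence[str]) -> np.ndarray:
    """Vectorized Nussinov-style minimum pseudo-energy for equal-length
    sequences.

    Maximizes summed pair bonuses (GC 1.0, AU 0.8, GU 0.5) with a minimum
    hairpin loop of 3 unpaired bases; the returned energy is the negated
    optimum (0.0 when no pair is possible).
    """
    n = len(seqs[0])
    enc = _encode_rna(seqs)
    bonus = np.zeros((4, 4))
    for (a, b), e in PAIR_ENERGY.items():
        bonus[RNA_ALPHABET.index(a), RNA_ALPHABET.index(b)] = -e
    B = len(seqs)
    score = np.zeros((B, n, n))
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = score[:, i, j - 1].copy()  # j unpaired
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                pair = bonus[enc[:, k], enc[:, j]]
                left = score[:, i, k - 1] if k > i else 0.0
                inner = score[:, k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                cand = left + inner + pair
                # a zero bonus means k-j cannot pair; cand then never beats
                # the unpaired branch because left+inner <= best already
                np.maximum(best, np.where(pair > 0, cand, -np.inf), out=best)
            score[:, i, j] = best
    return -score[:, 0, n - 1]


def _rnafold_mfe(seqs: Sequence[str], temperature: float) -> np.ndarray:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise MFEBackendUnavailableError(
            "RNAfold executable not found on PATH; install ViennaRNA or use "
            "mfe_backend='internal'"
        )
    proc = subprocess.run(
        [exe, "--noPS", "-T", str(temperature)],
        input="\n".join(to_rna(s) for s in seqs) + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    energies = []
    pat = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")
    for line in proc.stdout.splitlines():
        m = pat.search(line)
        if m and set(line.split()[0]) <= set(".()"):
            energies.append(float(m.group(1)))
    if len(energies) != len(seqs):
        raise RuntimeError(
            f"RNAfold returned {len(energies)} energies for {len(seqs)} "
            "sequences"
        )
    return np.array(energies)


def compute_mfe(
    seqs: Sequence[str],
    backend: str = "internal",
    temperature: float = 4.0,
) -> np.ndarray:
    """Minimum free energy per sequence (kcal/mol, <= 0).

    ``backend='rnafold'`` shells out to RNAfold at the given temperature
    (default 4 degC, no structure plots); ``'internal'`` uses the simplified
    Nussinov maximum-pairing model, which preserves the *ranking* of
    structured vs unstructured sequences but not RNAfold's energy scale.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences given")
    for s in seqs:
        if not s or set(to_rna(s)) - set(RNA_ALPHABET):
            raise ValueError(f"not an RNA sequence: {s!r}")
    if backend == "rnafold":
        return _rnafold_mfe(seqs, temperature)
    if backend != "internal":
        raise ValueError(f"unknown MFE backend {backend!r}")
    out = np.empty(len(seqs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idx in by_len.items():
        if length <= MIN_HAIRPIN_LOOP + 1:
            out[idx] = 0.0
        else:
            out[idx] = _nussinov_batch([seqs[i] for i in idx])
    return out


def score_candidate_mfe(
    candidate: SpikeInCandidateSet,
    mfe_sample_per_set: int = 2000,
    seed: int = 0,
    backend: str = "internal",
    temperature: float = 4.0,
) -> SpikeInCandidateSet:
    """Attach MFE scores for a seeded random subsample of the set's members."""
    members = candidate.sample_members(mfe_sample_per_set, seed)
    candidate.mfe_values = compute_mfe(members, backend, temperature)
    return candidate


def ks_distance(sample: np.ndarray, reference: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov D statistic."""
    return float(sps.ks_2samp(sample, reference).statistic)


def rank_candidates(
    candidates: Sequence[SpikeInCandidateSet], reference: MFEDistribution
) -> pd.DataFrame:
    """Per-candidate KS D versus the reference MFE distribution, ascending."""
    rows = []
    for cand in candidates:
        if cand.mfe_values is None or len(cand.mfe_values) == 0:
            raise ValueError(
                f"candidate {cand.core.seq} has no MFE scores; run "
                "score_candidate_mfe first"
            )
        rows.append(
            {
                "core": cand.core.seq,
                "ks_d": ks_distance(cand.mfe_values, reference.values),
                "n_scored": len(cand.mfe_values),
            }
        )
    df = pd.DataFrame(rows).sort_values(["ks_d", "core"], kind="mergesort")
    return df.reset_index(drop=True)


def select_sets(
    candidates: Sequence[SpikeInCandidateSet],
    reference: MFEDistribution,
    k: int = 8,
) -> tuple[list[SpikeInCandidateSet], pd.DataFrame]:
    """Keep the k candidates whose MFE distribution is closest (smallest
    KS D) to the reference; ties break by core lexicographic order."""
    if k > len(candidates):
        raise ValueError(
            f"cannot select {k} sets from {len(candidates)} candidates"
        )
    report = rank_candidates(candidates, reference)
    by_core = {c.core.seq: c for c in candidates}
    chosen = [by_core[core] for core in report["core"].head(k)]
    return chosen, report


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def formulate_mix(
    sets: Sequence[SpikeInCandidateSet],
    dynamic_range_log10: float = 4.0,
    max_molecules_per_ug: float = 1e6,
    set_id_prefix: str = "spike",
) -> SpikeInSheet:
    """Assign log10-equispaced input amounts spanning the given dynamic
    range, descending with set order."""
    if not sets:
        raise ValueError("need at least one set")
    if dynamic_range_log10 <= 0:
        raise ValueError("dynamic_range_log10 must be > 0")
    if max_molecules_per_ug <= 0:
        raise ValueError("max_molecules_per_ug must be > 0")
    k = len(sets)
    if k == 1:
        amounts = np.array([max_molecules_per_ug])
    else:
        exponents = np.linspace(0.0, -dynamic_range_log10, k)
        amounts = max_molecules_per_ug * 10.0**exponents
    return SpikeInSheet(
        set_ids=[f"{set_id_prefix}{i + 1}" for i in range(k)],
        cores=[s.core.seq for s in sets],
        molecules_per_ug=list(amounts),
        metadata={
            "chemistry": "5'-monophosphate; 2'-O-methyl 3' terminal ribose"
        },
    )


def design_spikein_sets(
    mirnas: Sequence[tuple[str, float]],
    genome: Sequence[SequenceRecord],
    config: DesignConfig = DesignConfig(),
    reference_mfe: Optional[MFEDistribution] = None,
) -> tuple[SpikeInSheet, pd.DataFrame, list[SpikeInCandidateSet]]:
    """Run the full design recipe and return (mix sheet, ranking report,
    selected sets).

    The reference MFE distribution defaults to the provided mature miRNAs
    folded with the configured backend.  Selected cores are additionally
    required to be pairwise Hamming >= ``config.min_core_hamming`` so the
    13 nt tags stay unambiguous.
    """
    matrix = build_frequency_matrix(mirnas, config.top_fraction)
    cores = sample_cores(matrix, config.n_candidates, config.seed)
    clean = filter_genome_matching(cores, genome)
    if len(clean) < config.n_select:
        raise RuntimeError(
            f"only {len(clean)} genome-clean cores; need {config.n_select}"
        )
    if reference_mfe is None:
        reference_mfe = MFEDistribution(
            compute_mfe(
                [to_rna(s) for s, _ in mirnas],
                config.mfe_backend,
                config.temperature_c,
            ),
            source="endogenous_mirna",
        )
    candidates = [
        score_candidate_mfe(
            expand_set(c, config.flank_len),
            config.mfe_sample_per_set,
            config.seed + i,
            config.mfe_backend,
            config.temperature_c,
        )
        for i, c in enumerate(clean)
    ]
    report = rank_candidates(candidates, reference_mfe)
    by_core = {c.core.seq: c for c in candidates}
    chosen: list[SpikeInCandidateSet] = []
    for core in report["core"]:
        if all(
            hamming(core, c.core.seq) >= config.min_core_hamming
            for c in chosen
        ):
            chosen.append(by_core[core])
        if len(chosen) == config.n_select:
            break
    if len(chosen) < config.n_select:
        raise RuntimeError(
            "could not find enough mutually distinct cores "
            f"(Hamming >= {config.min_core_hamming})"
        )
    sheet = formulate_mix(chosen)
    return sheet, report, chosen
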