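import itertools

import numpy as np
import pytest

from srnaspike._util import revcomp, to_dna
from srnaspike.design import (
    PAIR_ENERGY,
    BaseFrequencyMatrix,
    CoreSequence,
    DesignConfig,
    MFEDistribution,
    SpikeInCandidateSet,
    build_frequency_matrix,
    compute_mfe,
    design_spikein_sets,
    expand_set,
    filter_genome_matching,
    formulate_mix,
    hamming,
    sample_cores,
    select_sets,
)
from srnaspike.io import SequenceRecord


def uniform_matrix():
    return BaseFrequencyMatrix(np.full((13, 4), 0.25))


class TestFrequencyMatrix:
    def test_single_homopolymer_mirna(self):
        m = build_frequency_matrix([("A" * 21, 10.0)])
        assert m.freqs.shape == (13, 4)
        assert np.allclose(m.freqs[:, 0], 1.0)

    def test_width_is_positions_5_to_17(self):
        # sequence marking position 5 with C and position 17 with G
        seq = "AAAA" + "C" + "U" * 11 + "G" + "AAAA"
        m = build_frequency_matrix([(seq, 1.0)], top_fraction=1.0)
        assert m.freqs[0, 1] == 1.0  # column 1 == miRNA position 5 == C
        assert m.freqs[12, 2] == 1.0  # column 13 == position 17 == G

    def test_equal_abundance_split_column(self):
        a = "AAAA" + "A" * 13 + "AAAA"
        c = "AAAA" + "C" + "A" * 12 + "AAAA"
        m = build_frequency_matrix([(a, 5.0), (c, 5.0)], top_fraction=1.0)
        assert m.freqs[0, 0] == pytest.approx(0.5)
        assert m.freqs[0, 1] == pytest.approx(0.5)

    def test_top_fraction_ranks_by_abundance(self):
        # the low-abundance G-rich sequence must be excluded at 0.5
        seqs = [("A" * 21, 100.0), ("C" * 21, 90.0), ("G" * 21, 1.0)]
        m = build_frequency_matrix(seqs, top_fraction=0.5)
        assert np.all(m.freqs[:, 2] == 0.0)

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_bad_top_fraction(self, frac):
        with pytest.raises(ValueError):
            build_frequency_matrix([("A" * 21, 1.0)], top_fraction=frac)

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_frequency_matrix([("ACGU" * 4, 1.0)])


class TestSampleCores:
    def test_degenerate_matrix_fixed_core(self):
        freqs = np.zeros((13, 4))
        freqs[:, 2] = 1.0  # always G
        (core,) = sample_cores(BaseFrequencyMatrix(freqs), 1, seed=3)
        assert core.seq == "G" * 13

    def test_n_distinct_and_reproducible(self):
        cores1 = sample_cores(uniform_matrix(), 1000, seed=5)
        cores2 = sample_cores(uniform_matrix(), 1000, seed=5)
        assert len({c.seq for c in cores1}) == 1000
        assert [c.seq for c in cores1] == [c.seq for c in cores2]

    def test_column_frequency_binomial(self):
        # one concentrated column among otherwise uniform positions
        freqs = np.full((13, 4), 0.25)
        freqs[4] = [0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3]
        cores = sample_cores(BaseFrequencyMatrix(freqs), 10_000, seed=11)
        obs = np.mean([c.seq[4] == "A" for c in cores])
        se = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(obs - 0.9) < 3 * se

    def test_impossible_distinctness_errors(self):
        freqs = np.zeros((13, 4))
        freqs[:, 0] = 1.0
        with pytest.raises(RuntimeError, match="distinct"):
            sample_cores(BaseFrequencyMatrix(freqs), 2, seed=0)


def naive_genome_scan(core_seq: str, chroms) -> bool:
    """Oracle: does the core match anywhere on either strand?"""
    dna = to_dna(core_seq)
    for chrom in chroms:
        fwd = to_dna(chrom)
        rev = revcomp(fwd)
        if dna in fwd or dna in rev:
            return True
    return False


class TestGenomeFilter:
    def test_empty_genome_retains_all(self):
        cores = sample_cores(uniform_matrix(), 10, seed=1)
        out = filter_genome_matching(cores, [])
        assert [c.seq for c in out] == [c.seq for c in cores]
        assert all(c.genome_clean for c in out)

    def test_forward_substring_removed(self):
        core = CoreSequence("ACGUACGUACGUA")
        genome = [SequenceRecord("chr1", "TTTT" + "ACGTACGTACGTA" + "GGGG")]
        assert filter_genome_matching([core], genome) == []

    def test_reverse_complement_removed(self):
        core = CoreSequence("ACGUACGUACGUA")
        rc = revcomp("ACGTACGTACGTA")
        genome = [SequenceRecord("chr1", "TTTT" + rc + "GGGG")]
        assert filter_genome_matching([core], genome) == []

    def test_matches_naive_scan_on_random_genome(self):
        rng = np.random.default_rng(17)
        genome = [
            SequenceRecord(
                f"chr{i}", "".join(rng.choice(list("ACGT"), size=5000))
            )
            for i in range(2)
        ]
        cores = sample_cores(uniform_matrix(), 50, seed=17)
        # plant a handful so the scan has positives
        g0 = genome[0].seq
        planted = [
            CoreSequence(g0[100:113]),
            CoreSequence(revcomp(g0[300:313])),
        ]
        allc = cores + planted
        kept = {c.seq for c in filter_genome_matching(allc, genome)}
        for c in allc:
            expect_kept = not naive_genome_scan(c.seq, [g.seq for g in genome])
            assert (c.seq in kept) == expect_kept


class TestExpandSet:
    def test_flank1_enumeration(self):
        s = expand_set(CoreSequence("ACGUACGUACGUA"), flank_len=1)
        members = set(s.members())
        oracle = {
            a + "ACGUACGUACGUA" + b
            for a, b in itertools.product("ACGU", repeat=2)
        }
        assert members == oracle
        assert s.member_count == 16

    @pytest.mark.parametrize("flank_len", [1, 2, 3])
    def test_member_count_formula(self, flank_len):
        s = expand_set(CoreSequence("ACGUACGUACGUA"), flank_len)
        enumerated = sum(1 for _ in s.members())
        assert enumerated == 4 ** (2 * flank_len) == s.member_count

    def test_members_contain_core_at_fixed_position(self):
        core = CoreSequence("GGAUCCGGAUCCG")
        s = expand_set(core, flank_len=4)
        for m in s.sample_members(200, seed=0):
            assert len(m) == 21
            assert m[4:17] == core.seq

    def test_sampled_members_are_distinct(self):
        s = expand_set(CoreSequence("ACGUACGUACGUA"), 4)
        sample = s.sample_members(2000, seed=9)
        assert len(set(sample)) == 2000


def exhaustive_min_energy(seq: str) -> float:
    """Oracle: recursively enumerate every non-crossing structure."""

    def best(i: int, j: int) -> float:
        if j - i < 4:
            return 0.0
        # i unpaired
        out = best(i + 1, j)
        for k in range(i + 4, j + 1):
            e = PAIR_ENERGY.get((seq[i], seq[k]))
            if e is not None:
                out = min(out, e + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


class TestComputeMFE:
    def test_unpairable_sequence_scores_zero(self):
        assert compute_mfe(["A" * 21])[0] == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        seqs = ["GGGGAAAACCCC"] + [
            "".join(rng.choice(list("ACGU"), size=n))
            for n in range(4, 13)
            for _ in range(6)
        ]
        got = compute_mfe(seqs)
        want = [exhaustive_min_energy(s) for s in seqs]
        assert np.allclose(got, want, atol=1e-12)

    def test_rnafold_backend_matches_frozen_fixture(self):
        # energies computed once with RNAfold --noPS -T 4 (ViennaRNA 2.7.2)
        fixture = [
            ("AUGCCUAGAAGUGUGUGAUCG", -3.91),
            ("CAUUGCUGCCAAGUAUUCGAU", -4.69),
            ("GCAUCUGUUACCCAGAGGUGC", -10.87),
            ("UCCUCACUACAGCCAGGUCAU", -2.71),
            ("GGACUUCUUCUCAGGAUAUAU", -1.79),
            ("UUGCGCUGCGGAAAACGGCUG", -7.68),
            ("AUGGGGAGUCGACCUACCUUA", -7.9),
            ("AUAUCUCCGAGGUUGCCCUCA", -8.16),
            ("CAAAUGGCGAUGUACGCCACA", -11.24),
            ("CGGGCUACACUCUCGCCUUCU", -7.55),
            ("CGUCGCAACUACGAGCUGGAC", -6.36),
            ("UAUCGGCCGAGAGGAUCUAAC", -5.48),
            ("ACGAGAAGUACUUGCCGGCAA", -5.15),
            ("UCCCUAACCGCCUAGGCUCUC", -5.25),
            ("GGUCCACUAUGACGCAGGACA", -8.72),
            ("GGGUUCAGUUAAAAGGCCUCU", -6.69),
            ("UCAUGCGGUCUUAAGACCUUA", -8.8),
            ("UAGUUAUAGCCAUCGCCUAGG", -2.16),
            ("CCAUUAAAAUUAGACGGUAAC", -2.39),
            ("CUUCUCGCAUAAACAAGUACG", -1.81),
        ]
        got = compute_mfe([s for s, _ in fixture], backend="rnafold")
        assert np.allclose(got, [v for _, v in fixture], atol=1e-2)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            compute_mfe([])
        with pytest.raises(ValueError):
            compute_mfe(["ACGX"])
        with pytest.raises(ValueError):
            compute_mfe(["ACGU"], backend="nonsense")


def make_candidate(core: str, mfe: np.ndarray) -> SpikeInCandidateSet:
    cand = SpikeInCandidateSet(CoreSequence(core))
    cand.mfe_values = np.asarray(mfe, dtype=float)
    return cand


class TestSelectSets:
    def setup_method(self):
        rng = np.random.default_rng(31)
        self.reference = MFEDistribution(rng.normal(-5, 2, 400))
        cores = sample_cores(uniform_matrix(), 6, seed=31)
        self.candidates = [
            make_candidate(c.seq, rng.normal(-5 + 0.5 * i, 2, 300))
            for i, c in enumerate(cores)
        ]

    def test_k_equals_all_returns_all(self):
        chosen, _ = select_sets(self.candidates, self.reference, len(self.candidates))
        assert {c.core.seq for c in chosen} == {
            c.core.seq for c in self.candidates
        }

    def test_identical_distribution_ranked_first(self):
        twin = make_candidate("GGGGGGGGGGGGG", self.reference.values)
        chosen, report = select_sets(
            self.candidates + [twin], self.reference, 1
        )
        assert chosen[0].core.seq == twin.core.seq
        assert report.iloc[0]["ks_d"] == 0.0

    def test_ks_statistic_matches_ecdf_oracle(self):
        _, report = select_sets(self.candidates, self.reference, 2)
        for cand in self.candidates:
            x = np.sort(cand.mfe_values)
            y = np.sort(self.reference.values)
            grid = np.concatenate([x, y])
            d = np.max(np.abs(
                np.searchsorted(x, grid, side="right") / len(x)
                - np.searchsorted(y, grid, side="right") / len(y)
            ))
            row = report[report.core == cand.core.seq]
            assert row["ks_d"].iloc[0] == pytest.approx(d, abs=1e-12)

    def test_permutation_invariant(self):
        chosen1, _ = select_sets(self.candidates, self.reference, 3)
        chosen2, _ = select_sets(self.candidates[::-1], self.reference, 3)
        assert [c.core.seq for c in chosen1] == [c.core.seq for c in chosen2]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            select_sets(self.candidates, self.reference, 99)


class TestFormulateMix:
    def test_single_set_at_max(self):
        sheet = formulate_mix(
            [SpikeInCandidateSet(CoreSequence("ACGUACGUACGUA"))],
            max_molecules_per_ug=5e5,
        )
        assert sheet.molecules_per_ug == [5e5]

    def test_eight_sets_over_3p5_decades(self):
        sets = [
            SpikeInCandidateSet(c) for c in sample_cores(uniform_matrix(), 8, 2)
        ]
        sheet = formulate_mix(sets, dynamic_range_log10=3.5,
                              max_molecules_per_ug=1e6)
        logs = np.log10(sheet.molecules_per_ug)
        assert np.allclose(np.diff(logs), -0.5)

    def test_amounts_positive_and_decreasing(self):
        sets = [
            SpikeInCandidateSet(c) for c in sample_cores(uniform_matrix(), 5, 3)
        ]
        amounts = formulate_mix(sets).molecules_per_ug
        assert all(a > 0 for a in amounts)
        assert all(a > b for a, b in zip(amounts, amounts[1:]))

    def test_nonpositive_max_rejected(self):
        sets = [SpikeInCandidateSet(CoreSequence("ACGUACGUACGUA"))]
        with pytest.raises(ValueError):
            formulate_mix(sets, max_molecules_per_ug=0.0)


class TestDesignDriver:
    def test_small_end_to_end_design(self):
        rng = np.random.default_rng(41)
        mirnas = [
            ("".join(rng.choice(list("ACGU"), size=21)), float(a))
            for a in rng.uniform(1, 1000, 40)
        ]
        genome = [
            SequenceRecord("chr1", "".join(rng.choice(list("ACGT"), size=8000)))
        ]
        config = DesignConfig(
            n_candidates=60, n_select=3, mfe_sample_per_set=50, seed=41
        )
        sheet, report, chosen = design_spikein_sets(mirnas, genome, config)
        assert len(sheet) == 3
        assert len(report) >= 3
        for a, b in itertools.combinations([c.core.seq for c in chosen], 2):
            assert hamming(a, b) >= config.min_core_hamming
        for core in sheet.cores:
            assert not naive_genome_scan(core, [genome[0].seq])
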