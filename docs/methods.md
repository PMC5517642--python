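# Methods

## The problem and the estimator

Relative sRNA-Seq units (RPM) are ratios to the sequenced pool, so any
global change in the sRNA population redistributes RPM without any change
in absolute abundance. The spike-in approach adds exogenous 21 nt RNA
oligos at known molecules per µg of total RNA (MPU) before library
construction. Each spike-in *set* is read out by a 13 nt core sequence
that cannot match the genome; a dilution series of sets gives paired
(measured RPM, known MPU) points, and a fitted standard curve converts
any endogenous RPM to MPU.

The curve is fitted by ordinary least squares of log10(MPU) on
log10(RPM). A log–log fit is the package default because the calibration
points span about four decades: on linear axes the largest point would
dominate the residuals, while on log axes each decade contributes
equally. A `linear` scale is available for a literal straight-line fit.
Pearson r of the transformed points and the two-sided p-value of that
correlation (t approximation) are reported with every curve. Sets that
drew zero reads are dropped from the fit and logged, never imputed;
converting RPM 0 returns MPU 0 by convention.

## Spike-in design

1. **Base-frequency matrix.** For the top fraction (default 50%) of
   provided miRNAs ranked by mean abundance, tally base frequencies at
   positions 5–17 from the 5′ end (13 columns over {A,C,G,U},
   unweighted after selection). Positions 5–17 are used because the
   5′-terminal and 3′-terminal nucleotides of miRNAs carry strong
   identity biases tied to AGO loading and 3′ modification; the interior
   window captures typical composition without fixing the ends.
2. **Core sampling.** Draw 13-mers with each position independent from
   its matrix column (default 1,000 candidates), de-duplicating and
   redrawing until distinct.
3. **Genome exclusion.** Discard any core with a perfect match to the
   target genome on either strand. Both strands are checked because
   downstream alignment is strand-agnostic and a spike-in read cloned in
   either orientation must stay unambiguous.
4. **Flank expansion.** Each surviving core is flanked by every 4-mer on
   both sides: 256 × 256 = 65,536 21-mers per set. The set is quantified
   as a whole, so per-sequence ligation biases average out across the
   members.
5. **Structure matching.** MFE values are computed for a seeded random
   subsample (default 2,000 of 65,536) of each candidate set and compared
   to the MFE distribution of the endogenous miRNAs by the two-sample KS
   statistic; the k (default 8) candidates with the smallest D are
   selected, ties broken by core lexicographic order. Selected cores must
   additionally be pairwise Hamming ≥ 4 so the 13 nt tags cannot be
   confused by a few sequencing errors.
6. **Mix formulation.** Input amounts are log10-equispaced from a maximum
   (default 10⁶ molecules/µg) down across a configurable dynamic range
   (default 4 decades, matching the span of abundant plant miRNA
   families), one amount per set, descending with set order.

Two MFE backends exist. `rnafold` shells out to ViennaRNA's RNAfold
(default options `--noPS -T 4`; 4 °C matches the temperature at which
ligation reactions are commonly performed) and fails loudly if the
executable is absent — there is no silent fallback. `internal` is a
Nussinov-style dynamic program maximizing summed pair bonuses
(GC 1.0, AU 0.8, GU 0.5 — the ordering of stacking strengths — with a
minimum hairpin loop of 3), reported as a negated pseudo-energy clamped
at 0 for pairless optima. It is not on RNAfold's kcal/mol scale, but it
preserves the structured-vs-unstructured ranking that distribution
matching needs, and it is exactly checkable against exhaustive structure
enumeration for short sequences.

## Read processing

- **Trimming:** the insert upstream of the leftmost full 3′-adapter
  occurrence, or of the longest terminal adapter prefix of ≥ 8 nt; no
  mismatches. Inserts outside 18–30 nt are discarded and counted. The
  exact-match policy favors reproducibility over rescue of marginal
  reads; with perfect-match alignment downstream, mistrimmed reads could
  only be lost, not misassigned.
- **Collapsing:** identical inserts become one record with a count.
- **Alignment:** all perfect-match loci on both strands of the genome.
  A read with n ≤ 100 loci carries weight count/n per locus; above 100
  the read is discarded entirely (bowtie `-m` semantics). Output order is
  deterministic (chrom, start, sequence).
- **Spike-in counting:** a read belongs to a set iff that set's 13 nt
  core occurs as a substring (U/T-canonicalized); reads containing two
  distinct cores are discarded with a warning. Tag-identified reads are
  excluded from genome alignment — cores are genome-excluded by
  construction, so the two read classes are disjoint — and the RPM
  denominator is the summed count of genome-matching reads only.

## Quantification rules

- Mature miRNA/tasiRNA: read length 20–22 nt, same strand, and the hit
  interval contained within the annotated mature interval padded by 2 nt
  on each side. Containment-with-padding was chosen over per-end offset
  matching; the two readings differ only for reads shorter than the
  annotation, and containment is the stricter, easier-to-state rule.
- siRNA: read length 20–24 nt overlapping a transposon by ≥ 1 nt on
  either strand; 20–22 and 23–24 nt bins kept separate; a read
  overlapping k transposons contributes weight/k to each.
- Families sum their members; a transposon is its own siRNA family.
  Reads satisfying both the mature and the siRNA rule (overlapping
  annotations) are counted in both and the doubly-assigned weight is
  reported, not resolved.
- All aggregations conserve assigned weight to numerical precision and
  are invariant to input hit order.

## Statistics

Group comparisons use the classical pooled-variance two-sample Student's
t (not Welch) and the two-sample KS statistic with the asymptotic
Kolmogorov p-value; both are implemented from their closed forms and
cross-checked against scipy in the test suite. Differential family calls
require a ≥ 2-fold difference of replicate means *and* t-test p < 0.05,
computed independently on RPM and MPU inputs; no multiple-testing
correction is applied by default (Benjamini–Hochberg is available by
flag). The expression filter (≥ 1 RPM in every replicate, inclusive)
precedes the calls. Stoichiometry ratios divide mature-family MPU by the
partner transcript's MPU and report the group median; pairs whose
partner is below the mRNA detection filter are dropped with a count.

## Synthetic data model

`synth.make_genome` plants, in a uniform-random genome (default 60 kb):

- 20 miRNA hairpins — mature 21-mer + 15 nt loop + star arm
  (reverse complement with 3 substitutions, so the mature sequence stays
  genome-unique and single-mapping);
- 5 tasiRNA loci with four in-phase 21 nt registers from a fixed start
  (schematic phasing, sufficient for coordinate-rule testing, not for
  phasing biology);
- 10 transposons (600 bp) each carrying 20 fixed siRNA species of
  20–24 nt (biased toward 23–24 nt) on random strands.

True abundances are drawn log-uniformly per feature: miRNAs
10^3.5–10^6, tasiRNA registers 10^3–10^5, siRNA species 10^4–10^6
molecules/µg. With the default mix (10⁶ down 4 decades over 8 sets)
this puts the spike-ins at roughly 3% of the library — the same order as
the 1–2% of alignable reads the real protocol budgets for spike-ins —
and makes the miRNA families span the same decades as the dilution
series. Every planted sequence is verified to occur exactly once in the
genome (both strands) and no spike-in core may occur at all; generation
retries with a derived seed otherwise.

`synth.simulate_library` draws exactly `depth` reads multinomially with
probability ∝ molecules × bias. Spike-in molecules are spread uniformly
over each set's 65,536 members, and each member receives an independent
lognormal bias factor with sd(log₂) = 1 by default, normalized to unit
mean (bias is an efficiency relative to the library average; an
un-normalized bias would shift the whole pool's capture rate, which is
unidentifiable from sequencing data anyway). Endogenous features have a
separate bias parameter, default 0: the generator's purpose is to test
whether set-level averaging defeats per-sequence bias and whether the
pipeline recovers known inputs, not to model the (uncorrectable)
per-sequence bias of endogenous sRNAs. Consequently the end-to-end
recovery benchmark demonstrates pipeline and calibration fidelity under
spike-in-side bias; on real data, individual endogenous sRNAs retain
their own capture biases, which no set-averaging can remove.

Reads are insert + 3′ adapter truncated to 50 nt, with placeholder
qualities (quality scores are irrelevant to perfect-match alignment).
`make_mrna_tables` emits an ERCC-like sheet with known MPUs log-spaced
over ≥ 4 decades and TPM = 10⁻³ · MPU · 10^ε, ε ~ N(0, 0.05 log10
units), plus precursor transcripts whose TPMs derive from their true
MPUs (precursor MPU = mature-family MPU over a lognormal ratio with
median 2) and a few sub-1-TPM decoys.

## Benchmark problem sizes and readings

The acceptance benchmarks run at sizes a laptop handles in minutes: the
curve-fidelity check uses 10 libraries of 100,000 spike-in reads; the
end-to-end recovery check uses 20 libraries of 200,000 reads over the
default 60 kb genome. The recovery criterion — estimates within 20% of
truth for families with ≥ 50 expected reads — is evaluated **pooled over
(family, seed) pairs** (≥ 90% of pairs pass). A per-seed conjunction
over all eligible families would be dominated by the families sitting
exactly at the 50-read eligibility floor, where multinomial noise alone
(relative SD ≈ 14%) exceeds the 20% band in ~15% of draws per family.

## Numerical and degenerate-input conventions

- Interval arithmetic is 0-based half-open everywhere internally; GFF3's
  1-based inclusive convention is converted at I/O only.
- Sequences are stored as given; U/T are canonicalized only inside
  comparisons. DNA is the canonical alphabet for read-space operations.
- KS selection ties break by core lexicographic order, making set
  selection permutation-invariant.
- Curve fitting requires ≥ 2 usable points; identical-x degenerate fits
  propagate scipy's error rather than returning a fabricated slope.
- t-test with zero pooled variance returns t = 0, p = 1 for equal means
  and ±∞, p = 0 otherwise.

## Known limitations

- The internal MFE model ignores stacking, dangles and temperature; use
  the RNAfold backend when energy values (not just distribution shape)
  matter.
- The simulator has no sequencing errors, no quality model, no RNA
  degradation and no isomiR production; trimming and alignment therefore
  see cleaner data than reality.
- tasiRNA phasing is schematic; phasing-aware analyses are out of scope.
- Degradome-derived target pairs are consumed as provided; no cleavage
  inference is performed.
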