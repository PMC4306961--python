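# Methods

## Recovery model

A locus in one sample has `m` true alleles with amplification weights
`w_1..w_m > 0`, and each sequenced read is, independently, a correct copy of
allele `i` with probability `q_i = p · w_i / Σw` or an error with
probability `1 − p`, where `p` is the proportion of correct reads for the
enzyme/system combination. The recovery probability at total depth `n` is
the probability that every allele count reaches `k`:

P(all X_i ≥ k) = Σ_{S ⊆ {1..m}} (−1)^{|S|} P(X_i < k ∀ i ∈ S),

with each joint shortfall term a sum of `k^|S|` multinomial probabilities
(categories in S plus one marginalised remainder). Multinomial coefficients
are evaluated in log space (`gammaln`, `xlogy`), so depths in the tens of
thousands are safe; the result is clipped to [0, 1] against rounding at the
10⁻¹⁵ level. The term count grows as `k^m`, so exact computation is the
default for small allele counts (`m ≤ 4`); `mc_recovery` provides a seeded
multinomial Monte-Carlo estimate with a binomial standard error for larger
`m` and as an independent check.

`min_coverage` exploits monotonicity in `n`: start at the trivial bound
`m·k`, double until the confidence is met, then bisect; the returned `n_min`
satisfies `P(n_min) ≥ c` and `P(n_min − 1) < c` exactly (no ties, by
monotonicity). `p = 0` raises, since no finite depth reaches the target.
`consistent_p_interval` inverts the map in the other direction: since
`n_min` is non-increasing in `p`, the set of `p` values mapping to a given
published coverage is contiguous and is located by bisection on a `p` grid
(default resolution 10⁻³).

**Bias convention.** "One allele amplifies half as well as the other" is
modelled as correct reads splitting between alleles in proportion to
weights `(2, 1)` — the weaker allele receives `p/3` of all reads, the
stronger `2p/3`, and the error mass `1 − p` is unchanged. This is the
simplest convention consistent with scoring reads only correct/incorrect;
published two-allele coverage values that were derived from observed
per-allele read frequencies need not coincide with it, which is why the
weights are an explicit parameter rather than a constant. Errors are pooled
into a single spill-over category and never attributed to an allele.

Defaults `k = 3` and `c = 0.999` reflect the common rule of accepting an
allele only when seen in at least three identical reads, at 99.9%
confidence.

## Demultiplexing

Reads follow the two-round tailed-amplicon architecture:
`adaptor+key | MID(10 bp) | M13 tail | locus primer | insert |
rc(locus primer) | rc(M13 tail) | rc(MID) | rc(adaptor)`. Assignment
requires, in either orientation, the complete MID and tail and the complete
locus primers at both ends, matched exactly — IUPAC degeneracy is honoured
in primers only (the MHC class II primers contain Y/K/M/W/S codes); MIDs
and tails match literally. "Full length" is operationalised as both end
structures present plus insert length within the design's inclusive range.
There is no fuzzy barcode rescue or quality trimming; rejects are recorded
with a reason (`no_mid`, `incomplete_primer`, `length_out_of_range`,
`ambiguous_mid`) and the per-reason counts partition the input exactly. A
read whose structure matches two different sheet MIDs is rejected as
ambiguous — impossible for barcode sets designed with pairwise distance
≥ 3, but defined conservatively. Both orientations are accepted because
Lib-A-style libraries sequence amplicons from both ends. Sequences are
plain upper-case text with 0-based half-open coordinates internally.

## Correctness scoring

A read is correct iff its trimmed insert is character-identical (length
included — an indel makes a read incorrect) to a reference allele of its
individual at the locus; the reverse complement of an allele also counts, as
a safety net even though orientation is normalised at demux. Correct reads
are attributed to the matching allele; if two listed alleles were identical
the first in sorted id order would win, deterministically (the panel forbids
duplicates, so this is a tie-break in name only). Units enter statistics
only with strictly more than 10 reads. Pooling sums raw counts and
recomputes p̂, so it is exactly additive.

## Synthetic read generator

The generator emulates the post-basecalling product of a pyrosequencing run
of a tailed-amplicon library. Per read: a template allele is drawn in
proportion to the profile's allele weights; with probability
`chimera_fraction` the insert becomes a single-crossover chimera of two
distinct alleles at a uniform internal breakpoint (the partial-extension
artefact; multi-crossover chimeras are out of scope); substitutions are
applied per base and single-base indels at homopolymer runs of length ≥ 3
(the loci modelled have homopolymers up to 5 bp); the insert is wrapped in
the full amplicon structure and emitted in a random orientation. Degenerate
primer positions are emitted as a fixed concrete base so that the
IUPAC-aware demultiplexer is exercised from the pattern side. Errors touch
the insert only — MIDs, tails and primers are emitted intact — so filtering
and correctness remain decoupled. Ground truth (`is_correct`) is computed
from the *emitted* insert, so a back-mutation that regenerates a reference
counts as correct. Output is byte-deterministic for a fixed seed.

`calibrate_profile` back-solves the substitution rate so the expected
fraction of unaltered reads equals a target `p`: expected survival is
`(1 − chimera) · Σ_a ŵ_a (1 − sub)^{L_a} (1 − indel)^{s_a}` over alleles of
length `L_a` with `s_a` homopolymer sites, solved for `sub` by Brent's
method with chimera and indel rates held fixed (infeasible targets raise).
The tiny probability that a chimera of near-identical alleles equals a
reference is neglected in calibration.

What the generator does **not** model: flowgram-level 454 noise beyond the
per-site indel knob, quality scores, emulsion-PCR duplication, read-length
variation other than through indels, and unequal per-unit yields. Passing
tests therefore demonstrate that the analysis chain recovers the parameters
of this idealised error process, not that it is robust to every artefact of
real runs.

The bundled miniature experiment spans three marker systems (a haplotype
mtDNA control-region locus, 168–172 bp insert; a biallelic MHC class II
exon 2 locus, ~257 bp, degenerate primers; a multigene MHC class I exon 3
locus, ~184 bp, three alleles per individual), three individuals, two
cycling conditions, and enzyme profiles at target correctness 0.9 / 0.5 /
0.1 — spanning the per-enzyme range observed in practice — plus one enzyme
that never amplifies and one trace-yield unit (8 reads), so both report
flags (`n.a.` = no amplification, `i.d.` = ≤ 10 reads pooled) are
exercised. Reference alleles and MIDs (pairwise Hamming distance ≥ 3) are
generated deterministically from the seed; insert-length windows allow ±5 bp
around the nominal length so single-base indels remain classifiable rather
than being silently removed by the size filter.

## Condition comparison

The effect of cycling conditions on correctness is tested with a stratified
permutation test rather than a mixed model: within each
(system, enzyme, individual) stratum containing both conditions, condition
labels are exchangeable under the null and are permuted; the statistic is
the difference in read-weighted pooled proportions (Σ correct / Σ reads per
condition); p-values are two-sided with the add-one convention. Strata with
a single condition are dropped with a logged note. This choice keeps the
package self-contained and lets the test's operating characteristics be
verified directly: the suite checks that the null rejection rate at
α = 0.05 falls in [0.03, 0.07] over 1000 simulated datasets and that a
+0.075 shift in correctness (10 strata of 2000 reads) is detected with
power above 0.9.

## Problem sizes used in the test suite and acceptance script

Simulation-based checks use sizes chosen to make the statistical assertions
sharp while keeping the default run quick: correctness recovery averages 30
seeds × 2000 reads per target (standard error ≈ 0.002 ≪ the 0.02
tolerance), cycling through the three marker systems; the structural
demux/flag checks run the full miniature experiment once at 40–120 reads
per unit; oracle equivalence enumerates all multinomial outcomes for
n ≤ 15, m ≤ 3, k ≤ 3 and uses 10⁵ Monte-Carlo replicates on a coarser grid;
permutation calibration uses 299–499 permutations per dataset (granularity
well below the 0.05 threshold being checked). The acceptance script uses 10
seeds per correctness target and 400 null datasets, reporting the same
quantities.

## Known limitations

- Exact recovery probabilities are practical only for small allele counts;
  multigene families with unknown allele numbers are summarised by pooled
  proportions, not coverage numbers.
- The identity scoring rule cannot distinguish a true low-frequency allele
  from a repeated artefact; the model quantifies required depth given `p`,
  it does not call genotypes.
- Calibration matches expected correctness, not the full error spectrum;
  per-read error structure in real data is platform- and locus-dependent.
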