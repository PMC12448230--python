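# Methods

This note documents the model, the estimation algorithm, the simulator,
the evaluation statistics, and the numerical and design choices behind
them. Notation: the reference r has L0 positions (1-based) and L0−1
inter-base gaps, gap g lying between positions g and g+1; the consensus
haplotypes C_1..C_K are sequences over {A,C,G,T,−} indexed against the
reference, with inserted segments stored sparsely per gap; a read R_i
covers [s_i, e_i] in the same coordinates.

## Generative model

**Evolution stage.** Each haplotype evolves independently from the
reference. Per position: no mutation (γ_1), substitution (γ_2; the new
base uniform over the three alternatives), deletion (γ_3), with
γ_1+γ_2+γ_3 = 1. Per gap: a single-base insertion with probability β
(base uniform). The log-likelihood of a haplotype is therefore a sum of
count-weighted log-probabilities of its match/substitution/deletion/
insertion events.

**Sequencing stage.** Given its source haplotype, a read is generated
position by position over the consensus: correct emission (p1), mismatch
(p2, emitted base uniform over the three alternatives), or the start of a
deletion segment (p3), with p1+p2+p3 = 1 so the per-position emission is a
proper categorical distribution; a deletion segment deletes
1 + Poisson(λ_del) consensus positions (a *shifted* Poisson, so segment
lengths are ≥ 1 and the length log-pmf is
(L−1)log λ − λ − log((L−1)!)). Independently, each gap carries an
insertion error with probability p4, of length 1 + Poisson(λ_ins),
inserted bases uniform. Positions inside a deletion segment are not
emission trials; continuation is governed solely by the segment-length
law.

**Base content.** The uniform base-content constants — log(1/3) per
mismatched or substituted base, log(1/4) per inserted base — are included
in every likelihood, so exp(log-likelihood) is the actual probability of
the sequence. They matter: event counts differ across candidate
haplotypes, so these terms do not cancel in the responsibilities.

**Comparison conventions.** When a read is compared with a consensus:
positions where the consensus is '−' are excluded from emission counting
(a read base observed there is re-interpreted as an insertion at the gap
adjacent to the deleted run); a read insertion at a gap where the
consensus has none is an insertion error; a consensus insertion absent
from the read is a deletion segment of the inserted length; when both
carry insertions, a perfect copy is no event and differing bases count as
mismatch-equivalents. Ambiguous reference bases (N) are treated as
universal matches in the evolution stage and excluded from sequencing
emission counting. Deletion-run continuity is taken over the comparable
subsequence, so a consensus-deleted position inside a read-deletion run
does not split the segment.

## Classification annealing EM

The fit alternates three steps from a seeded initialization, with
multiple restarts:

- **AE**: responsibilities ∝ (α_k · P(R_i|C_k, ψ))^(1/T), normalized per
  read in log space; a read with zero likelihood under every haplotype is
  reported by name.
- **C**: per-read argmax, ties to the lowest haplotype index.
- **M**: closed forms — α̂_k = n_k/n; (p̂1,p̂2,p̂3) from pooled
  correct/mismatch/deletion-segment counts; p̂4 = V/(V+W);
  λ̂ = mean segment length − 1 (the shifted-Poisson MLE); γ̂, β̂ from
  consensus-vs-reference counts (per haplotype by default; a
  `tie_evolution` flag pools them for small data). The consensus update is
  exact coordinate ascent: per position, the state in {A,C,G,T,−}
  maximizing the assigned reads' emission terms plus the evolution prior;
  per gap, a consensus insertion is accepted when the with-insertion local
  objective beats the without-insertion one. Positions with no read
  coverage revert to the prior argmax (the reference state). Only strictly
  improving moves are taken.

Because the C step maximizes over labels given parameters and every M-step
component is an (constrained) argmax given labels, the complete-data
log-likelihood is non-decreasing over C+M iterations — the classification-
EM monotonicity property, asserted by the test suite on every seeded run.

**Temperature schedule.** T starts at T0 = 10 and cools geometrically by
0.9 per iteration with floor 1; convergence is declared at T = 1 when the
relative objective change falls below 1e−6 (at most 500 iterations;
non-convergence returns the best state with a warning). One property of
this reconstruction is worth stating plainly: with a deterministic argmax
C step, raising the responsibilities to 1/T is a monotone transform and
cannot change the hard labels, so annealing affects the reported
responsibilities but not the fitted trajectory. The schedule is kept for
interface fidelity and because the annealed responsibilities are
themselves outputs; where runtime matters (cross-validation sweeps) a
short schedule (T0 = 1.5, cooling 0.5) is used, which is exactly
equivalent for the fit.

**Initialization.** A purely random hard partition of reads makes all K
plurality consensuses nearly identical (every partition cell sees the same
allele fractions at every column), which collapses a hard-assignment EM:
all reads immediately classify to one component. The default
initialization therefore clusters reads on their alleles at candidate
variant columns — columns whose second-most-common read state is supported
by at least max(2, 0.15·coverage) reads — using k-means on ±1 allele
features; the first two restarts use clustering (different k-means seeds),
the rest use random partitions (`init="cluster"`/`"random"` force one
mode). Empty components are re-seeded with the worst-fitting read rather
than deleted, keeping K fixed during a fit.

**Numerical safeguards.** Probability estimates are floored
(1e−6 for γ/β, 1e−9 for the sequencing simplex and p4, 1e−6 for λ) using
the exact constrained MLE on the floored simplex (floor the deficient
components, rescale the rest); without the floor a single M step with zero
substitution count would set γ̂_2 = 0 and the resulting −∞ prior would
freeze the consensus at the reference forever. The constrained argmax
preserves monotonicity. Ties in the consensus update keep the incumbent
state; candidate evaluation order is fixed, so fits are bit-reproducible
given the seed.

**Model selection.** Reads are partitioned into five seeded folds; for
each candidate K the model is fitted on four folds and the held-out reads'
MECR against the fitted haplotypes is recorded. The chosen K minimizes the
mean held-out MECR, with near-ties within one standard error of the
minimizer broken toward smaller K — the held-out MECR typically improves
only marginally beyond the true ploidy, so the one-SE rule guards against
overfitting K. With fewer than five reads the selection falls back to
in-sample MECR with a warning. Cross-validation partitions reads (not
genomic segments).

## Simulator

The simulator runs the generative model forward and is first-class,
tested code. Defaults follow the published study conditions: evolution
parameters (0.9989, 0.001, 0.0001; β = 0.0001) for the two diploid
haplotypes and (0.98572, 0.0139, 0.00038; β = 0.00038) for a third,
higher-mutation haplotype; mixture weights (0.6, 0.4) for K = 2 and
(0.4, 0.4, 0.2) for K = 3; three error-profile presets with aggregate
mismatch/insertion/deletion percentages per base of
(1.30, 0.087, 0.34), (1.49, 4.0635, 1.75) and (1.68, 8.04, 3.16) — level
2 the midpoint of levels 1 and 3. The full-information scenario grid is
K ∈ {2,3} × 3 levels × n ∈ {50,100} reads = 12 runs.

The presets give aggregate indel *base* rates, not the per-segment/
length-rate split; with the default λ_ins = λ_del = 1 the per-segment
probabilities are solved from p·(1+λ) = aggregate rate, an interpretation
documented here because no split is published. Read mapping lengths default
to a log-normal (median 2000 bp, σ = 0.6, clipped to [500, L0]) standing in
for an empirical long-read panel length table, which can be supplied via
`EmpiricalLengths`. Structural variants (five types: insertion, deletion,
duplication, inversion, translocation; lengths uniform over
{50, 100, 500}; type probabilities configurable, default uniform) can be
injected into the consensuses before sequencing.

The generator records its own injected events; the test suite re-derives
them exactly with the model-side event summarizer (100 seeded reads).
Alignments are trimmed so they never start or end with a deletion, with
the recorded events adjusted; sequencing errors *within* inherited
consensus insertions are not simulated (insertions are copied verbatim).

**What the simulator does not emulate:** instrument-specific artifacts
(homopolymer-dependent error, chimeric reads, quality-score structure),
coverage biases, and alignment errors — reads are emitted already
correctly placed. Passing tests therefore demonstrate correctness of the
method under its own model assumptions, plus robustness to the modelled
error levels; they do not certify performance on real instrument data,
where mapping artifacts and non-uniform error are additional obstacles.

## Evaluation statistics

**CPR** (correct phasing ratio): under the optimal one-to-one matching χ
between inferred and true haplotypes (solved as an assignment problem,
equivalent to exhausting all K! permutations), the fraction of true-SNV
alleles reproduced: Σ_k Σ_{j∈D_χ(k)} 1(Ĥ_k(j) = H^T_χ(k)(j)) / Σ_k |D_χ(k)|.
The true SNV set D_m defaults to the positions where true haplotype m
substitutes the reference; it is undefined (reported absent) when no true
SNVs exist.

**MECR** (minimum error correction ratio):
Σ_i min_k Σ_{j∈O_i} 1(R_i(j) ≠ Ĥ_k(j)) / Σ_i |O_i|, with the interest set
O_i defaulting to all positions the read covers and restrictable to a
site list (TSV 1-based or BED 0-based half-open). A '−' against a base
counts one inconsistency per position; N positions are dropped. Unlike the
raw minimum-error-correction count, MECR is normalized to [0,1] and
comparable across datasets; when the fit is good it converges to the
sequencing error rate itself. Both scores are label-permutation invariant,
and MECR never increases when a haplotype is added.

**SNV byproduct:** one record per position where ≥ 1 inferred haplotype
substitutes the reference base, written as VCF 4.2 with a single polyploid
sample whose genotype lists each haplotype's allele index; consensus
indels are reported separately and flagged non-SNV.

## Test and reproduction problem sizes

The suite verifies likelihoods against brute-force product oracles on
instances with L0 ≤ 12; CAEM against exhaustive enumeration of all 2^n
labelings (with conditionally optimal consensuses per labeling) at
n = 5 reads; parameter recovery at K = 2, level-1 errors, L0 = 6000,
n = 200 reads over 10 seeded replicates (median CPR ≥ 0.95, mismatch-rate
error ≤ 30%); and ploidy selection at L0 = 300 with 60 full-length reads
and γ_2 = 0.03 (well-separated haplotypes) over 10 runs spanning
K ∈ {1,2,3}. The MECR–CPR anticorrelation is measured where it is
measurable: at high coverage every fit is essentially perfect and CPR
saturates, so the check uses the low-coverage regime (L0 = 1500, 30 reads
of 500 bp, γ_2 = 0.02, ~10× coverage) across the three error levels,
where fit difficulty — and hence both scores — genuinely varies. These
scales keep the full suite within minutes on one CPU while exercising the
same estimators as larger runs; `scripts/acceptance.py` recomputes the
headline quantities at the same scales from a single command-line seed.

## Known limitations

- Long/structural variants are simulated but not modelled during
  inference: the likelihood treats every indel as a short segment, and SV
  breakpoints are not detected.
- All haplotypes are assumed to descend from the one reference;
  recombination between haplotypes is outside the model.
- Base qualities are ignored; the error profile is global, not
  position- or context-specific.
- The MECR-based K selection can under-call ploidy when two haplotypes
  are nearly identical over the sequenced region (their merger costs few
  per-base inconsistencies).
- For long contigs, inference should be run on subregions
  (`--region contig:start-end`) and results concatenated; the
  implementation is single-contig per fit.
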