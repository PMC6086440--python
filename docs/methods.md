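# Methods

## Monophyly tests as posterior odds

For a hypothesis *H* (a set of 2 ≤ k < n taxa), the posterior probability
`P(H|D)` is estimated as the frequency of posterior trees in which the
taxon set is a clade, i.e. equals some node's descendant leaf set exactly.
The posterior odd `P(H|D)/(1 − P(H|D))` is reported for frequencies
strictly inside (0, 1). Bayes factors are deliberately not offered: they
require prior probabilities of topological hypotheses that are hard to
justify, whereas the posterior odd needs only the sample.

A zero observed frequency does not mean `P(H|D) = 0`; it means the
estimator has run out of resolution. The resolution limit is the number
of effectively independent topology draws, so the test reports the upper
bound `P(H|D) < 1/ESS_topology`, separately for both topological ESS
bases ("P" pseudo, "A" approximate) — no single "best" basis is chosen,
because the two estimators fail in different ways and an analyst should
see both. A frequency of one (always true of the root clade) gets the
symmetric lower bound `P(H|D) > 1 − 1/ESS_topology`; this symmetric
extension is this package's choice for a case the published rule leaves
open, justified by applying the same resolution argument to the
complement hypothesis.

Monophyly is evaluated on **rooted** trees by default, because dated
(clock) trees are rooted and clade identity depends on the root; the
path-distance machinery accepts `rooted=False` where unrooted bipartition
logic is wanted.

Bounds are carried unrounded through the computation (`1/ESS` exactly);
rounding happens only in the report layer — exact values and odds to 3
decimals, bounds to 2 significant figures in the `< 1.1 x 10-4 (P)`
style, matching the precision conventions of published odds tables.

## Path distance and topological ESS

A topology *T* on n taxa is embedded as the vector
`p(T) = (p_ij(T))_{i<j}` of edge counts on the i–j leaf paths;
`d(T1, T2) = ‖p(T1) − p(T2)‖₂`. This is a Euclidean metric on
topologies (identity, symmetry, triangle inequality hold by
construction), deliberately branch-length-free so that convergence of the
topology is measured independently of clock scaling. The degree-2 root
node contributes edges by default; an unrooted option suppresses it.

Scalar ESS uses `ESS = N / (1 + 2 Σ_{k≤K} ρ̂_k)` with biased-normalized
sample autocorrelations, truncated at the first negative `ρ̂_k` and
capped at `K_max = min(N − 1, 2000)`; results are clamped to `[1, N]`.
The first-negative rule is the standard desk-scale behaviour of MCMC
diagnostic tools; an independent implementation (arviz) is used as a
cross-check in the test suite, with agreement required only to 20%
(different window rules).

* **Pseudo-ESS**: for each of `n_focal = 20` focal trees drawn uniformly
  with replacement (seeded) from the trace, the distance-to-focal series
  is reduced by the scalar estimator; the replicate median is reported
  together with all replicates.
* **Approximate ESS**: mean distance `D̄(k)` over all in-order pairs at
  lag k is compared with `D̄_∞`, the mean distance over 500 seeded random
  pairs (an unbiased estimate of the all-pairs mean at a fraction of the
  O(N²) cost; the pair count is a parameter). The topological
  autocorrelation `ρ(k) = max(0, 1 − D̄(k)/D̄_∞)` enters the same ESS
  formula, truncated at the first zero.

On the regenerating ("sticky") chain that stays with probability α and
otherwise redraws from its stationary law, any state indicator has exact
lag-k autocorrelation α^k, so ACT = (1+α)/(1−α). Both topological
estimators are validated against this closed form (within 25% at
N = 20,000 for α ∈ {0.5, 0.8}); exact numerical equality with any
particular third-party implementation is not claimed — the definition
above reproduces the documented behaviour (autocorrelation of topological
distances), which is what the analytic oracle can check.

## MCC summarization

The MCC tree is the sampled tree maximizing `Σ log f(c)` over its
non-trivial clades (leaf sets and the root clade excluded; a clade of
frequency 1 contributes 0). The candidate set is the sample itself — no
majority-rule synthesis — so the returned tree is always a realized
topology. Ties (score difference ≤ 1e-12 between distinct topologies) go
to the earliest sample and are logged.

Node ages are computed under ultrametricity (`age = height − depth`,
leaves clamped to 0; trees whose root-to-leaf spread exceeds a tolerance,
default 1e-6 × height, are rejected). Each MCC clade is summarized
**only over the trace trees containing it** (posterior median + HPD),
matching the default behaviour of the standard tree annotator this
replaces; a consequence is that child medians can exceed parent medians
when the clades occur in different tree subsets — these inversions are
warned about and reported as-is, never clipped.

The HPD at level γ is the smallest-width window of `⌈γn⌉` order
statistics, earliest window on ties. Published "95% CI" values are
interpreted as HPD; an equal-tailed `central` option is provided since
the labelling is ambiguous in much of the literature. Divergence-time
queries resolve a taxon set to its MRCA clade in the MCC tree; sets that
are not monophyletic there are summarized at the MRCA and flagged rather
than rejected, since paraphyly of a queried group is itself a finding.

## Haplotypes and the length diagnostic

Haplotypes are equivalence classes of identical uppercased residue
strings. IUPAC ambiguity codes are **not** expanded (an `N` vs `A`
mismatch separates haplotypes): expansion would silently merge
distinguishable sequencing outcomes; instead records carrying ambiguity
codes are listed in a warning so the analyst can decide. Gaps, when
present, are ordinary characters (the supported COI matrices are
indel-free, so this path is exceptional). The default length classifier
ships the four diagnostic ITS1 amplicon classes with tolerance 0 and
warns that the 110/111 bp pair is indistinguishable on agarose gels; any
positive tolerance makes those two classes formally ambiguous, and
ambiguous calls list their candidates.

Heterozygous cloned nuclear variants are counted as distinct sequences;
specimen-level aggregation (both alleles vs one per specimen) is left to
the caller, as the mapping is a study-design decision.

## Synthetic generators (what they emulate, and what not)

**Sticky chains** emulate the one property of a Bayesian tree sampler
that the estimators under test depend on — an autocorrelated sequence of
topologies with a well-defined stationary law — while keeping both the
stationary clade probabilities (sum of π over the enumerated topologies,
(2n−3)!! of them, guarded at n ≤ 6) and the autocorrelation time exact.
They do *not* emulate the local-move geometry of real tree proposals
(NNI/SPR random walks), mixed convergence across tree regions, or any
likelihood landscape; a pass against the sticky oracle shows estimator
correctness, not that any real chain has converged.

**Birth–death / relaxed-clock / GTR+Γ+I simulation** follows the
generative model of the supported analyses. Defaults are the study
conditions where stated: gamma shape fixed at 11.1 with 6
equal-probability categories (category means; mean of the multipliers is
1 by construction), clock mean 0.0115 substitutions·site⁻¹·Myr⁻¹
(standard arthropod mitochondrial rate) or 0.004 in nuclear mode,
alignment length 658 bp (the COI fragment). Where only priors are
stated, fixed defaults are central values of those priors — speciation
rate e¹ ≈ 2.72 events/Myr (median of Lognormal(1, 1.25), log-scale
parameters, the convention of the inference software whose priors these
are), relative extinction 1/3 (mean of Beta(1, 2)), clock stdev
0.206 (mean of Gamma(0.5396, 0.3819)), invariant proportion 0.5 (mean of
Uniform(0, 1)), flat exchangeabilities and base frequencies — and
`sample_model_priors` draws full configurations from the priors
themselves for prior-predictive work.

Numerical choices: the birth–death simulator runs forward from a single
lineage and stops by the simple-sampling rule (first time the extant
count reaches n, advanced by a uniform fraction of the next inter-event
time), prunes extinct lineages and rejects runs that die out (budget
10⁵ attempts) — simple and adequate at the small n used here; the
uncorrelated lognormal clock pins the **real-scale** mean to the clock
mean (`log-mean = ln(mean) − stdev²/2`), stated explicitly because both
conventions exist; the GTR matrix is normalized to one expected
substitution per unit at equilibrium so branch lengths read as
substitutions/site; with invariant sites the overall mean site rate is
(1 − p_inv), i.e. variable-site multipliers are not re-inflated.

## Problem sizes and determinism

The validation suite works at desk scale chosen for tight oracles:
5-taxon topology spaces (105 trees, exhaustively enumerable), chains of
5,000–20,000 samples, alignments up to 50,000 sites for the Jukes–Cantor
closed-form check, 500-replicate coverage experiments (binomial ±3%
band). All generators and estimators take explicit seeds; runs are
bit-reproducible given a seed.

## Known limitations

* Burn-in applies to retained (post-thinning) samples, not generations;
  traces are assumed already thinned.
* Multiple chains are first-class but never pooled implicitly; pooling
  is an explicit option, and per-chain plus pooled results are all
  reported, since published bounds rarely state which was used.
* The MCC candidate set excludes unsampled topologies; for very diffuse
  posteriors the true clade-credibility optimum may be unsampled.
* Node-age summaries require ultrametric input; trees with missing
  branch lengths are rejected rather than imputed.
* `DATA`/`CHARACTERS` NEXUS blocks are not parsed (alignments come in as
  FASTA), and reticulate structures are out of scope.
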