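# phylotrace

Posterior tree-trace analysis for Bayesian phylogenetics, built around the
questions that arise when testing island-colonization scenarios with dated
molecular phylogenies: *do these taxa form a clade, and how sure is the
posterior?* — asked of species such as the Réunion Island black flies
(*Simulium*, Diptera: Simuliidae), where monophyly of the island fauna
separates *in-situ* diversification from repeated colonization.

The package consumes posterior tree samples produced elsewhere (e.g. by a
Bayesian MCMC sampler, as NEXUS trees files with translate blocks and
`[&...]` metadata, or plain Newick) and provides:

* **Monophyly tests as posterior odds.** For a hypothesis *H* (a taxon
  set), `P(H|D)` is estimated as the frequency of posterior trees in which
  *H* is a clade, and the posterior odd is

  ```
  odd(H) = P(H|D) / (1 − P(H|D))
  ```

  When the clade never occurs in the sample the frequency estimator is
  uninformative and `P(H|D)` is bounded above by `1/ESS_topology`, reported
  for both topological ESS bases: pseudo (`P`) and approximate (`A`). A
  clade present in every tree gets the symmetric lower bound
  `P(H|D) > 1 − 1/ESS_topology`.

* **Topological effective sample sizes.** Trees are embedded by their
  pairwise leaf path lengths; the *path distance* between two topologies is
  the Euclidean distance between those vectors. The pseudo-ESS applies the
  standard autocorrelation-time estimator `ESS = N / (1 + 2 Σ ρ̂_k)` to the
  series of distances to seeded focal trees (median over replicates); the
  approximate ESS builds a topological autocorrelation
  `ρ(k) = max(0, 1 − D̄(k)/D̄_∞)` from mean distances at lag *k*. Scalar
  parameter logs get the same estimator, with the usual ESS > 200
  convergence gate.

* **MCC summarization.** The maximum-clade-credibility tree (the sampled
  tree maximizing the product of posterior clade frequencies) annotated
  with clade supports, posterior **median node ages** and **95% HPD**
  intervals computed over the trees containing each clade, plus
  divergence-time tables for named taxon sets.

* **Haplotype tabulation.** Per-group collapsing of identical aligned
  sequences, shared-haplotype detection between populations (the
  mito-nuclear discordance check), and the ITS1 amplicon-length diagnostic
  (82 / 110 / 111 / 116 bp → *S. triplex* / *S. ruficorne* /
  *Simulium* sp. 1 / *S. borbonense*).

* **Synthetic generators with analytic truth.** A "sticky" topology chain
  whose stationary clade probabilities (enumeration over all rooted
  topologies, n ≤ 6) and autocorrelation time `(1+α)/(1−α)` are exact in
  closed form, and a birth–death / uncorrelated-lognormal-clock /
  GTR+Γ+I sequence simulator matching the generative model of the
  mitochondrial (COI) and nuclear (18S/28S) analyses it supports.

## Worked example

```python
from phylotrace import (MonophylyHypothesis, compute_ess_report,
                        monophyly_test, render_result_cells)
from phylotrace.synthetic import StickyChainConfig, sample_sticky_chain

config = StickyChainConfig(taxa=["borb", "rufi_RE", "rufi_AF", "trip", "out"],
                           alpha=0.8, n=5000, seed=1)
trace, truth = sample_sticky_chain(config)

ess = compute_ess_report(trace, seed=1)
print(f"N = {ess.n}, pseudo-ESS = {ess.pseudo_median:.1f}, "
      f"approx-ESS = {ess.approx:.1f}")

h = MonophylyHypothesis("H_rufi", frozenset({"rufi_RE", "rufi_AF"}))
result = monophyly_test(trace, h, ess)
print(f"P(H|D) = {result.frequency:.3f}  "
      f"(oracle {truth.clade_probability(h.taxa):.3f})")
print("report cells:", render_result_cells(result))
```

prints

```
N = 5000, pseudo-ESS = 522.6, approx-ESS = 573.5
P(H|D) = 0.092  (oracle 0.096)
report cells: {'p': '0.092', 'odds': '0.101'}
```

The chain of 5,000 correlated samples (stickiness α = 0.8) is worth about
520–570 independent topology draws. The clade `{rufi_RE, rufi_AF}`
appears in 9.2% of the sampled trees — within Monte-Carlo error of the
9.6% implied by the chain's known stationary distribution — so monophyly
is about ten times less likely than non-monophyly (odd 0.101). Had the
frequency been zero, the same call would have returned the two bound
cells, e.g. `< 1.1 x 10-4 (P)`.

The same operations are exposed as a command line:

```
phylotrace monophyly chain1.trees chain2.trees --hypotheses h.json --burnin 0.1
phylotrace summarize run.trees --pairs pairs.json --out-tree mcc.nex --out-table div.tsv
phylotrace haplotypes coi.fasta --groups groups.tsv --classify-lengths
phylotrace simulate sticky --taxa 5 --alpha 0.8 --n 20000 --seed 1 --out-prefix sim
```

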