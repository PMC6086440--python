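"""Synthetic data with analytically known truth, for testing every
pipeline stage without external downloads.

Two generators:

**Sticky topology chains.**  A Markov chain over the full set of rooted
binary topologies on up to 6 taxa: at each step the chain stays at the
current topology with probability ``alpha`` and otherwise redraws from
the stationary distribution ``pi``.  Because the chain regenerates with
probability ``1 - alpha``, the lag-k autocorrelation of any state
indicator is exactly ``alpha**k``, hence the autocorrelation time is
``(1 + alpha) / (1 - alpha)`` in closed form, and the stationary clade
probability of any taxon set is the enumeration sum of ``pi`` over
topologies containing it.  These exact quantities are the oracle for the
clade-posterior and topological-ESS estimators.

**Dated trees and alignments.**  Ultrametric birth-death trees
conditioned on the number of extant taxa, uncorrelated lognormal
per-branch rates, and GTR+G+I sequence evolution with the discrete-gamma
approximation (equal-probability categories, category means).  Defaults
follow the generative model of the black fly divergence study: clock
mean 0.0115 substitutions/site/Myr (the standard arthropod mitochondrial
rate; 0.004 for the nuclear mode), gamma shape fixed at 11.1 with six
categories, speciation rate ~ Lognormal(1, 1.25) (log scale), relative
extinction ~ Beta(1, 2), exchangeabilities ~ Gamma(1, 1), invariant
proportion ~ Uniform(0, 1), clock stdev ~ Gamma(shape 0.5396, scale
0.3819).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .errors import InputError, NumericalError
from .haplotypes import Alignment
from .treeio import TreeTrace, parse_newick

__all__ = [
    "StickyChainConfig",
    "SeqSimConfig",
    "SimTruth",
    "enumerate_rooted_topologies",
    "sample_sticky_chain",
    "simulate_bd_tree",
    "assign_relaxed_rates",
    "discrete_gamma_rates",
    "build_gtr_matrix",
    "simulate_alignment",
    "sample_model_priors",
    "write_fasta",
]

NUCLEOTIDES = "ACGT"

# -- study-condition constants -------------------------------------------
ARTHROPOD_MITO_RATE = 0.0115   # substitutions / site / Myr
NUCLEAR_RATE = 0.004           # calibrated to match the mito tree height
GAMMA_SHAPE = 11.1             # fixed; prior CV of site rates ~ 0.3
GAMMA_CATEGORIES = 6
UCLD_STDEV_PRIOR = (0.5396, 0.3819)    # Gamma(shape, scale)
BIRTH_RATE_PRIOR = (1.0, 1.25)         # Lognormal(log-mean, log-sd)
RELATIVE_DEATH_PRIOR = (1.0, 2.0)      # Beta(a, b)


# ---------------------------------------------------------------------------
# topology enumeration and sticky chains
# ---------------------------------------------------------------------------

def _canonical(shape):
    """Canonicalize a nested-tuple topology: children ordered by their
    smallest descendant label."""
    if isinstance(shape, str):
        return shape
    children = tuple(sorted((_canonical(c) for c in shape), key=_min_label))
    return children


def _min_label(shape) -> str:
    if isinstance(shape, str):
        return shape
    return min(_min_label(c) for c in shape)


def _to_newick(shape) -> str:
    if isinstance(shape, str):
        return shape
    return "(" + ",".join(_to_newick(c) for c in shape) + ")"


def _insert_everywhere(shape, label):
    """All topologies obtained by attaching *label* on every edge of
    *shape*, including above the root."""
    results = [(shape, label)]
    if not isinstance(shape, str):
        for i, child in enumerate(shape):
            for sub in _insert_everywhere(child, label):
                results.append(tuple(shape[:i]) + (sub,) + tuple(shape[i + 1:]))
    return results


def enumerate_rooted_topologies(taxa: Sequence[str]) -> list[dendropy.Tree]:
    """All (2n-3)!! rooted binary labelled topologies on 2 <= n <= 6
    taxa, in a deterministic order (trees carry no branch lengths)."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 2:
        raise InputError("topology enumeration needs at least 2 taxa")
    if n > 6:
        raise InputError(
            f"refusing to enumerate rooted topologies for n = {n} > 6 "
            f"({_double_factorial(2 * n - 3)} trees)"
        )
    shapes = [(taxa[0], taxa[1])]
    for label in taxa[2:]:
        shapes = [s for shape in shapes for s in _insert_everywhere(shape, label)]
    canonical = [_canonical(s) for s in shapes]
    return [parse_newick(_to_newick(s) + ";") for s in canonical]


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


@dataclass
class StickyChainConfig:
    """Configuration of the regenerating topology chain."""

    taxa: Sequence[str]
    alpha: float = 0.0
    n: int = 1000
    seed: int = 0
    pi: np.ndarray | None = None  # None -> Dirichlet(1) drawn under seed

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise InputError(f"stickiness alpha must be in [0, 1); got {self.alpha}")
        if self.n < 1:
            raise InputError("chain length must be >= 1")
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=np.float64)
            if abs(pi.sum() - 1.0) > 1e-12:
                raise InputError("stationary distribution must sum to 1")
            self.pi = pi


@dataclass
class SimTruth:
    """Ground truth attached to a synthetic dataset."""

    act: float = 1.0
    pi: np.ndarray | None = None
    topologies: list[dendropy.Tree] = field(default_factory=list)
    clade_sets: list[set] = field(default_factory=list)
    tree: dendropy.Tree | None = None
    branch_rates: dict | None = None

    def clade_probability(self, taxa: Iterable[str]) -> float:
        """Stationary probability that *taxa* forms a clade: the sum of
        ``pi`` over topologies containing it (enumeration oracle)."""
        taxa = frozenset(taxa)
        if len(taxa) < 2:
            return 1.0
        return float(
            sum(
                p
                for p, clades in zip(self.pi, self.clade_sets)
                if taxa in clades
            )
        )


def sample_sticky_chain(config: StickyChainConfig) -> tuple[TreeTrace, SimTruth]:
    """Simulate the sticky chain; returns the trace (repeated tree
    objects are shared) and its analytic truth."""
    from .cladecalc import extract_clades  # local import: one-way deps

    topologies = enumerate_rooted_topologies(list(config.taxa))
    k = len(topologies)
    rng = np.random.default_rng(config.seed)
    pi = config.pi if config.pi is not None else rng.dirichlet(np.ones(k))

    fresh = rng.choice(k, size=config.n, p=pi)
    stay = rng.random(config.n) < config.alpha
    states = np.empty(config.n, dtype=np.int64)
    states[0] = fresh[0]
    for t in range(1, config.n):
        states[t] = states[t - 1] if stay[t] else fresh[t]

    trace = TreeTrace(
        trees=[topologies[s] for s in states],
        taxa=frozenset(config.taxa),
        indices=list(range(1, config.n + 1)),
        source=f"sticky(alpha={config.alpha}, seed={config.seed})",
    )
    truth = SimTruth(
        act=(1.0 + config.alpha) / (1.0 - config.alpha),
        pi=np.asarray(pi),
        topologies=topologies,
        clade_sets=[extract_clades(t) for t in topologies],
    )
    return trace, truth


# ---------------------------------------------------------------------------
# birth-death trees and relaxed clocks
# ---------------------------------------------------------------------------

@dataclass
class SeqSimConfig:
    """Generative model configuration (rates per Myr, lengths in bp)."""

    n_taxa: int = 8
    birth_rate: float = math.e          # prior median of Lognormal(1, 1.25)
    relative_death_rate: float = 1.0 / 3.0  # prior mean of Beta(1, 2)
    clock_mean: float = ARTHROPOD_MITO_RATE
    clock_stdev: float = UCLD_STDEV_PRIOR[0] * UCLD_STDEV_PRIOR[1]  # prior mean
    gtr_rates: tuple = (1.0,) * 6       # AC, AG, AT, CG, CT, GT
    base_freqs: tuple = (0.25,) * 4     # A, C, G, T
    gamma_shape: float = GAMMA_SHAPE
    gamma_categories: int = GAMMA_CATEGORIES
    p_inv: float = 0.5                  # prior mean of Uniform(0, 1)
    length: int = 658                   # the mitochondrial COI fragment
    seed: int = 0
    rejection_budget: int = 100_000

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise InputError("speciation rate must be positive")
        if not (0.0 <= self.relative_death_rate < 1.0):
            raise InputError("relative extinction rate must be in [0, 1)")
        if self.clock_mean <= 0 or self.clock_stdev < 0:
            raise InputError("invalid clock parameters")
        if any(r <= 0 for r in self.gtr_rates) or len(self.gtr_rates) != 6:
            raise InputError("need 6 positive GTR exchangeability rates")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise InputError("base frequencies must be 4 values summing to 1")
        if not (0.0 <= self.p_inv <= 1.0):
            raise InputError("invariant proportion must be in [0, 1]")
        if self.gamma_categories < 1 or self.gamma_shape <= 0:
            raise InputError("invalid gamma rate-heterogeneity settings")


def simulate_bd_tree(
    config: SeqSimConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Ultrametric birth-death tree with exactly ``n_taxa`` extant
    leaves, in Myr.

    Forward simulation from a single lineage; the first time the extant
    count reaches n the clock is advanced by a uniform fraction of the
    next inter-event time (simple-sampling stopping rule), extinct
    lineages are pruned, and runs that die out are rejected (budget
    ``rejection_budget``).
    """
    if config.n_taxa < 2:
        raise InputError("need at least 2 extant taxa")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lam = config.birth_rate
    mu = lam * config.relative_death_rate
    for _ in range(config.rejection_budget):
        result = _simulate_bd_once(config.n_taxa, lam, mu, rng)
        if result is not None:
            return _build_dendropy_tree(*result)
    raise NumericalError(
        f"birth-death rejection budget ({config.rejection_budget}) "
        f"exhausted before reaching {config.n_taxa} extant taxa; consider "
        f"different speciation/extinction rates"
    )


def _simulate_bd_once(n_target, lam, mu, rng):
    # lineage records: parent index, start time; end time filled on event
    parents = [-1]
    starts = [0.0]
    ends = [None]
    active = [0]
    t = 0.0
    total = lam + mu
    while True:
        k = len(active)
        if k == 0:
            return None
        if k == n_target:
            t += rng.random() * rng.exponential(1.0 / (k * total))
            break
        t += rng.exponential(1.0 / (k * total))
        pos = rng.integers(k)
        lineage = active[pos]
        if rng.random() < lam / total:  # birth: split into two children
            ends[lineage] = t
            for _ in range(2):
                parents.append(lineage)
                starts.append(t)
                ends.append(None)
            active[pos] = len(parents) - 2
            active.append(len(parents) - 1)
        else:  # death
            ends[lineage] = t
            active.pop(pos)
    for lineage in active:
        ends[lineage] = t
    return parents, starts, ends, set(active)


def _build_dendropy_tree(parents, starts, ends, extant):
    # keep lineages with an extant descendant, prune the rest
    keep = set(extant)
    for i in range(len(parents) - 1, -1, -1):
        if i in keep and parents[i] >= 0:
            keep.add(parents[i])
    children: dict[int, list[int]] = {}
    for i in sorted(keep):
        if parents[i] in keep:
            children.setdefault(parents[i], []).append(i)

    taxa_counter = [0]
    namespace = dendropy.TaxonNamespace()

    def build(i: int) -> dendropy.Node:
        kids = [c for c in children.get(i, []) if c in keep]
        # suppress pruned unary chains
        while len(kids) == 1:
            i = kids[0]
            kids = [c for c in children.get(i, []) if c in keep]
        node = dendropy.Node()
        if not kids:  # extant leaf
            taxa_counter[0] += 1
            node.taxon = namespace.require_taxon(label=f"t{taxa_counter[0]}")
            node.end_time = ends[i]
        else:
            node.end_time = ends[i]
            for c in kids:
                node.add_child(build(c))
        return node

    root_idx = min(keep)
    root = build(root_idx)
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = root
    # trim a unary stem above the crown
    while len(tree.seed_node.child_nodes()) == 1:
        tree.seed_node = tree.seed_node.child_nodes()[0]
        tree.seed_node.parent_node = None
    _set_branch_lengths(tree)
    return tree


def _set_branch_lengths(tree: dendropy.Tree) -> None:
    def recurse(node, start_time):
        node.edge.length = node.end_time - start_time if start_time is not None else None
        for child in node.child_nodes():
            recurse(child, node.end_time)

    recurse(tree.seed_node, None)


def assign_relaxed_rates(
    tree: dendropy.Tree,
    clock_mean: float,
    clock_stdev: float,
    seed: int = 0,
) -> dict[dendropy.Node, float]:
    """Uncorrelated lognormal branch rates keyed by child node.

    Parameterized so the *real-scale* mean equals ``clock_mean`` and the
    log-scale standard deviation equals ``clock_stdev``:
    ``log-mean = ln(clock_mean) - clock_stdev**2 / 2``.  A stdev of 0
    degenerates to a strict clock.
    """
    if clock_mean <= 0 or clock_stdev < 0:
        raise InputError("invalid clock parameters")
    rng = np.random.default_rng(seed)
    mu_log = math.log(clock_mean) - clock_stdev**2 / 2.0
    rates: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rates[node] = float(rng.lognormal(mu_log, clock_stdev)) if clock_stdev > 0 else clock_mean
    return rates


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def build_gtr_matrix(gtr_rates: Sequence[float], base_freqs: Sequence[float]) -> np.ndarray:
    """GTR rate matrix (exchangeabilities in AC, AG, AT, CG, CT, GT
    order) normalized to one expected substitution per unit time at
    equilibrium, so branch lengths read as substitutions/site."""
    r = np.asarray(gtr_rates, dtype=np.float64)
    pi = np.asarray(base_freqs, dtype=np.float64)
    if np.any(r <= 0):
        raise InputError("GTR exchangeability rates must be positive")
    ex = np.zeros((4, 4))
    ex[0, 1], ex[0, 2], ex[0, 3] = r[0], r[1], r[2]
    ex[1, 2], ex[1, 3] = r[3], r[4]
    ex[2, 3] = r[5]
    ex = ex + ex.T
    q = ex * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(q)))
    return q / scale


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-one rate multipliers of the equal-probability discrete gamma
    approximation (category means)."""
    if k == 1:
        return np.ones(1)
    scale = 1.0 / shape
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=scale)
    upper_cdf = gamma_dist.cdf(cuts, a=shape + 1.0, scale=scale)
    return k * np.diff(np.concatenate([[0.0], upper_cdf, [1.0]]))


def simulate_alignment(
    tree: dendropy.Tree,
    rates: dict[dendropy.Node, float],
    config: SeqSimConfig,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve sequences along *tree* under GTR+G+I.

    Each site is invariant with probability ``p_inv``; otherwise it gets
    a discrete-gamma rate multiplier.  Expected substitutions on a
    branch are ``duration x branch rate x site multiplier``; the root
    state is drawn from the equilibrium frequencies.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = config.length
    q = build_gtr_matrix(config.gtr_rates, config.base_freqs)
    pi = np.asarray(config.base_freqs, dtype=np.float64)
    multipliers = discrete_gamma_rates(config.gamma_shape, config.gamma_categories)

    invariant = rng.random(length) < config.p_inv
    category = rng.integers(config.gamma_categories, size=length)
    site_rate = np.where(invariant, 0.0, multipliers[category])

    states: dict[dendropy.Node, np.ndarray] = {}
    states[tree.seed_node] = rng.choice(4, size=length, p=pi)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise InputError("simulate_alignment needs branch lengths everywhere")
        parent_states = states[node.parent_node]
        child = parent_states.copy()
        branch_subs = node.edge.length * rates[node]
        for c, m in enumerate(multipliers):
            sites = np.where(~invariant & (category == c))[0]
            if sites.size == 0:
                continue
            p_mat = expm(q * branch_subs * m)
            p_mat = np.clip(p_mat, 0.0, None)
            p_mat /= p_mat.sum(axis=1, keepdims=True)
            for s in range(4):
                sel = sites[parent_states[sites] == s]
                if sel.size:
                    child[sel] = rng.choice(4, size=sel.size, p=p_mat[s])
        states[node] = child

    records = [
        (leaf.taxon.label, "".join(NUCLEOTIDES[s] for s in states[leaf]))
        for leaf in tree.leaf_node_iter()
    ]
    return Alignment(records=records)


def sample_model_priors(seed: int = 0, mode: str = "mitochondrial") -> SeqSimConfig:
    """Draw one configuration from the model's priors (prior-predictive
    generator).  The clock mean is fixed per *mode*: 0.0115
    substitutions/site/Myr (mitochondrial) or 0.004 (nuclear)."""
    if mode not in ("mitochondrial", "nuclear"):
        raise InputError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    birth = float(rng.lognormal(*BIRTH_RATE_PRIOR))
    rel_death = float(rng.beta(*RELATIVE_DEATH_PRIOR))
    exchange = tuple(float(x) for x in rng.gamma(1.0, 1.0, size=6))
    freqs = rng.dirichlet(np.ones(4))
    freqs = tuple(float(x) for x in freqs / freqs.sum())
    stdev = float(rng.gamma(UCLD_STDEV_PRIOR[0], UCLD_STDEV_PRIOR[1]))
    p_inv = float(rng.random())
    return SeqSimConfig(
        birth_rate=birth,
        relative_death_rate=rel_death,
        clock_mean=ARTHROPOD_MITO_RATE if mode == "mitochondrial" else NUCLEAR_RATE,
        clock_stdev=stdev,
        gtr_rates=exchange,
        base_freqs=freqs,
        p_inv=p_inv,
        seed=seed,
    )


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in alignment.records:
            fh.write(f">{rid}\n{seq}\n")
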