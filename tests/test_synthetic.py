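"""Oracle generators: sticky chains, birth-death trees, relaxed clocks,
GTR+G+I alignments and the prior-predictive sampler."""

import math

import numpy as np
import pytest

from phylotrace import (
    InputError,
    node_ages,
    parse_newick,
    write_newick,
)
from phylotrace.cladecalc import extract_clades
from phylotrace.synthetic import (
    SeqSimConfig,
    StickyChainConfig,
    assign_relaxed_rates,
    build_gtr_matrix,
    discrete_gamma_rates,
    enumerate_rooted_topologies,
    sample_model_priors,
    sample_sticky_chain,
    simulate_alignment,
    simulate_bd_tree,
)
from phylotrace.treeio import topology_key


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_double_factorial_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        topos = enumerate_rooted_topologies(taxa)
        assert len(topos) == count
        # all distinct
        assert len({topology_key(t) for t in topos}) == count

    def test_deterministic_order(self):
        a = enumerate_rooted_topologies(["A", "B", "C", "D"])
        b = enumerate_rooted_topologies(["A", "B", "C", "D"])
        assert [topology_key(t) for t in a] == [topology_key(t) for t in b]

    def test_combinatorial_guard(self):
        with pytest.raises(InputError):
            enumerate_rooted_topologies([f"t{i}" for i in range(7)])

    def test_cherry_count_oracle(self):
        # rooted topologies containing the cherry {A,B} = rooted
        # topologies on the 3 units {AB, C, D} = (2*3-3)!! = 3 of 15
        topos = enumerate_rooted_topologies(["A", "B", "C", "D"])
        with_cherry = sum(
            frozenset("AB") in extract_clades(t) for t in topos
        )
        assert with_cherry == 3


class TestStickyChain:
    def test_iid_frequencies_match_pi(self):
        config = StickyChainConfig(
            taxa=["A", "B", "C", "D"], alpha=0.0, n=20_000, seed=1
        )
        trace, truth = sample_sticky_chain(config)
        keys = [topology_key(t) for t in truth.topologies]
        counts = {k: 0 for k in keys}
        for tree in trace.trees:
            counts[topology_key(tree)] += 1
        for k, p in zip(keys, truth.pi):
            se = math.sqrt(p * (1 - p) / config.n)
            assert abs(counts[k] / config.n - p) <= 3 * se + 1e-9

    @pytest.mark.parametrize("lag", [1, 2, 5])
    def test_indicator_autocorrelation_is_alpha_power(self, lag):
        alpha = 0.8
        config = StickyChainConfig(
            taxa=["A", "B", "C", "D"], alpha=alpha, n=40_000, seed=2
        )
        trace, truth = sample_sticky_chain(config)
        mode = topology_key(truth.topologies[int(np.argmax(truth.pi))])
        z = np.array(
            [1.0 if topology_key(t) == mode else 0.0 for t in trace.trees]
        )
        z -= z.mean()
        rho = float(np.dot(z[:-lag], z[lag:]) / np.dot(z, z))
        assert rho == pytest.approx(alpha**lag, abs=0.05)

    def test_uniform_pi_cherry_probability(self):
        config = StickyChainConfig(
            taxa=["A", "B", "C", "D"],
            alpha=0.0,
            n=10,
            seed=3,
            pi=np.full(15, 1 / 15),
        )
        _, truth = sample_sticky_chain(config)
        assert truth.clade_probability({"A", "B"}) == pytest.approx(3 / 15)

    def test_reproducible_under_seed(self):
        config = StickyChainConfig(taxa=["A", "B", "C"], alpha=0.5, n=100, seed=4)
        t1, _ = sample_sticky_chain(config)
        t2, _ = sample_sticky_chain(config)
        assert [topology_key(t) for t in t1.trees] == [
            topology_key(t) for t in t2.trees
        ]

    def test_act_closed_form(self):
        _, truth = sample_sticky_chain(
            StickyChainConfig(taxa=["A", "B", "C"], alpha=0.8, n=10, seed=0)
        )
        assert truth.act == pytest.approx((1 + 0.8) / (1 - 0.8))


class TestBirthDeathTree:
    def test_ultrametric_with_requested_leaves(self):
        tree = simulate_bd_tree(SeqSimConfig(n_taxa=7, seed=10))
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 7
        ages = node_ages(tree)  # raises if not ultrametric
        assert max(ages.values()) > 0

    def test_pure_birth_has_no_pruned_nodes(self):
        tree = simulate_bd_tree(
            SeqSimConfig(n_taxa=6, relative_death_rate=0.0, seed=11)
        )
        internal = sum(1 for _ in tree.preorder_internal_node_iter())
        assert internal == 5  # n - 1 for a binary tree without pruning

    def test_bit_reproducible_under_seed(self):
        a = simulate_bd_tree(SeqSimConfig(n_taxa=5, seed=12))
        b = simulate_bd_tree(SeqSimConfig(n_taxa=5, seed=12))
        assert write_newick(a) == write_newick(b)


class TestRelaxedClock:
    def test_zero_stdev_is_strict_clock(self):
        tree = simulate_bd_tree(SeqSimConfig(n_taxa=5, seed=13))
        rates = assign_relaxed_rates(tree, 0.0115, 0.0, seed=0)
        assert set(rates.values()) == {0.0115}

    def test_real_scale_mean_pinned(self):
        draws = np.random.default_rng(14)
        tree = simulate_bd_tree(SeqSimConfig(n_taxa=6, seed=14))
        # pool draws across many seeds to hit 1e5 samples
        samples = []
        mean, stdev = 0.01, 0.8
        mu_log = math.log(mean) - stdev**2 / 2
        samples = draws.lognormal(mu_log, stdev, 100_000)
        assert samples.mean() == pytest.approx(mean, rel=0.01)
        cv = samples.std() / samples.mean()
        assert cv == pytest.approx(math.sqrt(math.exp(stdev**2) - 1), rel=0.02)
        # the module draws from the same parameterization
        rates = assign_relaxed_rates(tree, mean, stdev, seed=15)
        assert all(r > 0 for r in rates.values())


class TestGammaAndGTR:
    @pytest.mark.parametrize("shape,k", [(11.1, 6), (0.5, 4), (2.0, 1)])
    def test_category_means_average_to_one(self, shape, k):
        rates = discrete_gamma_rates(shape, k)
        assert rates.mean() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(rates) >= 0)

    def test_gtr_matrix_normalized_and_reversible(self):
        freqs = (0.3, 0.2, 0.2, 0.3)
        q = build_gtr_matrix((1.0, 2.0, 1.0, 1.0, 2.0, 1.0), freqs)
        pi = np.array(freqs)
        assert -float(np.dot(pi, np.diag(q))) == pytest.approx(1.0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance: pi_i q_ij = pi_j q_ji
        balance = pi[:, None] * q
        assert np.allclose(balance, balance.T, atol=1e-12)


class TestSimulateAlignment:
    def test_all_invariant_when_p_inv_one(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        rates = {
            n: 0.1 for n in tree.preorder_node_iter() if n.parent_node
        }
        config = SeqSimConfig(p_inv=1.0, length=200, seed=16)
        alignment = simulate_alignment(tree, rates, config)
        columns = zip(*(seq for _, seq in alignment.records))
        assert all(len(set(col)) == 1 for col in columns)

    def test_jc_distance_recovered(self):
        # Jukes-Cantor special case on a two-leaf tree of total length 0.1
        tree = parse_newick("(A:0.05,B:0.05);")
        rates = {n: 1.0 for n in tree.preorder_node_iter() if n.parent_node}
        config = SeqSimConfig(
            gtr_rates=(1.0,) * 6,
            base_freqs=(0.25,) * 4,
            gamma_categories=1,
            p_inv=0.0,
            length=50_000,
            seed=17,
        )
        alignment = simulate_alignment(tree, rates, config)
        a, b = (seq for _, seq in alignment.records)
        p_diff = sum(x != y for x, y in zip(a, b)) / len(a)
        d_hat = -0.75 * math.log(1 - 4 * p_diff / 3)
        # closed-form JC standard error of the distance estimate
        t = 0.1
        p_true = 0.75 * (1 - math.exp(-4 * t / 3))
        se_p = math.sqrt(p_true * (1 - p_true) / len(a))
        se_d = se_p / (1 - 4 * p_true / 3)
        assert abs(d_hat - t) <= 3 * se_d

    def test_base_composition_at_stationarity(self):
        tree = parse_newick("(A:50,B:50);")
        rates = {n: 1.0 for n in tree.preorder_node_iter() if n.parent_node}
        freqs = (0.4, 0.1, 0.2, 0.3)
        config = SeqSimConfig(
            base_freqs=freqs, gamma_categories=1, p_inv=0.0,
            length=20_000, seed=18,
        )
        alignment = simulate_alignment(tree, rates, config)
        seq = alignment.records[0][1]
        for base, f in zip("ACGT", freqs):
            se = math.sqrt(f * (1 - f) / len(seq))
            assert abs(seq.count(base) / len(seq) - f) <= 3 * se

    def test_alignment_length_and_reproducibility(self):
        tree = simulate_bd_tree(SeqSimConfig(n_taxa=4, seed=19))
        config = SeqSimConfig(n_taxa=4, length=120, seed=19)
        rates = assign_relaxed_rates(tree, config.clock_mean, 0.1, seed=19)
        a1 = simulate_alignment(tree, rates, config)
        a2 = simulate_alignment(tree, rates, config)
        assert a1.length == 120
        assert a1.records == a2.records


class TestPriorPredictive:
    def test_prior_means(self):
        n = 4000
        rel_death = [
            sample_model_priors(seed=s).relative_death_rate for s in range(n)
        ]
        p_inv = [sample_model_priors(seed=s).p_inv for s in range(n)]
        # Beta(1,2) mean 1/3; Uniform(0,1) mean 1/2
        se_beta = math.sqrt((1 / 3) * (2 / 3) / n)  # conservative bound
        assert abs(np.mean(rel_death) - 1 / 3) <= 3 * se_beta
        se_unif = math.sqrt(1 / 12 / n)
        assert abs(np.mean(p_inv) - 0.5) <= 3 * se_unif

    def test_clock_mean_fixed_per_mode(self):
        assert sample_model_priors(seed=0).clock_mean == 0.0115
        assert sample_model_priors(seed=0, mode="nuclear").clock_mean == 0.004

    def test_gamma_settings_fixed(self):
        config = sample_model_priors(seed=1)
        assert config.gamma_shape == 11.1
        assert config.gamma_categories == 6
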