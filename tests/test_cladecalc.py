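"""Clade extraction, monophyly posterior odds, and 1/ESS bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylotrace import (
    InputError,
    MonophylyHypothesis,
    NumericalError,
    clade_posterior,
    extract_clades,
    format_bound,
    is_monophyletic,
    monophyly_test,
    parse_newick,
    posterior_odds,
    render_result_cells,
)
from phylotrace.cladecalc import load_hypotheses
from phylotrace.treedist_ess import ESSReport
from phylotrace.synthetic import StickyChainConfig, sample_sticky_chain

from conftest import make_trace


class TestExtractClades:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("((A,B),C);", {frozenset("AB"), frozenset("ABC")}),
            ("(A,B,C);", {frozenset("ABC")}),
            (
                "(((A,B),C),D);",
                {frozenset("AB"), frozenset("ABC"), frozenset("ABCD")},
            ),
        ],
    )
    def test_clade_sets(self, newick, expected):
        assert extract_clades(parse_newick(newick)) == expected


class TestIsMonophyletic:
    def test_cherry_is_clade(self):
        assert is_monophyletic(parse_newick("((A,B),C);"), {"A", "B"})

    def test_split_pair_is_not(self):
        assert not is_monophyletic(parse_newick("((A,B),C);"), {"A", "C"})

    def test_full_taxon_set_is_root_clade(self):
        assert is_monophyletic(parse_newick("((A,B),C);"), {"A", "B", "C"})

    def test_unknown_taxa_listed(self):
        with pytest.raises(InputError, match="X"):
            is_monophyletic(parse_newick("((A,B),C);"), {"A", "X"})


class TestCladePosterior:
    def test_frequency_estimator(self):
        trace = make_trace(
            ["((A,B),C);", "((A,C),B);", "((B,C),A);", "((A,C),B);"]
        )
        assert clade_posterior(trace, {"A", "B"}) == 0.25

    def test_root_clade_always_one(self):
        trace = make_trace(["((A,B),C);", "((A,C),B);"])
        assert clade_posterior(trace, {"A", "B", "C"}) == 1.0

    def test_invariant_under_trace_reordering(self):
        newicks = ["((A,B),C);", "((A,C),B);", "((B,C),A);"]
        forward = clade_posterior(make_trace(newicks), {"A", "B"})
        backward = clade_posterior(make_trace(newicks[::-1]), {"A", "B"})
        assert forward == backward

    def test_sticky_chain_matches_enumeration_oracle(self):
        """At small N the frequency estimator must fall within 3 MC
        standard errors (from the analytic ACT) of the sum-of-pi oracle."""
        config = StickyChainConfig(
            taxa=["A", "B", "C", "D", "E"], alpha=0.5, n=4000, seed=9
        )
        trace, truth = sample_sticky_chain(config)
        for clade in [{"A", "B"}, {"C", "D", "E"}, {"A", "B", "C"}]:
            p_true = truth.clade_probability(clade)
            se = np.sqrt(truth.act * p_true * (1 - p_true) / len(trace))
            assert abs(clade_posterior(trace, clade) - p_true) <= 3 * se


class TestPosteriorOdds:
    def test_published_worked_value(self):
        assert round(posterior_odds(0.096), 3) == 0.106

    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.9, 9.0)])
    def test_simple_odds(self, p, expected):
        assert posterior_odds(p) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_frequency_directed_to_bound_path(self, p):
        with pytest.raises(NumericalError, match="bound"):
            posterior_odds(p)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_symmetry_and_monotonicity(self, p):
        assert posterior_odds(p) * posterior_odds(1 - p) == pytest.approx(1.0)
        if p < 0.5:
            assert posterior_odds(p) < posterior_odds(0.5)


def _ess_report(n, pseudo, approx):
    return ESSReport(n=n, pseudo_median=pseudo, approx=approx)


class TestMonophylyTest:
    def test_exact_frequency_path(self):
        # clade present in 96 of 1000 trees -> P = 0.096, odd = 0.106
        newicks = ["((A,B),C);"] * 96 + ["((A,C),B);"] * 904
        trace = make_trace(newicks)
        result = monophyly_test(
            trace,
            MonophylyHypothesis("H2", frozenset("AB")),
            _ess_report(1000, 500.0, 600.0),
        )
        assert result.kind == "exact"
        assert result.p == pytest.approx(0.096)
        assert result.odds == pytest.approx(0.096 / 0.904)
        cells = render_result_cells(result)
        assert cells == {"p": "0.096", "odds": "0.106"}

    def test_zero_frequency_upper_bounds_both_bases(self):
        trace = make_trace(["((A,C),B);"] * 10)
        result = monophyly_test(
            trace,
            MonophylyHypothesis("H", frozenset("AB")),
            _ess_report(10, 9090.9, 13889.0),
        )
        assert result.kind == "upper"
        # bound is exactly 1/ESS before any rounding
        assert result.bounds["P"][0] == pytest.approx(1 / 9090.9)
        assert result.bounds["A"][0] == pytest.approx(1 / 13889.0)
        cells = render_result_cells(result)
        assert cells["p_P"] == "< 1.1 x 10-4 (P)"
        assert cells["p_A"] == "< 7.2 x 10-5 (A)"

    def test_frequency_one_lower_bound(self):
        trace = make_trace(["((A,B),C);"] * 5)
        result = monophyly_test(
            trace,
            MonophylyHypothesis("root-ish", frozenset("AB")),
            _ess_report(5, 100.0, 100.0),
        )
        assert result.kind == "lower"
        assert result.bounds["P"][0] == pytest.approx(1 - 1 / 100.0)
        assert render_result_cells(result)["p_P"].startswith(">")

    def test_missing_ess_rejected(self):
        trace = make_trace(["((A,C),B);"] * 3)
        with pytest.raises(NumericalError):
            monophyly_test(
                trace,
                MonophylyHypothesis("H", frozenset("AB")),
                _ess_report(3, None, 50.0),
            )


class TestFormatting:
    @pytest.mark.parametrize(
        "value,basis,expected",
        [
            (1 / 9090.9, "P", "< 1.1 x 10-4 (P)"),
            (1 / 13889.0, "A", "< 7.2 x 10-5 (A)"),
            (2.2e-4, "P", "< 2.2 x 10-4 (P)"),
            (2.0e-4, "A", "< 2.0 x 10-4 (A)"),
        ],
    )
    def test_two_sigfig_bound_style(self, value, basis, expected):
        assert format_bound(value, basis) == expected


class TestHypothesisFiles:
    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "h.json"
        path.write_text('[{"name": "H1", "taxa": ["A", "B"]}]')
        hyps = load_hypotheses(path)
        assert hyps[0].name == "H1" and hyps[0].taxa == frozenset("AB")

    def test_plain_text(self, tmp_path):
        path = tmp_path / "h.txt"
        path.write_text("H1\tA,B\nH2\tB, C\n")
        hyps = load_hypotheses(path)
        assert [h.name for h in hyps] == ["H1", "H2"]
        assert hyps[1].taxa == frozenset("BC")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "h.txt"
        path.write_text("")
        with pytest.raises(InputError):
            load_hypotheses(path)

    def test_singleton_hypothesis_rejected(self):
        with pytest.raises(InputError):
            MonophylyHypothesis("H", frozenset("A"))
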