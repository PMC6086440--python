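"""Clade posterior probabilities and monophyly tests as posterior odds.

The monophyly of a taxon set H is tested against a posterior sample of
trees: P(H|D) is estimated as the frequency of sampled trees in which H
forms a clade, and the posterior odd is P(H|D) / (1 - P(H|D)) — how many
times more likely monophyly is than non-monophyly under the posterior.

When the clade never appears in the sample the frequency estimator is
uninformative, and P(H|D) is instead bounded above by 1/ESS_topology,
the reciprocal of the topological effective sample size of the trace.
Both topological ESS bases are reported: "P" (pseudo-ESS, median over
focal-tree replicates) and "A" (approximate ESS from the autocorrelation
of topological distances).  Symmetrically, a clade present in every
sampled tree (e.g. the root clade) gets the lower bound
P(H|D) > 1 - 1/ESS_topology.

Report formatting mirrors the conventions of published monophyly-odds
tables: exact values to 3 decimals, bounds to 2 significant figures in
the style ``< 1.1 x 10-4 (P)``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

from .errors import InputError, NumericalError
from .treeio import TreeTrace, leaf_labels

__all__ = [
    "Clade",
    "MonophylyHypothesis",
    "MonophylyResult",
    "extract_clades",
    "is_monophyletic",
    "clade_posterior",
    "posterior_odds",
    "monophyly_test",
    "load_hypotheses",
    "format_probability",
    "format_bound",
    "render_result_cells",
]

#: a clade is an immutable set of leaf labels
Clade = frozenset


@dataclass(frozen=True)
class MonophylyHypothesis:
    """A named taxon set whose monophyly is to be tested."""

    name: str
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise InputError(
                f"hypothesis {self.name!r}: a meaningful monophyly test "
                f"needs at least 2 taxa"
            )


@dataclass
class MonophylyResult:
    """Outcome of a monophyly test on one trace.

    ``kind`` is ``"exact"`` when the clade frequency is strictly between
    0 and 1 (then ``p`` and ``odds`` are set), ``"upper"`` for
    zero-frequency clades and ``"lower"`` for frequency-one clades (then
    ``bounds`` maps each ESS basis, "P" and "A", to the (probability,
    odds) bound pair).
    """

    hypothesis: str
    n: int
    frequency: float
    kind: str
    p: float | None = None
    odds: float | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "exact":
            assert self.p is not None and 0.0 < self.p < 1.0
            assert self.odds is not None
            assert math.isclose(self.odds, self.p / (1.0 - self.p))
        else:
            assert self.kind in ("upper", "lower") and self.bounds


def extract_clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Descendant leaf sets of all internal nodes (root included,
    single-leaf sets excluded)."""
    clades: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return clades


def _check_taxa(taxa: Iterable[str], tree_taxa: frozenset[str]) -> frozenset[str]:
    taxa = frozenset(taxa)
    unknown = sorted(taxa - tree_taxa)
    if unknown:
        raise InputError(f"taxa not present in tree: {', '.join(unknown)}")
    if not taxa:
        raise InputError("empty taxon set")
    return taxa


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff some node's descendant leaf set equals *taxa* exactly."""
    tree_taxa = frozenset(leaf_labels(tree))
    taxa = _check_taxa(taxa, tree_taxa)
    if len(taxa) == 1:
        return True  # a single leaf is trivially a clade
    return taxa in extract_clades(tree)


def clade_posterior(trace: TreeTrace, taxa: Iterable[str]) -> float:
    """Frequency of trace trees in which *taxa* forms a clade."""
    taxa = _check_taxa(taxa, trace.taxa)
    if len(taxa) == 1:
        return 1.0
    # sticky-chain traces repeat tree objects; cache clade sets per object
    cache: dict[int, set[frozenset[str]]] = {}
    count = 0
    for tree in trace.trees:
        key = id(tree)
        clades = cache.get(key)
        if clades is None:
            clades = extract_clades(tree)
            cache[key] = clades
        if taxa in clades:
            count += 1
    return count / len(trace)


def posterior_odds(p: float) -> float:
    """Posterior odd p / (1 - p) for an exact posterior probability."""
    if not (0.0 < p < 1.0):
        raise NumericalError(
            f"posterior odds undefined for P(H|D) = {p}; a frequency of 0 "
            f"or 1 must go through the 1/ESS bound path of monophyly_test"
        )
    return p / (1.0 - p)


def monophyly_test(
    trace: TreeTrace,
    hypothesis: MonophylyHypothesis,
    ess,  # ESSReport; not imported to keep module dependencies one-way
) -> MonophylyResult:
    """Full monophyly test: exact odds, or 1/ESS_topology bounds when the
    clade frequency is 0 (upper bound) or 1 (lower bound).

    The ESS report must come from the same trace; both its topological
    bases are used: pseudo ("P") and approximate ("A").
    """
    ess_by_basis = {"P": ess.pseudo_median, "A": ess.approx}
    for basis, value in ess_by_basis.items():
        if value is None or not (value >= 1.0):
            raise NumericalError(
                f"topological ESS ({basis} basis) missing or < 1; cannot "
                f"bound a zero-frequency clade probability"
            )
    freq = clade_posterior(trace, hypothesis.taxa)
    n = len(trace)
    if 0.0 < freq < 1.0:
        return MonophylyResult(
            hypothesis=hypothesis.name,
            n=n,
            frequency=freq,
            kind="exact",
            p=freq,
            odds=posterior_odds(freq),
        )
    bounds: dict[str, tuple[float, float]] = {}
    if freq == 0.0:
        for basis, value in ess_by_basis.items():
            b = 1.0 / value
            bounds[basis] = (b, b / (1.0 - b))
        kind = "upper"
    else:  # freq == 1.0; symmetric extension of the zero-frequency rule
        for basis, value in ess_by_basis.items():
            b = 1.0 - 1.0 / value
            bounds[basis] = (b, b / (1.0 - b))
        kind = "lower"
    return MonophylyResult(
        hypothesis=hypothesis.name, n=n, frequency=freq, kind=kind, bounds=bounds
    )


# ---------------------------------------------------------------------------
# hypothesis files and report formatting
# ---------------------------------------------------------------------------

def load_hypotheses(path: str | Path) -> list[MonophylyHypothesis]:
    """Read hypotheses from JSON (``[{"name":..., "taxa": [...]}, ...]``)
    or from plain text lines ``name <TAB> taxon,taxon,...``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"hypotheses file not found: {path}")
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise InputError(f"hypotheses file is empty: {path}")
    hypotheses: list[MonophylyHypothesis] = []
    if path.suffix.lower() == ".json" or text.startswith("["):
        entries = json.loads(text)
        for entry in entries:
            hypotheses.append(
                MonophylyHypothesis(entry["name"], frozenset(entry["taxa"]))
            )
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rest = line.partition("\t")
            if not rest:
                name, _, rest = line.partition(":")
            taxa = [t.strip() for t in re.split(r"[,\s]+", rest.strip()) if t.strip()]
            hypotheses.append(MonophylyHypothesis(name.strip(), frozenset(taxa)))
    if not hypotheses:
        raise InputError(f"no hypotheses parsed from {path}")
    return hypotheses


def format_probability(p: float, decimals: int = 3) -> str:
    """Exact probabilities and odds rendered to fixed decimals (0.106)."""
    return f"{p:.{decimals}f}"


def _two_sigfig(value: float) -> tuple[float, int]:
    exponent = math.floor(math.log10(abs(value)))
    mantissa = round(value / 10.0 ** exponent, 1)
    if mantissa >= 10.0:
        mantissa /= 10.0
        exponent += 1
    return mantissa, exponent


def format_bound(value: float, basis: str, *, lower: bool = False) -> str:
    """Bound cells in the published style: ``< 1.1 x 10-4 (P)``.

    Bounds of magnitude >= 1e-3 (e.g. the frequency-one lower bound) are
    printed as plain 2-significant-figure decimals.
    """
    symbol = ">" if lower else "<"
    if abs(value) >= 1e-3:
        return f"{symbol} {value:.2g} ({basis})"
    mantissa, exponent = _two_sigfig(value)
    return f"{symbol} {mantissa:.1f} x 10{exponent} ({basis})"


def render_result_cells(result: MonophylyResult, decimals: int = 3) -> dict[str, str]:
    """Probability and odds cells for one result, keyed ``p``/``odds`` for
    exact results and ``p_P``/``p_A``/``odds_P``/``odds_A`` for bounds."""
    if result.kind == "exact":
        return {
            "p": format_probability(result.p, decimals),
            "odds": format_probability(result.odds, decimals),
        }
    cells: dict[str, str] = {}
    lower = result.kind == "lower"
    for basis, (p_bound, odds_bound) in result.bounds.items():
        cells[f"p_{basis}"] = format_bound(p_bound, basis, lower=lower)
        cells[f"odds_{basis}"] = format_bound(odds_bound, basis, lower=lower)
    return cells
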