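"""Maximum-clade-credibility summarization of a posterior tree sample.

The MCC tree is the *sampled* tree maximizing the sum over its
non-trivial clades of the log posterior clade frequency (equivalently,
the product of clade frequencies); ties go to the earliest sample.  No
consensus topology is synthesized: the candidate set is the sample
itself.

Internal nodes of the MCC tree are annotated with the posterior clade
support and with node-age summaries (median and highest-posterior-
density interval) computed **only over the trace trees that contain the
clade** — the conditional-clade convention of standard tree annotators.
Child medians may exceed parent medians because they are computed on
different tree subsets; such inversions are reported with a warning,
never clipped.

``hpd_interval`` returns the smallest-width window over the sorted
samples containing ``ceil(level * n)`` points, earliest window on ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InputError, NumericalError
from .cladecalc import extract_clades
from .treeio import TreeTrace, leaf_labels, node_ages, write_annotated_nexus

__all__ = [
    "AgeSummary",
    "AnnotatedTree",
    "hpd_interval",
    "central_interval",
    "mcc_tree",
    "annotate_ages",
    "divergence_table",
    "write_mcc_nexus",
]

logger = logging.getLogger(__name__)


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a sample.

    The smallest-width window ``[x_(i), x_(i+m-1)]`` over the sorted
    sample containing ``m = ceil(level * n)`` points; ties broken by the
    earliest window.
    """
    x = np.sort(np.asarray(samples, dtype=np.float64))
    n = x.size
    if n == 0:
        raise NumericalError("HPD interval of an empty sample is undefined")
    if not (0.0 < level < 1.0):
        raise InputError(f"HPD level must be in (0, 1); got {level}")
    m = math.ceil(level * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: earliest tie
    return float(x[i]), float(x[i + m - 1])


def central_interval(
    samples: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Central (equal-tailed) credible interval — the alternative reading
    of a published '95% CI'."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise NumericalError("credible interval of an empty sample is undefined")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    return float(lo), float(hi)


@dataclass
class AgeSummary:
    """Posterior node-age summary for one clade of the MCC tree."""

    median: float
    lower: float
    upper: float
    level: float
    support: float
    count: int
    low_support: bool = False

    def __post_init__(self) -> None:
        assert self.lower <= self.median <= self.upper
        assert 0.0 < self.support <= 1.0 and self.count >= 1


@dataclass
class AnnotatedTree:
    """An MCC tree with per-internal-clade supports, its log credibility
    score, and (after :func:`annotate_ages`) age summaries."""

    tree: dendropy.Tree
    log_score: float
    supports: dict[frozenset, float]
    counts: dict[frozenset, int]
    summaries: dict[frozenset, AgeSummary] = field(default_factory=dict)
    tied: bool = False

    def internal_clades(self) -> list[frozenset]:
        return [
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in self.tree.preorder_internal_node_iter()
        ]


def _trace_clade_sets(trace: TreeTrace) -> list[set[frozenset]]:
    cache: dict[int, set[frozenset]] = {}
    out = []
    for tree in trace.trees:
        key = id(tree)
        if key not in cache:
            cache[key] = extract_clades(tree)
        out.append(cache[key])
    return out


def mcc_tree(trace: TreeTrace) -> AnnotatedTree:
    """Select the maximum-clade-credibility tree from a trace.

    Scoring uses the natural log of posterior clade frequencies over
    non-trivial clades (leaf sets and the root clade excluded; a clade of
    frequency 1 contributes 0).
    """
    n = len(trace)
    full = trace.taxa
    clade_sets = _trace_clade_sets(trace)

    freq: dict[frozenset, int] = {}
    for clades in clade_sets:
        for c in clades:
            if c != full:
                freq[c] = freq.get(c, 0) + 1

    best_pos, best_score, tied = 0, -math.inf, False
    for pos, clades in enumerate(clade_sets):
        score = sum(math.log(freq[c] / n) for c in clades if c != full)
        if score > best_score + 1e-12:
            best_pos, best_score, tied = pos, score, False
        elif abs(score - best_score) <= 1e-12 and clades != clade_sets[best_pos]:
            tied = True
    if tied:
        logger.warning(
            "MCC score tie between distinct topologies; returning the "
            "earliest sampled tree"
        )

    best = trace.trees[best_pos]
    supports = {}
    counts = {}
    for c in extract_clades(best):
        if c == full:
            supports[c] = 1.0
            counts[c] = n
        else:
            supports[c] = freq[c] / n
            counts[c] = freq[c]
    return AnnotatedTree(
        tree=best, log_score=best_score, supports=supports, counts=counts, tied=tied
    )


def annotate_ages(
    annotated: AnnotatedTree,
    trace: TreeTrace,
    level: float = 0.95,
    *,
    support_floor: float = 0.0,
    interval: str = "hpd",
) -> AnnotatedTree:
    """Attach posterior median node ages and credible intervals to every
    internal clade of the MCC tree.

    Ages are collected only from trace trees containing the clade.
    ``interval`` selects ``"hpd"`` (default) or ``"central"``.
    """
    if interval not in ("hpd", "central"):
        raise InputError(f"unknown interval type {interval!r}")
    window = hpd_interval if interval == "hpd" else central_interval

    clade_sets = _trace_clade_sets(trace)
    age_cache: dict[int, dict[frozenset, float]] = {}
    ages_by_clade: dict[frozenset, list[float]] = {
        c: [] for c in annotated.supports
    }
    for tree, clades in zip(trace.trees, clade_sets):
        key = id(tree)
        by_clade = age_cache.get(key)
        if by_clade is None:
            ages = node_ages(tree)
            by_clade = {
                frozenset(l.taxon.label for l in node.leaf_iter()): age
                for node, age in ages.items()
                if not node.is_leaf()
            }
            age_cache[key] = by_clade
        for c in ages_by_clade:
            if c in by_clade and (c in clades or c == trace.taxa):
                ages_by_clade[c].append(by_clade[c])

    for clade, ages in ages_by_clade.items():
        assert ages, "an MCC clade must occur in at least one sampled tree"
        lo, hi = window(ages, level)
        annotated.summaries[clade] = AgeSummary(
            median=float(np.median(ages)),
            lower=lo,
            upper=hi,
            level=level,
            support=annotated.supports[clade],
            count=len(ages),
            low_support=annotated.supports[clade] < support_floor,
        )

    # conditional-clade medians can invert parent/child order; warn only
    for node in annotated.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        child_c = frozenset(l.taxon.label for l in node.leaf_iter())
        parent_c = frozenset(
            l.taxon.label for l in node.parent_node.leaf_iter()
        )
        if (
            child_c in annotated.summaries
            and parent_c in annotated.summaries
            and annotated.summaries[child_c].median
            > annotated.summaries[parent_c].median
        ):
            logger.warning(
                "median age inversion: clade of %d taxa older than its "
                "parent (conditional-clade summaries); reported as-is",
                len(child_c),
            )
    return annotated


def divergence_table(
    annotated: AnnotatedTree,
    named_pairs: Iterable[tuple[str, Iterable[str]]],
) -> list[dict]:
    """Divergence-time rows for named taxon sets.

    Each taxon set is resolved to its MRCA clade in the MCC tree; sets
    that are not monophyletic there are summarized at the MRCA and
    flagged.
    """
    if not annotated.summaries:
        raise InputError("annotate_ages must run before divergence_table")
    full = frozenset(
        l.taxon.label for l in annotated.tree.seed_node.leaf_iter()
    )
    rows = []
    for label, taxa in named_pairs:
        taxa = frozenset(taxa)
        unknown = sorted(taxa - full)
        if unknown:
            raise InputError(
                f"divergence pair {label!r}: unknown taxa {', '.join(unknown)}"
            )
        containing = [c for c in annotated.summaries if taxa <= c]
        mrca = min(containing, key=len)
        summary = annotated.summaries[mrca]
        monophyletic = mrca == taxa
        if not monophyletic:
            logger.warning(
                "pair %r is not monophyletic in the MCC tree; using its "
                "MRCA (%d taxa)", label, len(mrca),
            )
        rows.append(
            {
                "label": label,
                "median": summary.median,
                "lower": summary.lower,
                "upper": summary.upper,
                "support": summary.support,
                "monophyletic": monophyletic,
            }
        )
    return rows


def format_divergence_row(row: dict) -> str:
    """One published-style line: ``label  12.87  11.11  15.75  1.00``."""
    flag = "" if row["monophyletic"] else "\t[MRCA]"
    return (
        f"{row['label']}\t{row['median']:.2f}\t{row['lower']:.2f}\t"
        f"{row['upper']:.2f}\t{row['support']:.2f}{flag}"
    )


def write_mcc_nexus(annotated: AnnotatedTree, path) -> None:
    """Write the annotated MCC tree as NEXUS with
    ``[&posterior=..,age_median=..,age_hpd={..,..}]`` node comments."""
    annotations: dict[dendropy.Node, dict[str, object]] = {}
    for node in annotated.tree.preorder_internal_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        ann: dict[str, object] = {}
        if clade in annotated.supports:
            ann["posterior"] = annotated.supports[clade]
        summary = annotated.summaries.get(clade)
        if summary is not None:
            ann["age_median"] = summary.median
            ann["age_hpd"] = (summary.lower, summary.upper)
        if ann:
            annotations[node] = ann
    write_annotated_nexus(annotated.tree, annotations, path)
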