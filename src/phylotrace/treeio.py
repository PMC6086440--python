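"""Reading, writing and basic geometry of rooted trees and tree traces.

Trees are represented as :class:`dendropy.Tree` objects (rooted, leaf
labels unique).  This module wraps dendropy's Newick/NEXUS readers with
the conventions used throughout the package:

* underscores in unquoted labels are preserved verbatim (sample IDs such
  as ``GY018_borb`` rely on this);
* bracketed ``[&...]`` metadata comments are stripped by default and can
  be retained on request;
* traces read from samplers are burned in by discarding the leading
  ``floor(burnin * N)`` trees — burn-in applies to the retained
  (post-thinning) samples, not to generations;
* canonical Newick output orders the children of every node by their
  smallest descendant leaf label, so topologically equal trees serialize
  identically.

Node ages are derived under ultrametricity: ``age(v) = height - depth(v)``
with leaves at age 0, where ``height`` is the maximum root-to-leaf path
length.  Trees whose root-to-leaf spread exceeds the tolerance are
rejected.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import InputError, NewickParseError

__all__ = [
    "PipelineConfig",
    "TreeTrace",
    "parse_newick",
    "read_nexus_trees",
    "read_tree_trace",
    "node_ages",
    "leaf_labels",
    "topology_key",
    "write_newick",
    "write_annotated_nexus",
]


@dataclass
class PipelineConfig:
    """Run-wide settings shared by every pipeline stage.

    Parameters mirror the conventions of the Bayesian workflow the
    pipeline consumes: 10% of retained samples discarded as burn-in, 95%
    HPD intervals, and a scalar-ESS convergence gate of 200.
    """

    burnin: float = 0.10
    hpd_level: float = 0.95
    ess_threshold: float = 200.0
    seed: int = 0
    odds_decimals: int = 3
    bound_sigfigs: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.burnin < 1.0):
            raise InputError(f"burn-in fraction must be in [0, 1); got {self.burnin}")
        if not (0.0 < self.hpd_level < 1.0):
            raise InputError(f"HPD level must be in (0, 1); got {self.hpd_level}")
        if self.ess_threshold <= 0:
            raise InputError("ESS gate threshold must be positive")


@dataclass
class TreeTrace:
    """An ordered post-burn-in sample of trees over one shared taxon set."""

    trees: list[dendropy.Tree]
    taxa: frozenset[str]
    indices: list[int] = field(default_factory=list)
    source: str = ""
    burnin: float = 0.0

    def __post_init__(self) -> None:
        if not self.trees:
            raise InputError("a tree trace must contain at least one tree after burn-in")
        if not self.indices:
            self.indices = list(range(1, len(self.trees) + 1))
        if len(self.indices) != len(self.trees):
            raise InputError("sample indices and trees differ in length")
        if any(b >= a for a, b in zip(self.indices[1:], self.indices[:-1])):
            raise InputError("sample indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    in_quote = False
    in_comment = False
    for pos, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if in_comment:
            if ch == "]":
                in_comment = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "[":
            in_comment = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character position {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of input "
            f"(position {len(text)})"
        )


def parse_newick(text: str, keep_comments: bool = False) -> dendropy.Tree:
    """Parse a single Newick string into a rooted tree.

    ``[&...]`` comments are discarded unless *keep_comments* is set, in
    which case ``key=value`` items are attached as node annotations.
    Raises :class:`NewickParseError` (with the offending character
    position where determinable) for syntax errors, and
    :class:`InputError` for duplicate leaf labels.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty Newick input at character position 0")
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=keep_comments,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        pos = ""
        col = getattr(exc, "col_num", None)
        if col is not None:
            pos = f" at character position {col}"
        raise NewickParseError(f"Newick parse error{pos}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise InputError(f"duplicate leaf labels: {', '.join(dupes)}")
    return tree


def _looks_like_nexus(path: str | Path) -> bool:
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        head = fh.read(256).lstrip()
    return head.upper().startswith("#NEXUS")


def _sample_index(label: str | None, fallback: int) -> int:
    if label:
        m = re.search(r"(\d+)\s*$", label)
        if m:
            return int(m.group(1))
    return fallback


def read_nexus_trees(
    path: str | Path,
    config: PipelineConfig | None = None,
    *,
    burnin: float | None = None,
    keep_comments: bool = False,
) -> TreeTrace:
    """Read a trees file (NEXUS with translate block, or plain Newick).

    Translate indices are replaced by taxon labels; ``[&...]`` comments
    are stripped (or retained as annotations per *keep_comments*).  The
    leading ``floor(burnin * N)`` trees are discarded.
    """
    if config is None:
        config = PipelineConfig()
    frac = config.burnin if burnin is None else burnin
    if not (0.0 <= frac < 1.0):
        raise InputError(f"burn-in fraction must be in [0, 1); got {frac}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"trees file not found: {path}")
    schema = "nexus" if _looks_like_nexus(path) else "newick"
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=keep_comments,
        )
    except Exception as exc:
        raise InputError(f"failed to read trees from {path}: {exc}") from exc
    if len(tree_list) == 0:
        raise InputError(f"no trees found in {path} (missing or empty TREES block)")

    taxa_sets = [frozenset(leaf_labels(t)) for t in tree_list]
    first = taxa_sets[0]
    for i, ts in enumerate(taxa_sets[1:], start=2):
        if ts != first:
            diff = sorted(ts.symmetric_difference(first))
            raise InputError(
                f"tree {i} in {path} has a different taxon set "
                f"(symmetric difference: {', '.join(diff)})"
            )

    n_discard = math.floor(frac * len(tree_list))
    kept = list(tree_list)[n_discard:]
    raw_indices = [
        _sample_index(getattr(t, "label", None), i + 1)
        for i, t in enumerate(tree_list)
    ][n_discard:]
    if any(b >= a for a, b in zip(raw_indices[1:], raw_indices[:-1])):
        raw_indices = list(range(n_discard + 1, len(tree_list) + 1))
    return TreeTrace(
        trees=kept,
        taxa=first,
        indices=raw_indices,
        source=str(path),
        burnin=frac,
    )


#: alias; the reader transparently handles plain-Newick trace files too
read_tree_trace = read_nexus_trees


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf labels in the tree's own traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_ages(
    tree: dendropy.Tree, tolerance: float | None = None
) -> dict[dendropy.Node, float]:
    """Node ages of an ultrametric tree (leaves at 0, root oldest).

    *tolerance* bounds the allowed spread of root-to-leaf path lengths;
    the default is ``1e-6 x tree height`` (relative, covering floating
    point drift in exported trees).  Non-root nodes must all carry branch
    lengths.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise InputError(
                f"missing branch length above node {label}; ages undefined"
            )
        depths[node] = depths[parent] + node.edge.length
    leaf_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    spread = height - min(leaf_depths)
    tol = tolerance if tolerance is not None else 1e-6 * max(height, 1.0)
    if spread > tol:
        raise InputError(
            f"tree is not ultrametric: root-to-leaf spread {spread:.6g} "
            f"exceeds tolerance {tol:.6g}"
        )
    ages = {node: height - depth for node, depth in depths.items()}
    for leaf in tree.leaf_node_iter():
        ages[leaf] = 0.0
    return ages


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_UNQUOTED = re.compile(r"^[\w.\-|/]+$")


def _quote_label(label: str) -> str:
    if _UNQUOTED.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length: float | None) -> str:
    if length is None:
        return ""
    return f":{length:.12g}"


def _min_leaf(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def _newick_recurse(node: dendropy.Node, comment_for, with_lengths: bool) -> str:
    if node.is_leaf():
        core = _quote_label(node.taxon.label)
    else:
        children = sorted(node.child_nodes(), key=_min_leaf)
        inner = ",".join(
            _newick_recurse(c, comment_for, with_lengths) for c in children
        )
        core = f"({inner})"
    comment = comment_for(node) if comment_for else ""
    length = _format_length(node.edge.length) if with_lengths else ""
    return f"{core}{comment}{length}"


def write_newick(tree: dendropy.Tree, *, with_lengths: bool = True) -> str:
    """Serialize to canonical Newick (children ordered by smallest leaf
    label; lengths at 12 significant digits)."""
    return _newick_recurse(tree.seed_node, None, with_lengths) + ";"


def topology_key(tree: dendropy.Tree) -> str:
    """Canonical, length-free Newick string identifying the topology."""
    return write_newick(tree, with_lengths=False)


def _format_annotation_value(value) -> str:
    if isinstance(value, (tuple, list)):
        return "{" + ",".join(_format_annotation_value(v) for v in value) + "}"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_annotated_nexus(
    tree: dendropy.Tree,
    annotations: Mapping[dendropy.Node, Mapping[str, object]],
    path: str | Path,
    *,
    tree_name: str = "MCC",
) -> None:
    """Write a single tree as NEXUS with per-node ``[&key=value,...]``
    comments in the dialect standard tree viewers read."""

    def comment_for(node: dendropy.Node) -> str:
        ann = annotations.get(node)
        if not ann:
            return ""
        items = ",".join(
            f"{k}={_format_annotation_value(v)}" for k, v in ann.items()
        )
        return f"[&{items}]"

    taxa = sorted(leaf_labels(tree))
    newick = _newick_recurse(tree.seed_node, comment_for, True) + ";"
    text = (
        "#NEXUS\n"
        "Begin taxa;\n"
        f"\tDimensions ntax={len(taxa)};\n"
        "\tTaxlabels\n"
        + "".join(f"\t\t{_quote_label(t)}\n" for t in taxa)
        + "\t\t;\nEnd;\n"
        "Begin trees;\n"
        f"tree {tree_name} = [&R] {newick}\n"
        "End;\n"
    )
    Path(path).write_text(text, encoding="utf-8")
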