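"""Path distances between topologies and effective-sample-size estimators.

Three ESS estimators support convergence assessment of a posterior tree
trace:

* ``scalar_ess`` — the classic autocorrelation-time estimator for a real
  series: ``ESS = N / (1 + 2 * sum_k rho_k)`` with the sum truncated at
  the first negative sample autocorrelation (capped at ``K_max``) and the
  result clamped to ``[1, N]``.
* ``pseudo_topo_ess`` — the topological *pseudo*-ESS: for each of
  ``n_focal`` focal trees drawn (seeded, with replacement) from the
  trace, the series of path distances from every sampled tree to the
  focal tree is reduced with ``scalar_ess``; the replicate median is the
  reported value.
* ``approx_topo_ess`` — the topological *approximate* ESS: the mean path
  distance between samples at lag k, ``D(k)``, is compared with the mean
  distance between far-apart samples ``D_inf`` (estimated from seeded
  random pairs); the topological autocorrelation is
  ``rho(k) = max(0, 1 - D(k)/D_inf)`` and the usual ESS formula is
  applied, truncated at the first zero.

The distance is the *path distance*: each topology T is embedded as the
vector of pairwise leaf path lengths ``p_ij(T)`` (number of edges on the
i–j path), and ``d(T1, T2)`` is the Euclidean distance between the two
vectors.  Branch lengths are ignored; trees are treated as rooted by
default (the degree-2 root contributes edges), with an unrooted option.

On a regenerating ("sticky") chain that stays put with probability
``alpha`` and otherwise redraws from its stationary law, the indicator
autocorrelation is exactly ``alpha**k``, so the autocorrelation time is
``(1+alpha)/(1-alpha)`` — the analytic oracle both topological
estimators are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, NumericalError
from .treeio import TreeTrace, leaf_labels

__all__ = [
    "ESSReport",
    "path_vector",
    "path_distance",
    "scalar_ess",
    "pseudo_topo_ess",
    "approx_topo_ess",
    "ess_gate",
    "compute_ess_report",
    "read_log_file",
]

K_MAX = 2000  # autocorrelation truncation cap (Tracer-style desk scale)


# ---------------------------------------------------------------------------
# path distance
# ---------------------------------------------------------------------------

def path_vector(
    tree: dendropy.Tree,
    taxa_order: Sequence[str] | None = None,
    *,
    rooted: bool = True,
) -> np.ndarray:
    """Vector of pairwise leaf path lengths (edge counts), ordered by the
    sorted taxon pair index (i < j over *taxa_order*).

    With ``rooted=False`` a degree-2 root is suppressed: paths crossing
    such a root count one edge fewer.
    """
    labels = sorted(leaf_labels(tree)) if taxa_order is None else list(taxa_order)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0 if parent is None else depth[parent] + 1
    leaf_depth = np.zeros(n, dtype=np.int64)
    for leaf in tree.leaf_node_iter():
        leaf_depth[index[leaf.taxon.label]] = depth[leaf]

    root = tree.seed_node
    root_degree_two = len(root.child_nodes()) == 2
    pair = np.zeros(n * (n - 1) // 2, dtype=np.float64)

    def pair_pos(i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    # leaves below each node, assembled postorder; pairs first joined at a
    # node have that node as their MRCA
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [index[node.taxon.label]]
            continue
        groups = [below[c] for c in node.child_nodes()]
        d_mrca = depth[node]
        unroot_adjust = 1 if (not rooted and node is root and root_degree_two) else 0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    di = leaf_depth[i]
                    for j in groups[b]:
                        pair[pair_pos(i, j)] = (
                            di + leaf_depth[j] - 2 * d_mrca - unroot_adjust
                        )
        merged: list[int] = []
        for g in groups:
            merged.extend(g)
        below[node] = merged

    return pair


def path_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, *, rooted: bool = True
) -> float:
    """Euclidean distance between the pairwise path-length vectors of two
    topologies sharing a leaf set.  Branch lengths are ignored."""
    s1, s2 = frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))
    if s1 != s2:
        diff = sorted(s1.symmetric_difference(s2))
        raise InputError(f"leaf sets differ: {', '.join(diff)}")
    order = sorted(s1)
    v1 = path_vector(t1, order, rooted=rooted)
    v2 = path_vector(t2, order, rooted=rooted)
    return float(np.linalg.norm(v1 - v2))


# ---------------------------------------------------------------------------
# scalar ESS
# ---------------------------------------------------------------------------

def _autocorrelations(series: np.ndarray, k_max: int) -> np.ndarray:
    """Sample autocorrelations rho_1..rho_k_max (biased normalization)."""
    x = series - series.mean()
    n = x.size
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[: k_max + 1].real / n
    return acov[1:] / acov[0]


def scalar_ess(series: Sequence[float], k_max: int | None = None) -> float:
    """Autocorrelation-time ESS of a real series.

    Truncates the lag sum at the first negative sample autocorrelation
    (capped at ``K_max``); clamps the result to ``[1, N]``.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < 10:
        raise NumericalError(f"series too short for ESS estimation (N = {n} < 10)")
    if np.ptp(x) == 0.0 or x.var() == 0.0:
        raise NumericalError("zero-variance series: ESS undefined (degenerate trace)")
    cap = min(n - 1, K_MAX if k_max is None else k_max)
    rho = _autocorrelations(x, cap)
    total = 0.0
    for r in rho:
        if r < 0.0:
            break
        total += r
    act = 1.0 + 2.0 * total
    return float(min(max(n / act, 1.0), n))


# ---------------------------------------------------------------------------
# topological ESS
# ---------------------------------------------------------------------------

def _trace_vectors(
    trace: TreeTrace, rooted: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Unique path vectors and the per-sample index into them.

    Trees repeated by object identity (as emitted by the sticky-chain
    generator) are vectorized once.
    """
    order = sorted(trace.taxa)
    by_obj: dict[int, int] = {}
    vectors: list[np.ndarray] = []
    idx = np.empty(len(trace), dtype=np.int64)
    for pos, tree in enumerate(trace.trees):
        key = id(tree)
        u = by_obj.get(key)
        if u is None:
            u = len(vectors)
            vectors.append(path_vector(tree, order, rooted=rooted))
            by_obj[key] = u
        idx[pos] = u
    return np.vstack(vectors), idx


def _require_distinct(v: np.ndarray, idx: np.ndarray) -> None:
    distinct = np.unique(v[idx], axis=0).shape[0]
    if distinct < 2:
        raise NumericalError(
            "trace contains a single distinct topology: topological ESS undefined"
        )


@dataclass
class PseudoESSResult:
    replicates: list[float]
    median: float
    n_focal: int
    seed: int


def pseudo_topo_ess(
    trace: TreeTrace,
    n_focal: int = 20,
    seed: int = 0,
    *,
    rooted: bool = True,
) -> PseudoESSResult:
    """Topological pseudo-ESS: median over focal-tree replicates of the
    scalar ESS of the distance-to-focal series."""
    v, idx = _trace_vectors(trace, rooted)
    _require_distinct(v, idx)
    rng = np.random.default_rng(seed)
    focal_positions = rng.integers(0, len(trace), size=n_focal)
    replicates: list[float] = []
    for pos in focal_positions:
        series = np.linalg.norm(v[idx] - v[idx[pos]], axis=1)
        replicates.append(scalar_ess(series))
    return PseudoESSResult(
        replicates=replicates,
        median=float(np.median(replicates)),
        n_focal=n_focal,
        seed=seed,
    )


def approx_topo_ess(
    trace: TreeTrace,
    max_lag: int | None = None,
    *,
    n_pairs: int = 500,
    seed: int = 0,
    rooted: bool = True,
) -> float:
    """Topological approximate ESS from the lag profile of mean path
    distances, with ``D_inf`` estimated from seeded random pairs."""
    v, idx = _trace_vectors(trace, rooted)
    _require_distinct(v, idx)
    n = len(trace)
    cap = min(n - 1, K_MAX) if max_lag is None else min(max_lag, n - 1)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    keep = i != j
    if not np.any(keep):
        raise NumericalError("could not draw distinct random pairs")
    d_inf = float(
        np.linalg.norm(v[idx[i[keep]]] - v[idx[j[keep]]], axis=1).mean()
    )
    if d_inf == 0.0:
        raise NumericalError("all sampled trees identical: D_inf = 0")
    total = 0.0
    for k in range(1, cap + 1):
        d_k = float(np.linalg.norm(v[idx[:-k]] - v[idx[k:]], axis=1).mean())
        rho = max(0.0, 1.0 - d_k / d_inf)
        if rho == 0.0:
            break
        total += rho
    act = 1.0 + 2.0 * total
    return float(min(max(n / act, 1.0), n))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ESSReport:
    """ESS summary of one trace: scalar ESS per parameter plus both
    topological bases."""

    n: int
    scalar: dict[str, float] = field(default_factory=dict)
    pseudo_replicates: list[float] = field(default_factory=list)
    pseudo_median: float | None = None
    approx: float | None = None
    n_focal: int = 20
    seed: int = 0

    def all_values(self) -> dict[str, float]:
        values = dict(self.scalar)
        if self.pseudo_median is not None:
            values["topology_pseudo"] = self.pseudo_median
        if self.approx is not None:
            values["topology_approx"] = self.approx
        return values

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "scalar": self.scalar,
            "pseudo_replicates": self.pseudo_replicates,
            "pseudo_median": self.pseudo_median,
            "approx": self.approx,
            "n_focal": self.n_focal,
            "seed": self.seed,
        }


def ess_gate(report: ESSReport, threshold: float = 200.0) -> dict[str, bool]:
    """Per-entry pass/fail against the convergence threshold; the
    ``"overall"`` key is true iff every entry exceeds it."""
    results = {name: val > threshold for name, val in report.all_values().items()}
    results["overall"] = all(results.values()) if results else True
    return results


def compute_ess_report(
    trace: TreeTrace,
    scalar_series: Mapping[str, Sequence[float]] | None = None,
    *,
    n_focal: int = 20,
    max_lag: int | None = None,
    seed: int = 0,
    rooted: bool = True,
) -> ESSReport:
    """Convenience wrapper computing both topological estimators and any
    scalar parameter traces in one report."""
    pseudo = pseudo_topo_ess(trace, n_focal=n_focal, seed=seed, rooted=rooted)
    approx = approx_topo_ess(trace, max_lag, seed=seed, rooted=rooted)
    scalar = {
        name: scalar_ess(series) for name, series in (scalar_series or {}).items()
    }
    return ESSReport(
        n=len(trace),
        scalar=scalar,
        pseudo_replicates=pseudo.replicates,
        pseudo_median=pseudo.median,
        approx=approx,
        n_focal=n_focal,
        seed=seed,
    )


def read_log_file(path: str | Path) -> pd.DataFrame:
    """Read a sampler's tab-separated parameter log (comment lines start
    with '#'; first column is the state/generation index)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"log file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise InputError(f"log file {path} has no parameter columns")
    return df.set_index(df.columns[0])
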