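"""Binarization, graph-metric battery and edgewise group comparison.

Correlation matrices are cut at a strict r threshold (default 0.35, chosen
high so only strong edges survive) into binary undirected graphs; metrics
(mean clustering coefficient, global efficiency, degree assortativity,
Louvain modularity) are computed on those graphs.  Group differences are
assessed edgewise by unpaired t tests with Bonferroni correction over the
full C(n, 2) family — 435 pairs for a 30-node battery.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import warn_undefined
from .connectivity import ConnMatrix, average_conn_matrices


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph over named nodes with its threshold."""

    labels: list
    adjacency: np.ndarray
    r_threshold: float

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in idx)
        return g


@dataclass
class GraphMetrics:
    """Metric battery for one binary graph."""

    clustering: dict
    clustering_mean: float
    modularity_q: float
    partition: list            # list of sets of node labels
    assortativity: float       # NaN when undefined (regular graph)
    global_efficiency: float

    def __post_init__(self):
        if not -0.5 - 1e-9 <= self.modularity_q <= 1.0 + 1e-9:
            raise ValueError("modularity Q outside [-0.5, 1]")
        if not -1e-9 <= self.global_efficiency <= 1.0 + 1e-9:
            raise ValueError("global efficiency outside [0, 1]")
        covered = sorted(lab for part in self.partition for lab in part)
        if covered != sorted(self.clustering.keys()):
            raise ValueError("partition must cover every node exactly once")


@dataclass
class EdgewiseComparison:
    """Per node-pair group test statistics with Bonferroni-corrected flags."""

    table: pd.DataFrame        # node_a, node_b, mean_1, mean_2, t, p, flags
    m: int                     # family size = C(n_nodes, 2)
    alpha: float
    kind: str = "unpaired"


def binarize(cm: ConnMatrix, r_thresh: float = 0.35) -> BinaryGraph:
    """Edge iff r is strictly greater than the threshold.

    Negative correlations never become edges; undefined (NaN) entries are
    treated as no-edge with a warning.
    """
    vals = np.asarray(cm.values, dtype=float).copy()
    np.fill_diagonal(vals, 0.0)
    n_nan = int(np.isnan(np.triu(vals, k=1)).sum())
    if n_nan:
        warn_undefined(f"{n_nan} undefined pair(s) treated as no-edge")
    with np.errstate(invalid="ignore"):
        adj = vals > r_thresh
    return BinaryGraph(labels=list(cm.labels), adjacency=adj,
                       r_threshold=float(r_thresh))


def group_graph(cms, r_thresh: float = 0.35, fisher: bool = False) -> BinaryGraph:
    """Binarize the element-wise mean correlation matrix of a group."""
    if not cms:
        raise ValueError("no connectivity matrices given")
    return binarize(average_conn_matrices(cms, fisher=fisher), r_thresh)


def clustering_coefficient(g: BinaryGraph):
    """Per-node clustering coefficient (0 for degree < 2) and its mean."""
    cc = nx.clustering(g.to_networkx())
    values = {lab: float(cc[lab]) for lab in g.labels}
    return values, float(np.mean([values[lab] for lab in g.labels]))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest path length over ordered node pairs."""
    if g.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g.to_networkx()))


def assortativity(g: BinaryGraph) -> float:
    """Degree assortativity: Pearson correlation of degrees across edge ends.

    Undefined (NaN, warned) when the degree variance over edge endpoints is
    zero, e.g. on regular graphs.
    """
    if g.n_edges < 1:
        raise ValueError("assortativity needs at least one edge")
    deg = g.degrees
    ii, jj = np.nonzero(np.triu(g.adjacency, k=1))
    ends = np.concatenate([deg[ii], deg[jj]]).astype(float)
    other = np.concatenate([deg[jj], deg[ii]]).astype(float)
    if ends.std() == 0 or other.std() == 0:
        warn_undefined("assortativity undefined: zero degree variance over "
                       "edge endpoints (regular graph)")
        return float("nan")
    return float(nx.degree_assortativity_coefficient(g.to_networkx()))


def modularity_q(g: BinaryGraph, partition) -> float:
    """Standard binary-graph modularity of a partition (label sets)."""
    return float(nx.community.modularity(g.to_networkx(),
                                         [set(p) for p in partition]))


def louvain_modularity(g: BinaryGraph, seed: int = 0, n_restarts: int = 20):
    """Best-Q Louvain partition over seeded restarts.

    Deterministic for a fixed seed: restart seeds derive from ``seed`` and
    the best (ties: first) partition by Q is returned as
    ``(partition, Q)``.
    """
    if g.n_edges < 1:
        raise ValueError("Louvain modularity needs at least one edge")
    gx = g.to_networkx()
    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(max(1, int(n_restarts))):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        part = nx.community.louvain_communities(gx, seed=sub_seed)
        q = nx.community.modularity(gx, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return [set(p) for p in best_part], float(best_q)


def graph_metrics(g: BinaryGraph, seed: int = 0,
                  n_restarts: int = 20) -> GraphMetrics:
    """The full metric battery for one graph."""
    cc, cc_mean = clustering_coefficient(g)
    if g.n_edges >= 1:
        part, q = louvain_modularity(g, seed=seed, n_restarts=n_restarts)
        assort = assortativity(g)
    else:
        part, q = [{lab} for lab in g.labels], 0.0
        assort = float("nan")
    return GraphMetrics(clustering=cc, clustering_mean=cc_mean,
                        modularity_q=q, partition=part,
                        assortativity=assort,
                        global_efficiency=global_efficiency(g))


def compare_methods_paired(values_a, values_b):
    """Two-sided paired t test between per-subject scalars.

    Identical samples give (t=0, p=1); a constant non-zero difference has no
    within-pair variance and is flagged degenerate (NaN, NaN) with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warn_undefined("paired t degenerate: constant non-zero difference")
        return float("nan"), float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_groups_edgewise(cms_group1, cms_group2, alpha: float = 0.05,
                            equal_var: bool = True) -> EdgewiseComparison:
    """Edgewise unpaired t tests between two groups of connectivity matrices.

    Per node pair the correlation values of group 1 and group 2 are compared
    by a classic pooled-variance t test (Welch via ``equal_var=False``);
    undefined entries are excluded pairwise with logged counts.  Flags are
    reported at ``alpha`` and at the Bonferroni level ``alpha / m`` with
    m = C(n_nodes, 2), so the corrected flag implies the uncorrected one.
    """
    if len(cms_group1) < 2 or len(cms_group2) < 2:
        raise ValueError("need at least 2 subjects per group")
    labels = cms_group1[0].labels
    for cm in list(cms_group1) + list(cms_group2):
        if cm.labels != labels:
            raise ValueError("node batteries differ between matrices")
    n = len(labels)
    m = n * (n - 1) // 2
    s1 = np.stack([cm.values for cm in cms_group1])
    s2 = np.stack([cm.values for cm in cms_group2])
    rows = []
    n_dropped = 0
    for i, j in combinations(range(n), 2):
        x = s1[:, i, j]
        y = s2[:, i, j]
        n_dropped += int(np.isnan(x).sum() + np.isnan(y).sum())
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if x.size < 2 or y.size < 2 or (x.std() == 0 and y.std() == 0):
            t_val, p_val = float("nan"), float("nan")
        else:
            res = stats.ttest_ind(x, y, equal_var=equal_var)
            t_val, p_val = float(res.statistic), float(res.pvalue)
        rows.append((labels[i], labels[j],
                     float(x.mean()) if x.size else float("nan"),
                     float(y.mean()) if y.size else float("nan"),
                     t_val, p_val,
                     bool(p_val < alpha), bool(p_val < alpha / m)))
    if n_dropped:
        warn_undefined(f"{n_dropped} undefined value(s) excluded pairwise "
                       "from the edgewise comparison")
    table = pd.DataFrame(rows, columns=["node_a", "node_b", "mean_1", "mean_2",
                                        "t", "p", "sig_uncorrected",
                                        "sig_bonferroni"])
    return EdgewiseComparison(table=table, m=m, alpha=float(alpha))


def count_significant_edges(ec: EdgewiseComparison, within_network: bool = True,
                            direction: str = "any",
                            corrected: bool = True) -> int:
    """Count significant edges, optionally restricted to within-network pairs.

    ``direction='decrease'`` keeps edges whose group-2 mean is below the
    group-1 mean; ``'increase'`` the opposite; ``'any'`` keeps both.
    """
    t = ec.table
    keep = t["sig_bonferroni"] if corrected else t["sig_uncorrected"]
    keep = keep.copy()
    if within_network:
        same = t["node_a"].str.split(".").str[0] == \
            t["node_b"].str.split(".").str[0]
        keep &= same
    if direction == "decrease":
        keep &= t["mean_2"] < t["mean_1"]
    elif direction == "increase":
        keep &= t["mean_2"] > t["mean_1"]
    elif direction != "any":
        raise ValueError("direction must be 'any', 'decrease' or 'increase'")
    return int(keep.sum())
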