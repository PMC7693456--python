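"""Network-based statistic (NBS) for two-group connectivity comparison.

NBS is the graph analog of cluster-extent inference on images: (1) an
edge-wise two-sample t statistic is computed over subjects' Fisher-z
connectivity matrices; (2) edges whose statistic exceeds a primary
threshold (default 3.1) form a supra-threshold graph; (3) connected
components of that graph are the clusters, sized by edge count; (4) group
labels are permuted (default 5000 times), steps 1-3 are repeated, and the
maximal null component size forms the reference distribution.  A component
is FWER-significant when few permutations produce a maximal component at
least as large: p = (1 + #{null >= observed}) / (N + 1), which never
reaches zero.

The default direction is one-sided, group1 (patients) below group2
(controls), matching a connectivity-deficit hypothesis; a two-sided mode
thresholds |t|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .timeseries import ConnectivityMatrix

ONE_SIDED = "one_sided_group1_lt_group2"
TWO_SIDED = "two_sided"

#: Below this many distinct label assignments the null is enumerated exactly.
EXACT_ENUMERATION_LIMIT = 100_000


@dataclass
class NBSConfig:
    t_threshold: float = 3.1
    n_permutations: int = 5000
    sidedness: str = ONE_SIDED
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.sidedness not in (ONE_SIDED, TWO_SIDED):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class Component:
    """One supra-threshold connected component (cluster of edges)."""

    edges: List[Tuple[int, int]]
    nodes: Set[int]
    fwer_p: Optional[float] = None

    @property
    def size(self) -> int:
        """Component size = number of edges."""
        return len(self.edges)


@dataclass
class NBSResult:
    edge_t: np.ndarray
    components: List[Component]
    null_max_sizes: np.ndarray
    significant_mask: np.ndarray
    config: NBSConfig
    node_labels: Optional[List[str]] = None

    @property
    def significant_components(self) -> List[Component]:
        return [c for c in self.components if c.fwer_p < self.config.alpha]

    def edge_table(self) -> pd.DataFrame:
        """Significant edges with their |t|, sorted by |t| descending."""
        rows = []
        for c in self.significant_components:
            for i, j in c.edges:
                label = (
                    f"{self.node_labels[i]}--{self.node_labels[j]}"
                    if self.node_labels
                    else f"{i}--{j}"
                )
                rows.append(
                    {
                        "node_i": i,
                        "node_j": j,
                        "edge": label,
                        "t_value": abs(self.edge_t[i, j]),
                        "component_fwer_p": c.fwer_p,
                    }
                )
        df = pd.DataFrame(
            rows, columns=["node_i", "node_j", "edge", "t_value", "component_fwer_p"]
        )
        return df.sort_values(
            ["t_value", "node_i", "node_j"], ascending=[False, True, True]
        ).reset_index(drop=True)


def _stack_features(
    group1: Sequence[ConnectivityMatrix],
    group2: Sequence[ConnectivityMatrix],
) -> Tuple[np.ndarray, int, int, int, Optional[List[str]]]:
    """Validate and flatten matrices to a (subjects, edges) feature array."""
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need >= 2 subjects per group")
    mats = list(group1) + list(group2)
    n = mats[0].n_nodes
    scale = mats[0].scale
    labels = mats[0].node_labels
    for m in mats:
        if m.n_nodes != n:
            raise ValueError("matrices differ in size")
        if m.scale != scale:
            raise ValueError("matrices mix scales (pearson_r vs fisher_z)")
        if m.node_labels is not None and labels is not None and m.node_labels != labels:
            raise ValueError("matrices differ in node order")
    iu, ju = np.triu_indices(n, k=1)
    feats = np.stack([m.values[iu, ju] for m in mats])
    return feats, n, len(group1), len(group2), labels


def _pooled_t_matrix(
    feats: np.ndarray, in_group1: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Pooled two-sample t per edge for many label assignments at once.

    ``in_group1`` is a (P, S) 0/1 matrix selecting group-1 members per
    assignment; returns a (P, E) matrix of t statistics (group1 - group2).
    """
    tot_sum = feats.sum(axis=0)
    tot_ss = (feats**2).sum(axis=0)
    s1 = in_group1 @ feats
    ss1 = in_group1 @ (feats**2)
    m1 = s1 / n1
    m2 = (tot_sum - s1) / n2
    v1 = (ss1 - n1 * m1**2) / (n1 - 1)
    v2 = (tot_ss - ss1 - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def edgewise_t(
    group1: Sequence[ConnectivityMatrix],
    group2: Sequence[ConnectivityMatrix],
) -> np.ndarray:
    """Edge-wise pooled two-sample t matrix (group1 minus group2).

    Symmetric with a zero diagonal; entry (i, j) is the pooled t comparing
    the two groups' values on edge (i, j).
    """
    feats, n, n1, n2, _ = _stack_features(group1, group2)
    ind = np.zeros((1, n1 + n2))
    ind[0, :n1] = 1.0
    t_edges = _pooled_t_matrix(feats, ind, n1, n2)[0]
    iu, ju = np.triu_indices(n, k=1)
    t = np.zeros((n, n))
    t[iu, ju] = t_edges
    t[ju, iu] = t_edges
    return t


def _supra_edges(t_edges: np.ndarray, cfg: NBSConfig) -> np.ndarray:
    """Boolean supra-threshold selector; strict inequality ('exceeding')."""
    if cfg.sidedness == ONE_SIDED:
        return t_edges < -cfg.t_threshold
    return np.abs(t_edges) > cfg.t_threshold


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, a: int) -> int:
        p = self.parent.setdefault(a, a)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[a] = p
        return p

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _max_component_size(edge_idx: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> int:
    """Largest connected-component edge count among the given edges."""
    uf = _UnionFind()
    for e in edge_idx:
        uf.union(int(iu[e]), int(ju[e]))
    counts: dict[int, int] = {}
    for e in edge_idx:
        root = uf.find(int(iu[e]))
        counts[root] = counts.get(root, 0) + 1
    return max(counts.values(), default=0)


def threshold_components(edge_t: np.ndarray, cfg: NBSConfig) -> List[Component]:
    """Connected components of the supra-threshold graph, largest first.

    Component size is the number of supra-threshold edges it contains.
    """
    edge_t = np.asarray(edge_t, dtype=float)
    if edge_t.ndim != 2 or edge_t.shape[0] != edge_t.shape[1]:
        raise ValueError("edge_t must be square")
    if np.max(np.abs(edge_t - edge_t.T)) > 1e-9:
        raise ValueError("edge_t must be symmetric")
    n = edge_t.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    supra = _supra_edges(edge_t[iu, ju], cfg)
    g = nx.Graph()
    g.add_edges_from(zip(iu[supra].tolist(), ju[supra].tolist()))
    comps = []
    for nodes in nx.connected_components(g):
        edges = sorted(
            (min(a, b), max(a, b)) for a, b in g.subgraph(nodes).edges()
        )
        comps.append(Component(edges=edges, nodes=set(nodes)))
    comps.sort(key=lambda c: (-c.size, c.edges))
    return comps


def _assignment_matrix(
    n_subjects: int, n1: int, cfg: NBSConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, int]:
    """Group-1 indicator matrix for the permutation null.

    Enumerates all C(S, n1) assignments when feasible; otherwise samples
    ``n_permutations`` uniform label shuffles (with replacement, standard
    NBS practice).
    """
    n_distinct = math.comb(n_subjects, n1)
    if n_distinct <= min(EXACT_ENUMERATION_LIMIT, cfg.n_permutations):
        if cfg.n_permutations > n_distinct:
            warnings.warn(
                f"n_permutations={cfg.n_permutations} exceeds the "
                f"{n_distinct} distinct assignments; enumerating exactly",
                stacklevel=3,
            )
        ind = np.zeros((n_distinct, n_subjects))
        for row, members in enumerate(combinations(range(n_subjects), n1)):
            ind[row, list(members)] = 1.0
        return ind, n_distinct
    ind = np.zeros((cfg.n_permutations, n_subjects))
    for row in range(cfg.n_permutations):
        ind[row, rng.permutation(n_subjects)[:n1]] = 1.0
    return ind, cfg.n_permutations


def nbs_permutation_test(
    group1: Sequence[ConnectivityMatrix],
    group2: Sequence[ConnectivityMatrix],
    cfg: Optional[NBSConfig] = None,
) -> NBSResult:
    """Full NBS: observed components plus their permutation FWER p-values.

    ``group1`` is the patient group when using the default one-sided
    (group1 < group2) direction.  The significant mask marks every edge
    belonging to a component with fwer_p < alpha.
    """
    if cfg is None:
        cfg = NBSConfig()
    rng = np.random.default_rng(cfg.seed)
    feats, n, n1, n2, labels = _stack_features(group1, group2)
    iu, ju = np.triu_indices(n, k=1)

    obs_ind = np.zeros((1, n1 + n2))
    obs_ind[0, :n1] = 1.0
    t_edges = _pooled_t_matrix(feats, obs_ind, n1, n2)[0]
    edge_t = np.zeros((n, n))
    edge_t[iu, ju] = t_edges
    edge_t[ju, iu] = t_edges
    components = threshold_components(edge_t, cfg)

    ind, n_perm = _assignment_matrix(n1 + n2, n1, cfg, rng)
    null_max = np.zeros(n_perm, dtype=int)
    chunk = max(1, min(512, n_perm))
    for start in range(0, n_perm, chunk):
        block = ind[start : start + chunk]
        t_null = _pooled_t_matrix(feats, block, n1, n2)
        supra = _supra_edges(t_null, cfg)
        for r in np.flatnonzero(supra.any(axis=1)):
            null_max[start + r] = _max_component_size(
                np.flatnonzero(supra[r]), iu, ju
            )

    mask = np.zeros((n, n), dtype=int)
    for comp in components:
        comp.fwer_p = float(
            (1 + int(np.sum(null_max >= comp.size))) / (n_perm + 1)
        )
        if comp.fwer_p < cfg.alpha:
            for i, j in comp.edges:
                mask[i, j] = mask[j, i] = 1

    return NBSResult(
        edge_t=edge_t,
        components=components,
        null_max_sizes=null_max,
        significant_mask=mask,
        config=cfg,
        node_labels=labels,
    )


def extract_significant_z(
    mask: np.ndarray,
    subjects: Sequence[ConnectivityMatrix],
    node_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-subject z values of the masked edges.

    Rows are subjects (indexed by subject_id), columns are masked
    upper-triangle edges in lexicographic (i, j) order, labelled
    ``node_i--node_j``.  Equivalent to multiplying each subject's matrix
    elementwise by the binary mask and reading off the surviving entries.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("mask must be square")
    if not np.array_equal(mask, mask.T):
        raise ValueError("mask must be symmetric")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    n = mask.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    sel = mask[iu, ju].astype(bool)
    cols = []
    for i, j in zip(iu[sel], ju[sel]):
        if node_labels is not None:
            cols.append(f"{node_labels[i]}--{node_labels[j]}")
        else:
            cols.append(f"{i}--{j}")
    data = {}
    index = []
    values = []
    for k, m in enumerate(subjects):
        if m.n_nodes != n:
            raise ValueError(
                f"subject {m.subject_id or k}: matrix size {m.n_nodes} != mask {n}"
            )
        index.append(m.subject_id or f"subject_{k}")
        values.append(m.values[iu[sel], ju[sel]])
    return pd.DataFrame(
        np.array(values).reshape(len(subjects), -1), index=index, columns=cols
    )
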