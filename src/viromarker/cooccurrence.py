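"""Co-occurrence cluster analysis: Pearson association, UPGMA, SIMPROF,
virus--host network.

Candidates (not samples) are the clustered objects: their square-root
transformed normalized abundance profiles across samples are correlated
(Pearson), clustered by group-average (UPGMA) linkage on distance 1 - r, and
the dendrogram is descended with similarity-profile (SIMPROF) permutation
tests: a node whose members show significantly more internal association
structure than expected under independent profiles is split further, and the
maximal non-rejected subtrees are the output clusters.  Clusters containing
at least one virus and one host yield network edges for member pairs with
r above the edge threshold (default 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "SimprofNode",
    "SimprofResult",
    "pearson_matrix",
    "upgma_cluster",
    "simprof_test",
    "descend_tree",
    "build_network",
    "linkage_to_newick",
    "cluster_table",
]


def pearson_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Candidate x candidate Pearson r over samples (rows are candidates).

    Zero-variance rows are excluded with a warning; fewer than 3 samples is
    an error.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    variances = matrix.var(axis=1)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(
            f"excluding zero-variance candidates from correlation: {flat}",
            stacklevel=2,
        )
        matrix = matrix.drop(index=flat)
    r = np.corrcoef(matrix.to_numpy(dtype=float))
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


def upgma_cluster(r_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Group-average (UPGMA) linkage on distance 1 - r.

    Candidate ids are sorted lexicographically before clustering so merge
    order (and thus ties) is deterministic.  Returns (scipy linkage matrix,
    leaf labels in input order).
    """
    if r_matrix.shape[0] != r_matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    labels = sorted(r_matrix.index)
    d = 1.0 - r_matrix.loc[labels, labels].to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices_from(d, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Z, labels


@dataclass(frozen=True)
class SimprofResult:
    pi: float | None
    p_value: float | None
    significant: bool
    testable: bool
    n_members: int


def _sorted_pairwise_r(X: np.ndarray) -> np.ndarray:
    r = np.corrcoef(X)
    iu = np.triu_indices_from(r, k=1)
    return np.sort(r[iu])


def simprof_test(
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    n_perm_mean: int = 999,
    n_perm_p: int = 999,
    rng: np.random.Generator | int | None = None,
) -> SimprofResult:
    """Similarity-profile permutation test on a group of candidate profiles.

    The observed profile is the sorted vector of pairwise Pearson r among
    members.  Under the null each member's profile is independently permuted
    across samples; the mean null profile comes from ``n_perm_mean``
    permutations, pi = sum_i |obs_i - mean_i|, and the p-value from
    ``n_perm_p`` further permutations as (#{pi_null >= pi} + 1) /
    (n_perm_p + 1).  Groups of fewer than 3 members are untestable.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        return SimprofResult(None, None, False, False, n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd = X.std(axis=1)
    if (sd == 0).any():
        # a flat profile correlates with nothing; jittering is not our job —
        # treat the group as untestable rather than fabricate correlations
        return SimprofResult(None, None, False, False, n)

    obs = _sorted_pairwise_r(X)

    def permuted() -> np.ndarray:
        P = np.array([row[rng.permutation(X.shape[1])] for row in X])
        return _sorted_pairwise_r(P)

    mean_profile = np.zeros_like(obs)
    for _ in range(n_perm_mean):
        mean_profile += permuted()
    mean_profile /= n_perm_mean

    pi = float(np.abs(obs - mean_profile).sum())
    exceed = 0
    for _ in range(n_perm_p):
        pi_null = float(np.abs(permuted() - mean_profile).sum())
        if pi_null >= pi:
            exceed += 1
    p = (exceed + 1) / (n_perm_p + 1)
    return SimprofResult(pi, p, p <= alpha, True, n)


@dataclass
class SimprofNode:
    members: list[str]
    height: float
    result: SimprofResult
    children: list["SimprofNode"] = field(default_factory=list)
    is_cluster: bool = False  # maximal non-rejected subtree


def descend_tree(
    Z: np.ndarray,
    labels: Sequence[str],
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    n_perm_mean: int = 999,
    n_perm_p: int = 999,
    seed: int = 0,
) -> tuple[SimprofNode, list[SimprofNode]]:
    """Descend a dendrogram with SIMPROF tests; heterogeneous nodes split.

    Returns the annotated root and the list of output clusters (maximal
    subtrees the test failed to reject, plus untestable nodes of size <= 2).
    The cluster member sets partition the candidate set.
    """
    rng = np.random.default_rng(seed)
    root_sc, _ = hierarchy.to_tree(Z, rd=True)
    clusters: list[SimprofNode] = []

    def visit(node) -> SimprofNode:
        ids = node.pre_order(lambda leaf: labels[leaf.id])
        members = sorted(ids)
        res = simprof_test(
            profiles.loc[members], alpha, n_perm_mean, n_perm_p, rng
        )
        sn = SimprofNode(members=members, height=float(node.dist), result=res)
        if res.testable and res.significant and not node.is_leaf():
            sn.children = [visit(node.get_left()), visit(node.get_right())]
        else:
            sn.is_cluster = True
            clusters.append(sn)
        return sn

    root = visit(root_sc)
    return root, clusters


def build_network(
    clusters: Sequence[SimprofNode],
    r_matrix: pd.DataFrame,
    roles: Mapping[str, str],
    categories: Mapping[str, str] | None = None,
    r_threshold: float = 0.8,
) -> nx.Graph:
    """Virus--host co-occurrence network from significant mixed clusters.

    Clusters containing at least one virus and one host are retained; within
    each, an edge is emitted for every member pair with r > ``r_threshold``
    (weight = r).  Nodes left without any edge are dropped.  Edges never
    cross clusters.
    """
    G = nx.Graph()
    for k, cl in enumerate(clusters):
        member_roles = {roles[m] for m in cl.members}
        if not {"virus", "host"} <= member_roles:
            continue
        members = sorted(cl.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                r = float(r_matrix.at[a, b])
                if r > r_threshold:
                    for node in (a, b):
                        G.add_node(
                            node,
                            role=roles[node],
                            category=(categories or {}).get(node, ""),
                            cluster=k,
                        )
                    G.add_edge(a, b, weight=r)
    return G


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_table(clusters: Sequence[SimprofNode]) -> pd.DataFrame:
    """Tidy table: candidate, cluster id, pi, p, cluster size."""
    rows = []
    for k, cl in enumerate(clusters):
        for m in cl.members:
            rows.append(
                {
                    "candidate_id": m,
                    "cluster": k,
                    "n_members": cl.result.n_members,
                    "pi": cl.result.pi if cl.result.pi is not None else "",
                    "p_value": cl.result.p_value
                    if cl.result.p_value is not None
                    else "",
                    "testable": cl.result.testable,
                }
            )
    return pd.DataFrame(rows)
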