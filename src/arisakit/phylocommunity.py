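"""Phylogenetic community comparison: unweighted UniFrac and friends.

All statistics operate on a rooted tree with branch lengths whose leaves
are OTUs, plus a mapping of leaves to "environments" (an environment is
one individual's assemblage, or a whole age class).

* unweighted UniFrac: fraction of branch length unique to one of two
  environments, on the tree restricted to the leaves of the pair
  (branches above the restricted most recent common ancestor are dropped).
* UniFrac significance: permutation test of the observed UniFrac value
  against leaf-label shuffles.
* P test: minimum number of environment-label changes on the tree
  (Fitch/Hartigan parsimony; branch lengths ignored) against label shuffles.
* lineage-specific analysis: per-clade 2x2 exact test of environment
  membership inside vs outside the clade.
* PCoA: classical metric scaling via Gower double-centering.
* UPGMA with sequence-jackknife node support.

Monte-Carlo p-values use the (1 + exceedances) / (1 + permutations)
estimator, so they are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from skbio import TreeNode

__all__ = [
    "unifrac_pair",
    "unifrac_matrix",
    "unifrac_significance",
    "p_test",
    "fitch_changes",
    "lineage_specific",
    "pcoa",
    "PCoAResult",
    "upgma",
    "tree_clades",
    "jackknife_support",
]

logger = logging.getLogger(__name__)


class _IndexedTree:
    """Flat arrays over the branches of a rooted tree for fast UniFrac.

    Row b of ``desc`` marks which leaves descend through branch b (a leaf's
    own branch included); ``lengths[b]`` is the branch length to the parent.
    The root has no branch and is not represented.
    """

    def __init__(self, tree: TreeNode):
        self.leaf_names: list[str] = sorted(t.name for t in tree.tips())
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("tree leaf labels must be unique")
        leaf_index = {name: i for i, name in enumerate(self.leaf_names)}
        rows: list[np.ndarray] = []
        lengths: list[float] = []
        node_row: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                row = np.zeros(len(self.leaf_names), dtype=bool)
                row[leaf_index[node.name]] = True
            else:
                row = np.zeros(len(self.leaf_names), dtype=bool)
                for child in node.children:
                    row |= node_row[id(child)]
            node_row[id(node)] = row
            if node.parent is not None:  # root carries no branch
                rows.append(row)
                length = node.length if node.length is not None else 0.0
                if length < 0 or not np.isfinite(length):
                    raise ValueError("branch lengths must be finite and >= 0")
                lengths.append(float(length))
        self.desc = np.array(rows, dtype=np.int16)
        self.lengths = np.array(lengths, dtype=float)

    def membership(self, leaves: Iterable[str]) -> np.ndarray:
        vec = np.zeros(len(self.leaf_names), dtype=np.int16)
        index = {name: i for i, name in enumerate(self.leaf_names)}
        missing = []
        for name in leaves:
            if name in index:
                vec[index[name]] = 1
            else:
                missing.append(name)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)[:5]}")
        return vec


def _pair_u(lengths: np.ndarray, cA: np.ndarray, cB: np.ndarray, nA: int, nB: int) -> float:
    """Unweighted UniFrac from per-branch leaf counts of the two environments.

    Branches with no descendant in either environment do not exist on the
    restricted tree; branches containing *all* restricted leaves lie at or
    above the restricted MRCA and are excluded from both sums.
    """
    present = (cA + cB) > 0
    above = (cA == nA) & (cB == nB)
    keep = present & ~above
    total = float(lengths[keep].sum())
    if total == 0.0:
        raise ValueError(
            "total restricted branch length is zero; UniFrac is undefined "
            "for this pair of environments"
        )
    unique = ((cA > 0) & (cB == 0)) | ((cB > 0) & (cA == 0))
    return float(lengths[keep & unique].sum()) / total


def _pair_u_lenient(lengths, cA, cB, nA, nB) -> float:
    """Matrix variant: two identical single-leaf assemblages (the only way
    the restricted branch length can vanish) are at distance 0."""
    try:
        return _pair_u(lengths, cA, cB, nA, nB)
    except ValueError:
        logger.warning(
            "degenerate environment pair (identical single-leaf assemblages); "
            "distance set to 0"
        )
        return 0.0


def unifrac_pair(
    tree: TreeNode, leaves_a: Iterable[str], leaves_b: Iterable[str]
) -> float:
    """Unweighted UniFrac distance between two leaf sets, in [0, 1]."""
    a_set, b_set = set(leaves_a), set(leaves_b)
    if not a_set or not b_set:
        raise ValueError("both environments must contain at least one leaf")
    idx = _IndexedTree(tree)
    a = idx.membership(a_set)
    b = idx.membership(b_set)
    cA = idx.desc @ a
    cB = idx.desc @ b
    return _pair_u(idx.lengths, cA, cB, int(a.sum()), int(b.sum()))


def unifrac_matrix(
    tree: TreeNode, env_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """All pairwise unweighted UniFrac distances between environments."""
    envs = {}
    for env in sorted(env_sets):
        leaves = set(env_sets[env])
        if not leaves:
            logger.warning("environment %s has no leaves; excluded", env)
            continue
        envs[env] = leaves
    if len(envs) < 2:
        raise ValueError("need at least 2 non-empty environments")
    idx = _IndexedTree(tree)
    names = list(envs)
    counts = {}
    sizes = {}
    for env, leaves in envs.items():
        vec = idx.membership(leaves)
        counts[env] = idx.desc @ vec
        sizes[env] = int(vec.sum())
    mat = np.zeros((len(names), len(names)))
    for i, ei in enumerate(names):
        for j in range(i + 1, len(names)):
            ej = names[j]
            u = _pair_u_lenient(idx.lengths, counts[ei], counts[ej], sizes[ei], sizes[ej])
            mat[i, j] = mat[j, i] = u
    return pd.DataFrame(mat, index=names, columns=names)


def _two_env_arrays(
    tree: TreeNode, env_map: Mapping[str, str]
) -> tuple[_IndexedTree, np.ndarray, list[str], np.ndarray]:
    """Index the tree and encode a two-environment leaf labelling."""
    labels = sorted(set(env_map.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two environments required, got {labels}")
    idx = _IndexedTree(tree)
    mapped = [name for name in idx.leaf_names if name in env_map]
    if len(mapped) < 2:
        raise ValueError("need at least two mapped leaves")
    mapped_idx = np.array([idx.leaf_names.index(m) for m in mapped])
    is_first = np.array([env_map[m] == labels[0] for m in mapped], dtype=bool)
    return idx, mapped_idx, labels, is_first


def unifrac_significance(
    tree: TreeNode,
    env_map: Mapping[str, str],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the UniFrac distance between two environments.

    Leaf labels are shuffled among all mapped leaves, preserving class
    sizes; p = (1 + #{U_perm >= U_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    idx, mapped_idx, _, is_first = _two_env_arrays(tree, env_map)
    desc = idx.desc[:, mapped_idx]
    n1 = int(is_first.sum())
    n2 = int((~is_first).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both environments must contain mapped leaves")

    def u_of(labels: np.ndarray) -> float:
        lab = labels.astype(np.int16)
        cA = desc @ lab
        cB = desc @ (1 - lab)
        return _pair_u(idx.lengths, cA, cB, n1, n2)

    u_obs = u_of(is_first)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_first)
        if u_of(perm) >= u_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def fitch_changes(tree: TreeNode, leaf_labels: Mapping[str, str]) -> int:
    """Minimum number of label changes on the tree (Hartigan parsimony).

    Works on arbitrary (multifurcating) rooted trees; leaves without a
    label must not exist in the tree passed here.
    """
    changes = 0
    states: dict[int, frozenset[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name not in leaf_labels:
                raise ValueError(f"leaf {node.name!r} has no environment label")
            states[id(node)] = frozenset([leaf_labels[node.name]])
        else:
            votes: dict[str, int] = {}
            for child in node.children:
                for s in states[id(child)]:
                    votes[s] = votes.get(s, 0) + 1
            top = max(votes.values())
            states[id(node)] = frozenset(s for s, k in votes.items() if k == top)
            changes += len(node.children) - top
    return changes


def p_test(
    tree: TreeNode,
    env_map: Mapping[str, str],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, int]:
    """Parsimony test of community differentiation.

    The observed statistic is the parsimony count of environment-label
    changes on the tree restricted to mapped leaves (branch lengths are
    ignored); significance is assessed by shuffling leaf labels:
    p = (1 + #{changes_perm <= changes_obs}) / (1 + n_perm).

    Returns (p_value, observed_changes).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(set(env_map.values())) < 2:
        raise ValueError("P test requires at least two environments")
    rng = np.random.default_rng(seed)
    mapped = sorted(set(env_map) & {t.name for t in tree.tips()})
    if len(mapped) < 3:
        raise ValueError("need at least three mapped leaves")
    sub = tree.shear(mapped)
    sub.prune()
    labels = [env_map[m] for m in mapped]
    obs = fitch_changes(sub, dict(zip(mapped, labels)))
    at_most = 0
    labels_arr = np.array(labels)
    for _ in range(n_perm):
        perm = rng.permutation(labels_arr)
        if fitch_changes(sub, dict(zip(mapped, perm))) <= obs:
            at_most += 1
    return (1 + at_most) / (1 + n_perm), obs


def lineage_specific(
    tree: TreeNode,
    env_map: Mapping[str, str],
    min_descendants: int = 4,
) -> pd.DataFrame:
    """Per-clade test of uneven environment membership.

    For every internal node (root excluded) with at least
    ``min_descendants`` mapped leaf descendants, a 2x2 table
    (environment x inside/outside the clade) is built and a two-sided
    Fisher exact p-value computed. Rows are sorted by ascending p; a
    Benjamini-Hochberg ``q_value`` column is included.
    """
    labels = sorted(set(env_map.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two environments required, got {labels}")
    mapped = set(env_map) & {t.name for t in tree.tips()}
    total = {lab: sum(1 for m in mapped if env_map[m] == lab) for lab in labels}

    rows = []
    for i, node in enumerate(tree.postorder(include_self=False)):
        if node.is_tip():
            continue
        clade = {t.name for t in node.tips()} & mapped
        if len(clade) < min_descendants:
            continue
        inside = {lab: sum(1 for m in clade if env_map[m] == lab) for lab in labels}
        table = [
            [inside[labels[0]], total[labels[0]] - inside[labels[0]]],
            [inside[labels[1]], total[labels[1]] - inside[labels[1]]],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "node": node.name if node.name else f"node{i}",
                f"n_{labels[0]}_inside": inside[labels[0]],
                f"n_{labels[1]}_inside": inside[labels[1]],
                f"n_{labels[0]}_outside": total[labels[0]] - inside[labels[0]],
                f"n_{labels[1]}_outside": total[labels[1]] - inside[labels[1]],
                "p_value": float(p),
                "clade_leaves": ",".join(sorted(clade)),
            }
        )
    if not rows:
        logger.warning("no internal node has >= %d mapped descendants", min_descendants)
        return pd.DataFrame(
            columns=[
                "node",
                f"n_{labels[0]}_inside",
                f"n_{labels[1]}_inside",
                f"n_{labels[0]}_outside",
                f"n_{labels[1]}_outside",
                "p_value",
                "q_value",
                "clade_leaves",
            ]
        )
    df = pd.DataFrame(rows).sort_values(["p_value", "node"]).reset_index(drop=True)
    df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df[
        [
            "node",
            f"n_{labels[0]}_inside",
            f"n_{labels[1]}_inside",
            f"n_{labels[0]}_outside",
            f"n_{labels[1]}_outside",
            "p_value",
            "q_value",
            "clade_leaves",
        ]
    ]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


@dataclass
class PCoAResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # environments x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # percent, over positive eigenvalues


def pcoa(distances: pd.DataFrame) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Gower-centres the squared distances, B = -1/2 J D^2 J with
    J = I - 11^T/m, and eigendecomposes B. Coordinates are
    eigenvector * sqrt(eigenvalue) for positive eigenvalues; percent
    variation uses positive eigenvalues only. Each axis is oriented so
    its largest-magnitude coordinate is positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    ids = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(D.shape[0]))
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12 if eigvals.size else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):
        if coords.shape[0] and coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    percent = (
        eigvals[pos] / eigvals[pos].sum() * 100.0 if pos.any() else np.array([])
    )
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    return PCoAResult(coordinates=frame, eigenvalues=eigvals, proportion_explained=percent)


def upgma(distances: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration into an ultrametric dendrogram.

    Ties in merge distance are broken lexicographically on the member
    labels of the candidate clusters, so the dendrogram is deterministic.
    Branch lengths place each leaf at distance height/2 from every merge.
    """
    labels = [str(x) for x in distances.index]
    if len(labels) < 2:
        raise ValueError("need at least two environments")
    D = np.asarray(distances, dtype=float)
    clusters: dict[tuple[str, ...], tuple[TreeNode, int, float]] = {}
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    for i, lab in enumerate(labels):
        clusters[(lab,)] = (TreeNode(name=lab), 1, 0.0)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[frozenset(((labels[i],), (labels[j],)))] = float(D[i, j])

    while len(clusters) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, ka, kb = best
        node_a, size_a, h_a = clusters.pop(ka)
        node_b, size_b, h_b = clusters.pop(kb)
        height = d / 2.0
        node_a.length = max(height - h_a, 0.0)
        node_b.length = max(height - h_b, 0.0)
        merged = TreeNode(children=[node_a, node_b])
        km = tuple(sorted(ka + kb))
        # update average-linkage distances to the remaining clusters
        new_dist: dict[frozenset[tuple[str, ...]], float] = {}
        for pair, old in dist.items():
            if ka in pair or kb in pair:
                continue
            new_dist[pair] = old
        for kc in clusters:
            da = dist[frozenset((ka, kc))]
            db = dist[frozenset((kb, kc))]
            new_dist[frozenset((km, kc))] = (size_a * da + size_b * db) / (size_a + size_b)
        dist = new_dist
        clusters[km] = (merged, size_a + size_b, height)
    ((_, (root, _, _)),) = clusters.items()
    root.length = None
    return root


def tree_clades(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf-name sets of all internal nodes (root included)."""
    out = set()
    for node in tree.non_tips(include_self=True):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def jackknife_support(
    tree: TreeNode,
    env_sets: Mapping[str, Iterable[str]],
    keep: int = 5,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    small_env_policy: str = "whole",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """UPGMA dendrogram of environments with jackknife node support.

    Each replicate subsamples ``keep`` leaves per environment without
    replacement (environments with fewer leaves are used whole under the
    default policy, or removed with ``small_env_policy="drop"``), then the
    UniFrac matrix and UPGMA dendrogram are recomputed. The support of a
    node in the full-data dendrogram is the fraction of replicates whose
    dendrogram contains the same environment grouping. Internal node names
    of the returned tree carry the support values.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if small_env_policy not in ("whole", "drop"):
        raise ValueError("small_env_policy must be 'whole' or 'drop'")
    rng = np.random.default_rng(seed)
    envs = {env: sorted(set(leaves)) for env, leaves in env_sets.items()}
    if small_env_policy == "drop":
        dropped = [e for e, lv in envs.items() if len(lv) < keep]
        if dropped:
            logger.warning(
                "dropping %d environment(s) with fewer than %d leaves: %s",
                len(dropped), keep, ", ".join(sorted(dropped)),
            )
        envs = {e: lv for e, lv in envs.items() if len(lv) >= keep}
    if len(envs) < 2:
        raise ValueError("fewer than two environments remain for clustering")

    reference = upgma(unifrac_matrix(tree, envs))

    idx = _IndexedTree(tree)
    vecs = {e: idx.membership(lv) for e, lv in envs.items()}
    names = sorted(envs)
    hits: dict[frozenset[str], int] = {c: 0 for c in tree_clades(reference)}
    for _ in range(n_perm):
        counts = {}
        sizes = {}
        for e in names:
            leaves = envs[e]
            if len(leaves) > keep:
                chosen = rng.choice(len(leaves), size=keep, replace=False)
                vec = np.zeros_like(vecs[e])
                all_idx = np.flatnonzero(vecs[e])
                vec[all_idx[chosen]] = 1
            else:
                vec = vecs[e]
            counts[e] = idx.desc @ vec
            sizes[e] = int(vec.sum())
        mat = np.zeros((len(names), len(names)))
        for i, ei in enumerate(names):
            for j in range(i + 1, len(names)):
                ej = names[j]
                mat[i, j] = mat[j, i] = _pair_u_lenient(
                    idx.lengths, counts[ei], counts[ej], sizes[ei], sizes[ej]
                )
        rep_tree = upgma(pd.DataFrame(mat, index=names, columns=names))
        rep_clades = tree_clades(rep_tree)
        for clade in hits:
            if clade in rep_clades:
                hits[clade] += 1

    support = {clade: k / n_perm for clade, k in hits.items()}
    for node in reference.non_tips(include_self=True):
        clade = frozenset(t.name for t in node.tips())
        node.name = f"{support[clade]:.2f}"
    return reference, support
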