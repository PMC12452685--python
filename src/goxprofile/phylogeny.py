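"""UPGMA phylogeny, Newick serialization, tree cutting and cluster analytics.

UPGMA (unweighted pair-group method with arithmetic mean) merges the closest
pair of clusters at height d/2 under arithmetic-mean linkage, producing a
rooted ultrametric tree: every leaf sits at the same distance from the root.
Cutting away the k-1 highest internal nodes yields k monophyletic clusters;
cutting away only the g-1 highest of those same nodes yields the g coarser
"supergroups" seen when the tree is drawn unrooted.

Trees are held as :class:`skbio.TreeNode`, so Newick round-tripping and
traversals come from scikit-bio.  Ties during merging are broken
deterministically: among equally close pairs, the pair whose smallest original
leaf index is lowest (then the other index) is merged first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .distances import DistanceMatrix


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Build a UPGMA tree from a distance matrix.

    Node heights are d/2 at each merge; branch lengths are height differences,
    so the result is exactly ultrametric.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    work = dm.d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    nodes: list[TreeNode | None] = [TreeNode(name=label) for label in dm.labels]
    sizes = [1] * n
    heights = [0.0] * n
    min_leaf = list(range(n))  # smallest original leaf index per active cluster
    active = list(range(n))
    for _ in range(n - 1):
        sub = work[np.ix_(active, active)]
        best = np.min(sub)
        cand = np.argwhere(np.isclose(sub, best, rtol=0.0, atol=0.0))
        pairs = [
            (active[i], active[j]) for i, j in cand if i < j
        ]
        i, j = min(pairs, key=lambda p: (min(min_leaf[p[0]], min_leaf[p[1]]),
                                         max(min_leaf[p[0]], min_leaf[p[1]])))
        h = work[i, j] / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        # arithmetic-mean linkage update
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dk = (si * work[i, k] + sj * work[j, k]) / (si + sj)
            work[i, k] = work[k, i] = dk
        nodes[i] = parent
        sizes[i] = si + sj
        heights[i] = h
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
        nodes[j] = None
        active.remove(j)
    root = nodes[active[0]]
    root.length = None
    return root


def node_heights(tree: TreeNode) -> dict[int, float]:
    """Height of every node (max distance to a descendant leaf), keyed by id()."""
    heights: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            heights[id(node)] = 0.0
        else:
            heights[id(node)] = max(
                heights[id(c)] + (c.length or 0.0) for c in node.children
            )
    return heights


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = []

    def walk(node, depth):
        if node.is_tip():
            depths.append(depth)
        for c in node.children:
            walk(c, depth + (c.length or 0.0))

    walk(tree, 0.0)
    return max(depths) - min(depths) <= tol


def cophenetic_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Pairwise leaf distances implied by the tree (2x the LCA height)."""
    heights = node_heights(tree)
    idx = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for node in tree.postorder():
        if node.is_tip():
            continue
        # tips() of a leaf child is empty; handle leaf children explicitly
        child_leafsets = []
        for c in node.children:
            child_leafsets.append([c.name] if c.is_tip() else [t.name for t in c.tips()])
        h = heights[id(node)]
        for a in range(len(child_leafsets)):
            for b in range(a + 1, len(child_leafsets)):
                for x in child_leafsets[a]:
                    for y in child_leafsets[b]:
                        d[idx[x], idx[y]] = d[idx[y], idx[x]] = 2 * h
    return d


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def parse_newick(s: str) -> TreeNode:
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skbio format sniffer on StringIO
            return TreeNode.read(io.StringIO(s), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with a position
        raise ValueError(f"malformed Newick: {exc}") from exc


@dataclass
class ClusterAssignment:
    """Leaf -> cluster id (1..k) from cutting an ultrametric tree."""

    assignment: dict[str, int]
    k: int
    cut_height: float | None

    def members(self, cluster: int) -> list[str]:
        return [leaf for leaf, c in self.assignment.items() if c == cluster]


def _removed_nodes(tree: TreeNode, n_remove: int) -> set[int]:
    """ids of the n_remove highest internal nodes (ties: preorder first)."""
    heights = node_heights(tree)
    internal = [
        (heights[id(node)], order, id(node))
        for order, node in enumerate(tree.preorder())
        if not node.is_tip()
    ]
    internal.sort(key=lambda t: (-t[0], t[1]))
    return {nid for _, _, nid in internal[:n_remove]}


def _forest_roots(tree: TreeNode, removed: set[int]) -> list[TreeNode]:
    roots = []

    def walk(node):
        if id(node) in removed:
            for c in node.children:
                walk(c)
        else:
            roots.append(node)

    walk(tree)
    return roots


def cut_clusters(tree: TreeNode, k: int) -> ClusterAssignment:
    """Cut the tree into k monophyletic clusters.

    The k-1 highest internal nodes are removed; the resulting subtrees are the
    clusters, numbered 1..k by the first appearance of one of their leaves in
    the tree's tip order.
    """
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    removed = _removed_nodes(tree, k - 1)
    roots = _forest_roots(tree, removed)
    tip_pos = {name: i for i, name in enumerate(tips)}
    clusters = []
    for root in roots:
        leaves = [root.name] if root.is_tip() else [t.name for t in root.tips()]
        clusters.append(leaves)
    clusters.sort(key=lambda leaves: min(tip_pos[x] for x in leaves))
    assignment = {}
    for cid, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            assignment[leaf] = cid
    heights = node_heights(tree)
    cut_height = None
    if k > 1:
        cut_height = min(heights[nid] for nid in removed)
    return ClusterAssignment(assignment=assignment, k=k, cut_height=cut_height)


def supergroup_clusters(
    tree: TreeNode, assignment: ClusterAssignment, n_groups: int = 4
) -> dict[int, str]:
    """Group clusters by shared deep ancestry into n_groups supergroups.

    Cutting at the n_groups-1 highest internal nodes (a subset of the nodes
    removed to form the clusters) partitions the tree into n_groups subtrees;
    each cluster inherits the label (A, B, ...) of the subtree containing it.
    Labels are ordered by smallest member cluster id.
    """
    if n_groups > assignment.k:
        raise ValueError(f"n_groups={n_groups} exceeds k={assignment.k}")
    removed = _removed_nodes(tree, n_groups - 1)
    roots = _forest_roots(tree, removed)
    cluster_to_root: dict[int, int] = {}
    for ridx, root in enumerate(roots):
        leaves = [root.name] if root.is_tip() else [t.name for t in root.tips()]
        for leaf in leaves:
            cid = assignment.assignment[leaf]
            cluster_to_root[cid] = ridx
    # order groups by their smallest cluster id
    root_order = []
    for cid in sorted(cluster_to_root):
        ridx = cluster_to_root[cid]
        if ridx not in root_order:
            root_order.append(ridx)
    labels = {ridx: chr(ord("A") + i) for i, ridx in enumerate(root_order)}
    return {cid: labels[ridx] for cid, ridx in sorted(cluster_to_root.items())}


def cluster_composition(
    assignment: ClusterAssignment,
    records,
    subtype: str | None = None,
) -> dict:
    """Cluster-by-taxonomy-class and cluster-by-subtype composition tables.

    Returns a dict with ``class_counts`` (cluster x class), ``subtype_fraction``
    (cluster x grouped ontology), and, when ``subtype`` is given, the
    per-cluster fraction of that subtype plus its median over all clusters
    (zeros included).
    """
    by_acc = {r.accession: r for r in records}
    missing = [leaf for leaf in assignment.assignment if leaf not in by_acc]
    if missing:
        raise ValueError(f"no record for leaves: {', '.join(sorted(missing)[:5])}")
    rows = [
        {
            "cluster": cid,
            "class": by_acc[leaf].taxonomy.get("class", "Undefined"),
            "subtype": by_acc[leaf].ontology_grouped,
        }
        for leaf, cid in assignment.assignment.items()
    ]
    df = pd.DataFrame(rows)
    class_counts = pd.crosstab(df["cluster"], df["class"])
    subtype_counts = pd.crosstab(df["cluster"], df["subtype"])
    subtype_fraction = subtype_counts.div(subtype_counts.sum(axis=1), axis=0)
    out = {"class_counts": class_counts, "subtype_fraction": subtype_fraction}
    if subtype is not None:
        frac = pd.Series(0.0, index=range(1, assignment.k + 1), name=subtype)
        if subtype in subtype_fraction.columns:
            frac.update(subtype_fraction[subtype])
        out["subtype_cluster_fraction"] = frac
        out["subtype_median"] = float(np.median(frac.to_numpy()))
    return out


def select_representatives(
    records,
    assignment: ClusterAssignment,
    n: int = 120,
    seed: int = 0,
    reference: str | None = None,
) -> list:
    """Pick a reproducible representative subset covering clusters and subtypes.

    Greedy coverage first (one record per cluster and per grouped ontology,
    always keeping the reference when given), then fill proportionally to
    cluster sizes with a seeded RNG.
    """
    records = list(records)
    by_acc = {r.accession: r for r in records}
    clusters = sorted(set(assignment.assignment.values()))
    subtypes = sorted({r.ontology_grouped for r in records})
    if n < len(clusters) or n < len(subtypes):
        raise ValueError(
            f"n={n} cannot cover {len(clusters)} clusters and {len(subtypes)} subtypes"
        )
    if n > len(records):
        raise ValueError(f"n={n} exceeds dataset size {len(records)}")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    if reference is not None:
        if reference not in by_acc:
            raise ValueError(f"reference {reference!r} not in records")
        chosen.append(reference)
    cluster_of = assignment.assignment

    def covered_clusters():
        return {cluster_of[a] for a in chosen if a in cluster_of}

    def covered_subtypes():
        return {by_acc[a].ontology_grouped for a in chosen}

    for cid in clusters:
        if cid not in covered_clusters():
            members = sorted(a for a, c in cluster_of.items() if c == cid)
            chosen.append(members[int(rng.integers(len(members)))])
    for sub in subtypes:
        if sub not in covered_subtypes():
            members = sorted(r.accession for r in records if r.ontology_grouped == sub)
            chosen.append(members[int(rng.integers(len(members)))])
    remaining = sorted(set(by_acc) - set(chosen))
    while len(chosen) < n and remaining:
        weights = np.array(
            [len([a for a in remaining if cluster_of.get(a) == cluster_of.get(x)]) for x in remaining],
            dtype=float,
        )
        pick = remaining[int(rng.choice(len(remaining), p=weights / weights.sum()))]
        chosen.append(pick)
        remaining.remove(pick)
    return [by_acc[a] for a in chosen[:n]]
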