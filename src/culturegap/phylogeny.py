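"""Trees over universal OTUs: construction, tip distances, nearest-cultured
distances, pruning, and clade partitioning.

The culturability score of an OTU is its patristic distance (sum of branch
lengths) to the nearest tip whose cluster contains a cultured isolate, with
the zero-rule: an OTU whose own cluster contains a cultured sequence scores
zero.  The nearest-cultured search runs as a two-pass dynamic program over
the tree (best cultured tip within each subtree, then best via the parent),
linear in tree size rather than quadratic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PhyloTree:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree`; root placement is arbitrary
    and never affects tip-to-tip path sums.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tree.is_rooted = True  # arbitrary root; never affects path sums
        labels = [t.label for t in tree.taxon_namespace if t.label is not None]
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                edge.length = 1.0
                missing += 1
            elif edge.length < 0:
                raise ValueError("negative branch length")
        if missing:
            logger.warning(
                "%d branch lengths missing from newick; set to 1.0", missing
            )
        self._tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    # -- basics -------------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        return sorted(self._tips)

    def __contains__(self, label: str) -> bool:
        return label in self._tips

    def __len__(self) -> int:
        return len(self._tips)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def reroot_at(self, tip_label: str) -> "PhyloTree":
        """Reroot at the edge leading to a tip (for invariance checks)."""
        clone = self._tree.clone(depth=1)
        leaf = next(
            l for l in clone.leaf_node_iter() if l.taxon.label == tip_label
        )
        half = (leaf.edge.length or 0.0) / 2.0
        clone.reroot_at_edge(leaf.edge, length1=half, length2=half,
                             update_bipartitions=False)
        return PhyloTree(clone)


@dataclass
class NearestCulturedResult:
    otu_id: str
    distance: float
    nearest_cultured_otu_id: str | None


def nj_tree(distance_matrix: pd.DataFrame) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: taxa are processed in sorted-label order and Q-matrix
    ties break to the first (row-major) pair.  Negative estimated branch
    lengths are clamped to zero.
    """
    dm = distance_matrix
    ids = sorted(str(i) for i in dm.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if set(map(str, dm.index)) != set(map(str, dm.columns)):
        raise ValueError("distance matrix must be square over one taxon set")
    mat = dm.loc[ids, ids].to_numpy(dtype=float).copy()
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN")
    if (mat < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)

    D = mat
    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))          # row-major: deterministic ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
    root = dendropy.Node()
    half = max(D[0, 1] / 2.0, 0.0)
    for node in nodes:
        root.add_child(node)
        node.edge.length = half
    tree.seed_node = root
    return PhyloTree(tree)


def tip_to_tip_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Patristic distance: sum of branch lengths along the unique a-b path."""
    for label in (a, b):
        if label not in tree:
            raise ValueError(f"unknown tip label {label!r}")
    if a == b:
        return 0.0
    node_a = tree._tips[a]
    node_b = tree._tips[b]
    # ancestor chains with cumulative depths
    chain_a: dict[int, tuple[object, float]] = {}
    node, depth = node_a, 0.0
    while node is not None:
        chain_a[id(node)] = (node, depth)
        depth += node.edge.length or 0.0
        node = node.parent_node
    node, depth = node_b, 0.0
    while node is not None:
        if id(node) in chain_a:
            return chain_a[id(node)][1] + depth
        depth += node.edge.length or 0.0
        node = node.parent_node
    raise ValueError("tips are not connected")  # pragma: no cover


def nearest_cultured_distances(
    tree: PhyloTree,
    cultured_tip_set: Iterable[str],
    contains_cultured_flags: Mapping[str, bool] | None = None,
) -> list[NearestCulturedResult]:
    """Distance from every tip to its nearest cultured tip (two-pass DP).

    Tips flagged as containing a cultured sequence score zero with
    themselves as nearest (the zero-rule).  Other tips take the minimum
    patristic distance over all cultured tips; ties break to the
    lexicographically smallest cultured tip id.
    """
    cultured = set(cultured_tip_set)
    if not cultured:
        raise ValueError("cultured tip set must be non-empty")
    missing = cultured - set(tree.tips)
    if missing:
        raise ValueError(f"cultured tips not in tree: {sorted(missing)}")
    flags = dict(contains_cultured_flags or {})
    for tip in cultured:
        flags.setdefault(tip, True)

    INF = float("inf")
    t = tree.dendropy_tree
    down: dict[object, tuple[float, str | None]] = {}
    # down-pass: best cultured tip within each node's subtree
    def better(a: tuple[float, str | None], b: tuple[float, str | None]):
        """min by (distance, tip id); None tips lose to any real tip."""
        if a[1] is None:
            return b
        if b[1] is None:
            return a
        return min(a, b)

    for node in t.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            down[node] = (0.0, label) if label in cultured else (INF, None)
        else:
            best = (INF, None)
            for child in node.child_nodes():
                d, tip = down[child]
                if tip is not None:
                    best = better(best, (d + (child.edge.length or 0.0), tip))
            down[node] = best
    # up-pass: best cultured tip reachable through the parent
    up: dict[object, tuple[float, str | None]] = {t.seed_node: (INF, None)}
    for node in t.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            best = up[node]
            for sib in children:
                if sib is child:
                    continue
                d, tip = down[sib]
                if tip is not None:
                    best = better(best, (d + (sib.edge.length or 0.0), tip))
            if best[1] is not None:
                best = (best[0] + (child.edge.length or 0.0), best[1])
            up[child] = best

    results = []
    for label in tree.tips:
        if flags.get(label, False):
            results.append(NearestCulturedResult(label, 0.0, label))
            continue
        leaf = tree._tips[label]
        d_down, tip_down = down[leaf]
        d_up, tip_up = up[leaf]
        cands = [(d, tp) for d, tp in ((d_down, tip_down), (d_up, tip_up))
                 if tp is not None]
        if not cands:  # pragma: no cover - cultured set is non-empty
            raise RuntimeError("no cultured tip reachable")
        d, tp = min(cands)
        results.append(NearestCulturedResult(label, d, tp))
    return results


def prune_tree(tree: PhyloTree, keep_tips: Iterable[str]) -> PhyloTree:
    """Prune to ``keep_tips`` while preserving all kept-pair path distances.

    Degree-2 nodes left by the removal are collapsed with their incident
    branch lengths summed, so patristic distances among kept tips are
    unchanged.
    """
    keep = set(keep_tips)
    missing = sorted(keep - set(tree.tips))
    if missing:
        raise ValueError(f"keep_tips not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("keep_tips must contain at least 2 tips")
    clone = tree.dendropy_tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep))
    # collapse any residual root unifurcation, summing branch lengths
    root = clone.seed_node
    while len(root.child_nodes()) == 1 and not root.child_nodes()[0].is_leaf():
        child = root.child_nodes()[0]
        for grand in list(child.child_nodes()):
            child.remove_child(grand)
            root.add_child(grand)
            grand.edge.length = (grand.edge.length or 0.0) + (
                child.edge.length or 0.0
            )
        root.remove_child(child)
    return PhyloTree(clone)


def partition_clades(
    tree: PhyloTree, max_within_distance: float
) -> dict[str, str]:
    """Partition tips into monophyletic clades or singletons.

    Greedy top-down rule: a subtree is one clade iff its maximal
    within-subtree tip-to-tip distance is at most the threshold (and its
    parent's subtree exceeds it); tips reached individually become
    singletons.  Returns a map tip label -> clade id.
    """
    if max_within_distance <= 0:
        raise ValueError("max_within_distance must be > 0")
    t = tree.dendropy_tree
    depth: dict[object, float] = {}     # deepest tip below node
    within: dict[object, float] = {}    # max tip-to-tip distance inside subtree
    for node in t.postorder_node_iter():
        if node.is_leaf():
            depth[node] = 0.0
            within[node] = 0.0
            continue
        child_reach = [
            depth[c] + (c.edge.length or 0.0) for c in node.child_nodes()
        ]
        depth[node] = max(child_reach)
        w = max(within[c] for c in node.child_nodes())
        reach_sorted = sorted(child_reach, reverse=True)
        if len(reach_sorted) >= 2:
            w = max(w, reach_sorted[0] + reach_sorted[1])
        within[node] = w

    assignment: dict[str, str] = {}
    counter = 0

    def emit(node) -> None:
        nonlocal counter
        counter += 1
        cid = f"clade{counter:04d}"
        if node.is_leaf():
            assignment[node.taxon.label] = cid
        else:
            for leaf in node.leaf_iter():
                assignment[leaf.taxon.label] = cid

    stack = [t.seed_node]
    while stack:
        node = stack.pop()
        if within[node] <= max_within_distance:
            emit(node)
        else:
            stack.extend(reversed(node.child_nodes()))
    return assignment


def p_distance_matrix(
    seqs: Mapping[str, str],
) -> pd.DataFrame:
    """Pairwise p-distances (mismatches / compared positions, gaps excluded)
    from global alignments, as input for :func:`nj_tree`."""
    from .clustering import _align

    ids = sorted(seqs)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            if a == b:
                d = 0.0
            elif len(a) == len(b):
                arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
                arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
                d = float((arr_a != arr_b).mean())
            else:
                aln = _align(a, b)
                counts = aln.counts()
                compared = counts.identities + counts.mismatches
                d = counts.mismatches / compared if compared else 1.0
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def nearest_results_frame(results: Sequence[NearestCulturedResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "distance": [r.distance for r in results],
            "nearest_cultured_otu_id": [r.nearest_cultured_otu_id for r in results],
        },
        index=pd.Index([r.otu_id for r in results], name="otu_id"),
    )
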