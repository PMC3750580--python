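"""Tree construction and bookkeeping.

Trees are stored as :class:`dendropy.Tree` objects wrapped together with a
leaf-label -> taxon-group mapping and a bipartition -> bootstrap-support
table. Supports are keyed by canonical splits (frozensets of leaf labels)
rather than nodes, so they survive rerooting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

SplitKey = FrozenSet[str]


def canonical_split(subset: Iterable[str], all_labels: FrozenSet[str]) -> SplitKey:
    """Canonical key for the bipartition subset | complement: the side NOT
    containing the lexicographically smallest leaf."""
    subset = frozenset(subset)
    ref = min(all_labels)
    return frozenset(all_labels - subset) if ref in subset else subset


@dataclass
class PhyloTree:
    """Leaf-labeled tree plus taxon-group tags and split supports (0-100)."""

    tree: dendropy.Tree
    groups: Dict[str, str]
    supports: Dict[SplitKey, float] = field(default_factory=dict)

    def __post_init__(self):
        self._topo_index: Optional[_TopologyIndex] = None

    @property
    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def support_for(self, clade_labels: Iterable[str]) -> Optional[float]:
        key = canonical_split(clade_labels, frozenset(self.leaf_labels))
        return self.supports.get(key)

    def topology_index(self) -> "_TopologyIndex":
        """Cached parent/leafset index of the current (rooted) topology.
        Invalidated only by :meth:`invalidate`; reuse across group relabelings
        is safe because the index never stores group information."""
        if self._topo_index is None:
            self._topo_index = _TopologyIndex.from_tree(self.tree)
        return self._topo_index

    def invalidate(self) -> None:
        self._topo_index = None

    def write_newick(self, path) -> None:
        annotate_supports_on_nodes(self)
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True, real_value_format_specifier=".6g")


class _TopologyIndex:
    """Flat arrays describing a rooted topology: per-node parent, children,
    leaf label, and the frozenset of leaf labels below each node."""

    __slots__ = ("nodes", "parent", "children", "label", "leafset",
                 "leaf_node_of", "root", "all_labels")

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "_TopologyIndex":
        idx = cls()
        nodes = list(tree.preorder_node_iter())
        pos = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        idx.nodes = nodes
        idx.parent = [-1] * n
        idx.children = [[] for _ in range(n)]
        idx.label = [None] * n
        idx.leafset: List[FrozenSet[str]] = [frozenset()] * n
        idx.leaf_node_of = {}
        idx.root = 0
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = pos[id(node.parent_node)]
                idx.parent[i] = p
                idx.children[p].append(i)
            if node.is_leaf():
                idx.label[i] = node.taxon.label
                idx.leaf_node_of[node.taxon.label] = i
        for i in range(n - 1, -1, -1):
            if idx.label[i] is not None:
                idx.leafset[i] = frozenset((idx.label[i],))
            else:
                acc = set()
                for c in idx.children[i]:
                    acc |= idx.leafset[c]
                idx.leafset[i] = frozenset(acc)
        idx.all_labels = idx.leafset[idx.root]
        return idx


def annotate_supports_on_nodes(ptree: PhyloTree) -> None:
    """Copy split supports onto internal node labels for newick output."""
    all_labels = frozenset(ptree.leaf_labels)
    for node in ptree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sup = ptree.supports.get(canonical_split(below, all_labels))
        if sup is not None:
            node.label = f"{sup:g}"


def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial splits of a tree (both sides >= 2) as canonical keys."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_labels)
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= n - 2:
            out.add(canonical_split(below, all_labels))
    return out


def neighbor_joining(dist: np.ndarray, labels: Sequence[str],
                     taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                     ) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree (trifurcating seed node). On an additive input
    matrix the leaf-to-leaf path lengths reproduce the input exactly.
    Branch-length estimates that come out negative are clamped to zero;
    Q-matrix ties are broken toward the lowest (i, j) index pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label length mismatch")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have zero diagonal")

    tns = taxon_namespace or dendropy.TaxonNamespace()
    nodes: List[dendropy.Node] = []
    for lab in labels:
        taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    D = dist.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = lowest (i, j) tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        g_new = D.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [g_new]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = dendropy.Node()
    for g, length in ((a, 0.5 * (dab + dac - dbc)),
                      (b, 0.5 * (dab + dbc - dac)),
                      (c, 0.5 * (dac + dbc - dab))):
        nodes[g].edge.length = max(length, 0.0)
        root.add_child(nodes[g])
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> Dict[Tuple[str, str], float]:
    """All pairwise leaf-to-leaf path lengths, keyed both ways."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    out: Dict[Tuple[str, str], float] = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            d = pdm.patristic_distance(t1, t2)
            out[(t1.label, t2.label)] = d
            out[(t2.label, t1.label)] = d
    return out


def root_tree(ptree: PhyloTree, outgroup_groups: Optional[set] = None,
              exclude: Optional[set] = None) -> PhyloTree:
    """Return a rooted copy: by the outgroup taxon group when one is
    designated and present, otherwise by midpoint. ``exclude`` labels (e.g.
    the query) are never used as outgroup."""
    tree = ptree.tree.clone(depth=1)
    rooted = False
    if outgroup_groups:
        og = [lf.taxon.label for lf in tree.leaf_node_iter()
              if ptree.groups.get(lf.taxon.label) in outgroup_groups
              and (not exclude or lf.taxon.label not in exclude)]
        if og:
            try:
                mrca = tree.mrca(taxon_labels=og)
                if mrca is not tree.seed_node and mrca.edge.length is not None:
                    tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
                    rooted = True
            except Exception:
                rooted = False
    if not rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return PhyloTree(tree=tree, groups=dict(ptree.groups),
                     supports=dict(ptree.supports))


def parse_newick(path, groups: Mapping[str, str]) -> PhyloTree:
    """Read an externally built newick tree (e.g. an ML tree). Internal node
    labels, when numeric, are taken as bootstrap-style supports."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    supports: Dict[SplitKey, float] = {}
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or node.label is None:
            continue
        try:
            sup = float(node.label)
        except ValueError:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        supports[canonical_split(below, all_labels)] = sup
    return PhyloTree(tree=tree, groups=dict(groups), supports=supports)
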