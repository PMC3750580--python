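"""Distance-tree building and donor-nesting HGT classification.

The pipeline's tree method is neighbor joining on Poisson-corrected protein
distances with column-bootstrap supports. Externally built newick trees
(e.g. ML trees) can be fed straight to the classifier via
:func:`hgtscan.trees.parse_newick`.

A query is called HGT when some supported clade contains it, all the other
leaves of that clade belong to one donor group (recipient-group leaves are
tolerated inside, covering ancient pre-speciation transfers), and enough
distinct donor species sit basal to the clade.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .trees import PhyloTree, canonical_split, neighbor_joining, root_tree, tree_splits

GAP = "-"


@dataclass
class MultipleAlignment:
    """Aligned amino-acid rows with taxon-group tags."""

    labels: List[str]
    rows: List[str]
    groups: Dict[str, str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            len(self.rows), self.length)

    def subset_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        mat = self.matrix()[:, list(cols)]
        rows = [bytes(mat[i]).decode() for i in range(mat.shape[0])]
        return MultipleAlignment(labels=list(self.labels), rows=rows,
                                 groups=dict(self.groups))


def trim_conserved_blocks(aln: MultipleAlignment, max_gap_frac: float = 0.5,
                          min_block_len: int = 10,
                          min_conservation: float = 0.3
                          ) -> Tuple[MultipleAlignment, List[Tuple[int, int]]]:
    """Keep maximal runs of conserved columns (Gblocks-flavored trimming).

    A column is conserved when its gap fraction is <= max_gap_frac and its
    majority residue (gaps excluded) reaches frequency >= min_conservation
    among non-gap characters. Runs shorter than min_block_len are dropped.
    Returns the trimmed alignment and the kept [start, end) intervals.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    mat = aln.matrix()
    n_rows = mat.shape[0]
    keep = np.zeros(aln.length, dtype=bool)
    for c in range(aln.length):
        col = mat[:, c]
        gaps = int(np.count_nonzero(col == GAP.encode()))
        if gaps / n_rows > max_gap_frac:
            continue
        residues = col[col != GAP.encode()]
        if residues.size == 0:
            continue
        _, counts = np.unique(residues, return_counts=True)
        if counts.max() / residues.size >= min_conservation:
            keep[c] = True
    blocks: List[Tuple[int, int]] = []
    start = None
    for c in range(aln.length + 1):
        if c < aln.length and keep[c]:
            if start is None:
                start = c
        else:
            if start is not None:
                if c - start >= min_block_len:
                    blocks.append((start, c))
                start = None
    if not blocks:
        raise ValueError("no conserved blocks")
    cols = [c for (a, b) in blocks for c in range(a, b)]
    return aln.subset_columns(cols), blocks


def compute_distance_matrix(aln: MultipleAlignment, p_cap: float = 0.95
                            ) -> np.ndarray:
    """Poisson-corrected pairwise distances d = -ln(1 - p) over columns where
    both rows are non-gap; p >= p_cap is capped with a warning."""
    n = len(aln.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    mat = aln.matrix()
    nongap = mat != GAP.encode()
    D = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns for {aln.labels[i]} / {aln.labels[j]}")
            p = float(np.count_nonzero(mat[i, both] != mat[j, both])) / m
            if p >= p_cap:
                p = p_cap
                capped = True
            D[i, j] = D[j, i] = -math.log(1.0 - p)
    if capped:
        warnings.warn(f"some distances capped at p = {p_cap}")
    return D


def build_nj_tree(aln_or_matrix, labels: Optional[Sequence[str]] = None,
                  groups: Optional[Mapping[str, str]] = None) -> PhyloTree:
    """NJ tree from an alignment (distances computed here) or a distance
    matrix plus labels."""
    if isinstance(aln_or_matrix, MultipleAlignment):
        aln = aln_or_matrix
        D = compute_distance_matrix(aln)
        labels = aln.labels
        groups = aln.groups
    else:
        D = np.asarray(aln_or_matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        groups = dict(groups or {})
    tree = neighbor_joining(D, list(labels))
    return PhyloTree(tree=tree, groups=dict(groups))


def _distance_matrix_fast(mat: np.ndarray, nongap: np.ndarray,
                          p_cap: float = 0.95) -> np.ndarray:
    """Vectorized Poisson distances for bootstrap replicates."""
    n = mat.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        m = both.sum(axis=1)
        m = np.maximum(m, 1)
        p = diff.sum(axis=1) / m
        p = np.minimum(p, p_cap)
        D[i, i + 1:] = -np.log(1.0 - p)
    return D + D.T


def bootstrap_support(aln: MultipleAlignment, n_reps: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """Point-estimate NJ tree with column-bootstrap split supports (percent
    of replicates containing each split of the point tree)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.length < 1:
        raise ValueError("alignment must have at least one column")
    # canonical row order: makes supports invariant to input leaf order
    # despite deterministic index-based tie-breaking inside NJ
    order = sorted(range(len(aln.labels)), key=lambda i: aln.labels[i])
    aln = MultipleAlignment(labels=[aln.labels[i] for i in order],
                            rows=[aln.rows[i] for i in order],
                            groups=dict(aln.groups))
    point = build_nj_tree(aln)
    target_splits = tree_splits(point.tree)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    mat = aln.matrix()
    nongap = mat != GAP.encode()
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        Db = _distance_matrix_fast(mat[:, cols], nongap[:, cols])
        rep_tree = neighbor_joining(Db, aln.labels)
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    point.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return point


@dataclass(frozen=True)
class HgtParams:
    min_basal_donor_species: int = 3
    min_support: float = 70.0
    recipient_groups: frozenset = frozenset({"arthropod"})
    donor_groups: frozenset = frozenset({"bacteria", "fungi"})
    outgroup_groups: Optional[frozenset] = None


@dataclass
class HGTCall:
    query_id: str
    verdict: str                      # hgt | no_hgt | ambiguous
    donor_group: Optional[str] = None
    nesting_support: Optional[float] = None
    n_basal_donor_species: int = 0
    notes: str = ""


def _clade_support(ptree: PhyloTree, leafset, all_labels) -> Optional[float]:
    if not ptree.supports:
        return None  # unsupported tree: treated as fully supported
    return ptree.supports.get(canonical_split(leafset, all_labels))


def _evaluate_clade(ptree: PhyloTree, leafset, all_labels, query_id: str,
                    params: HgtParams) -> Optional[Tuple[str, float, int, bool]]:
    """Apply the nesting rule to one clade; return (donor_group, support,
    n_basal, has_recipient_inside) or None."""
    others = leafset - {query_id}
    if not others:
        return None
    groups = ptree.groups
    for donor in sorted(params.donor_groups):
        in_donor = [o for o in others if groups.get(o) == donor]
        tolerated = [o for o in others
                     if groups.get(o) in params.recipient_groups]
        if not in_donor:
            continue
        if len(in_donor) + len(tolerated) != len(others):
            continue
        outside = all_labels - leafset
        basal = {o for o in outside if groups.get(o) == donor}
        if len(basal) < params.min_basal_donor_species:
            continue
        sup = _clade_support(ptree, leafset, all_labels)
        if sup is None:
            sup = 100.0
        if sup < params.min_support:
            continue
        return donor, sup, len(basal), bool(tolerated)
    return None


def _verdict_from_candidates(ptree: PhyloTree, query_id: str,
                             candidates: List[Tuple[int, Tuple]],
                             smallest_containing: Optional[frozenset],
                             params: HgtParams) -> HGTCall:
    if candidates:
        candidates.sort(key=lambda t: t[0])
        _, (donor, sup, n_basal, tolerated) = candidates[0]
        notes = "pre-speciation transfer" if tolerated else ""
        return HGTCall(query_id=query_id, verdict="hgt", donor_group=donor,
                       nesting_support=sup, n_basal_donor_species=n_basal,
                       notes=notes)
    if smallest_containing is not None:
        others = smallest_containing - {query_id}
        if others and all(ptree.groups.get(o) in params.recipient_groups
                          for o in others):
            return HGTCall(query_id=query_id, verdict="no_hgt",
                           notes="clusters with recipient group")
    return HGTCall(query_id=query_id, verdict="ambiguous")


def classify_hgt_topology(ptree: PhyloTree, query_id: str,
                          params: HgtParams = HgtParams()) -> HGTCall:
    """Classify one query leaf on a tree.

    Unrooted input is rooted by the designated outgroup group when present,
    else by midpoint; trees flagged rooted are used as-is. Only ancestors of
    the query need checking: every clade containing the query is one of its
    ancestor nodes.
    """
    if query_id not in set(l for l in ptree.groups) and query_id not in set(
            lf.taxon.label for lf in ptree.tree.leaf_node_iter()):
        raise ValueError(f"query {query_id!r} absent from tree")
    rooted = ptree if ptree.tree.is_rooted else root_tree(
        ptree, params.outgroup_groups, exclude={query_id})
    idx = rooted.topology_index()
    if query_id not in idx.leaf_node_of:
        raise ValueError(f"query {query_id!r} absent from tree")
    all_labels = idx.all_labels
    node = idx.leaf_node_of[query_id]
    candidates: List[Tuple[int, Tuple]] = []
    smallest: Optional[frozenset] = None
    node = idx.parent[node]
    while node != -1:
        leafset = idx.leafset[node]
        if smallest is None and len(leafset) > 1:
            smallest = leafset
        if len(leafset) < len(all_labels):  # whole tree has no basal outside
            res = _evaluate_clade(rooted, leafset, all_labels, query_id, params)
            if res is not None:
                candidates.append((len(leafset), res))
        node = idx.parent[node]
    return _verdict_from_candidates(rooted, query_id, candidates, smallest, params)


def brute_force_classifier(ptree: PhyloTree, query_id: str,
                           params: HgtParams = HgtParams()) -> HGTCall:
    """Oracle: enumerate every clade of the rooted tree explicitly and apply
    the rule verbatim. Test-only; refuses trees with more than 12 leaves."""
    n_leaves = sum(1 for _ in ptree.tree.leaf_node_iter())
    if n_leaves > 12:
        raise ValueError("brute-force classifier limited to <= 12 leaves")
    rooted = ptree if ptree.tree.is_rooted else root_tree(
        ptree, params.outgroup_groups, exclude={query_id})
    all_clades: List[frozenset] = []
    for node in rooted.tree.preorder_node_iter():
        all_clades.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    all_labels = frozenset(lf.taxon.label for lf in rooted.tree.leaf_node_iter())
    if query_id not in all_labels:
        raise ValueError(f"query {query_id!r} absent from tree")
    candidates: List[Tuple[int, Tuple]] = []
    containing = [c for c in all_clades
                  if query_id in c and len(c) > 1]
    for clade in containing:
        if len(clade) == len(all_labels):
            continue
        res = _evaluate_clade(rooted, clade, all_labels, query_id, params)
        if res is not None:
            candidates.append((len(clade), res))
    smallest = min(containing, key=len) if containing else None
    return _verdict_from_candidates(rooted, query_id, candidates, smallest, params)


def calls_to_tsv(path, calls: Sequence[HGTCall]) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tverdict\tdonor_group\tnesting_support\t"
                 "n_basal_donor_species\tnotes\n")
        for c in calls:
            fh.write("\t".join([
                c.query_id, c.verdict, c.donor_group or "NA",
                "NA" if c.nesting_support is None else f"{c.nesting_support:.1f}",
                str(c.n_basal_donor_species), c.notes]) + "\n")
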