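"""Tree-building and HGT-classification tests."""

import math

import dendropy
import numpy as np
import pytest

from hgtscan import phylo, trees
from hgtscan.phylo import HgtParams, MultipleAlignment
from hgtscan.trees import PhyloTree, neighbor_joining, patristic_distances


def make_aln(rows, groups=None, labels=None):
    labels = labels or [f"t{i}" for i in range(len(rows))]
    groups = groups or {l: "bacteria" for l in labels}
    return MultipleAlignment(labels=labels, rows=rows, groups=groups)


def ptree_from_newick(newick, groups, supports=None):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = False
    pt = PhyloTree(tree=t, groups=groups)
    if supports is not None:
        all_labels = frozenset(l.taxon.label for l in t.leaf_node_iter())
        pt.supports = {trees.canonical_split(k, all_labels): v
                       for k, v in supports.items()}
    return pt


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def test_trim_identity_on_conserved():
    aln = make_aln(["MKVL", "MKVL", "MKVL"])
    trimmed, blocks = phylo.trim_conserved_blocks(aln, min_block_len=2)
    assert trimmed.rows == aln.rows
    assert blocks == [(0, 4)]


def test_trim_removes_all_gap_column():
    aln = make_aln(["MK-VLAAAAA", "MK-VLAAAAA", "MK-VLAAAAA"])
    trimmed, _ = phylo.trim_conserved_blocks(aln, min_block_len=2)
    assert trimmed.rows == ["MKVLAAAAA"] * 3 or all(
        "-" not in r for r in trimmed.rows)


def test_trim_matches_column_scan_oracle():
    rng = np.random.default_rng(2)
    alphabet = "ACDEFG-"
    rows = ["".join(rng.choice(list(alphabet), size=120)) for _ in range(6)]
    aln = make_aln(rows)
    params = dict(max_gap_frac=0.5, min_block_len=10, min_conservation=0.5)
    # independent column-by-column oracle
    keep = []
    for c in range(120):
        col = [r[c] for r in rows]
        gapfrac = col.count("-") / len(col)
        residues = [x for x in col if x != "-"]
        ok = gapfrac <= 0.5 and residues and (
            max(residues.count(x) for x in set(residues)) / len(residues) >= 0.5)
        keep.append(ok)
    oracle_cols = []
    start = None
    for c in range(121):
        if c < 120 and keep[c]:
            if start is None:
                start = c
        else:
            if start is not None and c - start >= 10:
                oracle_cols.extend(range(start, c))
            start = None
    if not oracle_cols:
        with pytest.raises(ValueError):
            phylo.trim_conserved_blocks(aln, **params)
    else:
        trimmed, _ = phylo.trim_conserved_blocks(aln, **params)
        want = ["".join(r[c] for c in oracle_cols) for r in rows]
        assert trimmed.rows == want


def test_trim_all_removed_errors():
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            for _ in range(8)]
    with pytest.raises(ValueError):
        phylo.trim_conserved_blocks(make_aln(rows), min_conservation=0.99)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_identical_rows_zero():
    D = phylo.compute_distance_matrix(make_aln(["MKVL", "MKVL"]))
    assert D[0, 1] == 0.0


def test_distance_closed_form():
    # 10% mismatching columns -> -ln(0.9)
    row_a = "A" * 100
    row_b = "A" * 90 + "C" * 10
    D = phylo.compute_distance_matrix(make_aln([row_a, row_b]))
    assert D[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)


def test_distance_monotone_in_p():
    prev = -1.0
    for k in range(0, 90, 10):
        row_a = "A" * 100
        row_b = "C" * k + "A" * (100 - k)
        d = phylo.compute_distance_matrix(make_aln([row_a, row_b]))[0, 1]
        assert d > prev
        prev = d


def test_distance_no_comparable_columns_errors():
    with pytest.raises(ValueError):
        phylo.compute_distance_matrix(make_aln(["A---", "---C"]))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = neighbor_joining(D, ["A", "B", "C"])
    pd = patristic_distances(tree)
    assert pd[("A", "B")] == pytest.approx(3.0, abs=1e-9)
    assert pd[("A", "C")] == pytest.approx(4.0, abs=1e-9)
    assert pd[("B", "C")] == pytest.approx(5.0, abs=1e-9)


def test_nj_four_taxon_roundtrip():
    # tree ((A:1,B:2):1,(C:3,D:1)); distances computed by hand
    D = np.array([
        [0, 3, 5, 3],
        [3, 0, 6, 4],
        [5, 6, 0, 4],
        [3, 4, 4, 0]], dtype=float)
    tree = neighbor_joining(D, list("ABCD"))
    pd = patristic_distances(tree)
    for (i, a) in enumerate("ABCD"):
        for (j, b) in enumerate("ABCD"):
            if i < j:
                assert pd[(a, b)] == pytest.approx(D[i, j], abs=1e-9)
    assert frozenset({"A", "B"}) in trees.tree_splits(tree) or \
        frozenset({"C", "D"}) in trees.tree_splits(tree)


def random_additive_case(rng, n=6):
    """Random binary tree over n leaves (independent representation:
    adjacency dict) and its exact path-length matrix."""
    nodes = [f"L{i}" for i in range(n)]
    adj = {x: {} for x in nodes}
    avail = nodes[:]
    nxt = 0
    while len(avail) > 2:
        i, j = sorted(rng.choice(len(avail), size=2, replace=False))
        a, b = avail[i], avail[j]
        new = f"I{nxt}"
        nxt += 1
        adj[new] = {}
        for x in (a, b):
            w = float(rng.uniform(0.1, 2.0))
            adj[new][x] = w
            adj[x][new] = w
        avail = [x for x in avail if x not in (a, b)] + [new]
    w = float(rng.uniform(0.1, 2.0))
    a, b = avail
    adj[a][b] = w
    adj[b][a] = w

    def dist(u, v):
        stack = [(u, None, 0.0)]
        while stack:
            node, prev, d = stack.pop()
            if node == v:
                return d
            for nb, wt in adj[node].items():
                if nb != prev:
                    stack.append((nb, node, d + wt))
        raise RuntimeError

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(nodes[i], nodes[j])
    # splits of the generating tree
    splits = set()
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    leafset = frozenset(nodes)
    for u, v in edges:
        side = set()
        stack = [(u, v)]
        while stack:
            node, prev = stack.pop()
            if node in leafset:
                side.add(node)
            for nb in adj[node]:
                if nb != prev:
                    stack.append((nb, node))
        if 2 <= len(side) <= n - 2:
            splits.add(trees.canonical_split(side, leafset))
    return nodes, D, splits


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(10)
    for _ in range(10):
        labels, D, want_splits = random_additive_case(rng)
        tree = neighbor_joining(D, labels)
        assert trees.tree_splits(tree) == want_splits
        pd = patristic_distances(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pd[(a, b)] == pytest.approx(D[i, j], abs=1e-9)


def test_nj_nonsymmetric_errors():
    D = np.array([[0, 1.0, 2], [1.1, 0, 2], [2, 2, 0.0]])
    with pytest.raises(ValueError):
        neighbor_joining(D, list("ABC"))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _clean_alignment(rng=None, per_edge=25):
    """Perfect hierarchical signal on ((a0,a1),(a2,a3)),((b0,b1),(b2,b3)):
    every clade of the generating tree gets its own diagnostic columns, so
    all supports should be maximal."""
    labels = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    clades = [set(labels[:4]), set(labels[4:]),
              {"a0", "a1"}, {"a2", "a3"}, {"b0", "b1"}, {"b2", "b3"}]
    clades += [{l} for l in labels]
    cols = []
    for clade in clades:
        for _ in range(per_edge):
            cols.append(["K" if l in clade else "A" for l in labels])
    rows = ["".join(col[i] for col in cols) for i in range(len(labels))]
    return make_aln(rows, labels=labels,
                    groups={l: ("arthropod" if l[0] == "a" else "bacteria")
                            for l in labels})


def test_bootstrap_clean_signal_high_support():
    aln = _clean_alignment(np.random.default_rng(1))
    pt = phylo.bootstrap_support(aln, n_reps=100, seed=5)
    assert pt.supports
    assert all(v >= 95 for v in pt.supports.values())


def test_bootstrap_single_rep_binary_supports():
    aln = _clean_alignment(np.random.default_rng(2))
    pt = phylo.bootstrap_support(aln, n_reps=1, seed=1)
    assert set(pt.supports.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic():
    aln = _clean_alignment(np.random.default_rng(3))
    s1 = phylo.bootstrap_support(aln, n_reps=30, seed=9).supports
    s2 = phylo.bootstrap_support(aln, n_reps=30, seed=9).supports
    assert s1 == s2


def test_bootstrap_invariant_to_leaf_order():
    rng = np.random.default_rng(4)
    aln = _clean_alignment(rng)
    perm = list(np.random.default_rng(0).permutation(len(aln.labels)))
    aln2 = MultipleAlignment(labels=[aln.labels[i] for i in perm],
                             rows=[aln.rows[i] for i in perm],
                             groups=aln.groups)
    s1 = phylo.bootstrap_support(aln, n_reps=50, seed=2).supports
    s2 = phylo.bootstrap_support(aln2, n_reps=50, seed=2).supports
    assert s1 == s2


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

GROUPS_SPEC = {"query": "arthropod",
               **{f"b{i}": "bacteria" for i in range(1, 6)},
               **{f"e{i}": "other_eukaryote" for i in range(1, 4)}}


def test_classify_nested_query_is_hgt():
    nwk = ("(((query:0.1,(b1:0.1,b2:0.1):0.1):0.1,((b3:0.1,b4:0.1):0.1,"
           "b5:0.1):0.1):0.5,(e1:0.1,(e2:0.1,e3:0.1):0.1):0.5);")
    pt = ptree_from_newick(nwk, GROUPS_SPEC)
    call = phylo.classify_hgt_topology(pt, "query")
    assert call.verdict == "hgt"
    assert call.donor_group == "bacteria"
    assert call.n_basal_donor_species >= 3
    oracle = phylo.brute_force_classifier(pt, "query")
    assert oracle.verdict == "hgt" and oracle.donor_group == "bacteria"


def test_classify_query_with_arthropods_no_hgt():
    groups = {"query": "arthropod", "a1": "arthropod", "a2": "arthropod",
              **{f"b{i}": "bacteria" for i in range(1, 5)}}
    nwk = ("((query:0.05,(a1:0.05,a2:0.05):0.05):0.5,"
           "((b1:0.1,b2:0.1):0.1,(b3:0.1,b4:0.1):0.1):0.5);")
    pt = ptree_from_newick(nwk, groups)
    call = phylo.classify_hgt_topology(pt, "query")
    assert call.verdict == "no_hgt"


def test_classify_pre_speciation_pattern():
    # query + other ecdysozoan homologs jointly nested within bacteria
    groups = {"query": "arthropod", "nem1": "arthropod", "art1": "arthropod",
              **{f"b{i}": "bacteria" for i in range(1, 7)},
              "e1": "other_eukaryote", "e2": "other_eukaryote"}
    nwk = ("((((query:0.1,(nem1:0.1,art1:0.1):0.05):0.1,(b1:0.1,b2:0.1):0.1)"
           ":0.1,((b3:0.1,b4:0.1):0.1,(b5:0.1,b6:0.1):0.1):0.1):0.6,"
           "(e1:0.1,e2:0.1):0.6);")
    pt = ptree_from_newick(nwk, groups)
    call = phylo.classify_hgt_topology(pt, "query")
    assert call.verdict == "hgt"
    assert call.donor_group == "bacteria"
    assert call.notes == "pre-speciation transfer"


def test_classify_low_support_blocks_call():
    nwk = ("(((query:0.1,(b1:0.1,b2:0.1):0.1):0.1,((b3:0.1,b4:0.1):0.1,"
           "b5:0.1):0.1):0.5,(e1:0.1,(e2:0.1,e3:0.1):0.1):0.5);")
    pt = ptree_from_newick(nwk, GROUPS_SPEC)
    all_labels = frozenset(GROUPS_SPEC)
    pt.supports = {trees.canonical_split(s, all_labels): 10.0
                   for s in [frozenset({"query", "b1", "b2"}),
                             frozenset({"query", "b1", "b2", "b3", "b4", "b5"})]}
    call = phylo.classify_hgt_topology(pt, "query")
    assert call.verdict != "hgt"


def test_star_tree_ambiguous():
    labels = ["query"] + [f"b{i}" for i in range(1, 6)] + ["e1"]
    nwk = "(" + ",".join(f"{l}:1.0" for l in labels) + ");"
    groups = {"query": "arthropod", "e1": "other_eukaryote",
              **{f"b{i}": "bacteria" for i in range(1, 6)}}
    pt = ptree_from_newick(nwk, groups)
    call = phylo.classify_hgt_topology(pt, "query")
    assert call.verdict == "ambiguous"
    oracle = phylo.brute_force_classifier(pt, "query")
    assert oracle.verdict == "ambiguous"


def test_query_absent_errors():
    pt = ptree_from_newick("((b1:1,b2:1):1,(b3:1,b4:1):1);",
                           {f"b{i}": "bacteria" for i in range(1, 5)})
    with pytest.raises(ValueError):
        phylo.classify_hgt_topology(pt, "nope")


def test_brute_force_refuses_large_trees():
    labels = [f"b{i}" for i in range(13)]
    nwk = "(" + ",".join(f"{l}:1" for l in labels) + ");"
    pt = ptree_from_newick(nwk, {l: "bacteria" for l in labels})
    with pytest.raises(ValueError):
        phylo.brute_force_classifier(pt, "b0")


def random_newick(labels, rng):
    """Random unrooted topology by sequential leaf attachment."""
    parts = {l: f"{l}:{rng.uniform(0.2, 1.5):.3f}" for l in labels[:3]}
    subtrees = list(parts.values())
    for lab in labels[3:]:
        i = int(rng.integers(len(subtrees)))
        old = subtrees[i]
        subtrees[i] = (f"({old},{lab}:{rng.uniform(0.2, 1.5):.3f})"
                       f":{rng.uniform(0.2, 1.5):.3f}")
        if rng.random() < 0.5:
            subtrees.append(subtrees.pop(i))
    return "(" + ",".join(subtrees) + ");"


def test_classifiers_agree_on_random_trees():
    rng = np.random.default_rng(8)
    params = HgtParams(min_basal_donor_species=2)
    for rep in range(60):
        n = int(rng.integers(4, 9))
        labels = ["query"] + [f"x{i}" for i in range(n - 1)]
        nwk = random_newick(labels, rng)
        groups = {lab: ("arthropod" if lab == "query"
                        else ("bacteria" if rng.random() < 0.5 else "arthropod"))
                  for lab in labels}
        pt = ptree_from_newick(nwk, groups)
        a = phylo.classify_hgt_topology(pt, "query", params)
        b = phylo.brute_force_classifier(pt, "query", params)
        assert (a.verdict, a.donor_group) == (b.verdict, b.donor_group), rep


def test_newick_roundtrip_with_supports(tmp_path):
    aln = _clean_alignment(np.random.default_rng(6))
    pt = phylo.bootstrap_support(aln, n_reps=20, seed=3)
    path = tmp_path / "tree.nwk"
    pt.write_newick(path)
    back = trees.parse_newick(path, pt.groups)
    assert set(back.supports.values()) <= set(
        round(v, 6) for v in pt.supports.values()) | set(pt.supports.values())
    assert sorted(back.leaf_labels) == sorted(pt.leaf_labels)
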