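import numpy as np
import pytest
import skbio

from sagkit.phylo import (
    SupportedTree,
    bootstrap_support,
    build_tree,
    jc_distance_matrix,
    neighbor_joining,
    read_newick,
    topology_concordance,
    tree_splits,
)
from tests.conftest import random_dna


def test_jc_distance_matrix_closed_form():
    aln = [("a", "A" * 100), ("b", "A" * 90 + "C" * 10), ("c", "A" * 100)]
    names, D = jc_distance_matrix(aln)
    expected = -0.75 * np.log(1 - 0.4 / 3)
    assert D[names.index("a"), names.index("b")] == pytest.approx(expected)
    assert D[names.index("a"), names.index("c")] == 0.0


def test_jc_distance_saturation_names_pair():
    aln = [("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA")]
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        jc_distance_matrix(aln)


def test_nj_additive_four_taxon_matrix():
    # additive distances on the tree ((A:1,B:1):2,C:2,D:2) with AB|CD split
    names = ["A", "B", "C", "D"]
    D = np.array([
        [0, 2, 5, 5],
        [2, 0, 5, 5],
        [5, 5, 0, 4],
        [5, 5, 4, 0],
    ], dtype=float)
    root = neighbor_joining(names, D)
    splits = tree_splits(root)
    assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits
    # additive matrix: NJ recovers exact path lengths
    def leaf_depths(node, acc=0.0, out=None):
        out = {} if out is None else out
        if not node.children:
            out[node.name] = acc + node.length
        for c in node.children:
            leaf_depths(c, acc + (node.length if node.name is None else 0), out)
        return out
    assert sorted(root.leaves()) == names


def test_nj_rejects_too_few_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(["a", "b"], np.zeros((2, 2)))


def test_nj_matches_skbio_topology(rng):
    seqs = {}
    anc = random_dna(rng, 400)
    drift = {"a": 2, "b": 4, "c": 18, "d": 20, "e": 40}
    for name, n_mut in drift.items():
        s = list(anc)
        for pos in rng.choice(400, size=n_mut, replace=False):
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
        seqs[name] = "".join(s)
    aln = sorted(seqs.items())
    names, D = jc_distance_matrix(aln)
    ours = tree_splits(neighbor_joining(names, D))
    dm = skbio.DistanceMatrix(D, ids=names)
    sk_tree = skbio.tree.nj(dm)
    theirs = set()
    taxa = set(names)
    anchor = min(taxa)
    for node in sk_tree.non_tips():
        below = {t.name for t in node.tips()}
        if 2 <= len(below) <= len(taxa) - 2:
            theirs.add(frozenset(below if anchor not in below else taxa - below))
    assert ours == theirs


def test_bootstrap_supports_range_and_determinism(rng):
    anc = random_dna(rng, 300)
    aln = []
    for i, n_mut in enumerate((3, 5, 25, 30)):
        s = list(anc)
        for pos in rng.choice(300, size=n_mut, replace=False):
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 2) % 4]
        aln.append((f"t{i}", "".join(s)))
    t1 = bootstrap_support(aln, reps=20, seed=11)
    t2 = bootstrap_support(aln, reps=20, seed=11)
    assert t1.newick() == t2.newick()
    assert all(0.0 <= v <= 100.0 for v in t1.supports.values())
    single = bootstrap_support(aln, reps=1, seed=11)
    assert all(v in (0.0, 100.0) for v in single.supports.values())
    with pytest.raises(ValueError):
        bootstrap_support(aln, reps=0)


def test_newick_round_trip():
    tree = read_newick("((a:1,b:1):0.5,c:2,d:2);")
    assert sorted(tree.root.leaves()) == ["a", "b", "c", "d"]
    assert tree_splits(tree.root) == {frozenset({"c", "d"})}
    # canonical orientation: side not containing the smallest taxon


def test_topology_concordance_counts():
    ref = read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    congruent = read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    congruent.supports = {s: 95.0 for s in tree_splits(congruent.root)}
    incongruent = read_newick("((a:1,c:1):1,(b:1,d:1):1,e:1);")
    incongruent.supports = {s: 99.0 for s in tree_splits(incongruent.root)}
    weak = read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    weak.supports = {s: 40.0 for s in tree_splits(weak.root)}
    result = topology_concordance([congruent, incongruent, weak], ref,
                                  support_threshold=80.0)
    split_cd = frozenset({"c", "d"})
    assert result[split_cd]["testable"] == 3
    assert result[split_cd]["congruent"] == 2
    assert result[split_cd]["supported"] == 1
    assert result[split_cd]["percent"] == pytest.approx(200.0 / 3)


def test_concordance_excludes_trees_missing_taxa():
    ref = read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    reduced = read_newick("((a:1,b:1):1,c:1,e:1);")  # cannot display cd split
    result = topology_concordance([reduced], ref)
    assert result[frozenset({"c", "d"})]["testable"] == 0
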