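import numpy as np
import pytest

from sagkit.iodata import GeneRecord
from sagkit.orthomap import (
    SimilarityHit,
    all_vs_all_search,
    build_graph_and_cluster,
    classify_unclustered,
    markov_cluster,
    resolve_paralogs,
    shared_and_accessory_sets,
)


def _gene(genome, gene_id, protein):
    cds = "ATG" + "GCT" * max(1, len(protein)) + "TAA"
    g = GeneRecord(genome, "c", gene_id, 0, len(cds), "+", cds)
    g.protein = protein
    return g


def _protein(rng, n=120):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(20, size=n))


def _mutate(rng, protein, n_changes):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    for pos in rng.choice(len(out), size=n_changes, replace=False):
        out[pos] = aas[(aas.index(out[pos]) + 1) % 20]
    return "".join(out)


def test_all_vs_all_identical_pair(rng):
    p = _protein(rng)
    hits = all_vs_all_search([_gene("A", "a1", p), _gene("B", "b1", p)])
    assert len(hits) == 1
    h = hits[0]
    assert h.identity == pytest.approx(100.0)
    assert h.query_coverage == pytest.approx(1.0)
    assert h.evalue < 1e-5


def test_all_vs_all_skips_unrelated(rng):
    hits = all_vs_all_search([_gene("A", "a1", _protein(rng)),
                              _gene("B", "b1", _protein(rng))])
    assert hits == []


def test_markov_cluster_two_triangles():
    edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
    clusters = markov_cluster(list("abcxyz"), edges)
    assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]


def test_markov_cluster_singleton_and_empty():
    assert markov_cluster([], []) == []
    clusters = markov_cluster(["a", "b", "q"], [("a", "b", 2.0)])
    assert sorted(map(sorted, clusters)) == [["a", "b"], ["q"]]


def test_markov_cluster_weak_bridge_splits():
    # two dense cliques joined by one weak edge separate at inflation 1.5
    edges = [("a", "b", 5.0), ("b", "c", 5.0), ("a", "c", 5.0),
             ("x", "y", 5.0), ("y", "z", 5.0), ("x", "z", 5.0),
             ("c", "x", 0.05)]
    clusters = markov_cluster(list("abcxyz"), edges)
    assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]


def test_build_graph_filters_and_names_clusters(rng):
    p = _protein(rng)
    genes = [_gene("A", "a1", p), _gene("B", "b1", _mutate(rng, p, 6)),
             _gene("C", "c1", _protein(rng))]
    hits = all_vs_all_search(genes)
    catalog = build_graph_and_cluster(hits, genes)
    assert list(catalog.clusters) == ["OG00001"]
    assert catalog.clusters["OG00001"] == ["a1", "b1"]
    assert catalog.cluster_of("a1") == "OG00001"
    assert catalog.cluster_of("c1") is None


def test_low_identity_hits_do_not_cluster(rng):
    p = _protein(rng)
    genes = [_gene("A", "a1", p), _gene("B", "b1", _mutate(rng, p, 70))]
    hits = all_vs_all_search(genes)
    catalog = build_graph_and_cluster(hits, genes)
    assert catalog.clusters == {}


def test_resolve_paralogs_keeps_most_similar_copy(rng):
    p = _protein(rng)
    genes = [_gene("A", "a1", p), _gene("A", "a2", _mutate(rng, p, 10)),
             _gene("B", "b1", p)]
    hits = all_vs_all_search(genes)
    catalog = build_graph_and_cluster(hits, genes)
    catalog = resolve_paralogs(catalog, hits)
    assert catalog.clusters["OG00001"] == ["a1", "b1"]
    assert catalog.classifications["a2"] == "paralog_dropped"


def test_resolve_paralogs_tie_keeps_smaller_id():
    catalog_hits = [
        SimilarityHit("a1", "b1", 90.0, 1, 1, 100, 1e-30),
        SimilarityHit("a2", "b1", 90.0, 1, 1, 100, 1e-30),
    ]
    from sagkit.orthomap import OrthologCatalog
    catalog = OrthologCatalog(
        clusters={"OG00001": ["a1", "a2", "b1"]},
        classifications={g: "clustered" for g in ("a1", "a2", "b1")},
        gene_genome={"a1": "A", "a2": "A", "b1": "B"})
    catalog = resolve_paralogs(catalog, catalog_hits)
    assert catalog.clusters["OG00001"] == ["a1", "b1"]


def test_classify_unclustered(rng):
    p = _protein(rng)
    # b1 hits a1 but below clustering thresholds (remnant); c1 hits nothing
    genes = [_gene("A", "a1", p), _gene("B", "b1", _mutate(rng, p, 70)),
             _gene("C", "c1", _protein(rng))]
    hits = all_vs_all_search(genes)
    catalog = build_graph_and_cluster(hits, genes)
    catalog = classify_unclustered(genes, hits, catalog)
    assert catalog.classifications["c1"] == "genome_specific"
    if hits:  # divergent pair still aligned: remnant
        assert catalog.classifications["b1"] == "remnant"


def test_shared_and_accessory_sets(rng):
    from sagkit.orthomap import OrthologCatalog
    catalog = OrthologCatalog(
        clusters={"OG1": ["a1", "b1", "c1"], "OG2": ["b2", "c2"]},
        classifications={"a1": "clustered", "b1": "clustered", "c1": "clustered",
                         "b2": "clustered", "c2": "clustered",
                         "a9": "genome_specific", "b9": "genome_specific",
                         "c9": "remnant"},
        gene_genome={"a1": "A", "b1": "B", "c1": "C", "b2": "B", "c2": "C",
                     "a9": "A", "b9": "B", "c9": "C"})
    genes = [_gene("A", "a9", "X" * 100), _gene("B", "b9", "X" * 10)]
    sets = shared_and_accessory_sets(catalog, ["A", "B", "C"], "A", genes)
    assert sets["core"] == ["OG1"]
    assert sets["accessory_to_reference"] == ["OG2"]
    assert sets["shared_counts"][frozenset({"B", "C"})] == 1
    # b9 is a small gene (<50 aa) and never counts; c9 is a remnant
    assert sets["unique_per_genome"] == {"A": 1, "B": 0, "C": 0}
    with pytest.raises(ValueError):
        shared_and_accessory_sets(catalog, ["A", "B", "C"], "Z")


def test_presence_matrix():
    from sagkit.orthomap import OrthologCatalog
    catalog = OrthologCatalog(clusters={"OG1": ["a1", "b1"]},
                              gene_genome={"a1": "A", "b1": "B", "c1": "C"})
    matrix = catalog.presence_matrix()
    assert matrix["OG1"] == {"A": True, "B": True, "C": False}
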