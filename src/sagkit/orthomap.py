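"""Ortholog inference: all-vs-all protein similarity + Markov clustering.

Proteins are compared all-against-all by local alignment; hits at >=50%
identity covering >50% of both sequences feed a score-weighted graph that
is clustered with the MCL algorithm (expansion 2, configurable inflation).
Genomes contributing several members to one cluster are reduced to the copy
most similar to the other genomes (paralog resolution); unclustered genes
are classified as remnants (a partial hit elsewhere) or genome-specific
(no hit), and shared/core/accessory gene sets are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from sagkit import palign


@dataclass
class SimilarityHit:
    query: str
    subject: str
    identity: float  # percent over aligned columns
    query_coverage: float
    subject_coverage: float
    score: float
    evalue: float


@dataclass
class OrthologCatalog:
    clusters: dict = field(default_factory=dict)  # cluster id -> sorted member gene ids
    classifications: dict = field(default_factory=dict)  # gene id -> class
    gene_genome: dict = field(default_factory=dict)  # gene id -> genome

    def presence_matrix(self):
        genomes = sorted(set(self.gene_genome.values()))
        matrix = {}
        for cid, members in self.clusters.items():
            present = {self.gene_genome[g] for g in members}
            matrix[cid] = {g: (g in present) for g in genomes}
        return matrix

    def cluster_of(self, gene_id):
        for cid, members in self.clusters.items():
            if gene_id in members:
                return cid
        return None


def _kmer_set(seq: str, k: int = 6):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_search(genes, e_cutoff: float = 1e-5, prefilter_k: int = 6):
    """Local-alignment similarity hits between all protein pairs.

    ``genes`` is a list of GeneRecord (``protein`` populated).  Self-hits
    are excluded; each unordered pair is scored once.  Pairs sharing no
    ``prefilter_k``-mer are skipped without alignment.  Only hits at
    E <= ``e_cutoff`` are returned.
    """
    usable = [g for g in genes if g.protein]
    kmers = {g.gene_id: _kmer_set(g.protein, prefilter_k) for g in usable}
    hits = []
    for g1, g2 in combinations(usable, 2):
        if not (kmers[g1.gene_id] & kmers[g2.gene_id]):
            continue
        res = palign.align_pair(g1.protein, g2.protein)
        if res is None or res["evalue"] > e_cutoff:
            continue
        hits.append(
            SimilarityHit(
                query=g1.gene_id, subject=g2.gene_id,
                identity=res["identity"],
                query_coverage=res["query_coverage"],
                subject_coverage=res["subject_coverage"],
                score=res["score"], evalue=res["evalue"],
            )
        )
    return hits


def markov_cluster(nodes, edges, inflation: float = 1.5, expansion: int = 2,
                   max_iter: int = 200, tol: float = 1e-8, prune: float = 1e-6):
    """MCL on an undirected weighted graph; returns list of node-id sets.

    Raises ``RuntimeError`` reporting the residual on non-convergence.
    """
    nodes = sorted(nodes)
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, w in edges:
        i, j = idx[a], idx[b]
        M[i, j] = M[j, i] = max(M[i, j], w)
    M[np.diag_indices(n)] = np.maximum(M.max(axis=0), 1e-12)  # self loops
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        residual = float(np.abs(M - prev).max())
        if residual < tol:
            break
    else:
        raise RuntimeError(f"MCL did not converge; residual {residual:.2e}")
    clusters = []
    seen = set()
    attractors = np.nonzero(np.diag(M) > 1e-6)[0]
    for a in attractors:
        members = set(np.nonzero(M[a] > 1e-6)[0]) | {a}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # cascade merges
            changed = True
            while changed:
                changed = False
                for c1, c2 in combinations(list(clusters), 2):
                    if c1 & c2 and c1 in clusters and c2 in clusters:
                        clusters.remove(c2)
                        c1 |= c2
                        changed = True
        else:
            clusters.append(members)
        seen |= members
    for i in range(n):
        if i not in seen:
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters]


def build_graph_and_cluster(hits, genes, min_identity: float = 0.5,
                            min_coverage: float = 0.5,
                            inflation: float = 1.5) -> OrthologCatalog:
    """Filter hits, cluster the similarity graph, and build the catalog.

    ``min_identity``/``min_coverage`` are fractions; a hit passes at
    >= 50% identity covering > 50% of both sequences.  Hits are sorted
    canonically before clustering so the result is input-order invariant.
    Singletons are not clusters.
    """
    catalog = OrthologCatalog(gene_genome={g.gene_id: g.genome for g in genes})
    passing = [
        h for h in hits
        if h.identity >= 100 * min_identity
        and h.query_coverage > min_coverage
        and h.subject_coverage > min_coverage
    ]
    passing.sort(key=lambda h: (h.query, h.subject))
    nodes = sorted({h.query for h in passing} | {h.subject for h in passing})
    edges = [(h.query, h.subject, h.score) for h in passing]
    raw_clusters = markov_cluster(nodes, edges, inflation=inflation)
    cid = 0
    for members in sorted(raw_clusters, key=lambda c: sorted(c)[0]):
        if len(members) < 2:
            continue
        cid += 1
        catalog.clusters[f"OG{cid:05d}"] = sorted(members)
        for g in members:
            catalog.classifications[g] = "clustered"
    return catalog


def resolve_paralogs(catalog: OrthologCatalog, hits) -> OrthologCatalog:
    """Keep one gene per genome per cluster: the copy most similar to the rest.

    Similarity is mean percent identity to all members from other genomes
    (missing pairs count 0); ties keep the lexicographically smaller id.
    Dropped copies are classified ``paralog_dropped``.
    """
    ident = {}
    for h in hits:
        key = frozenset((h.query, h.subject))
        ident[key] = max(ident.get(key, 0.0), h.identity)
    for cid, members in list(catalog.clusters.items()):
        by_genome = {}
        for g in members:
            by_genome.setdefault(catalog.gene_genome[g], []).append(g)
        retained = []
        for genome, copies in sorted(by_genome.items()):
            if len(copies) == 1:
                retained.extend(copies)
                continue
            others = [g for g in members if catalog.gene_genome[g] != genome]
            def mean_ident(g):
                if not others:
                    return 0.0
                return float(np.mean([ident.get(frozenset((g, o)), 0.0)
                                      for o in others]))
            best = sorted(copies, key=lambda g: (-mean_ident(g), g))[0]
            retained.append(best)
            for g in copies:
                if g != best:
                    catalog.classifications[g] = "paralog_dropped"
        catalog.clusters[cid] = sorted(retained)
    return catalog


def classify_unclustered(genes, hits, catalog: OrthologCatalog,
                         partial_coverage: float = 0.5) -> OrthologCatalog:
    """Label unclustered genes as remnants or genome-specific.

    A gene outside every cluster is a ``remnant`` when it has a hit in
    another genome whose alignment covers <``partial_coverage`` of the hit
    (subject) length — a partial, sub-threshold homology — or indeed any
    hit at the E-threshold; genes with no hit at all are ``genome_specific``.
    Clustered and paralog-dropped genes are left untouched.
    """
    partners = {}
    for h in hits:
        partners.setdefault(h.query, []).append(h)
        partners.setdefault(h.subject, []).append(h)
    for g in genes:
        if g.gene_id in catalog.classifications:
            continue
        cross = [h for h in partners.get(g.gene_id, [])
                 if catalog.gene_genome.get(
                     h.subject if h.query == g.gene_id else h.query) != g.genome]
        catalog.classifications[g.gene_id] = "remnant" if cross else "genome_specific"
    return catalog


def shared_and_accessory_sets(catalog: OrthologCatalog, genomes, reference: str,
                              genes=None, small_gene_aa: int = 50):
    """Core, per-subset shared, accessory, and per-genome unique gene counts.

    ``core`` counts clusters present in every genome; ``shared`` maps each
    genome subset (frozenset) to its cluster count; ``accessory`` lists
    clusters absent from the ``reference`` genome.  Per-genome unique counts
    take genome_specific genes and subtract remnants, dropped paralogs and
    small genes (<``small_gene_aa`` aa, potential false positives) — those
    are never counted.  Raises ``ValueError`` if the reference is unknown.
    """
    genomes = sorted(genomes)
    if reference not in genomes:
        raise ValueError(f"reference genome {reference!r} not among {genomes}")
    shared = {}
    core = []
    accessory = []
    for cid, members in catalog.clusters.items():
        present = frozenset(catalog.gene_genome[g] for g in members)
        shared[present] = shared.get(present, 0) + 1
        if present == frozenset(genomes):
            core.append(cid)
        if reference not in present:
            accessory.append(cid)
    protein_len = {g.gene_id: len(g.protein) for g in (genes or [])}
    unique = {g: 0 for g in genomes}
    for gene_id, cls in catalog.classifications.items():
        if cls != "genome_specific":
            continue
        if protein_len.get(gene_id, small_gene_aa) < small_gene_aa:
            continue
        genome = catalog.gene_genome.get(gene_id)
        if genome in unique:
            unique[genome] += 1
    return {
        "core": sorted(core),
        "shared_counts": shared,
        "accessory_to_reference": sorted(accessory),
        "unique_per_genome": unique,
    }
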