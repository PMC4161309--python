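import numpy as np
import pytest

from sagkit.codon import STOP_CODONS, translate_cds
from sagkit.divstats import pairwise_identity
from sagkit.simulate import (
    SimParams,
    evolve_strains,
    generate_ancestor,
    mutate_cds,
    remap_genes,
    simulate_partial_recovery,
    simulate_reads,
    simulate_study,
)

SMALL = dict(ancestor_length=20_000, gene_count=10, gene_length_mean=600,
             n_strains=2, divergence_times=(0.1, 0.1))


def test_params_validation():
    with pytest.raises(ValueError):
        SimParams(dropout_fraction=1.0)
    with pytest.raises(ValueError):
        SimParams(misassignment_rate=0.2)
    with pytest.raises(ValueError):
        SimParams(n_strains=2, divergence_times=(0.1,))
    with pytest.raises(ValueError):
        SimParams(n_strains=2, divergence_times=(-0.1, 0.1))


def test_generate_ancestor_structure():
    params = SimParams(**SMALL)
    anc = generate_ancestor(params)
    assert len(anc.seq) == params.ancestor_length
    assert len(anc.genes) == params.gene_count
    prev_end = 0
    for g in sorted(anc.genes, key=lambda g: g.start):
        assert g.start >= prev_end
        prev_end = g.end
        assert g.cds.startswith("ATG") and g.cds.endswith("TAA")
        assert len(g.cds) % 3 == 0
        assert "*" not in translate_cds(g.cds)[:-1]
    r0, r1 = anc.rrna
    assert 0 <= r0 < r1 <= len(anc.seq)
    assert r1 - r0 == params.rrna_length
    for g in anc.genes:  # rRNA locus does not overlap genes
        assert g.end <= r0 or g.start >= r1


def test_generate_ancestor_packing_error():
    with pytest.raises(ValueError, match="pack"):
        generate_ancestor(SimParams(ancestor_length=5000, gene_count=10,
                                    n_strains=2, divergence_times=(0.1, 0.1)))


def test_mutate_cds_omega_zero_preserves_protein(rng):
    anc = generate_ancestor(SimParams(**SMALL))
    for g in anc.genes[:5]:
        mutated = mutate_cds(g.cds, 0.3, 0.0, rng)
        assert translate_cds(mutated) == translate_cds(g.cds)
        assert mutated != g.cds  # at d=0.3 some synonymous change happened


def test_evolve_strains_deterministic_and_origins_valid():
    params = SimParams(**SMALL, recomb_rate=2.0, seed=5)
    anc = generate_ancestor(params, np.random.default_rng(5))
    g1, led1 = evolve_strains(anc, params, np.random.default_rng(5))
    g2, led2 = evolve_strains(anc, params, np.random.default_rng(5))
    assert g1 == g2
    assert led1.recomb_tracts == led2.recomb_tracts
    for strain, origins in led1.site_origins.items():
        assert set(origins.values()) <= {0, 1}
        for pos in origins:
            assert g1[strain][pos] != anc.seq[pos]


def test_rrna_homogenization_keeps_locus_identical():
    params = SimParams(ancestor_length=20_000, gene_count=10, gene_length_mean=600,
                       n_strains=2, divergence_times=(0.4, 0.4), seed=3)
    anc = generate_ancestor(params, np.random.default_rng(3))
    genomes, _ = evolve_strains(anc, params, np.random.default_rng(3))
    r0, r1 = anc.rrna
    locus_ident = pairwise_identity(genomes["s0"][r0:r1], genomes["s1"][r0:r1])
    assert locus_ident >= 99.0
    # genome-wide the strains are far more diverged than the rRNA locus
    diffs = sum(a != b for a, b in zip(genomes["s0"], genomes["s1"]))
    assert diffs / len(anc.seq) > 0.05


def test_partial_recovery_exact_dropout_fraction():
    params = SimParams(**SMALL, dropout_fraction=0.15, seed=2)
    genome = "ACGT" * 5000
    asm, intervals, hotspots = simulate_partial_recovery(
        "s0", genome, params, np.random.default_rng(2))
    removed = sum(e - s for s, e in intervals)
    assert removed == round(0.15 * len(genome))
    assert asm.total_length() == len(genome) - removed
    assert len(hotspots) == params.n_hotspots
    for cid in hotspots:
        assert asm.contigs[cid].coverage > params.hotspot_threshold


def test_simulate_reads_pairing_and_misassignment():
    params = SimParams(**SMALL, misassignment_rate=0.01, seed=9)
    sim = simulate_study(params)
    ledger = sim["ledger"]
    assert ledger.misassigned_read_ids
    all_ids = {rid for reads in sim["reads"].values() for rid, _ in reads}
    assert ledger.misassigned_read_ids <= all_ids
    for rid in ledger.misassigned_read_ids:
        source = rid.split(":")[0]
        holder = next(g for g, reads in sim["reads"].items()
                      if any(r == rid for r, _ in reads))
        assert holder != source  # hopped reads sit in a foreign read set
    for reads in sim["reads"].values():
        for rid, seq in reads:
            assert len(seq) == params.read_length
            assert rid.endswith(("/1", "/2"))


def test_simulate_reads_requires_two_genomes_for_hopping():
    params = SimParams(ancestor_length=20_000, gene_count=10, n_strains=1,
                       divergence_times=(0.1,), misassignment_rate=0.01)
    anc = generate_ancestor(params)
    genomes, ledger = evolve_strains(anc, params)
    asm, _, _ = simulate_partial_recovery("s0", genomes["s0"], params)
    with pytest.raises(ValueError, match="at least 2"):
        simulate_reads({"s0": asm}, params, ledger)


def test_remap_genes_drops_genes_hit_by_dropout():
    params = SimParams(**SMALL, dropout_fraction=0.2, seed=4)
    sim = simulate_study(params)
    for strain in sim["assemblies"]:
        intervals = sim["ledger"].dropout_intervals[strain]
        remapped = remap_genes(sim["genes"][strain], intervals,
                               len(sim["genomes"][strain]), strain)
        assert 0 < len(remapped) <= len(sim["genes"][strain])
        asm = sim["assemblies"][strain]
        for g in remapped:
            contig = asm.contigs[g.contig]
            piece = contig.seq[g.start:g.end]
            if g.strand == "-":
                from sagkit.iodata import revcomp
                piece = revcomp(piece)
            assert piece == g.cds


def test_simulate_study_deterministic():
    params = SimParams(**SMALL, seed=8)
    a = simulate_study(params)
    b = simulate_study(params)
    assert a["genomes"] == b["genomes"]
    assert a["reads"] == b["reads"]
    assert a["ledger"].misassigned_read_ids == b["ledger"].misassigned_read_ids
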