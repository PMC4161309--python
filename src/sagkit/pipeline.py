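"""End-to-end orchestration of the SAG comparative-genomics pipeline.

Chains the stages — read cleanup, contig QC, ortholog clustering, divergence
statistics, recombination detection, phylogenetics — over a *manifest*: a
dict of per-genome assemblies + gene records (plus optional read sets, 16S
sequences and a simulator truth ledger).  Every stage writes a TSV report
stamped with the config hash; runs are deterministic given the config seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from sagkit import contigqc, divstats, orthomap, phylo, readclean, recomb
from sagkit.codon import backtranslate
from sagkit.config import PipelineConfig
from sagkit.palign import global_protein_alignment
from sagkit.simulate import remap_genes

log = logging.getLogger("sagkit")


def manifest_from_simulation(sim: dict, params) -> dict:
    """Build a pipeline manifest from :func:`sagkit.simulate.simulate_study` output."""
    ledger = sim["ledger"]
    genomes = {}
    rrna = {}
    r0, r1 = sim["ancestor"].rrna
    for strain, assembly in sim["assemblies"].items():
        genes = remap_genes(sim["genes"][strain],
                            ledger.dropout_intervals.get(strain, []),
                            len(sim["genomes"][strain]), strain)
        genomes[strain] = (assembly, genes)
        rrna[strain] = sim["genomes"][strain][r0:r1]
    reference = sorted(genomes)[0]
    return {
        "genomes": genomes,
        "reads": sim.get("reads"),
        "rrna": rrna,
        "reference": reference,
        "ledger": ledger,
    }


def _write_tsv(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _codon_alignment_for_pair(genes_by_id, ga, gb):
    """Codon alignment of two orthologous genes via their proteins."""
    rec_a, rec_b = genes_by_id[ga], genes_by_id[gb]
    if len(rec_a.cds) == len(rec_b.cds):
        return rec_a.cds, rec_b.cds
    pa, pb = global_protein_alignment(rec_a.protein, rec_b.protein)
    aln = backtranslate([(ga, pa), (gb, pb)], {ga: rec_a.cds, gb: rec_b.cds})
    return aln[0][1], aln[1][1]


def run_pipeline(config: PipelineConfig, manifest: dict, outdir) -> Path:
    """Run every applicable stage and write reports under ``outdir``.

    With fewer than two genomes the divergence/recombination/phylogeny
    stages are skipped with a logged warning.  Returns the report directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(handler)
    log.info("config hash %s", config.config_hash())
    for key, value in vars(config).items():
        log.info("config %s = %r", key, value)

    genomes = manifest["genomes"]
    reference = manifest["reference"]
    ledger = manifest.get("ledger")

    # ---- stage 1: read cleanup -------------------------------------------
    reads = manifest.get("reads")
    cleaned_reads = {}
    if reads:
        assemblies = {gid: asm for gid, (asm, _genes) in genomes.items()}
        rows = []
        for gid in sorted(reads):
            kept, report = readclean.clean_read_set(
                reads[gid], assemblies[gid], assemblies, config)
            cleaned_reads[gid] = kept
            rows.append((gid, report.total_reads, len(report.removed_ids),
                         len(report.rescued_ids), report.kept))
        _write_tsv(outdir / "cleanup.tsv",
                   pd.DataFrame(rows, columns=["genome", "total", "removed",
                                               "rescued", "kept"]), config)

    # ---- stage 2: contig QC ----------------------------------------------
    ref_proteins = [g.protein for g in genomes[reference][1] if g.protein]
    panel = [g.protein for _gid, (_a, gs) in sorted(genomes.items())
             for g in gs if g.protein]
    qc_rows = []
    filtered = {}
    for gid in sorted(genomes):
        assembly, genes = genomes[gid]
        assembly, redundancy = contigqc.remove_redundant_contigs(assembly)
        verdicts = contigqc.filter_contigs(assembly, ref_proteins, panel, config,
                                           warn=log.warning)
        assembly = contigqc.apply_verdicts(assembly, verdicts)
        kept_contigs = set(assembly.contigs)
        filtered[gid] = (assembly, [g for g in genes if g.contig in kept_contigs])
        for v in redundancy + verdicts:
            if not v.retained or v.reason != "pass":
                qc_rows.append((gid, v.contig, v.retained, v.reason))
        completeness = contigqc.estimate_completeness(
            filtered[gid][1], ref_proteins,
            config.min_hit_identity, config.min_hit_coverage)
        qc_rows.append((gid, "*completeness*", True,
                        f"{completeness.fraction:.1f}%"))
    _write_tsv(outdir / "qc.tsv",
               pd.DataFrame(qc_rows, columns=["genome", "contig", "retained",
                                              "reason"]), config)

    # ---- stage 3: orthologs ----------------------------------------------
    all_genes = [g for _gid, (_a, gs) in sorted(filtered.items()) for g in gs
                 if not g.partial]
    hits = orthomap.all_vs_all_search(all_genes, config.evalue_cutoff)
    catalog = orthomap.build_graph_and_cluster(
        hits, all_genes, config.min_hit_identity, config.min_hit_coverage,
        config.mcl_inflation)
    catalog = orthomap.resolve_paralogs(catalog, hits)
    catalog = orthomap.classify_unclustered(all_genes, hits, catalog)
    sets = orthomap.shared_and_accessory_sets(
        catalog, sorted(genomes), reference, all_genes)
    _write_tsv(outdir / "orthologs.tsv",
               pd.DataFrame(
                   [(cid, ";".join(members))
                    for cid, members in sorted(catalog.clusters.items())],
                   columns=["cluster", "members"]), config)
    _write_tsv(outdir / "ortholog_sets.tsv",
               pd.DataFrame(
                   [("core", len(sets["core"]))] +
                   [(f"unique:{g}", n) for g, n in sorted(
                       sets["unique_per_genome"].items())],
                   columns=["set", "count"]), config)

    if len(genomes) < 2:
        log.warning("fewer than 2 genomes: divergence, recombination and "
                    "phylogeny stages skipped")
        log.removeHandler(handler)
        handler.close()
        return outdir

    # ---- stage 4: divergence ---------------------------------------------
    genes_by_id = {g.gene_id: g for g in all_genes}
    genome_of = catalog.gene_genome
    shared_clusters = {
        cid: members for cid, members in catalog.clusters.items()
        if len({genome_of[m] for m in members}) == len(members)
    }
    div_rows = []
    pair_gene_alignments = {}  # (ga_genome, gb_genome) -> {cluster: (cds_a, cds_b)}
    for cid, members in sorted(shared_clusters.items()):
        members = sorted(members, key=lambda m: genome_of[m])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ga, gb = members[i], members[j]
                pair = (genome_of[ga], genome_of[gb])
                try:
                    cds_a, cds_b = _codon_alignment_for_pair(genes_by_id, ga, gb)
                except ValueError as exc:
                    log.warning("cluster %s pair %s: %s", cid, pair, exc)
                    continue
                try:
                    ng = divstats.ng86_divergence(cds_a, cds_b, pair, cid,
                                                  config.ds_cap)
                except ValueError:
                    continue
                div_rows.append((cid, *pair, ng.dS, ng.dN, ng.omega,
                                 ng.estimator, ng.saturated))
                pair_gene_alignments.setdefault(pair, {})[cid] = (cds_a, cds_b)
    for pair, alignments in sorted(pair_gene_alignments.items()):
        rec = divstats.concat_divergence(alignments, pair, config.ds_cap)
        div_rows.append(("concatenated", *pair, rec.dS, rec.dN, rec.omega,
                         rec.estimator, rec.saturated))
    _write_tsv(outdir / "divergence.tsv",
               pd.DataFrame(div_rows,
                            columns=["gene", "genome_a", "genome_b", "dS",
                                     "dN", "omega", "estimator", "saturated"]),
               config)

    rrna = manifest.get("rrna") or {}
    if len(rrna) >= 2:
        names = sorted(rrna)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ident = divstats.pairwise_identity(rrna[names[i]], rrna[names[j]])
                rows.append((names[i], names[j], ident))
        pi = divstats.nucleotide_diversity([(n, rrna[n]) for n in names]) \
            if len({len(s) for s in rrna.values()}) == 1 else float("nan")
        rows.append(("*pi*", "*all*", pi))
        _write_tsv(outdir / "rrna_identity.tsv",
                   pd.DataFrame(rows, columns=["a", "b", "value"]), config)

    # ternary analysis over the first three genomes sharing clusters
    genome_names = sorted(genomes)
    if len(genome_names) >= 3:
        trio = tuple(genome_names[:3])
        pairs = [(trio[0], trio[1]), (trio[0], trio[2]), (trio[1], trio[2])]
        ds_by_pair = {}
        for row in div_rows:
            cid, ga, gb = row[0], row[1], row[2]
            if cid != "concatenated":
                ds_by_pair.setdefault(cid, {})[(ga, gb)] = row[3]
        triplets = {
            cid: tuple(vals[p] for p in pairs)
            for cid, vals in ds_by_pair.items()
            if all(p in vals for p in pairs)
        }
        if triplets:
            points, spread_mean, dropped = divstats.ternary_analysis(
                triplets, config.ds_cap, "mean")
            _points, spread_median, _ = divstats.ternary_analysis(
                triplets, config.ds_cap, "median")
            rows = [(p.gene_id, *p.xyz, p.category, p.capped) for p in points]
            rows.append(("*spread_mean*", spread_mean, "", "", "", ""))
            rows.append(("*spread_median*", spread_median, "", "", "", ""))
            _write_tsv(outdir / "ternary.tsv",
                       pd.DataFrame(rows, columns=["gene", "x", "y", "z",
                                                   "category", "capped"]),
                       config)

    # ---- stage 5: recombination ------------------------------------------
    rm_rows = []
    frag_rows = []
    per_gene_fragments = {}
    multi_clusters = {
        cid: members for cid, members in sorted(shared_clusters.items())
        if len(members) >= 3
    }
    for k, (cid, members) in enumerate(sorted(multi_clusters.items())):
        cds = {m: genes_by_id[m].cds for m in members}
        if len({len(s) for s in cds.values()}) != 1:
            continue
        aln = [(genome_of[m], cds[m]) for m in sorted(members,
                                                      key=lambda m: genome_of[m])]
        rm_rows.append((cid, recomb.minimum_recombination_events(aln)))
        frags = recomb.detect_fragments_multi_gscale(
            aln, config.gscale_set, config.fragment_p_cutoff,
            n_permutations=2000, seed=config.random_seed + k)
        per_gene_fragments[cid] = frags
        for f in frags:
            frag_rows.append((cid, *f.pair, f.nt_span[0] + 1, f.nt_span[1] + 1,
                              f.length, f.score, f.p_value, f.gscale))
    _write_tsv(outdir / "rm.tsv",
               pd.DataFrame(rm_rows, columns=["gene", "Rm"]), config)
    _write_tsv(outdir / "fragments.tsv",
               pd.DataFrame(frag_rows,
                            columns=["gene", "a", "b", "start", "end",
                                     "length", "score", "p", "gscale"]),
               config)

    if ledger is not None and ledger.site_origins:
        rows = []
        for strain in sorted(ledger.site_origins):
            origins = list(ledger.site_origins[strain].values())
            if not origins:
                continue
            for method in ("all_positions", "confident_only"):
                rows.append((strain, method,
                             recomb.r_over_m(origins, method)))
        if rows:
            _write_tsv(outdir / "roverm.tsv",
                       pd.DataFrame(rows, columns=["strain", "method", "r_over_m"]),
                       config)

    # ---- stage 6: phylogeny ----------------------------------------------
    full_clusters = {
        cid: members for cid, members in shared_clusters.items()
        if len(members) == len(genomes) and len(genomes) >= 3
    }
    if len(full_clusters) >= 3:
        concat = {gid: [] for gid in genome_names}
        gene_trees = []
        for cid, members in sorted(full_clusters.items()):
            cds = {genome_of[m]: genes_by_id[m].cds for m in members}
            if len({len(s) for s in cds.values()}) != 1:
                continue
            for gid in genome_names:
                concat[gid].append(cds[gid])
            aln = [(gid, cds[gid]) for gid in genome_names]
            try:
                gene_trees.append(phylo.bootstrap_support(
                    aln, reps=max(20, config.bootstrap_reps // 5),
                    seed=config.random_seed))
            except ValueError as exc:
                log.warning("gene tree %s skipped: %s", cid, exc)
        concat_aln = [(gid, "".join(parts)) for gid, parts in concat.items()]
        try:
            ref_tree = phylo.bootstrap_support(concat_aln, config.bootstrap_reps,
                                               seed=config.random_seed)
            (outdir / "tree.nwk").write_text(ref_tree.newick() + "\n")
            concordance = phylo.topology_concordance(
                gene_trees, ref_tree, config.support_threshold, warn=log.warning)
            rows = [
                ("|".join(sorted(split)), v["congruent"], v["supported"],
                 v["testable"], v["percent"])
                for split, v in concordance.items()
            ]
            _write_tsv(outdir / "concordance.tsv",
                       pd.DataFrame(rows, columns=["split", "congruent",
                                                   "supported", "testable",
                                                   "percent"]), config)
        except ValueError as exc:
            log.warning("phylogeny stage skipped: %s", exc)

    log.removeHandler(handler)
    handler.close()
    return outdir
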