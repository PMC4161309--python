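"""Synthetic strain-genome simulator with ground truth.

Emulates the data-generating process the analysis assumes: strains diverge
from a common ancestor by point substitution (synonymous sites at the branch
rate, nonsynonymous changes thinned by omega), exchange homologous
recombination tracts (optionally homogenizing an rRNA-like locus), lose
random genome intervals to incomplete single-cell recovery, and are
sequenced as error-free paired short reads with a configurable cross-library
misassignment rate concentrated on ultra-high-coverage (MDA hotspot)
contigs.  Every stochastic event is written to a :class:`TruthLedger` so the
downstream analysis stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from sagkit.codon import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from sagkit.iodata import Contig, GenomeAssembly, GeneRecord, revcomp

_BASES = "ACGT"


@dataclass
class SimParams:
    """Knobs of the strain simulator.

    ``divergence_times`` are expected substitutions per site at synonymous
    sites along each strain's branch from the ancestor (star phylogeny).
    ``misassignment_rate`` is the fraction of read pairs relabeled to a
    foreign library (index hopping), drawn preferentially from hotspot
    contigs whose declared coverage exceeds the cleanup threshold.
    """

    ancestor_length: int = 50_000
    gene_count: int = 40
    gene_length_mean: int = 900
    n_strains: int = 3
    divergence_times: tuple = (0.1, 0.1, 0.1)
    omega: float = 0.1
    recomb_rate: float = 0.0  # expected tracts per genome per branch
    tract_length_mean: int = 300
    rrna_homogenize: bool = True
    rrna_length: int = 1500
    rrna_residual_rate: float = 0.002  # post-homogenization point mutations/site
    dropout_fraction: float = 0.0
    dropout_interval_mean: int = 20_000
    coverage_lognormal_sigma: float = 1.0
    coverage_median: float = 60.0  # declared per-contig mean depth (median)
    n_hotspots: int = 1
    hotspot_coverage: float = 8000.0
    sequencing_depth: float = 30.0  # emitted read depth per contig
    read_length: int = 76
    insert_size: int = 400
    misassignment_rate: float = 0.003
    hotspot_threshold: float = 5000.0  # declared depth above which a contig sheds hopped reads
    hotspot_hop_fraction: float = 0.99  # fraction of hopped pairs drawn from hotspot contigs
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if not (0 <= self.misassignment_rate <= 0.05):
            raise ValueError("misassignment_rate must be in [0, 0.05]")
        if any(d < 0 for d in self.divergence_times):
            raise ValueError("divergence_times must be non-negative")
        if len(self.divergence_times) != self.n_strains:
            raise ValueError("need one divergence time per strain")


@dataclass
class TruthLedger:
    """Ground truth of one simulation run."""

    recomb_tracts: list = field(default_factory=list)  # (donor, recipient, contig, start, end)
    site_origins: dict = field(default_factory=dict)  # strain -> {pos: 0 mutation / 1 recombination}
    misassigned_read_ids: set = field(default_factory=set)
    dropout_intervals: dict = field(default_factory=dict)  # strain -> [(start, end)]
    hotspot_contigs: dict = field(default_factory=dict)  # strain -> [contig ids]
    true_tree: str = ""


@dataclass
class Ancestor:
    seq: str
    genes: list  # GeneRecord on the single ancestral replicon
    rrna: tuple  # (start, end) of the rRNA-like locus


def _random_sense_codon(rng) -> str:
    return SENSE_CODONS[rng.integers(len(SENSE_CODONS))]


def generate_ancestor(params: SimParams, rng=None) -> Ancestor:
    """Build a random ancestral genome with non-overlapping genes.

    Genes are written as ATG + random sense codons + TAA on random strands;
    one extra rRNA-like locus of ``rrna_length`` is placed among them.
    Raises ``ValueError`` when the requested genes cannot be packed.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    lengths = []
    for _ in range(params.gene_count):
        n_codons = max(30, int(round(rng.normal(params.gene_length_mean,
                                                params.gene_length_mean / 10) / 3)))
        lengths.append(3 * n_codons)
    needed = sum(lengths) + params.rrna_length
    spare = params.ancestor_length - needed
    n_slots = params.gene_count + 2  # +1 rRNA feature, +1 trailing gap
    if spare < 2 * n_slots:
        raise ValueError(
            f"cannot pack {params.gene_count} genes of mean {params.gene_length_mean} nt "
            f"plus rRNA into {params.ancestor_length} nt; reduce gene_count"
        )
    gaps = rng.multinomial(spare - n_slots, np.full(n_slots, 1.0 / n_slots)) + 1
    features = [("gene", ln) for ln in lengths]
    rrna_slot = int(rng.integers(len(features) + 1))
    features.insert(rrna_slot, ("rrna", params.rrna_length))

    seq = []
    genes = []
    pos = 0
    rrna_interval = None

    def emit_random(n):
        nonlocal pos
        seq.append("".join(_BASES[i] for i in rng.integers(4, size=n)))
        pos += n

    gene_no = 0
    for k, (kind, ln) in enumerate(features):
        emit_random(int(gaps[k]))
        start = pos
        if kind == "rrna":
            emit_random(ln)
            rrna_interval = (start, start + ln)
            continue
        body = "".join(_random_sense_codon(rng) for _ in range(ln // 3 - 2))
        cds = "ATG" + body + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        seq.append(cds if strand == "+" else revcomp(cds))
        pos += ln
        gene_no += 1
        genes.append(
            GeneRecord(
                genome="ancestor", contig="chr", gene_id=f"g{gene_no:04d}",
                start=start, end=start + ln, strand=strand, cds=cds,
                product=f"simulated protein {gene_no}",
            )
        )
    emit_random(int(gaps[-1]))
    if pos < params.ancestor_length:
        emit_random(params.ancestor_length - pos)
    return Ancestor("".join(seq), genes, rrna_interval)


def _coding_map(ancestor: Ancestor) -> np.ndarray:
    """Per-position gene index (-1 intergenic) on the ancestral replicon."""
    cmap = np.full(len(ancestor.seq), -1, dtype=np.int64)
    for gi, g in enumerate(ancestor.genes):
        cmap[g.start : g.end] = gi
    return cmap


def _codon_at(seq: list, gene: GeneRecord, genome_pos: int) -> tuple:
    """(codon string read in frame, offset of genome_pos within it, codon genome span)."""
    if gene.strand == "+":
        off = (genome_pos - gene.start) % 3
        c0 = genome_pos - off
        codon = "".join(seq[c0 : c0 + 3])
        return codon, off, (c0, c0 + 3)
    off_rev = (gene.end - 1 - genome_pos) % 3
    c_end = genome_pos + off_rev + 1
    codon = revcomp("".join(seq[c_end - 3 : c_end]))
    return codon, off_rev, (c_end - 3, c_end)


def mutate_cds(cds: str, d: float, omega: float, rng) -> str:
    """Evolve one CDS by ``d`` expected substitutions per synonymous site.

    Proposals arrive per site as Poisson(d), each to a uniform different
    base; synonymous changes are always accepted, nonsynonymous (including
    stop gain/loss) with probability ``omega``.
    """
    seq = list(cds)
    n_prop = rng.poisson(d * len(seq))
    positions = rng.integers(len(seq), size=n_prop)
    for pos in positions:
        old = seq[pos]
        new = _BASES[(({"A": 0, "C": 1, "G": 2, "T": 3}[old]) + 1 + rng.integers(3)) % 4]
        c0 = pos - pos % 3
        codon = "".join(seq[c0 : c0 + 3])
        alt = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        syn = (
            codon not in STOP_CODONS and alt not in STOP_CODONS
            and GENETIC_CODE[codon] == GENETIC_CODE[alt]
        )
        if syn or rng.random() < omega:
            seq[pos] = new
    return "".join(seq)


def simulate_codon_pair(n_codons: int, d_total: float, omega: float, rng):
    """Two CDS descended from one random ancestor, ``d_total`` apart.

    Each lineage receives ``d_total / 2`` expected synonymous substitutions
    per site.  Returns (cds_a, cds_b) of equal, gap-free length.
    """
    ancestor = "".join(_random_sense_codon(rng) for _ in range(n_codons))
    a = mutate_cds(ancestor, d_total / 2.0, omega, rng)
    b = mutate_cds(ancestor, d_total / 2.0, omega, rng)
    return a, b


def _evolve_one(ancestor: Ancestor, cmap: np.ndarray, d: float, omega: float, rng):
    """Point-substitution phase along one branch; returns (seq list, {pos: base})."""
    seq = list(ancestor.seq)
    changed = {}
    n_prop = rng.poisson(d * len(seq))
    positions = rng.integers(len(seq), size=n_prop)
    for pos in positions:
        old = seq[pos]
        new = _BASES[(({"A": 0, "C": 1, "G": 2, "T": 3}[old]) + 1 + rng.integers(3)) % 4]
        gi = cmap[pos]
        accept = True
        if gi >= 0:
            gene = ancestor.genes[gi]
            codon, off, _span = _codon_at(seq, gene, pos)
            base_in_frame = new if gene.strand == "+" else revcomp(new)
            alt = codon[:off] + base_in_frame + codon[off + 1 :]
            syn = (
                codon not in STOP_CODONS and alt not in STOP_CODONS
                and GENETIC_CODE.get(codon) == GENETIC_CODE.get(alt)
            )
            accept = syn or (rng.random() < omega)
        if accept:
            seq[pos] = new
            if new != ancestor.seq[pos]:
                changed[int(pos)] = new
            else:
                changed.pop(int(pos), None)
    return seq, changed


def evolve_strains(ancestor: Ancestor, params: SimParams, rng=None):
    """Evolve ``n_strains`` tips from the ancestor on a star phylogeny.

    Returns (dict strain id -> genome string, TruthLedger).  Recombination
    overwrites recipient tracts with donor sequence (geometric tract length,
    uniform donor) and marks the affected substituted sites with origin 1;
    point mutations carry origin 0.  With ``rrna_homogenize`` every strain's
    rRNA-like locus is overwritten by the first strain's copy (a recorded
    donor tract) plus a trickle of residual point mutations, so 16S-style
    identity stays >99% regardless of genome-wide divergence.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    cmap = _coding_map(ancestor)
    names = [f"s{i}" for i in range(params.n_strains)]
    ledger = TruthLedger()
    ledger.true_tree = (
        "(" + ",".join(f"{n}:{d}" for n, d in zip(names, params.divergence_times)) + ");"
    )
    seqs = {}
    origins = {}
    for name, d in zip(names, params.divergence_times):
        seq, changed = _evolve_one(ancestor, cmap, d, params.omega, rng)
        seqs[name] = seq
        origins[name] = {pos: 0 for pos in changed}

    def apply_tract(donor, recipient, start, end):
        donor_piece = seqs[donor][start:end]
        seqs[recipient][start:end] = donor_piece
        ledger.recomb_tracts.append((donor, recipient, "chr", int(start), int(end)))
        anc = ancestor.seq
        org = origins[recipient]
        for pos in range(start, end):
            if seqs[recipient][pos] != anc[pos]:
                org[pos] = 1
            else:
                org.pop(pos, None)

    if params.recomb_rate > 0 and params.n_strains >= 2:
        for name in names:
            for _ in range(rng.poisson(params.recomb_rate)):
                donor = names[rng.integers(len(names) - 1)]
                if donor == name:
                    donor = names[-1]
                length = max(1, int(rng.geometric(1.0 / params.tract_length_mean)))
                start = int(rng.integers(max(1, len(ancestor.seq) - length)))
                apply_tract(donor, name, start, min(start + length, len(ancestor.seq)))

    if params.rrna_homogenize and params.n_strains >= 2 and ancestor.rrna:
        r0, r1 = ancestor.rrna
        for name in names[1:]:
            apply_tract(names[0], name, r0, r1)
        if params.rrna_residual_rate > 0:
            for name in names:
                n_res = rng.poisson(params.rrna_residual_rate * (r1 - r0))
                for pos in rng.integers(r0, r1, size=n_res):
                    pos = int(pos)
                    old = seqs[name][pos]
                    new = _BASES[(({"A": 0, "C": 1, "G": 2, "T": 3}[old]) + 1
                                  + rng.integers(3)) % 4]
                    seqs[name][pos] = new
                    if new != ancestor.seq[pos]:
                        origins[name][pos] = 0
                    else:
                        origins[name].pop(pos, None)

    ledger.site_origins = origins
    return {name: "".join(seq) for name, seq in seqs.items()}, ledger


def strain_gene_records(ancestor: Ancestor, strain: str, genome: str):
    """Project the ancestral gene model onto one evolved (unfragmented) genome."""
    out = []
    for g in ancestor.genes:
        cds = genome[g.start : g.end]
        if g.strand == "-":
            cds = revcomp(cds)
        out.append(replace(g, genome=strain, gene_id=f"{strain}_{g.gene_id}", cds=cds,
                           protein=""))
    return out


def simulate_partial_recovery(strain: str, genome: str, params: SimParams, rng=None):
    """Fragment a genome into contigs, dropping ``dropout_fraction`` of it.

    Non-overlapping removal intervals (mean length ``dropout_interval_mean``)
    remove exactly round(dropout_fraction * L) nt; the retained segments become
    contigs with lognormal declared mean coverage, of which ``n_hotspots``
    are boosted to ``hotspot_coverage`` to emulate MDA amplification
    hotspots.  Returns (GenomeAssembly, dropout interval list, hotspot contig ids).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    L = len(genome)
    total_remove = int(round(params.dropout_fraction * L))
    if total_remove == 0:
        intervals = []
        keep_segments = [(0, L)]
    else:
        n_int = max(1, int(round(total_remove / params.dropout_interval_mean)))
        cuts = rng.multinomial(total_remove - n_int, np.full(n_int, 1.0 / n_int)) + 1
        keep_total = L - total_remove
        keeps = rng.multinomial(keep_total - (n_int + 1),
                                np.full(n_int + 1, 1.0 / (n_int + 1))) + 1
        intervals = []
        keep_segments = []
        pos = 0
        for i in range(n_int):
            keep_segments.append((pos, pos + int(keeps[i])))
            pos += int(keeps[i])
            intervals.append((pos, pos + int(cuts[i])))
            pos += int(cuts[i])
        keep_segments.append((pos, pos + int(keeps[-1])))

    contigs = {}
    for k, (s0, s1) in enumerate(keep_segments):
        if s1 <= s0:
            continue
        cov = float(np.exp(rng.normal(np.log(params.coverage_median),
                                      params.coverage_lognormal_sigma)))
        contigs[f"{strain}_c{k + 1}"] = Contig(f"{strain}_c{k + 1}", genome[s0:s1], cov)

    hotspots = []
    ids = sorted(contigs)
    if params.n_hotspots > 0 and ids:
        chosen = rng.choice(len(ids), size=min(params.n_hotspots, len(ids)),
                            replace=False)
        for idx in np.atleast_1d(chosen):
            cid = ids[int(idx)]
            contigs[cid].coverage = params.hotspot_coverage * (1.0 + 0.2 * rng.random())
            hotspots.append(cid)

    assembly = GenomeAssembly(genome_id=strain, contigs=contigs)
    return assembly, intervals, hotspots


def _revcomp_read(seq: str) -> str:
    return revcomp(seq)


def simulate_reads(assemblies: dict, params: SimParams, ledger: TruthLedger, rng=None):
    """Paired error-free reads per genome, with cross-library misassignment.

    Emitted depth per contig is ``sequencing_depth`` (declared coverage-table
    depth is deliberately independent; see package docs).  A Binomial
    (n_pairs, misassignment_rate) number of pairs per genome is relabeled to
    a random other genome.  Hopped pairs come from contigs declared above
    ``hotspot_threshold`` with probability ``hotspot_hop_fraction``
    (coverage-weighted within the hotspot pool), mirroring the extreme MDA
    coverage skew that concentrates index hopping on ultra-high-coverage
    regions.  Returns dict genome -> list[(read id, sequence)]; misassigned
    ids are added to ``ledger``.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    names = sorted(assemblies)
    if params.misassignment_rate > 0 and len(names) < 2:
        raise ValueError("misassignment requires at least 2 genomes")
    rl = params.read_length
    per_genome_pairs = {}
    for name in names:
        pairs = []
        for contig in sorted(assemblies[name].contigs):
            c = assemblies[name].contigs[contig]
            if len(c) < rl:
                continue
            insert = min(params.insert_size, len(c))
            n_pairs = max(1, int(round(len(c) * params.sequencing_depth / (2.0 * rl))))
            starts = rng.integers(0, len(c) - insert + 1, size=n_pairs)
            for k, s in enumerate(starts):
                s = int(s)
                r1 = c.seq[s : s + rl]
                r2 = _revcomp_read(c.seq[s + insert - rl : s + insert])
                base = f"{name}:{contig}:{k}"
                pairs.append((base, c.coverage, r1, r2))
        per_genome_pairs[name] = pairs

    if params.error_rate > 0:
        for name in names:
            mutated = []
            for base, cov, r1, r2 in per_genome_pairs[name]:
                r1 = _add_errors(r1, params.error_rate, rng)
                r2 = _add_errors(r2, params.error_rate, rng)
                mutated.append((base, cov, r1, r2))
            per_genome_pairs[name] = mutated

    read_sets = {name: [] for name in names}
    for name in names:
        pairs = per_genome_pairs[name]
        n_mis = rng.binomial(len(pairs), params.misassignment_rate) if params.misassignment_rate else 0
        mis_idx = set()
        if n_mis:
            cov = np.array([p[1] for p in pairs], dtype=float)
            hot = np.nonzero(cov > params.hotspot_threshold)[0]
            cold = np.nonzero(cov <= params.hotspot_threshold)[0]
            if len(hot) == 0:
                hot, cold = cold, hot  # no hotspots: fall back to coverage weighting
            n_hot = rng.binomial(n_mis, params.hotspot_hop_fraction) if len(cold) else n_mis
            n_hot = min(n_hot, len(hot))
            n_cold = min(n_mis - n_hot, len(cold))
            w_hot = cov[hot] / cov[hot].sum()
            mis_idx = set(int(i) for i in
                          rng.choice(hot, size=n_hot, replace=False, p=w_hot))
            if n_cold:
                w_cold = cov[cold] / cov[cold].sum()
                mis_idx |= set(int(i) for i in
                               rng.choice(cold, size=n_cold, replace=False, p=w_cold))
        for i, (base, _cov, r1, r2) in enumerate(pairs):
            if i in mis_idx:
                target = names[(names.index(name) + 1 + int(rng.integers(len(names) - 1)))
                               % len(names)]
                read_sets[target].append((base + "/1", r1))
                read_sets[target].append((base + "/2", r2))
                ledger.misassigned_read_ids.update({base + "/1", base + "/2"})
            else:
                read_sets[name].append((base + "/1", r1))
                read_sets[name].append((base + "/2", r2))
    return read_sets


def _add_errors(read: str, rate: float, rng) -> str:
    seq = list(read)
    for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
        old = seq[pos]
        seq[pos] = _BASES[(({"A": 0, "C": 1, "G": 2, "T": 3}[old]) + 1 + rng.integers(3)) % 4]
    return "".join(seq)


def simulate_study(params: SimParams):
    """End-to-end simulation: ancestor -> strains -> fragmented SAGs -> reads.

    Returns a dict with keys ``ancestor``, ``genomes`` (strain -> full
    sequence), ``assemblies`` (strain -> fragmented GenomeAssembly),
    ``genes`` (strain -> GeneRecord list on the full genome), ``reads``
    (strain -> [(id, seq)]), and ``ledger``.
    """
    rng = np.random.default_rng(params.seed)
    ancestor = generate_ancestor(params, rng)
    genomes, ledger = evolve_strains(ancestor, params, rng)
    assemblies = {}
    genes = {}
    for strain, genome in genomes.items():
        asm, intervals, hotspots = simulate_partial_recovery(strain, genome, params, rng)
        assemblies[strain] = asm
        ledger.dropout_intervals[strain] = intervals
        ledger.hotspot_contigs[strain] = hotspots
        genes[strain] = strain_gene_records(ancestor, strain, genome)
    reads = simulate_reads(assemblies, params, ledger, rng)
    return {
        "ancestor": ancestor,
        "genomes": genomes,
        "assemblies": assemblies,
        "genes": genes,
        "reads": reads,
        "ledger": ledger,
    }


def remap_genes(genes, dropout_intervals, genome_length: int, strain: str):
    """Project full-genome gene records onto the fragmented contigs.

    Genes fully contained in a retained segment are remapped to contig
    coordinates (contig ids follow ``simulate_partial_recovery`` naming);
    genes overlapping a dropout interval are lost.
    """
    segments = []
    pos = 0
    for s0, s1 in sorted(dropout_intervals):
        if pos < s0:
            segments.append((pos, s0))
        pos = s1
    if pos < genome_length:
        segments.append((pos, genome_length))
    out = []
    for g in genes:
        for k, (s0, s1) in enumerate(segments):
            if g.start >= s0 and g.end <= s1:
                out.append(replace(g, genome=strain,
                                   contig=f"{strain}_c{k + 1}",
                                   start=g.start - s0, end=g.end - s0))
                break
    return out


def write_simulation(sim: dict, outdir) -> None:
    """Write a simulation to disk: FASTA/FASTQ/TSV bundles plus truth ledger."""
    from pathlib import Path

    import pandas as pd

    from sagkit import iodata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = sim["ledger"]
    for strain, assembly in sim["assemblies"].items():
        iodata.write_fasta(outdir / f"{strain}.fasta",
                           [(c.id, c.seq) for c in assembly])
        iodata.write_coverage_table(outdir / f"{strain}.coverage.tsv", assembly)
        genes = remap_genes(sim["genes"][strain],
                            ledger.dropout_intervals.get(strain, []),
                            len(sim["genomes"][strain]), strain)
        iodata.write_gene_table(outdir / f"{strain}.genes.tsv", genes)
        if sim.get("reads"):
            iodata.write_fastq(outdir / f"{strain}.fastq", sim["reads"][strain])
    pd.DataFrame(ledger.recomb_tracts,
                 columns=["donor", "recipient", "contig", "start", "end"]
                 ).to_csv(outdir / "truth_tracts.tsv", sep="\t", index=False)
    origin_rows = [
        (strain, pos, origin)
        for strain in sorted(ledger.site_origins)
        for pos, origin in sorted(ledger.site_origins[strain].items())
    ]
    pd.DataFrame(origin_rows, columns=["strain", "position", "origin"]
                 ).to_csv(outdir / "truth_origins.tsv", sep="\t", index=False)
    with open(outdir / "truth_misassigned.txt", "w") as fh:
        for rid in sorted(ledger.misassigned_read_ids):
            fh.write(rid + "\n")
    (outdir / "true_tree.nwk").write_text(ledger.true_tree + "\n")
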