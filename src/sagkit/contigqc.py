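"""Contig quality filtering for single-amplified genome assemblies.

Three exclusion rules applied in order — (i) contigs shorter than 250 bp;
(ii) contigs shorter than 500 bp whose read coverage is below 5x or that
lack a translated-search hit against the species reference proteome at
E <= 1e-5; (iii) contigs with no translated-search hit against a bacterial
protein panel — followed by removal of contigs identical to (or exact
substrings of, either strand) larger contigs, and completeness estimation
against a minimal essential gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

from sagkit import palign
from sagkit.iodata import GenomeAssembly, revcomp


@dataclass
class ContigVerdict:
    contig: str
    retained: bool
    reason: str  # short | short_lowcov_nohit | no_bacterial_hit | redundant | pass


@dataclass
class CompletenessEstimate:
    genes_found: int
    gene_set_size: int

    @property
    def fraction(self) -> float:
        return round(100.0 * self.genes_found / self.gene_set_size, 1)


def filter_contigs(assembly: GenomeAssembly, reference_proteome, bacterial_panel,
                   config, warn=None):
    """Apply the three exclusion rules; returns a ContigVerdict per contig.

    ``reference_proteome`` and ``bacterial_panel`` are iterables of protein
    sequences.  An empty bacterial panel skips rule (iii) with a warning
    (via ``warn`` callback when given).
    """
    reference_index = palign.PanelIndex(list(reference_proteome))
    bacterial_index = palign.PanelIndex(list(bacterial_panel))
    if not len(bacterial_index) and warn is not None:
        warn("empty bacterial panel: contamination rule skipped")
    verdicts = []
    for cid in sorted(assembly.contigs):
        c = assembly.contigs[cid]
        if len(c) < 250:
            verdicts.append(ContigVerdict(cid, False, "short"))
            continue
        if len(c) < 500 and (
            c.coverage < 5
            or not reference_index.has_translated_hit(c.seq, config.evalue_cutoff)
        ):
            verdicts.append(ContigVerdict(cid, False, "short_lowcov_nohit"))
            continue
        if len(bacterial_index) and not bacterial_index.has_translated_hit(
                c.seq, config.evalue_cutoff):
            verdicts.append(ContigVerdict(cid, False, "no_bacterial_hit"))
            continue
        verdicts.append(ContigVerdict(cid, True, "pass"))
    return verdicts


def remove_redundant_contigs(assembly: GenomeAssembly):
    """Drop contigs contained in strictly longer contigs (either strand).

    Two identical contigs of equal length keep the lexicographically
    smaller id.  Returns (filtered GenomeAssembly, verdict list).
    """
    order = sorted(assembly.contigs,
                   key=lambda cid: (-len(assembly.contigs[cid]), cid))
    kept = {}
    verdicts = []
    for cid in order:
        seq = assembly.contigs[cid].seq
        redundant = False
        for kid, kseq in kept.items():
            if len(seq) < len(kseq.seq) and (seq in kseq.seq or revcomp(seq) in kseq.seq):
                redundant = True
                break
            if len(seq) == len(kseq.seq) and (seq == kseq.seq or revcomp(seq) == kseq.seq):
                redundant = True  # equal length: later id (cid > kid by order) dropped
                break
        if redundant:
            verdicts.append(ContigVerdict(cid, False, "redundant"))
        else:
            kept[cid] = assembly.contigs[cid]
            verdicts.append(ContigVerdict(cid, True, "pass"))
    filtered = GenomeAssembly(assembly.genome_id,
                              {cid: assembly.contigs[cid] for cid in sorted(kept)})
    return filtered, sorted(verdicts, key=lambda v: v.contig)


def apply_verdicts(assembly: GenomeAssembly, verdicts) -> GenomeAssembly:
    keep = {v.contig for v in verdicts if v.retained}
    return GenomeAssembly(
        assembly.genome_id,
        {cid: c for cid, c in assembly.contigs.items() if cid in keep},
    )


def estimate_completeness(genes, essential_set, min_identity: float = 0.5,
                          min_coverage: float = 0.5) -> CompletenessEstimate:
    """Fraction of a minimal essential gene set recovered in ``genes``.

    An essential protein counts as found when some gene's protein aligns to
    it at >= ``min_identity`` identity covering >= ``min_coverage`` of both
    sequences.  Exact substring matches short-circuit the alignment.
    """
    essential = list(essential_set)
    if not essential:
        raise ValueError("essential gene set is empty")
    proteins = [g.protein for g in genes if g.protein]
    found = 0
    for target in essential:
        hit = False
        for prot in proteins:
            if target == prot or (len(target) >= 40 and target in prot):
                hit = True
                break
            res = palign.align_pair(prot, target)
            if (res is not None and res["identity"] >= 100 * min_identity
                    and res["query_coverage"] >= min_coverage
                    and res["subject_coverage"] >= min_coverage):
                hit = True
                break
        if hit:
            found += 1
    return CompletenessEstimate(found, len(essential))
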