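"""Removal of cross-library misassigned reads (index hopping cleanup).

Index hopping on a multiplexed flow cell preferentially leaks reads from
ultra-high-coverage regions of one library into the others, where they pile
up thinly.  The cleanup therefore (1) collects foreign regions whose mean
coverage exceeds a threshold (default 5000x), (2) maps each read set against
those regions with a mismatch cap, and (3) removes reads whose pile-up depth
over their own footprint is at or below the removal depth (default 20x);
deeper-piling reads are kept only if they also align to the read's own
assembly at high identity (a conserved-region rescue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from sagkit.iodata import GenomeAssembly, revcomp

SEED_K = 25  # guarantees a hit for any read with <=2 mismatches over 76 nt


@dataclass
class HighCoverageRegion:
    genome: str
    contig: str
    start: int
    end: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MappedRead:
    read_id: str
    seq: str
    region_index: int
    start: int  # position on the region
    mismatches: int
    pileup_depth: float = float("nan")


@dataclass
class CleanupReport:
    genome: str
    total_reads: int
    removed_ids: set = field(default_factory=set)
    rescued_ids: set = field(default_factory=set)
    pileup_depths: dict = field(default_factory=dict)  # read id -> depth

    @property
    def kept(self) -> int:
        return self.total_reads - len(self.removed_ids)


def find_high_coverage_regions(assembly: GenomeAssembly, threshold: float,
                               min_length: int = 76):
    """Contigs whose mean read coverage exceeds ``threshold``.

    Each qualifying contig of at least ``min_length`` nt becomes one region
    spanning the whole contig.  An empty list is a valid result.
    """
    regions = []
    for cid in sorted(assembly.contigs):
        c = assembly.contigs[cid]
        if c.coverage > threshold and len(c) >= min_length:
            regions.append(HighCoverageRegion(assembly.genome_id, cid, 0, len(c),
                                              float(c.coverage)))
    return regions


class _RegionIndex:
    """Exact k-mer index over region sequences, both strands."""

    def __init__(self, regions, k: int = SEED_K):
        self.k = k
        self.regions = regions
        self.index = {}
        for ridx, (region, seq) in enumerate(regions):
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for pos in range(len(s) - k + 1):
                    self.index.setdefault(s[pos : pos + k], []).append((ridx, strand, pos))

    def map_read(self, read: str, max_mismatches: int):
        """Best ungapped placement with <= max_mismatches, or None."""
        k = self.k
        if len(read) < k:
            return None
        best = None
        for off in range(len(read) - k + 1):
            for ridx, strand, pos in self.index.get(read[off : off + k], ()):
                _region, seq = self.regions[ridx]
                s = seq if strand == "+" else revcomp(seq)
                start = pos - off
                if start < 0 or start + len(read) > len(s):
                    continue
                mm = 0
                for a, b in zip(read, s[start : start + len(read)]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    # report coordinates on the forward strand of the region
                    fwd_start = start if strand == "+" else len(s) - start - len(read)
                    cand = (mm, ridx, fwd_start)
                    if best is None or cand < best:
                        best = cand
                        if mm == 0:
                            return best
        return best


def cross_map_reads(reads, regions, max_mismatches: int = 2):
    """Map one read set against foreign high-coverage regions.

    ``reads`` is a list of (read id, sequence); ``regions`` a list of
    (HighCoverageRegion, sequence).  Each mapped read is annotated with the
    average pile-up depth of this same read set over its footprint, computed
    as (overlapping mapped reads x read length) / footprint length and
    rounded to 1 decimal.  Returns a list of :class:`MappedRead`.
    """
    if not regions:
        return []
    index = _RegionIndex(regions)
    mapped = []
    for read_id, seq in reads:
        hit = index.map_read(seq, max_mismatches)
        if hit is not None:
            mm, ridx, start = hit
            mapped.append(MappedRead(read_id, seq, ridx, start, mm))
    # pile-up depth per mapped read from the mapped reads of this same set
    by_region = {}
    for m in mapped:
        by_region.setdefault(m.region_index, []).append(m)
    for ridx, group in by_region.items():
        starts = np.sort(np.array([m.start for m in group]))
        for m in group:
            rl = len(m.seq)
            lo = np.searchsorted(starts, m.start - rl, side="right")
            hi = np.searchsorted(starts, m.start + rl, side="left")
            overlapping = hi - lo
            m.pileup_depth = round(overlapping * rl / float(rl), 1)
    return mapped


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -1
    return aligner


def _rescued_by_own_assembly(seq: str, own_assembly: GenomeAssembly,
                             min_identity: float, min_coverage: float = 0.9) -> bool:
    """True when the read aligns to its own assembly at high identity."""
    aligner = _local_aligner()
    for query in (seq, revcomp(seq)):
        for contig in own_assembly:
            if len(contig.seq) < 10:
                continue
            alns = aligner.align(contig.seq, query)
            if len(alns) == 0:
                continue
            aln = alns[0]
            blocks_t, blocks_q = aln.aligned
            matches = 0
            columns = 0
            span = 0
            for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
                span += q1 - q0
                for ca, cb in zip(contig.seq[t0:t1], query[q0:q1]):
                    columns += 1
                    if ca == cb:
                        matches += 1
            if columns and span >= min_coverage * len(seq) \
                    and matches / columns >= min_identity:
                return True
    return False


def _pair_base(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def classify_and_remove(reads, mapped, depth_threshold: float,
                        own_assembly: GenomeAssembly,
                        min_rescue_identity: float = 0.90,
                        remove_pairs: bool = True) -> CleanupReport:
    """Classify mapped reads as misassigned or genuine and build the report.

    Mapped reads with pile-up depth <= ``depth_threshold`` are removed.
    Reads piling deeper are candidates from conserved regions: they are kept
    (rescued) when they align to the read's own assembly at
    >= ``min_rescue_identity`` identity over >= 90% of the read, else
    removed.  With ``remove_pairs`` a removed mate takes its partner along.
    """
    report = CleanupReport(genome=own_assembly.genome_id, total_reads=len(reads))
    removed = set()
    rescued = set()
    own_index = None
    for m in mapped:
        report.pileup_depths[m.read_id] = m.pileup_depth
        if m.pileup_depth <= depth_threshold:
            removed.add(m.read_id)
        else:
            if own_index is None:
                own_index = _RegionIndex([(None, c.seq) for c in own_assembly])
            # fast path: an ungapped own-assembly hit within the identity
            # budget implies the rescue criterion; fall back to local
            # alignment only when seeding fails (gapped or partial matches)
            budget = int((1.0 - min_rescue_identity) * len(m.seq))
            if own_index.map_read(m.seq, budget) is not None \
                    or _rescued_by_own_assembly(m.seq, own_assembly,
                                                min_rescue_identity):
                rescued.add(m.read_id)
            else:
                removed.add(m.read_id)
    if remove_pairs:
        removed_bases = {_pair_base(r) for r in removed}
        for read_id, _seq in reads:
            if _pair_base(read_id) in removed_bases:
                removed.add(read_id)
    report.removed_ids = removed
    report.rescued_ids = rescued - removed
    return report


def clean_read_set(reads, own_assembly, foreign_assemblies, config):
    """Full cleanup of one read set against every foreign assembly.

    ``foreign_assemblies`` maps genome id -> GenomeAssembly (with declared
    contig coverage).  Returns (kept reads, CleanupReport).
    """
    regions = []
    for gid in sorted(foreign_assemblies):
        if gid == own_assembly.genome_id:
            continue
        for region in find_high_coverage_regions(
                foreign_assemblies[gid], config.coverage_region_threshold,
                min_length=config.read_length):
            seq = foreign_assemblies[gid].contigs[region.contig].seq[region.start:region.end]
            regions.append((region, seq))
    mapped = cross_map_reads(reads, regions, config.mapper_max_mismatches)
    report = classify_and_remove(reads, mapped, config.read_removal_depth,
                                 own_assembly, config.min_rescue_identity)
    kept = [(rid, seq) for rid, seq in reads if rid not in report.removed_ids]
    return kept, report
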