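"""Sequence-divergence statistics between strains.

Covers the codon-level estimators (Nei–Gojobori counting and pairwise ML
dS/dN, per gene and on concatenated alignments), 16S-style nucleotide
diversity and pairwise identity, sliding-window Jukes–Cantor divergence
tracks, and the ternary (simplex) analysis of relative dS across ortholog
triplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align

from sagkit import mlcodon
from sagkit.codon import comparable_codon_pairs, ng86_pair_tables

SATURATION_DS = 3.0


def jc_correct(p: float):
    """Jukes–Cantor multiple-hit correction; None when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion of differences must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DivergenceRecord:
    pair: tuple
    gene_id: str
    dS: float
    dN: float
    omega: float
    estimator: str  # "NG86" or "ML"
    saturated: bool

    @classmethod
    def build(cls, pair, gene_id, dS, dN, estimator, ds_cap=SATURATION_DS):
        saturated = dS >= SATURATION_DS or not np.isfinite(dS)
        dS = min(dS, ds_cap) if np.isfinite(dS) else ds_cap
        omega = dN / dS if dS > 0 else 0.0
        return cls(tuple(pair), gene_id, float(dS), float(dN), float(omega),
                   estimator, saturated)


def ng86_divergence(cds1: str, cds2: str, pair=("A", "B"), gene_id="gene",
                    ds_cap=SATURATION_DS, min_codons: int = 10) -> DivergenceRecord:
    """Nei–Gojobori (1986) dS/dN with Jukes–Cantor correction.

    Counts synonymous/nonsynonymous sites and differences over codon columns
    comparable in both sequences (complete deletion of gapped or ambiguous
    columns), averaging multi-position codon differences over shortest
    mutational paths, then applies d = -(3/4) ln(1 - 4p/3) to pS and pN.
    pS >= 3/4 is reported saturated with dS capped at ``ds_cap``.
    """
    i1, i2 = comparable_codon_pairs(cds1, cds2)
    if len(i1) < min_codons:
        raise ValueError(f"only {len(i1)} comparable codons (<{min_codons})")
    S, N, SD, ND = ng86_pair_tables()
    s_sites = 0.5 * (S[i1].sum() + S[i2].sum())
    n_sites = 0.5 * (N[i1].sum() + N[i2].sum())
    sd = SD[i1, i2].sum()
    nd = ND[i1, i2].sum()
    pS = sd / s_sites if s_sites > 0 else 0.0
    pN = nd / n_sites if n_sites > 0 else 0.0
    dS = jc_correct(pS)
    dN = jc_correct(pN)
    dS = math.inf if dS is None else dS
    dN = math.inf if dN is None else dN
    return DivergenceRecord.build(pair, gene_id, dS, dN, "NG86", ds_cap)


def ml_pairwise_divergence(cds1: str, cds2: str, pair=("A", "B"), gene_id="gene",
                           ds_cap=SATURATION_DS, min_codons: int = 10) -> DivergenceRecord:
    """Pairwise ML dS/dN under the GY-style codon model (see ``mlcodon``)."""
    fit = mlcodon.ml_pairwise(cds1, cds2, min_codons=min_codons)
    return DivergenceRecord.build(pair, gene_id, fit["dS"], fit["dN"], "ML", ds_cap)


def concat_divergence(gene_alignments: dict, pair=("A", "B"),
                      ds_cap=SATURATION_DS) -> DivergenceRecord:
    """ML divergence of the concatenation of all shared genes for one pair.

    ``gene_alignments`` maps gene id -> (aligned CDS of genome A, aligned CDS
    of genome B).  Genes are concatenated in sorted gene-id order so the
    result is invariant to input order.
    """
    if not gene_alignments:
        raise ValueError("empty gene set")
    parts1, parts2 = [], []
    for gene_id in sorted(gene_alignments):
        a, b = gene_alignments[gene_id]
        parts1.append(a)
        parts2.append(b)
    rec = ml_pairwise_divergence("".join(parts1), "".join(parts2), pair,
                                 gene_id="concatenated", ds_cap=ds_cap)
    return rec


def _pair_p_distance(s1: str, s2: str):
    """(p, n_comparable): proportion of differing ungapped comparable sites."""
    comparable = 0
    diffs = 0
    for a, b in zip(s1, s2):
        if a in "ACGT" and b in "ACGT":
            comparable += 1
            if a != b:
                diffs += 1
    return (diffs / comparable if comparable else None), comparable


def nucleotide_diversity(alignment) -> float:
    """pi: average pairwise proportion of differing sites in an alignment.

    ``alignment`` is a list of (name, aligned sequence); comparisons use
    ungapped comparable columns per pair.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    ps = []
    for (_, s1), (_, s2) in combinations(alignment, 2):
        p, n = _pair_p_distance(s1, s2)
        if p is None:
            raise ValueError("a sequence pair shares no comparable columns")
        ps.append(p)
    return float(np.mean(ps))


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    # terminal gaps are free so identity excludes end gaps
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment, excluding end gaps.

    100 x matches / aligned columns (internal gaps count as columns),
    rounded to 2 decimals.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    columns = 0
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            columns += (a0 - prev_a) + (b0 - prev_b)  # internal gap columns
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            columns += 1
            if ca == cb:
                matches += 1
        prev_a, prev_b = a1, b1
    if columns == 0:
        return 0.0
    return round(100.0 * matches / columns, 2)


def strip_gap_columns(alignment):
    """Remove every column holding a gap in any row."""
    seqs = [s for _, s in alignment]
    keep = [i for i in range(len(seqs[0])) if all(s[i] != "-" for s in seqs)]
    return [(name, "".join(s[i] for i in keep)) for name, s in alignment]


def sliding_window_divergence(alignment, window: int, step: int):
    """Per-pair JC-corrected divergence in sliding windows.

    The alignment is stripped of all gap columns first.  Windows start at
    0, step, 2*step, ...; the final full window is always included.  Windows
    with p >= 3/4 are reported as NaN (saturated).

    Returns a dict mapping (name_a, name_b) -> list of (midpoint, value).
    """
    if step > window:
        raise ValueError("step must not exceed window")
    stripped = strip_gap_columns(alignment)
    length = len(stripped[0][1]) if stripped else 0
    if length < window:
        raise ValueError(f"gap-stripped alignment length {length} < window {window}")
    starts = list(range(0, length - window + 1, step))
    if starts[-1] != length - window:
        starts.append(length - window)
    tracks = {}
    for (na, sa), (nb, sb) in combinations(stripped, 2):
        track = []
        arr_a = np.frombuffer(sa.encode(), dtype="S1")
        arr_b = np.frombuffer(sb.encode(), dtype="S1")
        diff = arr_a != arr_b
        for s0 in starts:
            p = float(diff[s0 : s0 + window].mean())
            d = jc_correct(p)
            track.append((s0 + window / 2.0, float("nan") if d is None else d))
        tracks[(na, nb)] = track
    return tracks


@dataclass
class TernaryPoint:
    gene_id: str
    xyz: tuple  # normalized triplet, sums to 1
    category: str  # yellow (<0.1), orange (>=0.1), red (>=1), by max raw dS
    capped: bool


def _simplex_xy(xyz):
    """Map a normalized triplet to 2D ternary-plot coordinates."""
    _, y, z = xyz
    return (y + 0.5 * z, (math.sqrt(3) / 2.0) * z)


def ternary_analysis(triplets: dict, cap: float = SATURATION_DS,
                     spread_mode: str = "mean"):
    """Normalize per-gene dS triplets onto the 2-simplex and measure spread.

    ``triplets`` maps gene id -> (dS_ab, dS_ac, dS_bc) raw values; each is
    capped at ``cap`` before normalizing the triplet to sum 1.  Genes whose
    capped triplet sums to 0 are dropped (and listed).  Spread is the mean
    (or median) Euclidean distance, in ternary-plot coordinates, of gene
    points to their mean point.  Color categories follow the max raw dS of
    the triplet: <0.1 yellow, >=0.1 orange, >=1 red.

    Returns (list of TernaryPoint, spread, dropped gene ids).
    """
    if spread_mode not in ("mean", "median"):
        raise ValueError("spread_mode must be 'mean' or 'median'")
    points = []
    dropped = []
    for gene_id in sorted(triplets):
        raw = triplets[gene_id]
        if any(v < 0 for v in raw):
            raise ValueError(f"negative dS for gene {gene_id}")
        capped_vals = tuple(min(v, cap) for v in raw)
        total = sum(capped_vals)
        if total == 0:
            dropped.append(gene_id)
            continue
        xyz = tuple(v / total for v in capped_vals)
        mx = max(raw)
        category = "red" if mx >= 1 else ("orange" if mx >= 0.1 else "yellow")
        points.append(TernaryPoint(gene_id, xyz, category,
                                   capped=any(v > cap for v in raw)))
    if not points:
        return points, float("nan"), dropped
    coords = np.array([_simplex_xy(p.xyz) for p in points])
    center = coords.mean(axis=0)
    dists = np.linalg.norm(coords - center, axis=1)
    spread = float(np.mean(dists) if spread_mode == "mean" else np.median(dists))
    return points, spread, dropped
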