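"""Genetic-code tables and codon-level primitives.

Provides the standard bacterial genetic code, Nei–Gojobori (1986) synonymous
and nonsynonymous site/difference counting with shortest-path averaging for
multi-position codon differences, and protein-guided back-translation of CDS
into codon alignments.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

# Standard genetic code in TCAG order.
GENETIC_CODE = dict(
    zip(
        CODONS,
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIMMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
)

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate_codon(codon: str) -> str:
    return GENETIC_CODE.get(codon, "X")


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def is_synonymous(c1: str, c2: str) -> bool:
    return GENETIC_CODE[c1] == GENETIC_CODE[c2]


@lru_cache(maxsize=None)
def ng86_sites(codon: str):
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three single-base changes
    that are synonymous; changes creating a stop codon count as
    nonsynonymous (the original counting convention).
    """
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and is_synonymous(codon, alt):
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(c1: str, c2: str):
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Codons differing at k positions are scored by averaging over all k!
    orderings of the single-base steps; orderings passing through a stop
    codon are excluded (all orderings are used if every path is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1
            elif is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = float(np.mean([p[1] for p in usable]))
    nd = float(np.mean([p[2] for p in usable]))
    return sd, nd


@lru_cache(maxsize=1)
def ng86_pair_tables():
    """Vectorised NG86 lookup tables over the 61 sense codons.

    Returns ``(S, N, SD, ND)`` where ``S``/``N`` are per-codon site counts
    (length 61) and ``SD``/``ND`` are 61x61 difference counts.
    """
    n = len(SENSE_CODONS)
    S = np.empty(n)
    N = np.empty(n)
    for i, c in enumerate(SENSE_CODONS):
        S[i], N[i] = ng86_sites(c)
    SD = np.zeros((n, n))
    ND = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i < j:
                sd, nd = ng86_differences(c1, c2)
                SD[i, j] = SD[j, i] = sd
                ND[i, j] = ND[j, i] = nd
    return S, N, SD, ND


def codon_indices(cds: str) -> np.ndarray:
    """CDS -> array of sense-codon indices; -1 for stops/ambiguous codons."""
    out = np.empty(len(cds) // 3, dtype=np.int64)
    for k in range(len(out)):
        out[k] = SENSE_INDEX.get(cds[3 * k : 3 * k + 3], -1)
    return out


def comparable_codon_pairs(cds1: str, cds2: str):
    """Indices of codon columns comparable in both aligned CDS.

    Columns containing a gap, an ambiguous base, or a stop codon in either
    sequence are excluded pairwise (complete deletion per pair).
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned CDS lengths differ")
    i1 = codon_indices(cds1)
    i2 = codon_indices(cds2)
    keep = (i1 >= 0) & (i2 >= 0)
    return i1[keep], i2[keep]


def backtranslate(protein_alignment, cds_map):
    """Thread CDS onto a protein alignment, producing a codon alignment.

    Parameters
    ----------
    protein_alignment : list of (name, aligned protein with '-' gaps)
    cds_map : mapping name -> ungapped CDS (may include the stop codon)

    Each aligned residue is replaced by its codon; protein gaps become
    triple-nucleotide gaps.  Raises ``ValueError`` naming the sequence and
    position on any residue/codon translation mismatch.
    """
    out = []
    for name, aligned in protein_alignment:
        cds = cds_map[name]
        if len(cds) % 3:
            raise ValueError(f"{name}: CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = aligned.replace("-", "")
        if len(residues) != len(codons):
            raise ValueError(
                f"{name}: protein length {len(residues)} does not match "
                f"{len(codons)} codons"
            )
        k = 0
        pieces = []
        for col, aa in enumerate(aligned):
            if aa == "-":
                pieces.append("---")
                continue
            codon = codons[k]
            if translate_codon(codon) != aa:
                raise ValueError(
                    f"{name}: residue {aa} at alignment column {col + 1} does not "
                    f"match codon {codon}"
                )
            pieces.append(codon)
            k += 1
        out.append((name, "".join(pieces)))
    return out
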