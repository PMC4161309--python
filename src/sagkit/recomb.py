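"""Recombination statistics: four-gamete bound, gene-conversion fragments, r/m.

``minimum_recombination_events`` implements the Hudson–Kaplan lower bound Rm
under the infinite-sites model.  ``detect_gi_fragments`` is a
runs-of-agreement ("global inner") gene-conversion scan in the spirit of
Sawyer's method: pairwise maximal-scoring segments over polymorphic sites,
assessed by joint permutation of polymorphic columns with a Bonferroni
correction across pairs.  ``r_over_m`` turns per-site recombination-origin
probabilities into the two standard ratio estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

_ACGT = frozenset("ACGT")


def _column(alignment, i):
    return [s[i] for _, s in alignment]


def segregating_biallelic_sites(alignment):
    """Indices of columns that are biallelic with ACGT in every sequence."""
    length = len(alignment[0][1])
    sites = []
    for i in range(length):
        col = _column(alignment, i)
        if not set(col) <= _ACGT:
            continue
        if len(set(col)) == 2:
            sites.append(i)
    return sites


def incompatible_site_pairs(alignment, sites=None):
    """Pairs of biallelic sites exhibiting all four gametes."""
    if sites is None:
        sites = segregating_biallelic_sites(alignment)
    cols = {i: _column(alignment, i) for i in sites}
    out = []
    for a, b in combinations(sites, 2):
        gametes = {(x, y) for x, y in zip(cols[a], cols[b])}
        if len(gametes) == 4:
            out.append((a, b))
    return out


def minimum_recombination_events(alignment) -> int:
    """Hudson–Kaplan lower bound on the number of recombination events.

    Every four-gamete-incompatible site pair needs a breakpoint strictly
    between its two sites; Rm is the minimum number of breakpoints stabbing
    all such intervals (computed exactly by the right-endpoint greedy).
    Alignments with fewer than 2 segregating sites return 0.
    """
    sites = segregating_biallelic_sites(alignment)
    if len(sites) < 2:
        return 0
    intervals = incompatible_site_pairs(alignment, sites)
    if not intervals:
        return 0
    intervals.sort(key=lambda ab: ab[1])
    rm = 0
    last_break = -1  # breakpoint placed just left of this coordinate
    for a, b in intervals:
        if a >= last_break:  # not yet stabbed
            rm += 1
            last_break = b  # breakpoint in (b-1, b): stabs every (a', b') with a' < b <= b'
    return rm


@dataclass
class RecombFragment:
    pair: tuple  # (name_a, name_b)
    site_span: tuple  # (first, last) polymorphic-site ordinals, inclusive
    nt_span: tuple  # (start, end) nucleotide columns, inclusive
    score: float
    p_value: float
    gscale: int

    @property
    def length(self) -> int:
        return self.nt_span[1] - self.nt_span[0] + 1


def polymorphic_sites(alignment):
    """Columns with >=2 alleles where every sequence has an ACGT base."""
    length = len(alignment[0][1])
    sites = []
    for i in range(length):
        col = _column(alignment, i)
        if set(col) <= _ACGT and len(set(col)) >= 2:
            sites.append(i)
    return sites


def _kadane(values: np.ndarray):
    """(best segment score, start, end) of the max-scoring non-empty segment."""
    best = -np.inf
    best_span = (0, 0)
    cur = 0.0
    cur_start = 0
    for k, v in enumerate(values):
        if cur <= 0:
            cur = v
            cur_start = k
        else:
            cur += v
        if cur > best:
            best = cur
            best_span = (cur_start, k)
    return best, best_span


def _kadane_max_vectorized(V: np.ndarray) -> np.ndarray:
    """Row-wise max non-empty segment sums of a 2-D array."""
    cur = V[:, 0].copy()
    best = cur.copy()
    for k in range(1, V.shape[1]):
        cur = np.maximum(V[:, k], cur + V[:, k])
        np.maximum(best, cur, out=best)
    return best


def mismatch_penalty(gscale: int) -> float:
    """Per-mismatch penalty: gscale 0 ends runs outright; 1/2 increase it."""
    if gscale == 0:
        return -1e9
    return -(2.0 * gscale + 1.0)


def detect_gi_fragments(alignment, gscale: int = 1, p_cutoff: float = 0.05,
                        n_permutations: int = 10_000, seed: int = 0,
                        _shared_null=None):
    """Global-inner gene-conversion fragments between all sequence pairs.

    Restricting to polymorphic columns, every pair's agreement vector
    (+1 match, ``mismatch_penalty(gscale)`` per mismatch) is scanned for its
    maximal-scoring segment.  Significance is the fraction of
    ``n_permutations`` joint column permutations whose maximal segment score
    reaches the observed one, Bonferroni-corrected across pairs.  Fragments
    with corrected p <= ``p_cutoff`` are returned with nucleotide
    coordinates.  Needs >=3 sequences; no polymorphic sites -> empty list.
    """
    if len(alignment) < 3:
        raise ValueError("global-inner detection needs at least 3 sequences")
    sites = polymorphic_sites(alignment)
    if not sites:
        return []
    S = len(sites)
    pen = mismatch_penalty(gscale)
    pairs = list(combinations(range(len(alignment)), 2))
    rng = np.random.default_rng(seed)
    if _shared_null is None:
        perm_idx = np.argsort(rng.random((n_permutations, S)), axis=1)
    else:
        perm_idx = _shared_null
    fragments = []
    for ia, ib in pairs:
        na, sa = alignment[ia]
        nb, sb = alignment[ib]
        match = np.array([sa[i] == sb[i] for i in sites])
        if match.all() or not match.any():
            continue  # identical or fully mismatched on polymorphic sites
        v = np.where(match, 1.0, pen)
        obs, (k0, k1) = _kadane(v)
        if obs <= 0:
            continue
        null_best = _kadane_max_vectorized(v[perm_idx])
        p = (1.0 + float(np.sum(null_best >= obs))) / (1.0 + perm_idx.shape[0])
        p_corr = min(1.0, p * len(pairs))
        if p_corr <= p_cutoff:
            fragments.append(
                RecombFragment(
                    pair=(na, nb), site_span=(k0, k1),
                    nt_span=(sites[k0], sites[k1]),
                    score=float(obs), p_value=float(p_corr), gscale=gscale,
                )
            )
    return fragments


def detect_fragments_multi_gscale(alignment, gscale_set=(0, 1, 2),
                                  p_cutoff: float = 0.05,
                                  n_permutations: int = 10_000, seed: int = 0):
    """Union of GI fragments over several mismatch-penalty scales."""
    sites = polymorphic_sites(alignment)
    if not sites or len(alignment) < 3:
        return []
    rng = np.random.default_rng(seed)
    shared = np.argsort(rng.random((n_permutations, len(sites))), axis=1)
    out = []
    for g in sorted(gscale_set):
        out.extend(detect_gi_fragments(alignment, g, p_cutoff,
                                       n_permutations, seed, _shared_null=shared))
    return out


def summarize_fragments(per_gene_fragments: dict, pair):
    """Per-pair gene count and mean fragment length across genes.

    ``per_gene_fragments`` maps gene id -> fragment list (possibly several
    gscales); a gene counts once if any of its fragments involves ``pair``.
    Returns (count of genes with >=1 fragment, mean length or None).
    """
    pair = tuple(sorted(pair))
    lengths = []
    genes_hit = 0
    for _gene, fragments in sorted(per_gene_fragments.items()):
        here = [f for f in fragments if tuple(sorted(f.pair)) == pair]
        if here:
            genes_hit += 1
            lengths.extend(f.length for f in here)
    mean_len = float(np.mean(lengths)) if lengths else None
    return genes_hit, mean_len


def r_over_m(origin_probabilities, method: str = "all_positions") -> float:
    """Ratio of recombination- to mutation-derived substitutions.

    ``all_positions``: sum of recombination probabilities over the sum of
    their complements, across every substituted site.  ``confident_only``:
    sites with p >= 0.95 count as recombinant, p <= 0.05 as mutational,
    everything else excluded; the ratio of the two counts (infinity when no
    mutational site remains but recombinant ones do).
    """
    p = np.asarray(list(origin_probabilities), dtype=float)
    if p.size == 0:
        raise ValueError("no substituted sites")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("origin probabilities must lie in [0, 1]")
    if method == "all_positions":
        r = float(p.sum())
        m = float((1.0 - p).sum())
    elif method == "confident_only":
        r = float(np.sum(p >= 0.95))
        m = float(np.sum(p <= 0.05))
    else:
        raise ValueError("method must be 'all_positions' or 'confident_only'")
    if m == 0:
        return float("inf") if r > 0 else 0.0
    return r / m
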