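"""Shared fixtures and oracle helpers for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from sagkit.recomb import incompatible_site_pairs, segregating_biallelic_sites

BASES = "ACGT"


def brute_force_rm(alignment) -> int:
    """Exhaustive minimum number of breakpoints stabbing all four-gamete intervals.

    A breakpoint at column c (between c-1 and c) stabs an incompatible pair
    (a, b) iff a < c <= b.  Any stabbing point can be slid right to the next
    segregating site, so the segregating-site positions are a complete
    candidate set and subset enumeration over them is exact.
    """
    sites = segregating_biallelic_sites(alignment)
    intervals = incompatible_site_pairs(alignment, sites)
    if not intervals:
        return 0
    candidates = sites
    for k in range(1, len(candidates) + 1):
        for combo in combinations(candidates, k):
            if all(any(a < c <= b for c in combo) for a, b in intervals):
                return k
    raise AssertionError("no stabbing set found")  # pragma: no cover


def random_biallelic_alignment(rng, n_seq=5, n_variable=None, n_constant=8):
    """Random alignment with a controlled number of biallelic columns."""
    if n_variable is None:
        n_variable = int(rng.integers(2, 13))
    cols = []
    for _ in range(n_constant):
        cols.append([BASES[rng.integers(4)]] * n_seq)
    for _ in range(n_variable):
        b1, b2 = rng.choice(list(BASES), size=2, replace=False)
        col = [b1 if rng.random() < 0.5 else b2 for _ in range(n_seq)]
        if len(set(col)) < 2:  # force both alleles present
            col[0], col[1] = b1, b2
        cols.append(col)
    order = rng.permutation(len(cols))
    cols = [cols[i] for i in order]
    seqs = ["".join(col[i] for col in cols) for i in range(n_seq)]
    return [(f"t{i}", s) for i, s in enumerate(seqs)]


def random_dna(rng, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
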