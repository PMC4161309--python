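import numpy as np
import pytest

from sagkit.recomb import (
    RecombFragment,
    _kadane,
    detect_fragments_multi_gscale,
    detect_gi_fragments,
    incompatible_site_pairs,
    minimum_recombination_events,
    mismatch_penalty,
    polymorphic_sites,
    r_over_m,
    segregating_biallelic_sites,
    summarize_fragments,
)
from tests.conftest import brute_force_rm, random_biallelic_alignment, random_dna


def test_segregating_and_polymorphic_sites():
    aln = [("a", "AACGN"), ("b", "ATCGN"), ("c", "ATAGN"), ("d", "AAAGN")]
    assert segregating_biallelic_sites(aln) == [1, 2]
    assert polymorphic_sites(aln) == [1, 2]  # N column excluded


def test_four_gamete_detection():
    # sites 0 and 1 show all four gametes; site 2 is constant
    aln = [("a", "AAC"), ("b", "ATC"), ("c", "TAC"), ("d", "TTC")]
    assert incompatible_site_pairs(aln) == [(0, 1)]
    assert minimum_recombination_events(aln) == 1


def test_rm_zero_without_incompatibility():
    aln = [("a", "AAAA"), ("b", "AATT"), ("c", "TTTT")]
    assert minimum_recombination_events(aln) == 0
    assert minimum_recombination_events([("a", "ACGT"), ("b", "ACGT")]) == 0


def test_rm_matches_brute_force_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(150):
        aln = random_biallelic_alignment(rng)
        assert minimum_recombination_events(aln) == brute_force_rm(aln)


def test_kadane_and_penalties():
    best, span = _kadane(np.array([-1.0, 2.0, 3.0, -10.0, 1.0]))
    assert best == 5.0 and span == (1, 2)
    assert mismatch_penalty(0) == -1e9
    assert mismatch_penalty(1) == -3.0
    assert mismatch_penalty(2) == -5.0


def test_detect_needs_three_sequences():
    with pytest.raises(ValueError):
        detect_gi_fragments([("a", "ACGT"), ("b", "ACGT")])


def test_detect_no_polymorphism_is_empty():
    aln = [("a", "ACGT" * 5), ("b", "ACGT" * 5), ("c", "ACGT" * 5)]
    assert detect_gi_fragments(aln) == []
    assert detect_fragments_multi_gscale(aln) == []


def _implant_tract(rng, n_seq=3, length=1200, divergence=0.08, tract=(400, 700)):
    anc = random_dna(rng, length)
    seqs = []
    for _ in range(n_seq):
        s = list(anc)
        for pos in np.nonzero(rng.random(length) < divergence)[0]:
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1 + rng.integers(3)) % 4]
        seqs.append(s)
    seqs[1][tract[0]:tract[1]] = seqs[0][tract[0]:tract[1]]  # conversion event
    return [(f"t{i}", "".join(s)) for i, s in enumerate(seqs)]


def test_detect_finds_implanted_tract(rng):
    aln = _implant_tract(rng)
    frags = detect_gi_fragments(aln, gscale=1, n_permutations=1000, seed=1)
    hit = [f for f in frags if set(f.pair) == {"t0", "t1"}]
    assert hit
    f = max(hit, key=lambda f: f.score)
    overlap = min(f.nt_span[1], 699) - max(f.nt_span[0], 400) + 1
    assert overlap / 300 >= 0.8
    assert f.p_value <= 0.05


def test_multi_gscale_union_is_superset(rng):
    aln = _implant_tract(rng)
    single = detect_gi_fragments(aln, gscale=1, n_permutations=500, seed=3)
    multi = detect_fragments_multi_gscale(aln, (0, 1, 2), n_permutations=500, seed=3)
    assert len(multi) >= len(single)
    assert {f.gscale for f in multi} <= {0, 1, 2}


def test_fragment_length_property():
    f = RecombFragment(("a", "b"), (0, 4), (10, 59), 5.0, 0.01, 1)
    assert f.length == 50


def test_summarize_fragments():
    f1 = RecombFragment(("a", "b"), (0, 4), (10, 59), 5.0, 0.01, 1)
    f2 = RecombFragment(("b", "a"), (0, 4), (0, 99), 5.0, 0.01, 2)
    f3 = RecombFragment(("a", "c"), (0, 4), (0, 19), 5.0, 0.01, 1)
    count, mean_len = summarize_fragments({"g1": [f1, f2], "g2": [f3]}, ("a", "b"))
    assert count == 1
    assert mean_len == pytest.approx(75.0)
    count, mean_len = summarize_fragments({"g1": [f3]}, ("a", "b"))
    assert count == 0 and mean_len is None


def test_r_over_m_examples():
    origins = [1.0] * 30 + [0.0] * 10
    assert r_over_m(origins, "all_positions") == pytest.approx(3.0)
    assert r_over_m(origins, "confident_only") == pytest.approx(3.0)
    worked = [1.0, 1.0, 0.9, 0.0]
    assert r_over_m(worked, "all_positions") == pytest.approx(2.9 / 1.1)
    assert r_over_m(worked, "confident_only") == pytest.approx(2.0)


def test_r_over_m_edge_cases():
    assert r_over_m([1.0, 1.0], "all_positions") == float("inf")
    assert r_over_m([0.0, 0.0], "all_positions") == 0.0
    with pytest.raises(ValueError):
        r_over_m([], "all_positions")
    with pytest.raises(ValueError):
        r_over_m([1.2], "all_positions")
    with pytest.raises(ValueError):
        r_over_m([0.5], "sometimes")
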