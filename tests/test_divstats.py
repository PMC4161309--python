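import math

import numpy as np
import pytest

from sagkit import divstats
from sagkit.divstats import (
    DivergenceRecord,
    concat_divergence,
    jc_correct,
    ng86_divergence,
    nucleotide_diversity,
    pairwise_identity,
    sliding_window_divergence,
    strip_gap_columns,
    ternary_analysis,
)


def test_jc_correct_closed_form():
    assert jc_correct(0.0) == 0.0
    assert jc_correct(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
    assert jc_correct(0.75) is None
    assert jc_correct(0.9) is None
    with pytest.raises(ValueError):
        jc_correct(-0.01)


def test_ng86_hand_example():
    a = "TTT" * 10
    b = "TTT" * 9 + "TTC"
    rec = ng86_divergence(a, b)
    assert rec.dS == pytest.approx(0.3831, abs=5e-5)
    assert rec.dN == 0.0
    assert rec.estimator == "NG86"
    assert not rec.saturated


def test_ng86_identical_is_zero():
    a = "ATGAAATTTGGCCAG" * 4
    rec = ng86_divergence(a, a)
    assert rec.dS == 0.0 and rec.dN == 0.0


def test_ng86_requires_min_codons():
    with pytest.raises(ValueError, match="comparable codons"):
        ng86_divergence("ATGTTT", "ATGTTC")


def test_divergence_record_caps_and_flags_saturation():
    rec = DivergenceRecord.build(("a", "b"), "g", dS=4.2, dN=0.1, estimator="NG86")
    assert rec.saturated and rec.dS == 3.0
    rec = DivergenceRecord.build(("a", "b"), "g", dS=math.inf, dN=0.1,
                                 estimator="NG86", ds_cap=2.0)
    assert rec.saturated and rec.dS == 2.0
    rec = DivergenceRecord.build(("a", "b"), "g", dS=0.2, dN=0.02, estimator="ML")
    assert not rec.saturated
    assert rec.omega == pytest.approx(0.1)


def test_concat_divergence_order_invariant():
    rng = np.random.default_rng(42)
    from sagkit.simulate import simulate_codon_pair
    genes = {}
    for name in ("gB", "gA", "gC"):
        genes[name] = simulate_codon_pair(80, 0.15, 0.1, rng)
    r1 = concat_divergence(dict(sorted(genes.items())), ("x", "y"))
    r2 = concat_divergence(dict(reversed(list(genes.items()))), ("x", "y"))
    assert r1.dS == r2.dS and r1.dN == r2.dN
    with pytest.raises(ValueError):
        concat_divergence({}, ("x", "y"))


def test_pairwise_identity_arithmetic():
    assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0
    assert pairwise_identity("AAAAATAAAA", "AAAAACAAAA") == 90.0
    # a pure prefix aligns with free end gaps: identity over aligned columns
    assert pairwise_identity("ACGTACGTACGT", "ACGTACGT") == 100.0
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def test_nucleotide_diversity():
    aln = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAT"), ("c", "AAAAAAAAAT")]
    # pairwise p: ab 0.1, ac 0.1, bc 0.0 -> mean 1/15
    assert nucleotide_diversity(aln) == pytest.approx(0.2 / 3)
    with pytest.raises(ValueError):
        nucleotide_diversity([("a", "AAAA")])


def test_strip_gap_columns():
    aln = [("a", "A-CG"), ("b", "AAC-")]
    assert strip_gap_columns(aln) == [("a", "AC"), ("b", "AC")]


def test_sliding_window_starts_and_final_window():
    aln = [("a", "A" * 130), ("b", "A" * 130)]
    tracks = sliding_window_divergence(aln, window=100, step=20)
    track = tracks[("a", "b")]
    starts = [m - 50.0 for m, _ in track]
    assert starts == [0, 20, 30]  # final full window appended
    assert all(v == 0.0 for _, v in track)


def test_sliding_window_saturation_is_nan():
    a = "A" * 100
    b = "C" * 100
    track = sliding_window_divergence([("a", a), ("b", b)], 100, 50)[("a", "b")]
    assert math.isnan(track[0][1])


def test_sliding_window_validation():
    aln = [("a", "ACGT" * 10), ("b", "ACGT" * 10)]
    with pytest.raises(ValueError):
        sliding_window_divergence(aln, window=10, step=20)
    with pytest.raises(ValueError):
        sliding_window_divergence(aln, window=100, step=10)


def test_ternary_triplets_sum_to_one_and_symmetric_centroid():
    points, spread, dropped = ternary_analysis(
        {"g1": (0.2, 0.2, 0.2), "g2": (0.05, 0.05, 0.05)})
    assert dropped == []
    for p in points:
        assert sum(p.xyz) == pytest.approx(1.0)
        assert p.xyz == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert spread == pytest.approx(0.0)


def test_ternary_categories_and_capping():
    points, _, _ = ternary_analysis(
        {"y": (0.01, 0.02, 0.03), "o": (0.5, 0.2, 0.1), "r": (4.0, 0.2, 0.2)})
    cats = {p.gene_id: p.category for p in points}
    assert cats == {"y": "yellow", "o": "orange", "r": "red"}
    capped = {p.gene_id: p.capped for p in points}
    assert capped == {"y": False, "o": False, "r": True}
    # the capped component contributes cap=3, not 4
    xyz = next(p.xyz for p in points if p.gene_id == "r")
    assert xyz[0] == pytest.approx(3.0 / 3.4)


def test_ternary_drops_zero_triplets_and_validates():
    points, spread, dropped = ternary_analysis({"z": (0.0, 0.0, 0.0)})
    assert points == [] and dropped == ["z"] and math.isnan(spread)
    with pytest.raises(ValueError):
        ternary_analysis({"n": (-0.1, 0.2, 0.2)})
    with pytest.raises(ValueError):
        ternary_analysis({"g": (0.1, 0.1, 0.1)}, spread_mode="mode")


def test_ternary_spread_median_vs_mean():
    trip = {f"g{i}": (0.1 + 0.01 * i, 0.1, 0.1) for i in range(9)}
    _, s_mean, _ = ternary_analysis(trip, spread_mode="mean")
    _, s_median, _ = ternary_analysis(trip, spread_mode="median")
    assert s_mean > 0 and s_median > 0
    assert s_mean != s_median
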