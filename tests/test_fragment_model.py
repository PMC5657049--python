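import numpy as np
import pytest

from oracles import histogram_probs
from shortpair import fragment_model as fm
from shortpair.io_formats import SeedAlignment
from shortpair.profile_hmm import DomainHit, build_from_msa
from shortpair.simulate import SimScenario, simulate_family


def _hit(fam, ms, me, rid="r", end=1):
    return DomainHit(read_id=rid, end=end, frame=1, family_id=fam,
                     model_start=ms, model_end=me, seq_start=1,
                     seq_end=me - ms + 1, score=10.0)


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def test_conversion_identity_on_ungapped():
    msa = SeedAlignment("f", [("a", "A" * 20), ("b", "C" * 20)], 20)
    m = np.arange(1, 21)
    assert fm.model_span_to_seed_span(msa, m, 0, 3, 10) == (3, 10)
    assert fm.model_span_to_seed_span(msa, m, 1, 1, 20) == (1, 20)


def test_conversion_skips_gap_columns():
    # column 3 is an insert column (not in the model map); the row's gap
    # there contributes nothing to its residue count
    msa = SeedAlignment("f", [("a", "AC-EF"), ("b", "ACDEF")], 5)
    m = np.array([1, 2, 4, 5])
    assert fm.model_span_to_seed_span(msa, m, 0, 3, 4) == (3, 4)
    assert fm.model_span_to_seed_span(msa, m, 1, 3, 4) == (4, 5)


def test_conversion_unanchored_span_is_absent():
    msa = SeedAlignment("f", [("a", "--AAA"), ("b", "CCAAA")], 5)
    m = np.arange(1, 6)
    assert fm.model_span_to_seed_span(msa, m, 0, 1, 2) is None


def test_conversion_seed_row_out_of_range():
    msa = SeedAlignment("f", [("a", "ACDEF")], 5)
    with pytest.raises(IndexError):
        fm.model_span_to_seed_span(msa, np.arange(1, 6), 3, 1, 2)


def test_conversion_identity_property_on_random_ungapped_alignments():
    rng = np.random.default_rng(17)
    for seed in range(20):
        msa, _, _ = simulate_family(
            SimScenario(family_length=40, indel_rate=0.0, fragment_mean=35,
                        fragment_sd=2, fragment_min=30, fragment_max=40,
                        read_length_nt=76, rng_seed=seed), "F", rng)
        m = build_from_msa(msa).map_to_column
        a = int(rng.integers(1, 40))
        b = int(rng.integers(a, 41))
        row = int(rng.integers(len(msa.rows)))
        assert fm.model_span_to_seed_span(msa, m, row, a, b) == (a, b)


def test_converted_span_bounded_by_model_span_plus_inserts():
    msa = SeedAlignment("f", [("a", "ACWWDEF"), ("b", "AC--DEF")], 7,
                        rf="xx..xxx")
    m = build_from_msa(msa).map_to_column
    s_a = fm.model_span_to_seed_span(msa, m, 0, 1, 5)
    s_b = fm.model_span_to_seed_span(msa, m, 1, 1, 5)
    assert s_a == (1, 7)   # 5 match residues + 2 inserts
    assert s_b == (1, 5)
    assert s_a[1] - s_a[0] + 1 == 5 + 2
    assert s_b[1] - s_b[0] + 1 == 5


# ---------------------------------------------------------------------------
# fragment length estimation
# ---------------------------------------------------------------------------

def test_fragment_length_ungapped_outer_span():
    msa = SeedAlignment("f", [("a", "A" * 50), ("b", "A" * 50)], 50)
    m = np.arange(1, 51)
    assert fm.estimate_fragment_length(msa, m, _hit("f", 1, 10), _hit("f", 41, 50)) == 50


def test_fragment_length_two_seed_average_with_insert_block():
    # seed B carries a private 5-residue insert block between the two
    # hit spans: per-seed outer spans are 50 and 55, mean 52.5 -> 53
    cols = 55
    row_a = "A" * 25 + "-" * 5 + "A" * 25
    row_b = "A" * 55
    rf = "x" * 25 + "." * 5 + "x" * 25
    msa = SeedAlignment("f", [("a", row_a), ("b", row_b)], cols, rf=rf)
    m = build_from_msa(msa).map_to_column
    assert len(m) == 50
    assert fm.estimate_fragment_length(msa, m, _hit("f", 1, 10), _hit("f", 41, 50)) == 53


def test_fragment_length_overlapping_hits_use_outer_coordinates():
    msa = SeedAlignment("f", [("a", "A" * 50)], 50)
    m = np.arange(1, 51)
    assert fm.estimate_fragment_length(msa, m, _hit("f", 5, 30), _hit("f", 10, 20)) == 26


def test_fragment_length_mismatched_families_rejected():
    msa = SeedAlignment("f", [("a", "A" * 50)], 50)
    with pytest.raises(ValueError):
        fm.estimate_fragment_length(msa, np.arange(1, 51), _hit("f", 1, 5), _hit("g", 6, 9))


def test_fragment_length_no_anchoring_seed_is_an_error():
    msa = SeedAlignment("f", [("a", "--AAA")], 5)
    m = np.arange(1, 6)
    with pytest.raises(ValueError, match="anchors"):
        fm.estimate_fragment_length(msa, m, _hit("f", 1, 2), _hit("f", 1, 2))


# ---------------------------------------------------------------------------
# distribution building
# ---------------------------------------------------------------------------

def test_point_mass_without_smoothing():
    d = fm.build_distribution([100] * 10, smoothing=0.0)
    assert d.prob(100) == pytest.approx(1.0)
    assert (d.support_min, d.support_max) == (100, 100)


def test_two_point_distribution_matches_histogram_oracle():
    d0 = fm.build_distribution([100, 200], smoothing=0.0)
    assert d0.prob(100) == pytest.approx(0.5)
    assert d0.prob(150) == 0.0
    d1 = fm.build_distribution([100, 200], smoothing=1.0)
    oracle = histogram_probs([100, 200], smoothing=1.0)
    for length, p in oracle.items():
        assert d1.prob(length) == pytest.approx(p, abs=1e-12)
    assert d1.prob(150) == pytest.approx((1 / 101) / 3, abs=1e-12)
    assert d1.prob(150) > 0


def test_distribution_normalises_and_floors():
    rng = np.random.default_rng(2)
    lengths = rng.integers(80, 120, size=500).tolist()
    d = fm.build_distribution(lengths, smoothing=1.0)
    total = sum(d.probs.values())
    assert total == pytest.approx(1.0, abs=1e-9)
    assert d.prob(10_000) == d.floor > 0


def test_clip_range_drops_outliers():
    d = fm.build_distribution([50, 100, 101, 999], smoothing=0.0, clip_range=(60, 200))
    assert (d.support_min, d.support_max) == (100, 101)
    assert d.n_observations == 2


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        fm.build_distribution([], smoothing=1.0)


# ---------------------------------------------------------------------------
# unique-pair collection
# ---------------------------------------------------------------------------

def test_collect_unique_pairs_rules():
    table = {
        "both_unique_same": {1: [_hit("F1", 1, 5)], 2: [_hit("F1", 6, 9)]},
        "end1_multi": {1: [_hit("F1", 1, 5), _hit("F2", 1, 5)], 2: [_hit("F1", 6, 9)]},
        "different_family": {1: [_hit("F1", 1, 5)], 2: [_hit("F2", 6, 9)]},
        "one_end_only": {1: [_hit("F1", 1, 5)], 2: []},
    }
    got = fm.collect_unique_pairs(table)
    assert len(got) == 1
    assert got[0][0].family_id == "F1"


def test_collect_unique_pairs_matches_direct_filter_on_random_tables():
    rng = np.random.default_rng(23)
    fams = ["F1", "F2", "F3"]
    table = {}
    for i in range(300):
        ends = {}
        for e in (1, 2):
            k = int(rng.integers(0, 3))
            ends[e] = [_hit(f, 1, 5, rid=f"r{i}", end=e)
                       for f in rng.choice(fams, size=k, replace=False)]
        table[f"r{i}"] = ends
    expected = {
        rid for rid, ends in table.items()
        if len(ends[1]) == 1 and len(ends[2]) == 1
        and ends[1][0].family_id == ends[2][0].family_id
    }
    got = {h1.read_id for h1, _ in fm.collect_unique_pairs(table)}
    assert got == expected
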