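import math

import numpy as np
import pytest
from scipy import stats

from oracles import count_emissions, enumerate_viterbi_score, random_peptide, random_toy_hmm
from shortpair.io_formats import SeedAlignment
from shortpair.profile_hmm import (
    build_from_msa,
    calibrate_gumbel,
    evalue,
    fit_gumbel,
    viterbi_align,
    viterbi_score,
)
from shortpair.simulate import SimScenario, simulate_family


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def test_ungapped_columns_all_match():
    msa = SeedAlignment("f", [("a", "ACDEF"), ("b", "ACDEF")], 5)
    hmm = build_from_msa(msa)
    assert hmm.L == 5
    np.testing.assert_array_equal(hmm.map_to_column, [1, 2, 3, 4, 5])


def test_half_gap_column_is_insert():
    # gap fraction at column 3 is exactly 0.5, which is not < 0.5
    msa = SeedAlignment("f", [("a", "AC-EF"), ("b", "ACDEF")], 5)
    hmm = build_from_msa(msa)
    assert hmm.L == 4
    np.testing.assert_array_equal(hmm.map_to_column, [1, 2, 4, 5])


def test_rf_annotation_overrides_gap_rule():
    msa = SeedAlignment("f", [("a", "AC-EF"), ("b", "ACDEF")], 5, rf="xx.xx")
    assert build_from_msa(msa).L == 4
    msa2 = SeedAlignment("f", [("a", "AC-EF"), ("b", "ACDEF")], 5, rf="xxxxx")
    assert build_from_msa(msa2).L == 5


def test_match_emissions_against_counting_oracle():
    rows = ["ACDEF", "ACDEF", "AADEF", "ACDEC"]
    msa = SeedAlignment("f", [(f"s{i}", r) for i, r in enumerate(rows)], 5)
    hmm = build_from_msa(msa)
    for col in range(5):
        np.testing.assert_allclose(
            hmm.match_emissions[col],
            count_emissions(rows, col, hmm.background),
            atol=1e-12,
        )


def test_exclusion_and_empty_errors():
    msa = SeedAlignment("f", [("a", "ACDEF"), ("b", "ACDEF")], 5)
    hmm = build_from_msa(msa, exclude_ids={"a"})
    assert hmm.L == 5
    with pytest.raises(ValueError, match="excluded"):
        build_from_msa(msa, exclude_ids={"a", "b"})


def test_simulated_alignments_build_normalised_models():
    rng = np.random.default_rng(9)
    for seed in range(5):
        msa, _, _ = simulate_family(
            SimScenario(family_length=60, indel_rate=0.1, fragment_mean=40,
                        fragment_sd=5, fragment_min=26, fragment_max=55, rng_seed=seed), "F", rng)
        hmm = build_from_msa(msa)  # validate() runs in the constructor
        assert hmm.L >= 1
        assert np.all(np.diff(hmm.map_to_column) > 0)


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def test_consensus_self_alignment(tiny_hmm):
    hit = viterbi_align(tiny_hmm, "ACDEFGHIK")
    assert hit is not None
    assert (hit.model_start, hit.model_end) == (1, 9)
    assert (hit.seq_start, hit.seq_end) == (1, 9)
    assert hit.score > 0


def test_stop_codon_never_aligns(tiny_hmm):
    assert viterbi_align(tiny_hmm, "*") is None


def test_stop_truncates_alignment(tiny_hmm):
    hit = viterbi_align(tiny_hmm, "ACDE*GHIK")
    assert hit is not None
    span = hit.seq_end - hit.seq_start + 1
    assert span <= 4  # cannot cross position 5


def test_two_state_toys_match_enumeration_exactly():
    rng = np.random.default_rng(5)
    for _ in range(100):
        hmm = random_toy_hmm(rng, L=2)
        pep = random_peptide(rng, int(rng.integers(1, 4)))
        assert viterbi_score(hmm, pep) == enumerate_viterbi_score(hmm, pep)


def test_flanking_residues_outside_window_do_not_change_score(tiny_hmm):
    base = viterbi_score(tiny_hmm, "ACDEFGHIK")
    # tryptophan never appears in the seeds, so flanks only add
    # negative-scoring options the local alignment is free to skip
    assert viterbi_score(tiny_hmm, "WWACDEFGHIKWW") == pytest.approx(base, abs=1e-12)


def test_traceback_coordinates_cover_local_window(tiny_hmm):
    hit = viterbi_align(tiny_hmm, "WWWCDEFGHWWW")
    assert hit is not None
    assert hit.seq_start >= 4 and hit.seq_end <= 9
    assert hit.model_start >= 2 and hit.model_end <= 8


# ---------------------------------------------------------------------------
# E-values and calibration
# ---------------------------------------------------------------------------

def test_evalue_closed_form(tiny_hmm):
    tiny_hmm.gumbel_mu, tiny_hmm.gumbel_lambda = 5.0, 0.7
    assert evalue(tiny_hmm, 5.0, 1000) == pytest.approx(1000.0)
    assert evalue(tiny_hmm, 15.0, 1000) == pytest.approx(1000 * math.exp(-7.0), rel=1e-12)
    assert evalue(tiny_hmm, 1e6, 1000) == pytest.approx(0.0, abs=1e-250)


def test_evalue_monotone_in_score_and_linear_in_size(tiny_hmm):
    tiny_hmm.gumbel_mu, tiny_hmm.gumbel_lambda = 2.0, 0.6
    scores = np.linspace(3, 40, 50)
    es = [evalue(tiny_hmm, s, 500) for s in scores]
    assert all(a > b for a, b in zip(es, es[1:]))
    assert evalue(tiny_hmm, 30, 2000) == pytest.approx(4 * evalue(tiny_hmm, 30, 500))


def test_evalue_requires_gumbel_parameters(tiny_hmm):
    tiny_hmm.gumbel_mu = tiny_hmm.gumbel_lambda = None
    with pytest.raises(ValueError, match="calibrate"):
        evalue(tiny_hmm, 10, 100)


def test_gumbel_fit_recovers_known_parameters():
    rng = np.random.default_rng(13)
    scores = stats.gumbel_r.rvs(loc=4.0, scale=1 / 0.67, size=5000, random_state=rng)
    mu, lam = fit_gumbel(scores)
    assert mu == pytest.approx(4.0, abs=0.2)
    assert lam == pytest.approx(0.67, abs=0.05)


def test_calibration_determinism_and_precondition(tiny_hmm):
    a = calibrate_gumbel(tiny_hmm, n_random=200, seed=3, peptide_length=9)
    b = calibrate_gumbel(tiny_hmm, n_random=200, seed=3, peptide_length=9)
    assert a == b
    with pytest.raises(ValueError, match="200"):
        calibrate_gumbel(tiny_hmm, n_random=100, seed=3)
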