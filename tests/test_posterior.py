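import math

import numpy as np
import pytest

from oracles import plain_posteriors
from shortpair.fragment_model import FragmentLengthDistribution
from shortpair.posterior import (
    DEFAULT_T,
    CandidatePair,
    ScoringConfig,
    filter_by_tau,
    score_candidates,
)
from shortpair.profile_hmm import DomainHit


def _dist(probs):
    return FragmentLengthDistribution.from_probs(probs)


def _cand(fam, s1, s2, flen, rid="r"):
    h1 = DomainHit(rid, 1, 1, fam, 1, 10, 1, 10, s1)
    h2 = DomainHit(rid, 2, 1, fam, 20, 30, 1, 11, s2)
    return CandidatePair(rid, fam, h1, h2, flen)


def test_singleton_posterior_is_one():
    c = [_cand("F1", 12.0, 8.0, 100)]
    score_candidates(c, _dist({100: 1.0}))
    assert c[0].posterior == pytest.approx(1.0)


def test_equal_scores_fragment_probability_ratio():
    # scores cancel; posteriors follow Pr(f) 0.2 : 0.1 -> 2/3 : 1/3
    c = [_cand("F1", 10.0, 10.0, 100), _cand("F2", 10.0, 10.0, 150)]
    score_candidates(c, _dist({100: 0.2, 150: 0.1}))
    assert c[0].posterior == pytest.approx(2 / 3, abs=1e-12)
    assert c[1].posterior == pytest.approx(1 / 3, abs=1e-12)


def test_one_bit_gap_doubles_the_odds():
    # at T = 1/ln2, exp(ds/T) = 2**ds, so a 1-bit gap gives a 2:1 ratio
    c = [_cand("F1", 11.0, 10.0, 100), _cand("F2", 10.0, 10.0, 100)]
    score_candidates(c, _dist({100: 0.3}), ScoringConfig(T=DEFAULT_T))
    assert c[0].posterior / c[1].posterior == pytest.approx(2.0, abs=1e-9)


def test_posteriors_match_plain_arithmetic_oracle():
    rng = np.random.default_rng(31)
    for _ in range(200):
        n = int(rng.integers(1, 6))
        scores = [(float(rng.uniform(-30, 30)), float(rng.uniform(-30, 30)))
                  for _ in range(n)]
        pf = rng.uniform(0.01, 0.2, size=n)
        flens = list(range(100, 100 + n))
        dist = _dist({f: p for f, p in zip(flens, pf)})
        cands = [_cand(f"F{i}", s1, s2, f)
                 for i, ((s1, s2), f) in enumerate(zip(scores, flens))]
        T = float(rng.uniform(0.5, 3.0))
        score_candidates(cands, dist, ScoringConfig(T=T))
        expect = plain_posteriors(scores, list(pf), T)
        got = [c.posterior for c in cands]
        np.testing.assert_allclose(got, expect, atol=1e-9)
        assert sum(got) == pytest.approx(1.0, abs=1e-9)


def test_posterior_monotone_in_score_and_fragment_probability():
    base = [_cand("F1", 10.0, 10.0, 100), _cand("F2", 12.0, 9.0, 150)]
    score_candidates(base, _dist({100: 0.1, 150: 0.1}))
    p0 = base[0].posterior
    up_score = [_cand("F1", 13.0, 10.0, 100), _cand("F2", 12.0, 9.0, 150)]
    score_candidates(up_score, _dist({100: 0.1, 150: 0.1}))
    assert up_score[0].posterior > p0
    up_pf = [_cand("F1", 10.0, 10.0, 100), _cand("F2", 12.0, 9.0, 150)]
    score_candidates(up_pf, _dist({100: 0.3, 150: 0.1}))
    assert up_pf[0].posterior > p0


def test_posterior_invariant_under_fragment_probability_scaling():
    c1 = [_cand("F1", 10.0, 5.0, 100), _cand("F2", 8.0, 9.0, 150)]
    c2 = [_cand("F1", 10.0, 5.0, 100), _cand("F2", 8.0, 9.0, 150)]
    score_candidates(c1, _dist({100: 0.2, 150: 0.05}))
    score_candidates(c2, _dist({100: 0.02, 150: 0.005}))
    for a, b in zip(c1, c2):
        assert a.posterior == pytest.approx(b.posterior, abs=1e-12)


def test_huge_scores_do_not_overflow():
    c = [_cand("F1", 5000.0, 4000.0, 100), _cand("F2", 4999.0, 4000.0, 100)]
    score_candidates(c, _dist({100: 0.5}))
    assert c[0].posterior == pytest.approx(2 / 3, abs=1e-9)


def test_empty_candidate_set_rejected():
    with pytest.raises(ValueError):
        score_candidates([], _dist({100: 1.0}))
    with pytest.raises(ValueError):
        filter_by_tau([], 0.4)


# ---------------------------------------------------------------------------
# tau retention
# ---------------------------------------------------------------------------

def _scored(posteriors):
    cands = [_cand(f"F{i}", 10.0, 10.0, 100) for i in range(len(posteriors))]
    for c, p in zip(cands, posteriors):
        c.posterior = p
    return cands


def test_tau_rule_worked_example():
    kept = filter_by_tau(_scored([0.6, 0.3, 0.1]), tau=0.4)
    assert [c.posterior for c in kept] == [0.6, 0.3]


def test_tau_one_keeps_only_the_maximum():
    kept = filter_by_tau(_scored([0.5, 0.3, 0.2]), tau=1.0)
    assert [c.posterior for c in kept] == [0.5]


def test_tau_monotone_and_argmax_always_kept():
    rng = np.random.default_rng(41)
    for _ in range(50):
        raw = rng.dirichlet(np.ones(int(rng.integers(1, 8))))
        cands = _scored(list(raw))
        prev = None
        for tau in (0.1, 0.4, 0.7, 1.0):
            kept = {c.family_id for c in filter_by_tau(cands, tau)}
            assert any(c.family_id in kept for c in cands
                       if c.posterior == max(raw))
            if prev is not None:
                assert kept <= prev
            prev = kept


def test_default_tau_is_forty_percent():
    assert ScoringConfig().tau == 0.40
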