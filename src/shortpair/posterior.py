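"""Posterior ranking of candidate family assignments for a read pair.

For a read pair (r1, r2) with candidate alignments a1, a2 to the same
family, the posterior of the assignment is proportional to

    exp(s_a1 / T) * exp(s_a2 / T) * Pr(f)

where s are the alignment bit scores, f the fragment length implied by
the two alignments, and T a scaling factor.  With the default
T = 1/ln 2 the exponential of a bit score is exactly 2**s, i.e. the
model-versus-null odds of the alignment, so the posterior combines the
two ends' odds with the fragment-length likelihood.  Normalisation runs
over all candidate families of the read pair, making posteriors
comparable across families; weights are accumulated in log space.

A retention rule then keeps every candidate whose posterior is at least
p_max * tau, where p_max is the pair's best posterior and tau defaults
to 0.40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .fragment_model import FragmentLengthDistribution
from .profile_hmm import DomainHit

DEFAULT_T = 1.0 / math.log(2.0)
DEFAULT_TAU = 0.40


@dataclass(slots=True)
class ScoringConfig:
    T: float = DEFAULT_T
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("scaling factor T must be positive")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must lie in (0, 1]")


@dataclass(slots=True)
class CandidatePair:
    """A (hit1, hit2, family) triple with its fragment length and, after
    scoring, its posterior probability within the read pair."""

    read_id: str
    family_id: str
    hit1: DomainHit
    hit2: DomainHit
    fragment_length: int
    posterior: float = math.nan

    def __post_init__(self) -> None:
        if self.hit1.family_id != self.family_id or self.hit2.family_id != self.family_id:
            raise ValueError("both hits must belong to the candidate's family")


def score_candidates(candidates: list[CandidatePair],
                     dist: FragmentLengthDistribution,
                     cfg: ScoringConfig | None = None) -> list[CandidatePair]:
    """Assign posteriors to one read pair's candidate set (in place).

    Log weights ``s1/T + s2/T + ln Pr(f)`` are normalised with
    log-sum-exp, so arbitrarily large bit scores cannot overflow and
    the result is independent of candidate order.
    """
    cfg = cfg or ScoringConfig()
    if not candidates:
        raise ValueError("empty candidate set")
    logw = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        pf = dist.prob(c.fragment_length)
        logw[i] = (c.hit1.score + c.hit2.score) / cfg.T + \
            (math.log(pf) if pf > 0 else -math.inf)
    total = logsumexp(logw)
    if not np.isfinite(total):
        raise ValueError(
            "all candidate weights vanished; build the fragment distribution "
            "with positive smoothing so Pr(f) has a floor")
    post = np.exp(logw - total)
    for c, p in zip(candidates, post):
        c.posterior = float(p)
    return candidates


def filter_by_tau(candidates: list[CandidatePair], tau: float = DEFAULT_TAU
                  ) -> list[CandidatePair]:
    """Keep candidates with posterior >= p_max * tau (the argmax always
    survives), sorted by posterior descending with deterministic
    tie-breaking on (family id, model start)."""
    if not candidates:
        raise ValueError("empty candidate set")
    if not (0 < tau <= 1):
        raise ValueError("tau must lie in (0, 1]")
    p_max = max(c.posterior for c in candidates)
    kept = [c for c in candidates if c.posterior >= p_max * tau]
    kept.sort(key=lambda c: (-c.posterior, c.family_id, c.hit1.model_start))
    return kept
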