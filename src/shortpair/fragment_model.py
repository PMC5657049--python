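"""Reference-free fragment-length distribution estimation.

Paired-end reads are sequenced from the two ends of one DNA fragment,
so the distance between the two mates' alignments carries the fragment
length.  Without a reference genome that distance cannot be read off a
mapping; instead, each mate's span over the profile's match states is
converted — through the seed multiple alignment — into positions along
every seed sequence, and the fragment length is taken as the average
outer span over the seeds (it is unknown which seed is closest to the
unobserved source gene).  Pooling these estimates over all read pairs
that align uniquely to a single family yields a global distribution
over fragment lengths, measured in amino acids throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import GAP_CHARS, SeedAlignment
from .profile_hmm import DomainHit


@dataclass(slots=True)
class FragmentLengthDistribution:
    """Smoothed probability over integer fragment lengths (amino acids).

    ``floor`` is the probability assigned to any length outside the
    observed support (and, with smoothing on, the mass every empty bin
    inside the support received); it is never zero when the
    distribution was built with positive smoothing, so downstream
    posterior weights cannot vanish on an unseen length.
    """

    probs: dict[int, float]
    support_min: int
    support_max: int
    floor: float
    n_observations: int

    def prob(self, length: int) -> float:
        if length < self.support_min or length > self.support_max:
            return self.floor
        return self.probs.get(length, self.floor)

    @classmethod
    def from_probs(cls, probs: dict[int, float]) -> "FragmentLengthDistribution":
        smin, smax = min(probs), max(probs)
        positive = [p for p in probs.values() if p > 0]
        floor = min(positive) if positive else 0.0
        return cls(dict(probs), smin, smax, floor, n_observations=0)


def model_span_to_seed_span(msa: SeedAlignment, map_to_column: np.ndarray,
                            seed_row: int, model_start: int, model_end: int
                            ) -> tuple[int, int] | None:
    """Convert a match-state span into 1-based positions on one seed.

    The span's terminal match states are mapped to their MSA columns;
    each column maps to the count of non-gap characters in the row up
    to and including it.  When the row has a gap at both terminal
    columns no residue anchors the span and ``None`` is returned.
    """
    if not (0 <= seed_row < len(msa.rows)):
        raise IndexError(f"seed row {seed_row} out of range")
    L = len(map_to_column)
    if not (1 <= model_start <= model_end <= L):
        raise ValueError("model span out of range")
    c1 = int(map_to_column[model_start - 1])
    c2 = int(map_to_column[model_end - 1])
    row = msa.rows[seed_row][1]
    if row[c1 - 1] in GAP_CHARS and row[c2 - 1] in GAP_CHARS:
        return None
    start = sum(1 for ch in row[:c1] if ch not in GAP_CHARS)
    end = sum(1 for ch in row[:c2] if ch not in GAP_CHARS)
    # a gap at the start column with no residue before it anchors at the
    # first residue of the row
    start = max(start, 1)
    return start, end


def estimate_fragment_length(msa: SeedAlignment, map_to_column: np.ndarray,
                             hit1: DomainHit, hit2: DomainHit) -> int:
    """Fragment length in amino acids from a pair of same-family hits.

    For every seed the outer span (min converted start to max converted
    end over the two hits) is measured; the fragment length is the mean
    of the per-seed span lengths, rounded half away from zero to the
    nearest integer.
    """
    if hit1.family_id != hit2.family_id:
        raise ValueError("hits must be on the same family model")
    distances = []
    for r in range(len(msa.rows)):
        s1 = model_span_to_seed_span(msa, map_to_column, r, hit1.model_start, hit1.model_end)
        s2 = model_span_to_seed_span(msa, map_to_column, r, hit2.model_start, hit2.model_end)
        if s1 is None or s2 is None:
            continue
        start = min(s1[0], s2[0])
        end = max(s1[1], s2[1])
        distances.append(end - start + 1)
    if not distances:
        raise ValueError(
            f"pair {hit1.read_id!r}: no seed sequence anchors both alignments")
    return int(math.floor(sum(distances) / len(distances) + 0.5))


def build_distribution(lengths, smoothing: float = 1.0,
                       clip_range: tuple[int, int] | None = None
                       ) -> FragmentLengthDistribution:
    """Histogram the pooled fragment lengths at 1-aa resolution.

    Each bin over [min, max] of the surviving inputs receives
    ``smoothing / n_bins`` pseudo-mass before renormalisation, so every
    length inside the support (and, via ``floor``, outside it) has
    positive probability whenever ``smoothing > 0``.  Lengths outside
    ``clip_range`` are dropped first as estimation outliers.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    lengths = [int(x) for x in lengths]
    if clip_range is not None:
        lo, hi = clip_range
        lengths = [x for x in lengths if lo <= x <= hi]
    if not lengths:
        raise ValueError("no fragment lengths to build a distribution from")
    smin, smax = min(lengths), max(lengths)
    n_bins = smax - smin + 1
    counts = np.zeros(n_bins)
    for x in lengths:
        counts[x - smin] += 1.0
    counts += smoothing / n_bins
    total = counts.sum()
    probs = {smin + i: counts[i] / total for i in range(n_bins)}
    floor = (smoothing / n_bins) / total
    return FragmentLengthDistribution(
        probs=probs, support_min=smin, support_max=smax,
        floor=float(floor), n_observations=len(lengths),
    )


def collect_unique_pairs(hits_by_pair: dict[str, dict[int, list[DomainHit]]]
                         ) -> list[tuple[DomainHit, DomainHit]]:
    """Select read pairs where both ends align to exactly one family and
    it is the same family; these anchor the length distribution.

    ``hits_by_pair`` maps read id -> {1: hits, 2: hits} (one hit per
    family per end, as produced by the step-1 scan).
    """
    out = []
    for rid in hits_by_pair:
        ends = hits_by_pair[rid]
        h1, h2 = ends.get(1, []), ends.get(2, [])
        fams1 = {h.family_id for h in h1}
        fams2 = {h.family_id for h in h2}
        if len(fams1) == 1 and len(fams2) == 1 and fams1 == fams2:
            out.append((h1[0], h2[0]))
    return out
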