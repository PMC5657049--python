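"""Independent reference implementations used as test oracles.

Each function here re-derives a quantity by a route deliberately
different from the package's own (exhaustive enumeration, plain
arithmetic, direct counting), so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math

import numpy as np

from shortpair.io_formats import AMINO_ALPHABET
from shortpair.profile_hmm import ProfileHMM, encode_peptide, _emission_rows


# ---------------------------------------------------------------------------
# exhaustive Viterbi oracle
# ---------------------------------------------------------------------------

def enumerate_viterbi_score(hmm: ProfileHMM, peptide: str) -> float:
    """Best local alignment score by exhaustive enumeration of every
    legal state path (entry at any match state, exit at any match
    state).  Shares the model's log-odds tables with the aligner but
    explores paths by brute-force recursion instead of dynamic
    programming; additions follow the same left-to-right order so the
    comparison is float-exact.
    """
    lodds_m, lodds_i, ltr, entry = hmm._tables()
    codes = encode_peptide(peptide)
    mesc = _emission_rows(lodds_m, codes)
    iesc = _emission_rows(lodds_i, codes)
    n, L = mesc.shape
    best = [-math.inf]

    def step(state: str, i: int, k: int, acc: float) -> None:
        # state M/I at node k (0-based) just emitted residue i; D at node k
        if state == "M":
            if acc > best[0]:
                best[0] = acc
            if i + 1 < n and k + 1 < L:
                step("M", i + 1, k + 1, (acc + ltr[k, 0]) + mesc[i + 1, k + 1])
            if i + 1 < n and k < L - 1:
                step("I", i + 1, k, (acc + ltr[k, 1]) + iesc[i + 1, k])
            if k + 1 < L:
                step("D", i, k + 1, acc + ltr[k, 2])
        elif state == "I":
            if i + 1 < n and k + 1 < L:
                step("M", i + 1, k + 1, (acc + ltr[k, 3]) + mesc[i + 1, k + 1])
            if i + 1 < n:
                step("I", i + 1, k, (acc + ltr[k, 4]) + iesc[i + 1, k])
        else:  # D
            if i + 1 < n and k + 1 < L:
                step("M", i + 1, k + 1, (acc + ltr[k, 5]) + mesc[i + 1, k + 1])
            if k + 1 < L:
                step("D", i, k + 1, acc + ltr[k, 6])

    for i0 in range(n):
        for k0 in range(L):
            step("M", i0, k0, entry + mesc[i0, k0])
    return best[0]


def random_toy_hmm(rng: np.random.Generator, L: int) -> ProfileHMM:
    """A valid random profile with Dirichlet emissions and transitions."""
    match = rng.dirichlet(np.ones(20), size=L)
    bg = np.full(20, 1.0 / 20.0)
    insert = np.tile(bg, (L, 1))
    trans = np.zeros((L, 7))
    trans[:, 0:3] = rng.dirichlet(np.ones(3), size=L)
    trans[:, 3:5] = rng.dirichlet(np.ones(2), size=L)
    trans[:, 5:7] = rng.dirichlet(np.ones(2), size=L)
    trans[L - 1] = [1, 0, 0, 1, 0, 1, 0]
    return ProfileHMM(
        family_id="toy", L=L, match_emissions=match, insert_emissions=insert,
        transitions=trans, background=bg,
        map_to_column=np.arange(1, L + 1),
    )


def random_peptide(rng: np.random.Generator, length: int, alphabet: str = "ACDE") -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


# ---------------------------------------------------------------------------
# plain-arithmetic posterior oracle
# ---------------------------------------------------------------------------

def plain_posteriors(scores: list[tuple[float, float]], fragment_probs: list[float],
                     T: float) -> list[float]:
    """Posteriors by direct (non-log) evaluation of
    exp(s1/T) * exp(s2/T) * Pr(f), normalised over the candidate set."""
    ws = [math.exp(s1 / T) * math.exp(s2 / T) * pf
          for (s1, s2), pf in zip(scores, fragment_probs)]
    total = sum(ws)
    return [w / total for w in ws]


# ---------------------------------------------------------------------------
# counting / averaging oracles
# ---------------------------------------------------------------------------

def count_emissions(rows: list[str], column: int, background: np.ndarray) -> np.ndarray:
    """Match-emission estimate for one MSA column by direct counting
    plus one unit of background-distributed pseudocount."""
    counts = np.array(background, dtype=float)
    n = 0.0
    for row in rows:
        ch = row[column]
        if ch in "-.":
            continue
        counts[AMINO_ALPHABET.index(ch.upper())] += 1.0
        n += 1.0
    return counts / (n + 1.0)


def loop_average_metrics(truth: dict[str, set[str]], preds: dict[str, set[str]],
                         universe: set[str]):
    """Per-pair metric means by an explicit loop over pairs."""
    rows = []
    for rid, tp in truth.items():
        if not tp:
            continue
        c = preds.get(rid, set())
        sens = len(tp & c) / len(tp)
        fpr = len(c - tp) / len(universe - tp)
        ppv = len(tp & c) / len(c) if c else 0.0
        f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else 0.0
        rows.append((sens, fpr, f, ppv))
    arr = np.array(rows)
    return arr.mean(axis=0)


def histogram_probs(lengths: list[int], smoothing: float) -> dict[int, float]:
    """Fragment-length histogram with uniform pseudo-mass, coded from
    the definition."""
    lo, hi = min(lengths), max(lengths)
    bins = {x: 0.0 for x in range(lo, hi + 1)}
    for x in lengths:
        bins[x] += 1.0
    k = len(bins)
    total = len(lengths) + smoothing
    return {x: (c + smoothing / k) / total for x, c in bins.items()}
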