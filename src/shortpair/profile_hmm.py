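"""Profile HMM construction, local Viterbi alignment, and E-values.

This is a deliberately small Plan7-like aligner: match/insert/delete
states per consensus column, Smith-Waterman-style local entry/exit over
match states, and log-odds scoring in bits against an i.i.d. background
model.  It stands in for both a default profile scan and a
maximum-sensitivity rescan (no heuristic filters are implemented: every
alignment is scored by full Viterbi), and external scans can be
substituted at file level through :mod:`shortpair.io_formats`.

Model structure
---------------
* Entry: begin -> M_k with uniform probability 1/L for every match state.
* Exit: any M_k may end the alignment at no cost (the score is that of
  the best-scoring local segment, as in Smith-Waterman).
* Core transitions per node: {M->M, M->I, M->D}, {I->M, I->I},
  {D->M, D->D}, each bundle a probability distribution.
* Insert states emit the background distribution, so insertions cost
  only their transitions.

Scores are log2 likelihood ratios (bits) of the Viterbi path versus a
null emitting every residue from the background.  A peptide whose best
local score is not positive produces no hit.  Stop codons ``'*'`` have
zero emission probability everywhere; ``'X'`` and other ambiguity codes
emit the background (log-odds zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .io_formats import AA_INDEX, AMINO_ALPHABET, GAP_CHARS, SeedAlignment, TRANS_ORDER

NEG_INF = -np.inf

# peptide encoding: 0..19 residues, 20 = background wildcard, 21 = stop
_X_CODE = 20
_STOP_CODE = 21


@dataclass
class ProfileHMM:
    """A profile hidden Markov model over the 20 standard amino acids.

    ``transitions`` has one row per node in :data:`TRANS_ORDER` order
    (MM, MI, MD, IM, II, DM, DD); the last row encodes the forced exit
    (M_L -> end) as MM = 1 with MD = DD = 0.  ``map_to_column`` records
    each match state's 1-based column in the source MSA.
    """

    family_id: str
    L: int
    match_emissions: np.ndarray   # (L, 20)
    insert_emissions: np.ndarray  # (L, 20)
    transitions: np.ndarray       # (L, 7)
    background: np.ndarray        # (20,)
    map_to_column: np.ndarray     # (L,), 1-based, strictly increasing
    gumbel_mu: float | None = None      # bits
    gumbel_lambda: float | None = None  # 1/bits
    background_from_compo: bool = False
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("model must have at least one match state")
        self.match_emissions = np.asarray(self.match_emissions, dtype=np.float64)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        self.map_to_column = np.asarray(self.map_to_column, dtype=np.int64)
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        if self.match_emissions.shape != (self.L, 20):
            raise ValueError("match emission table must be L x 20")
        for name, table in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            sums = table.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValueError(f"{name} emission rows must sum to 1")
            if np.any(table < 0):
                raise ValueError(f"negative {name} emission probability")
        for sl, label in ((slice(0, 3), "M"), (slice(3, 5), "I"), (slice(5, 7), "D")):
            sums = self.transitions[:, sl].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValueError(f"{label} transition bundle must sum to 1")
        if np.any(np.diff(self.map_to_column) <= 0):
            raise ValueError("map_to_column must be strictly increasing")

    # -- cached scoring tables ------------------------------------------------

    def _tables(self):
        tabs = self._cache.get("tables")
        if tabs is None:
            with np.errstate(divide="ignore"):
                lodds_m = np.log2(self.match_emissions / self.background)
                lodds_i = np.log2(self.insert_emissions / self.background)
                ltr = np.log2(self.transitions)
            entry = math.log2(1.0 / self.L)
            tabs = (np.ascontiguousarray(lodds_m), np.ascontiguousarray(lodds_i),
                    np.ascontiguousarray(ltr), entry)
            self._cache["tables"] = tabs
        return tabs


@dataclass(slots=True)
class DomainHit:
    """One read end's local alignment to one family.

    Coordinates are 1-based inclusive: ``model_start..model_end`` over
    match states, ``seq_start..seq_end`` over the framed peptide.
    """

    read_id: str
    end: int
    frame: int
    family_id: str
    model_start: int
    model_end: int
    seq_start: int
    seq_end: int
    score: float
    evalue: float = math.nan
    provenance: str = "step1"

    def __post_init__(self) -> None:
        if not (1 <= self.model_start <= self.model_end):
            raise ValueError("model coordinates must satisfy 1 <= start <= end")
        if self.seq_start > self.seq_end:
            raise ValueError("peptide coordinates must satisfy start <= end")
        if not math.isfinite(self.score):
            raise ValueError("bit score must be finite")


# ---------------------------------------------------------------------------
# model estimation from a seed alignment
# ---------------------------------------------------------------------------

def match_columns(msa: SeedAlignment) -> list[int]:
    """0-based indices of match columns.

    Columns flagged in the ``#=GC RF`` annotation win when present;
    otherwise a column is a match column iff its gap fraction is
    strictly below 0.5.
    """
    if msa.rf is not None:
        return [c for c in range(msa.n_columns) if msa.rf[c] not in ".-~"]
    n = len(msa.rows)
    cols = []
    for c in range(msa.n_columns):
        gaps = sum(1 for _, row in msa.rows if row[c] in GAP_CHARS)
        if gaps / n < 0.5:
            cols.append(c)
    return cols


def build_from_msa(msa: SeedAlignment, exclude_ids: set[str] | None = None,
                   background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a ProfileHMM from a seed alignment.

    Emissions are residue counts plus one unit of pseudocount mass
    distributed as the background; transitions are counted from each
    row's implied match/insert/delete state path plus pseudocount 1 per
    transition type.  Rows named in ``exclude_ids`` are dropped first
    (this supports holding held-out member genes out of training).
    """
    rows = [(sid, aligned) for sid, aligned in msa.rows
            if not exclude_ids or sid not in exclude_ids]
    if not rows:
        raise ValueError(f"family {msa.family_id!r}: all rows excluded")
    sub = SeedAlignment(msa.family_id, rows, msa.n_columns, msa.rf)
    cols = match_columns(sub)
    if not cols:
        raise ValueError(f"family {msa.family_id!r}: zero match columns")
    L = len(cols)
    if background is None:
        background = np.full(20, 1.0 / 20.0)

    is_match = np.zeros(msa.n_columns, dtype=bool)
    node_of_col = np.full(msa.n_columns, -1)
    for k, c in enumerate(cols):
        is_match[c] = True
        node_of_col[c] = k

    counts = np.zeros((L, 20))
    # transition counts per node, TRANS_ORDER layout
    tcounts = np.zeros((L, 7))
    t_index = {("M", "M"): 0, ("M", "I"): 1, ("M", "D"): 2,
               ("I", "M"): 3, ("I", "I"): 4, ("D", "M"): 5, ("D", "D"): 6}

    for _, aligned in rows:
        path: list[tuple[str, int]] = []  # (state, node) with node 0-based
        for c, ch in enumerate(aligned):
            gap = ch in GAP_CHARS
            if is_match[c]:
                k = node_of_col[c]
                if gap:
                    path.append(("D", k))
                else:
                    path.append(("M", k))
                    idx = AA_INDEX.get(ch.upper())
                    if idx is not None:
                        counts[k, idx] += 1.0
            elif not gap:
                # insert column residue: belongs to the insert state of the
                # most recent match node (flanking inserts are ignored)
                if path:
                    path.append(("I", path[-1][1]))
        # trim flanking deletes: local model enters/exits at match states
        while path and path[0][0] != "M":
            path.pop(0)
        while path and path[-1][0] != "M":
            path.pop()
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            idx = t_index.get((s1, s2))
            if idx is not None:  # D->I / I->D adjacencies are not modelled
                tcounts[k1, idx] += 1.0

    match_em = (counts + background) / (counts.sum(axis=1) + 1.0)[:, None]
    insert_em = np.tile(background, (L, 1))

    trans = np.zeros((L, 7))
    for sl in (slice(0, 3), slice(3, 5), slice(5, 7)):
        block = tcounts[:, sl] + 1.0
        trans[:, sl] = block / block.sum(axis=1, keepdims=True)
    trans[L - 1] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]  # forced exit at node L

    return ProfileHMM(
        family_id=msa.family_id, L=L,
        match_emissions=match_em, insert_emissions=insert_em,
        transitions=trans, background=background,
        map_to_column=np.array([c + 1 for c in cols], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def encode_peptide(peptide: str) -> np.ndarray:
    codes = np.empty(len(peptide), dtype=np.int64)
    for i, ch in enumerate(peptide):
        if ch == "*":
            codes[i] = _STOP_CODE
        else:
            codes[i] = AA_INDEX.get(ch.upper(), _X_CODE)
    return codes


@njit(cache=True)
def _viterbi_kernel(mesc, iesc, ltr, entry):  # pragma: no cover - numba
    n, L = mesc.shape
    VM = np.full((n, L), NEG_INF)
    VI = np.full((n, L), NEG_INF)
    VD = np.full((n, L), NEG_INF)
    PM = np.zeros((n, L), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    PI = np.zeros((n, L), dtype=np.int8)  # 1 M, 2 I
    PD = np.zeros((n, L), dtype=np.int8)  # 1 M, 3 D
    best = NEG_INF
    bi = -1
    bk = -1
    for i in range(n):
        for k in range(L):
            # match state M_{k+1}
            b = entry
            p = np.int8(0)
            if i > 0 and k > 0:
                c = VM[i - 1, k - 1] + ltr[k - 1, 0]
                if c > b:
                    b = c
                    p = np.int8(1)
                c = VI[i - 1, k - 1] + ltr[k - 1, 3]
                if c > b:
                    b = c
                    p = np.int8(2)
                c = VD[i - 1, k - 1] + ltr[k - 1, 5]
                if c > b:
                    b = c
                    p = np.int8(3)
            VM[i, k] = mesc[i, k] + b
            PM[i, k] = p
            if VM[i, k] > best:
                best = VM[i, k]
                bi = i
                bk = k
            # insert state I_{k+1} (absent after the last node)
            if k < L - 1 and i > 0:
                bI = VM[i - 1, k] + ltr[k, 1]
                pI = np.int8(1)
                c = VI[i - 1, k] + ltr[k, 4]
                if c > bI:
                    bI = c
                    pI = np.int8(2)
                VI[i, k] = iesc[i, k] + bI
                PI[i, k] = pI
            # delete state D_{k+1}, fed within the same row
            if k > 0:
                bD = VM[i, k - 1] + ltr[k - 1, 2]
                pD = np.int8(1)
                c = VD[i, k - 1] + ltr[k - 1, 6]
                if c > bD:
                    bD = c
                    pD = np.int8(3)
                VD[i, k] = bD
                PD[i, k] = pD
    return best, bi, bk, PM, PI, PD


def _emission_rows(lodds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    L = lodds.shape[0]
    out = np.zeros((n, L))
    std = codes < 20
    if std.any():
        out[std] = lodds[:, codes[std]].T
    out[codes == _STOP_CODE] = NEG_INF
    return out


def viterbi_score(hmm: ProfileHMM, peptide: str) -> float:
    """Raw best local Viterbi score in bits (may be <= 0 or -inf)."""
    if not peptide:
        raise ValueError("empty peptide")
    lodds_m, lodds_i, ltr, entry = hmm._tables()
    codes = encode_peptide(peptide)
    mesc = _emission_rows(lodds_m, codes)
    iesc = _emission_rows(lodds_i, codes)
    best, _, _, _, _, _ = _viterbi_kernel(mesc, iesc, ltr, entry)
    return float(best)


def viterbi_align(hmm: ProfileHMM, peptide: str, read_id: str = "", end: int = 1,
                  frame: int = 1) -> DomainHit | None:
    """Best local alignment of ``peptide`` to ``hmm``; None if score <= 0."""
    if not peptide:
        raise ValueError("empty peptide")
    lodds_m, lodds_i, ltr, entry = hmm._tables()
    codes = encode_peptide(peptide)
    mesc = _emission_rows(lodds_m, codes)
    iesc = _emission_rows(lodds_i, codes)
    best, bi, bk, PM, PI, PD = _viterbi_kernel(mesc, iesc, ltr, entry)
    if not best > 0.0:
        return None
    # traceback from the best-scoring match cell to the entry point
    i, k, state = bi, bk, "M"
    while True:
        if state == "M":
            p = PM[i, k]
            if p == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(p)]
            i -= 1
            k -= 1
        elif state == "I":
            p = PI[i, k]
            state = "M" if p == 1 else "I"
            i -= 1
        else:  # D
            p = PD[i, k]
            state = "M" if p == 1 else "D"
            k -= 1
    return DomainHit(
        read_id=read_id, end=end, frame=frame, family_id=hmm.family_id,
        model_start=k + 1, model_end=bk + 1,
        seq_start=i + 1, seq_end=bi + 1,
        score=float(best),
    )


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def evalue(hmm: ProfileHMM, score: float, database_size: float) -> float:
    """Gumbel E-value for a bit score in a search of ``database_size``
    comparisons: ``E = N * exp(-lambda * (score - mu))``, clipped to
    [0, N].  Strictly decreasing in ``score`` before clipping.
    """
    if hmm.gumbel_mu is None or hmm.gumbel_lambda is None:
        raise ValueError(
            f"family {hmm.family_id!r} has no Gumbel parameters; run "
            "calibrate_gumbel() or load a .hmm with a STATS LOCAL VITERBI line"
        )
    e = database_size * math.exp(-hmm.gumbel_lambda * (score - hmm.gumbel_mu))
    return min(max(e, 0.0), database_size)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda = 1/scale)."""
    scores = np.asarray(scores, dtype=np.float64)
    if np.std(scores) == 0.0:
        raise ValueError("degenerate score distribution (zero variance)")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def sample_background_peptides(background: np.ndarray, n: int, length: int,
                               rng: np.random.Generator) -> list[str]:
    letters = np.array(list(AMINO_ALPHABET))
    draws = rng.choice(20, size=(n, length), p=background)
    return ["".join(letters[row]) for row in draws]


def calibrate_gumbel(hmm: ProfileHMM, n_random: int = 500, seed: int = 0,
                     peptide_length: int = 25) -> tuple[float, float]:
    """Fit the score null by scoring random background peptides.

    Scores ``n_random`` i.i.d. background peptides of the typical
    read-peptide length with the full Viterbi aligner and fits a Gumbel
    by maximum likelihood.  Deterministic given ``seed``.  Sets and
    returns ``(gumbel_mu, gumbel_lambda)`` on the model.
    """
    if n_random < 200:
        raise ValueError("n_random must be at least 200 for a stable fit")
    rng = np.random.default_rng(seed)
    peptides = sample_background_peptides(hmm.background, n_random, peptide_length, rng)
    scores = np.array([viterbi_score(hmm, p) for p in peptides])
    mu, lam = fit_gumbel(scores)
    hmm.gumbel_mu, hmm.gumbel_lambda = mu, lam
    return mu, lam
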