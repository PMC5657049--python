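"""Three-step paired-end homology search pipeline.

Step 1 scans every read end (six-frame translated) against every
family model and keeps, per end and family, the best-frame hit passing
the E-value cutoff (default 10 — deliberately permissive, since short
reads rarely reach curated per-family thresholds).  Read pairs aligned
uniquely to one family anchor the fragment-length distribution.  Step
2 rescues each pair with exactly one aligned end: the other end is
re-aligned by full Viterbi against only the families its mate hit, and
any positive-bit-score alignment is admitted with no E-value gate —
maximum sensitivity, with specificity deferred to step 3.  Step 3
scores every family with hits on both ends by the fragment-aware
posterior and retains candidates by the p_max*tau rule.

Pairs are classified as case 1 (one end aligned), case 2 (both ends
aligned to a common family) or case 3 (neither end aligned).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fragment_model, posterior
from .fragment_model import FragmentLengthDistribution
from .io_formats import ReadPair, SeedAlignment
from .posterior import CandidatePair, ScoringConfig, DEFAULT_T, DEFAULT_TAU
from .profile_hmm import DomainHit, ProfileHMM, calibrate_gumbel, evalue, viterbi_align
from .translate import six_frame_translate

log = logging.getLogger("shortpair")


@dataclass(slots=True)
class FamilyModel:
    """A family's profile plus the seed MSA backing coordinate conversion."""
    hmm: ProfileHMM
    msa: SeedAlignment | None = None


@dataclass(slots=True)
class RunConfig:
    evalue_cutoff: float = 10.0
    tau: float = DEFAULT_TAU
    T: float = DEFAULT_T
    smoothing: float = 1.0
    fragment_clip: tuple[int, int] | None = None  # amino acids
    database_size: float | None = None  # default: number of framed peptides
    calibration_n: int = 500
    seed: int = 0
    frag_dist: FragmentLengthDistribution | None = None

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("E-value cutoff must be positive")


@dataclass(slots=True)
class PairResult:
    read_id: str
    case: int
    retained: list  # CandidatePair (case 2) or DomainHit (case 1)


HitTable = dict[str, dict[int, list[DomainHit]]]  # read id -> end -> hits


def _best_frame_hits(pair_id: str, end: int, seq: str, models: dict[str, FamilyModel]
                     ) -> list[DomainHit]:
    """Best-scoring frame per family for one read end (no E-value gate)."""
    peptides = six_frame_translate(seq, pair_id, end)
    best: dict[str, DomainHit] = {}
    for fp in peptides:
        if not fp.peptide:
            continue
        for fid, fam in models.items():
            hit = viterbi_align(fam.hmm, fp.peptide, pair_id, end, fp.frame)
            if hit is None:
                continue
            prev = best.get(fid)
            if prev is None or hit.score > prev.score:
                best[fid] = hit
    return [best[fid] for fid in sorted(best)]


def _ensure_calibrated(models: dict[str, FamilyModel], cfg: RunConfig,
                       read_length_nt: int) -> None:
    pep_len = max(read_length_nt // 3, 10)
    for fid in sorted(models):
        hmm = models[fid].hmm
        if hmm.gumbel_mu is None or hmm.gumbel_lambda is None:
            calibrate_gumbel(hmm, n_random=cfg.calibration_n, seed=cfg.seed,
                             peptide_length=pep_len)


def step1_scan(pairs: list[ReadPair], models: dict[str, FamilyModel],
               cfg: RunConfig) -> HitTable:
    """Scan all ends against all families; keep hits with E <= cutoff."""
    if not models:
        raise ValueError("no family models loaded")
    if not pairs:
        return {}
    _ensure_calibrated(models, cfg, len(pairs[0].end1))
    N = cfg.database_size if cfg.database_size is not None else 12.0 * len(pairs)
    hits: HitTable = {}
    for pair in pairs:
        per_end: dict[int, list[DomainHit]] = {}
        for end, seq in ((1, pair.end1), (2, pair.end2)):
            kept = []
            for hit in _best_frame_hits(pair.id, end, seq, models):
                hit.evalue = evalue(models[hit.family_id].hmm, hit.score, N)
                if hit.evalue <= cfg.evalue_cutoff:
                    kept.append(hit)
            per_end[end] = kept
        hits[pair.id] = per_end
    log.info("step1: %d pairs scanned, %d ends with hits", len(pairs),
             sum(1 for e in hits.values() for h in e.values() if h))
    return hits


def apply_evalue_cutoff(hits: list[DomainHit], cfg: RunConfig) -> HitTable:
    """Group externally computed per-end hits (e.g. domtblout) and apply
    the step-1 E-value cutoff, one best hit per (end, family)."""
    table: HitTable = {}
    for h in hits:
        if h.evalue > cfg.evalue_cutoff:
            continue
        per_end = table.setdefault(h.read_id, {1: [], 2: []})
        bucket = per_end.setdefault(h.end, [])
        for i, prev in enumerate(bucket):
            if prev.family_id == h.family_id:
                if h.score > prev.score:
                    bucket[i] = h
                break
        else:
            bucket.append(h)
    return table


def step2_rescue(pairs: list[ReadPair], hits: HitTable,
                 models: dict[str, FamilyModel], cfg: RunConfig) -> HitTable:
    """Rescue the unaligned mate of one-end pairs.

    The missing end's six frames are aligned by full Viterbi against
    only the families hit by the aligned end; any positive-score
    alignment is admitted (no E-value gate) and flagged ``rescued``.
    Returns a new hit table; the input is not modified.
    """
    out: HitTable = {rid: {e: list(hs) for e, hs in ends.items()}
                     for rid, ends in hits.items()}
    by_id = {p.id: p for p in pairs}
    n_rescued = 0
    for rid, ends in out.items():
        have1, have2 = bool(ends.get(1)), bool(ends.get(2))
        if have1 == have2:
            continue  # case 2 or case 3: nothing to rescue
        aligned_end = 1 if have1 else 2
        missing_end = 2 if have1 else 1
        pair = by_id[rid]
        seq = pair.end1 if missing_end == 1 else pair.end2
        anchor_families = sorted({h.family_id for h in ends[aligned_end]})
        anchor_models = {fid: models[fid] for fid in anchor_families if fid in models}
        rescued = _best_frame_hits(rid, missing_end, seq, anchor_models)
        for h in rescued:
            h.provenance = "rescued"
        if rescued:
            n_rescued += 1
            ends[missing_end] = rescued
    log.info("step2: %d pairs rescued", n_rescued)
    return out


def _candidates_for_pair(rid: str, ends: dict[int, list[DomainHit]],
                         models: dict[str, FamilyModel]) -> list[CandidatePair]:
    by_fam1 = {h.family_id: h for h in ends.get(1, [])}
    by_fam2 = {h.family_id: h for h in ends.get(2, [])}
    cands = []
    for fid in sorted(set(by_fam1) & set(by_fam2)):
        fam = models[fid]
        if fam.msa is None:
            raise ValueError(f"family {fid!r}: seed MSA required for fragment lengths")
        try:
            flen = fragment_model.estimate_fragment_length(
                fam.msa, fam.hmm.map_to_column, by_fam1[fid], by_fam2[fid])
        except ValueError:
            continue  # no seed anchors the span: unusable candidate
        cands.append(CandidatePair(rid, fid, by_fam1[fid], by_fam2[fid], flen))
    return cands


def step3_rank(pairs: list[ReadPair], hits: HitTable,
               dist: FragmentLengthDistribution, models: dict[str, FamilyModel],
               cfg: RunConfig) -> list[PairResult]:
    """Posterior-score candidate families and classify pairs, in input order."""
    if dist is None:
        raise ValueError("fragment-length distribution missing")
    scfg = ScoringConfig(T=cfg.T, tau=cfg.tau)
    results = []
    for pair in pairs:
        ends = hits.get(pair.id, {})
        cands = _candidates_for_pair(pair.id, ends, models)
        if cands:
            posterior.score_candidates(cands, dist, scfg)
            retained = posterior.filter_by_tau(cands, scfg.tau)
            results.append(PairResult(pair.id, 2, retained))
        elif ends.get(1) or ends.get(2):
            single = sorted((ends.get(1, []) + ends.get(2, [])),
                            key=lambda h: (h.evalue if np.isfinite(h.evalue) else np.inf,
                                           h.family_id))
            results.append(PairResult(pair.id, 1, single))
        else:
            results.append(PairResult(pair.id, 3, []))
    return results


@dataclass(slots=True)
class RunSummary:
    n_pairs: int
    case_counts: dict[int, int]
    case_counts_step1: dict[int, int]
    abundance: dict[str, int]
    fragdist: FragmentLengthDistribution | None

    def case_percent(self, case: int, step1: bool = False) -> float:
        counts = self.case_counts_step1 if step1 else self.case_counts
        return 100.0 * counts.get(case, 0) / self.n_pairs if self.n_pairs else 0.0


def classify_cases(hits: HitTable, pairs: list[ReadPair]) -> dict[int, int]:
    """Case tally from a hit table alone (family shared by both ends ->
    case 2; any hit -> case 1; none -> case 3)."""
    counts = {1: 0, 2: 0, 3: 0}
    for pair in pairs:
        ends = hits.get(pair.id, {})
        f1 = {h.family_id for h in ends.get(1, [])}
        f2 = {h.family_id for h in ends.get(2, [])}
        if f1 & f2:
            counts[2] += 1
        elif f1 or f2:
            counts[1] += 1
        else:
            counts[3] += 1
    return counts


def run_short_pair(pairs: list[ReadPair], models: dict[str, FamilyModel],
                   cfg: RunConfig) -> tuple[list[PairResult], RunSummary]:
    """Execute scan -> distribution -> rescue -> rank.

    The fragment-length distribution is built from step-1 uniquely
    aligned pairs before rescue; rescue only adds hits, so the case-2
    share can only grow between the step-1 tally and the final one.
    """
    if not pairs:
        log.warning("no read pairs supplied; empty result")
        return [], RunSummary(0, {1: 0, 2: 0, 3: 0}, {1: 0, 2: 0, 3: 0}, {}, None)
    hits1 = step1_scan(pairs, models, cfg)
    step1_cases = classify_cases(hits1, pairs)

    dist = cfg.frag_dist
    if dist is None:
        unique = fragment_model.collect_unique_pairs(hits1)
        lengths = []
        for h1, h2 in unique:
            fam = models[h1.family_id]
            try:
                lengths.append(fragment_model.estimate_fragment_length(
                    fam.msa, fam.hmm.map_to_column, h1, h2))
            except ValueError:
                continue
        if not lengths:
            raise ValueError(
                "no uniquely aligned pairs to build the fragment distribution; "
                "supply one with RunConfig.frag_dist")
        dist = fragment_model.build_distribution(
            lengths, smoothing=cfg.smoothing, clip_range=cfg.fragment_clip)
        log.info("fragment distribution from %d unique pairs, support %d-%d aa",
                 dist.n_observations, dist.support_min, dist.support_max)

    hits2 = step2_rescue(pairs, hits1, models, cfg)
    results = step3_rank(pairs, hits2, dist, models, cfg)

    case_counts = {c: 0 for c in (1, 2, 3)}
    abundance: dict[str, int] = {}
    for r in results:
        case_counts[r.case] += 1
        if r.case == 2:
            for cand in r.retained:
                abundance[cand.family_id] = abundance.get(cand.family_id, 0) + 1
    summary = RunSummary(len(pairs), case_counts, step1_cases, abundance, dist)
    return results, summary


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _span(a: int, b: int) -> str:
    return f"{a}-{b}"


def write_pairs_tsv(results: list[PairResult], path: str | Path) -> None:
    cols = ("read_id", "case", "family_id", "end1_score_bits", "end2_score_bits",
            "end1_model_span", "end2_model_span", "fragment_len_aa", "posterior",
            "provenance")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            if r.case == 3:
                fh.write(f"{r.read_id}\t3\tNA\tNA\tNA\tNA\tNA\tNA\tNA\tNA\n")
            elif r.case == 2:
                for c in r.retained:
                    prov = f"{c.hit1.provenance},{c.hit2.provenance}"
                    fh.write(f"{r.read_id}\t2\t{c.family_id}\t{c.hit1.score:.4f}\t"
                             f"{c.hit2.score:.4f}\t{_span(c.hit1.model_start, c.hit1.model_end)}\t"
                             f"{_span(c.hit2.model_start, c.hit2.model_end)}\t"
                             f"{c.fragment_length}\t{c.posterior:.6g}\t{prov}\n")
            else:
                for h in r.retained:
                    s1 = f"{h.score:.4f}" if h.end == 1 else "NA"
                    s2 = f"{h.score:.4f}" if h.end == 2 else "NA"
                    sp1 = _span(h.model_start, h.model_end) if h.end == 1 else "NA"
                    sp2 = _span(h.model_start, h.model_end) if h.end == 2 else "NA"
                    fh.write(f"{r.read_id}\t1\t{h.family_id}\t{s1}\t{s2}\t{sp1}\t{sp2}\t"
                             f"NA\tNA\t{h.provenance}\n")


def write_abundance_tsv(summary: RunSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tread_pair_count\n")
        for fid in sorted(summary.abundance):
            fh.write(f"{fid}\t{summary.abundance[fid]}\n")


def retained_families(results: list[PairResult], include_case1: bool = False
                      ) -> dict[str, set[str]]:
    """Predicted family set per read pair (case-2 retained candidates;
    optionally case-1 single-end hits too)."""
    out: dict[str, set[str]] = {}
    for r in results:
        if r.case == 2:
            out[r.read_id] = {c.family_id for c in r.retained}
        elif r.case == 1 and include_case1:
            out[r.read_id] = {h.family_id for h in r.retained}
        else:
            out[r.read_id] = set()
    return out
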